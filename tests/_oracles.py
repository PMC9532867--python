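"""Shared hand-built oracle tables and small fixtures used by several test modules."""

import pandas as pd

from sspmine.expression import Contrast, ContrastDesign, ExpressionMatrix

#: Hand-built CEP/PIP oracle: C-terminus -> expected family.  The spacer
#: between SGPS and the nearest following GxGH decides: one residue -> CEP
#: (proline in canonical members), two residues -> PIP, anything else neither.
CEP_PIP_ORACLE = [
    ("QQQSGPSPGVGHA", "CEP"),     # spacer P
    ("NNESGPSPGSGH", "CEP"),      # spacer P, different GxGH
    ("DDRSGPSAGTGH", "CEP"),      # non-P single spacer (warns)
    ("KKTSGPSTGHGH", "CEP"),      # non-P single spacer
    ("QQQSGPSKRGSGH", "PIP"),     # spacer KR
    ("EEGSGPSNNGAGH", "PIP"),     # spacer NN
    ("RRHSGPSQEGGGH", "PIP"),     # spacer QE
    ("TTPSGPSHHGPGH", "PIP"),     # spacer HH
    ("QQQSGPSGVGH", None),        # spacer length 0
    ("EEESGPSGAGH", None),        # spacer length 0
    ("QQQSGPSNNNGAGH", None),     # spacer length 3
    ("DDDSGPSKRQEGSGH", None),    # spacer length 4
    ("QQQSGPSKRQENGVGH", None),   # spacer length 5
    ("QQQQQQQQGVGH", None),       # no SGPS
    ("QQQSGPSQQQQQQ", None),      # no GxGH after SGPS
    ("GVGHSGPSQQQQ", None),       # GxGH only before SGPS
    ("SGPSPGVGH", "CEP"),         # motif right at the start
    ("SGPSQQGGGH", "PIP"),
    ("QQSGPSSGPSPGVGH", None),    # anchors at the first SGPS: spacer SGPSP
    ("DDDDDDDDDDDD", None),       # nothing at all
]

#: Three-contrast design sharing a leaf control, used by expression tests.
SMALL_DESIGN = ContrastDesign((
    Contrast("DS", "CK", "drought", "6h"),
    Contrast("HS", "CK", "heat", "6h"),
    Contrast("SS", "CK_R", "salt", "6h"),
))


def make_matrix(rows, columns=("CK", "DS", "HS", "CK_R", "SS")):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))
    return ExpressionMatrix(df)


def category_of(calls, gene, stress):
    return next(
        c.category for c in calls
        if c.gene_id == gene and c.contrast.stress_condition == stress
    )
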