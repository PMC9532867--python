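"""Seeded synthetic proteomes and TPM matrices with planted ground truth.

Every generated sequence belongs to exactly one category and is constructed
so that the secretion funnel treats it as designed:

* ``planted_ssp`` — a precursor with a built signal peptide (charged
  n-region, eight-residue hydrophobic core, A-x-A cleavage site) that the
  built-in heuristic recognises by construction, a hydrophilic variable
  middle, and a family consensus domain at the C-terminus;
* ``tm_decoy`` — same scaffold plus a 21-leucine transmembrane stretch in
  the mature region (rejected at the transmembrane stage);
* ``kdel_decoy`` — same scaffold ending in an ER-retention tetrapeptide
  (rejected at the ER stage);
* ``truncated_decoy`` — same scaffold with an internal stop, a missing
  initiator methionine, or an ambiguous X (rejected at the truncation
  stage);
* ``oversize_decoy`` — longer than the precursor size limit (rejected at the
  length stage);
* ``background`` — a non-secreted protein: i.i.d. residues at
  plant-proteome-like frequencies, resampled until the built-in heuristic
  reports no signal peptide, so the category semantics hold exactly
  (rejected at the signal-peptide stage).

Because each category dies at its designed stage, per-stage survivor counts
have a closed form (:func:`funnel_expectation`) and planted-SSP recall and
precision of the built-in route are 1.0 on clean plants; ``hard_mode``
weakens a fraction of planted h-regions for threshold-sensitivity testing.

The expression generator mirrors a drought/heat/combined (1 h, 6 h) plus
salt (6-48 h) contrast design: log-normal baselines (median 5 TPM), planted
fold-changes in the designated contrasts, planted "specific" genes with
control below and stress above the meaningful-TPM level in every replicate
by construction, and multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .expression import Contrast, ContrastDesign, ExpressionMatrix
from .families import FamilyRegistry, load_family_registry
from .proteome import ProteinRecord
from .secretion import (
    SignalPeptideCall,
    TopologyCall,
    detect_tm_builtin,
    predict_signal_peptide_builtin,
)

CATEGORIES = (
    "planted_ssp",
    "tm_decoy",
    "kdel_decoy",
    "truncated_decoy",
    "oversize_decoy",
    "background",
)

#: Hydrophilic alphabet for variable regions: never hydrophobic enough for a
#: transmembrane window, no cysteine, no tyrosine (avoids spurious CRP or
#: DY-motif signals in planted sequences).
VARIABLE_ALPHABET = "DENQSTGPKRH"
HCORE_ALPHABET = "LVIF"
SPACER_ALPHABET = "NQEDHKR"

#: Approximate plant proteome residue frequencies for background sequences.
PLANT_FREQUENCIES = {
    "A": 0.063, "R": 0.054, "N": 0.045, "D": 0.054, "C": 0.018, "Q": 0.035,
    "E": 0.062, "G": 0.064, "H": 0.023, "I": 0.053, "L": 0.096, "K": 0.064,
    "M": 0.024, "F": 0.044, "P": 0.048, "S": 0.090, "T": 0.048, "W": 0.012,
    "Y": 0.029, "V": 0.069,
}


@dataclass(frozen=True)
class ProteomeCounts:
    """Sequences per category; the default mix is 100 sequences."""

    planted_ssp: int = 50
    tm_decoy: int = 10
    kdel_decoy: int = 5
    truncated_decoy: int = 5
    oversize_decoy: int = 0
    background: int = 30

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            if getattr(self, cat) < 0:
                raise ValueError(f"count for {cat} must be >= 0")

    @property
    def total(self) -> int:
        return sum(getattr(self, cat) for cat in CATEGORIES)


@dataclass(frozen=True)
class SequenceTruth:
    gene_id: str
    category: str
    family: Optional[str] = None
    sp_cleavage_after: Optional[int] = None
    domain_span: Optional[Tuple[int, int]] = None  # proprotein, 1-based inclusive

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "planted_ssp" and (
            self.family is None or self.sp_cleavage_after is None
        ):
            raise ValueError("a planted SSP requires a family and a cleavage site")


@dataclass
class SyntheticProteome:
    records: List[ProteinRecord]
    truth: Dict[str, SequenceTruth]  # keyed by gene_id
    sp_calls: Dict[str, SignalPeptideCall]  # truth-fed predictor map
    tm_calls: Dict[str, TopologyCall]


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _build_signal_peptide(
    rng: np.random.Generator, hard: bool = False
) -> Tuple[str, int]:
    """Signal peptide satisfying the built-in heuristic by construction.

    Layout: M + K (n-region), eight hydrophobic residues (h-region), a 2-6
    residue non-small spacer, then A-x-A so the (-3, -1) rule fires exactly
    at the intended cleavage site.  ``hard`` weakens the h-region to 5/8
    hydrophobic residues (below the heuristic's 6/8 requirement).
    """
    core = list(_draw(rng, HCORE_ALPHABET, 8))
    if hard:
        for pos in rng.choice(8, size=3, replace=False):
            core[pos] = "N"
    gap = int(rng.integers(2, 7))
    spacer = _draw(rng, SPACER_ALPHABET, gap)
    x = SPACER_ALPHABET[rng.integers(0, len(SPACER_ALPHABET))]
    sp = "MK" + "".join(core) + spacer + "A" + x + "A"
    return sp, len(sp)  # cleavage after the final A


def _variable_region(rng: np.random.Generator, n: int) -> str:
    return _draw(rng, VARIABLE_ALPHABET, n)


def _background_sequence(
    rng: np.random.Generator, config: PipelineConfig
) -> str:
    residues = list(PLANT_FREQUENCIES)
    probs = np.array(list(PLANT_FREQUENCIES.values()))
    probs = probs / probs.sum()
    while True:
        n = int(rng.integers(60, 241))
        body = "".join(rng.choice(residues, size=n - 1, p=probs))
        seq = "M" + body
        call = predict_signal_peptide_builtin(seq, config)
        if not call.has_sp:
            return seq


def generate_proteome(
    counts: ProteomeCounts = ProteomeCounts(),
    family_mix: Optional[Sequence[str]] = None,
    seed: int = 0,
    registry: Optional[FamilyRegistry] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    hard_mode_fraction: float = 0.0,
) -> SyntheticProteome:
    """Generate a seeded proteome with per-sequence ground truth.

    ``family_mix`` lists the families planted (cycled over the planted
    SSPs); the default cycles every registry family carrying a motif.  The
    returned truth-fed predictor maps reproduce the planted signal-peptide
    and topology labels exactly.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    if registry is None:
        registry = load_family_registry(config=config)
    if family_mix is None:
        family_mix = [e.name for e in registry if e.motif is not None]
    for name in family_mix:
        if name not in registry:
            raise ValueError(f"family mix references unknown family {name!r}")
        if registry[name].motif is None or registry[name].motif.kind != "consensus":
            raise ValueError(f"family {name!r} has no plantable consensus motif")

    records: List[ProteinRecord] = []
    truth: Dict[str, SequenceTruth] = {}
    sp_calls: Dict[str, SignalPeptideCall] = {}
    tm_calls: Dict[str, TopologyCall] = {}
    serial = 0

    def new_ids() -> Tuple[str, str]:
        nonlocal serial
        serial += 1
        gene = f"SYNG{serial:04d}"
        return gene, f"{gene}.1"

    def add(seq: str, tr: SequenceTruth, has_sp: bool, cleavage: Optional[int],
            has_tm: bool) -> None:
        gene, transcript = tr.gene_id, tr.gene_id + ".1"
        records.append(ProteinRecord(gene, transcript, seq))
        truth[gene] = tr
        sp_calls[gene] = (
            SignalPeptideCall(True, cleavage_after=cleavage, score=1.0,
                              source="external-file")
            if has_sp
            else SignalPeptideCall(False, source="external-file")
        )
        tm_calls[gene] = TopologyCall(has_tm, source="external-file")

    # planted SSPs
    for i in range(counts.planted_ssp):
        gene, _ = new_ids()
        family = family_mix[i % len(family_mix)]
        consensus = registry[family].motif.consensus
        hard = hard_mode_fraction > 0 and rng.random() < hard_mode_fraction
        sp, cleavage = _build_signal_peptide(rng, hard=hard)
        var = _variable_region(rng, int(rng.integers(30, 121)))
        seq = sp + var + consensus
        assert len(seq) <= config.max_length
        if not hard:  # construction guarantees, checked cheaply
            assert predict_signal_peptide_builtin(seq, config).cleavage_after == cleavage
            assert not detect_tm_builtin(seq[cleavage:], config).has_tm
        span = (len(seq) - len(consensus) + 1, len(seq))
        add(seq, SequenceTruth(gene, "planted_ssp", family, cleavage, span),
            True, cleavage, False)

    # transmembrane decoys
    for _ in range(counts.tm_decoy):
        gene, _ = new_ids()
        sp, cleavage = _build_signal_peptide(rng)
        seq = (sp + _variable_region(rng, int(rng.integers(10, 41)))
               + "L" * 21 + _variable_region(rng, int(rng.integers(10, 41))))
        add(seq, SequenceTruth(gene, "tm_decoy", sp_cleavage_after=cleavage),
            True, cleavage, True)

    # ER-retention decoys
    kdel_tails = sorted(config.kdel_motifs)
    for i in range(counts.kdel_decoy):
        gene, _ = new_ids()
        sp, cleavage = _build_signal_peptide(rng)
        seq = sp + _variable_region(rng, int(rng.integers(30, 121))) + kdel_tails[i % len(kdel_tails)]
        add(seq, SequenceTruth(gene, "kdel_decoy", sp_cleavage_after=cleavage),
            True, cleavage, False)

    # truncated decoys: rotate the three defect kinds
    for i in range(counts.truncated_decoy):
        gene, _ = new_ids()
        sp, cleavage = _build_signal_peptide(rng)
        var = list(_variable_region(rng, int(rng.integers(30, 121))))
        kind = i % 3
        if kind == 0:
            var[len(var) // 2] = "*"
            seq = sp + "".join(var)
        elif kind == 1:
            seq = "K" + sp[1:] + "".join(var)
        else:
            var[len(var) // 2] = "X"
            seq = sp + "".join(var)
        add(seq, SequenceTruth(gene, "truncated_decoy", sp_cleavage_after=cleavage),
            True, cleavage, False)

    # oversize decoys
    for _ in range(counts.oversize_decoy):
        gene, _ = new_ids()
        sp, cleavage = _build_signal_peptide(rng)
        seq = sp + _variable_region(rng, config.max_length - len(sp) + int(rng.integers(1, 51)))
        add(seq, SequenceTruth(gene, "oversize_decoy", sp_cleavage_after=cleavage),
            True, cleavage, False)

    # non-secreted background
    for _ in range(counts.background):
        gene, _ = new_ids()
        seq = _background_sequence(rng, config)
        add(seq, SequenceTruth(gene, "background"), False, None, False)

    return SyntheticProteome(records, truth, sp_calls, tm_calls)


def funnel_expectation(truth: Mapping[str, SequenceTruth]) -> Dict[str, int]:
    """Closed-form expected survivor counts per funnel stage.

    Each category dies exactly at its designed stage, so the survivors after
    each stage follow by subtraction.
    """
    n = {cat: sum(t.category == cat for t in truth.values()) for cat in CATEGORIES}
    total = len(truth)
    after_length = total - n["oversize_decoy"]
    after_sp = after_length - n["background"]
    after_tm = after_sp - n["tm_decoy"]
    after_er = after_tm - n["kdel_decoy"]
    after_trunc = after_er - n["truncated_decoy"]
    return {
        "input": total,
        "length": after_length,
        "signal_peptide": after_sp,
        "transmembrane": after_tm,
        "er_retention": after_er,
        "truncation": after_trunc,
    }


def make_multidomain_record(
    families: Sequence[str],
    gene_id: str = "SYNMD0001",
    min_gap: int = 2,
    seed: int = 0,
    registry: Optional[FamilyRegistry] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Tuple[ProteinRecord, SignalPeptideCall, List[Tuple[str, int, int]]]:
    """Build a precursor carrying the given domain consensus sequences in order.

    Returns the record, its (truth) signal-peptide call, and the planted
    (family, start, end) spans in proprotein coordinates.  Consecutive
    domains are separated by ``max(min_gap, 1)`` hydrophilic residues.
    """
    if registry is None:
        registry = load_family_registry(config=config)
    rng = np.random.default_rng(seed)
    sp, cleavage = _build_signal_peptide(rng)
    gap = max(min_gap, 1)
    parts = [sp, _variable_region(rng, 6)]
    spans: List[Tuple[str, int, int]] = []
    pos = sum(len(p) for p in parts)
    for i, family in enumerate(families):
        consensus = registry[family].motif.consensus
        spans.append((family, pos + 1, pos + len(consensus)))
        parts.append(consensus)
        pos += len(consensus)
        if i < len(families) - 1:
            parts.append(_variable_region(rng, gap))
            pos += gap
    seq = "".join(parts)
    if len(seq) > config.max_length:
        raise ValueError("multi-domain construct exceeds the precursor size limit")
    record = ProteinRecord(gene_id, gene_id + ".1", seq)
    call = SignalPeptideCall(True, cleavage_after=cleavage, score=1.0,
                             source="external-file")
    return record, call, spans


# ---------------------------------------------------------------------------
# Expression


def default_design() -> ContrastDesign:
    """Drought/heat/combined (1 h, 6 h) leaf contrasts and salt (6-48 h) root
    contrasts, each stress against its matched control condition."""
    leaf = [
        ("DS_1h", "CK_L_1h", "drought", "1h"),
        ("DS_6h", "CK_L_6h", "drought", "6h"),
        ("HS_1h", "CK_L_1h", "heat", "1h"),
        ("HS_6h", "CK_L_6h", "heat", "6h"),
        ("DHS_1h", "CK_L_1h", "drought+heat", "1h"),
        ("DHS_6h", "CK_L_6h", "drought+heat", "6h"),
    ]
    root = [
        ("SS_6h", "CK_R_6h", "salt", "6h"),
        ("SS_12h", "CK_R_12h", "salt", "12h"),
        ("SS_24h", "CK_R_24h", "salt", "24h"),
        ("SS_48h", "CK_R_48h", "salt", "48h"),
    ]
    return ContrastDesign(tuple(Contrast(*args) for args in leaf + root))


@dataclass(frozen=True)
class PlantedEffect:
    """``n_genes`` planted with ``category`` in every contrast of the listed
    stress types (fold applies to the ratio category only)."""

    n_genes: int
    stress_types: Tuple[str, ...]
    category: str  # "upregulated" | "specific"

    def __post_init__(self) -> None:
        if self.category not in ("upregulated", "specific"):
            raise ValueError(f"unknown planted category {self.category!r}")


def default_expression_plan() -> List[PlantedEffect]:
    """Planted response structure: a core set responsive to all leaf
    stresses, per-type sets, and stress-switched-on ("specific") sets."""
    return [
        PlantedEffect(10, ("drought", "heat", "drought+heat"), "upregulated"),
        PlantedEffect(40, ("drought",), "upregulated"),
        PlantedEffect(30, ("heat",), "upregulated"),
        PlantedEffect(20, ("drought+heat",), "upregulated"),
        PlantedEffect(60, ("salt",), "upregulated"),
        PlantedEffect(15, ("drought",), "specific"),
        PlantedEffect(25, ("salt",), "specific"),
    ]


ExpressionTruth = Dict[str, Dict[str, Tuple[str, float]]]


def generate_expression(
    gene_ids: Sequence[str],
    design: Optional[ContrastDesign] = None,
    plan: Optional[Sequence[PlantedEffect]] = None,
    fold: float = 4.0,
    noise_sigma: float = 0.2,
    baseline_median: float = 5.0,
    baseline_sigma: float = 0.5,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Tuple[ExpressionMatrix, ExpressionTruth]:
    """Generate a TPM matrix with planted upregulation ground truth.

    Genes are assigned to the plan's effects in list order; remaining genes
    are nulls.  Baselines are log-normal with the given median; genes
    planted with a ratio effect have baselines redrawn to at least twice the
    meaningful-TPM level so the planted category survives the caller's
    branch order; "specific" genes are built with all cells below the
    meaningful level except the planted stress cells, and their planted
    control/stress cells are clamped below/above the meaningful level after
    noise so the construction holds in every replicate.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if design is None:
        design = default_design()
    if plan is None:
        plan = default_expression_plan()
    needed = sum(e.n_genes for e in plan)
    if needed > len(gene_ids):
        raise ValueError(f"plan needs {needed} genes, only {len(gene_ids)} provided")

    rng = np.random.default_rng(seed)
    meaningful = config.tpm_meaningful
    conditions: List[str] = []
    for c in design.contrasts:
        for cond in (c.control_condition, c.stress_condition):
            if cond not in conditions:
                conditions.append(cond)
    by_type: Dict[str, List[Contrast]] = {}
    for c in design.contrasts:
        by_type.setdefault(c.stress_type, []).append(c)

    truth: ExpressionTruth = {}
    gene_iter = iter(gene_ids)
    assignments: List[Tuple[str, Optional[PlantedEffect]]] = []
    for effect in plan:
        for t in effect.stress_types:
            if t not in by_type:
                raise ValueError(f"plan references stress type {t!r} not in design")
        for _ in range(effect.n_genes):
            assignments.append((next(gene_iter), effect))
    for gene in gene_iter:
        assignments.append((gene, None))

    values = np.empty((len(gene_ids), len(conditions)))
    col_index = {cond: j for j, cond in enumerate(conditions)}
    mu = np.log(baseline_median)

    for i, (gene, effect) in enumerate(assignments):
        planted: Dict[str, Tuple[str, float]] = {}
        if effect is not None and effect.category == "upregulated":
            base = float(np.exp(mu + baseline_sigma * rng.standard_normal()))
            while base < 2 * meaningful:
                base = float(np.exp(mu + baseline_sigma * rng.standard_normal()))
            row = np.full(len(conditions), base)
            for t in effect.stress_types:
                for contrast in by_type[t]:
                    row[col_index[contrast.stress_condition]] = base * fold
                    planted[contrast.contrast_id] = ("upregulated", fold)
        elif effect is not None:  # specific
            base = float(rng.uniform(0.1, 0.5))
            row = np.full(len(conditions), base)
            for t in effect.stress_types:
                for contrast in by_type[t]:
                    row[col_index[contrast.stress_condition]] = float(rng.uniform(2.0, 6.0))
                    planted[contrast.contrast_id] = ("specific", float("nan"))
        else:
            base = float(np.exp(mu + baseline_sigma * rng.standard_normal()))
            row = np.full(len(conditions), base)

        if noise_sigma > 0:
            row = row * np.exp(noise_sigma * rng.standard_normal(len(conditions)))

        # construction guarantee for planted specific genes
        if effect is not None and effect.category == "specific":
            for t in effect.stress_types:
                for contrast in by_type[t]:
                    jc = col_index[contrast.control_condition]
                    js = col_index[contrast.stress_condition]
                    row[jc] = min(row[jc], 0.95 * meaningful)
                    row[js] = max(row[js], 1.05 * meaningful)

        values[i] = row
        truth[gene] = planted

    df = pd.DataFrame(values, index=[g for g, _ in assignments], columns=conditions)
    df = df.loc[list(gene_ids)]  # original gene order
    return ExpressionMatrix(df), truth
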