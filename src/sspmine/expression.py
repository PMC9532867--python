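"""Threshold-based stress-upregulation calling on TPM matrices.

The caller reproduces a pure thresholding procedure: TPM >= 1 is
"meaningful" expression, a stress/control ratio >= 2 (both sides meaningful)
is an upregulation call, and a gene switching from < 1 TPM in control to
>= 1 TPM under a stress is "specifically upregulated".  No statistical test
or multiple-testing correction is involved; calls are a deterministic pure
function of the matrix, the contrast design, and the thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import TableParseError
from .families import FamilyAssignment

CATEGORY_UP = "upregulated"
CATEGORY_SPECIFIC = "specifically_upregulated"
CATEGORY_NOT = "not_called"


class ExpressionMatrix:
    """A genes x conditions TPM matrix backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise TableParseError(f"duplicate gene ids: {dupes}")
        if df.columns.duplicated().any():
            raise TableParseError("duplicate condition ids")
        if (df.values < 0).any():
            raise TableParseError("negative TPM values")
        self.df = df.astype(float)

    @property
    def genes(self) -> List[str]:
        return list(self.df.index)

    @property
    def conditions(self) -> List[str]:
        return list(self.df.columns)

    def value(self, gene: str, condition: str) -> float:
        return float(self.df.at[gene, condition])


def load_tpm(path) -> ExpressionMatrix:
    """Read a TSV of gene rows x condition columns into an ExpressionMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        non_numeric = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or non_numeric.any():
            bad = df.index[df[col].isna() | non_numeric][0]
            raise TableParseError(f"non-numeric TPM cell at gene {bad!r}, condition {col!r}")
        df[col] = pd.to_numeric(df[col])
    return ExpressionMatrix(df)


@dataclass(frozen=True)
class Contrast:
    stress_condition: str
    control_condition: str
    stress_type: str  # e.g. drought / heat / drought+heat / salt
    timepoint: str

    @property
    def contrast_id(self) -> str:
        return f"{self.stress_condition}_vs_{self.control_condition}"

    def __post_init__(self) -> None:
        if self.stress_condition == self.control_condition:
            raise ValueError("a control is never its own stress")


@dataclass(frozen=True)
class ContrastDesign:
    contrasts: Tuple[Contrast, ...]

    def validate(self, matrix: ExpressionMatrix) -> None:
        conditions = set(matrix.conditions)
        for contrast in self.contrasts:
            for cond in (contrast.stress_condition, contrast.control_condition):
                if cond not in conditions:
                    raise TableParseError(
                        f"design references condition {cond!r} absent from the matrix"
                    )

    @property
    def stress_types(self) -> List[str]:
        seen = []
        for c in self.contrasts:
            if c.stress_type not in seen:
                seen.append(c.stress_type)
        return seen


def read_design(path) -> ContrastDesign:
    """Load a contrast design TSV: stress_condition, control_condition, stress_type, timepoint."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"stress_condition", "control_condition", "stress_type", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"design table missing columns: {sorted(missing)}")
    return ContrastDesign(
        tuple(
            Contrast(r.stress_condition, r.control_condition, r.stress_type, r.timepoint)
            for r in df.itertuples(index=False)
        )
    )


@dataclass(frozen=True)
class UpregulationCall:
    gene_id: str
    contrast: Contrast
    category: str
    ratio: Optional[float] = None  # reported when control TPM is meaningful


def call_upregulation(
    matrix: ExpressionMatrix,
    design: ContrastDesign,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[UpregulationCall]:
    """Call per gene x contrast upregulation categories.

    Branch order matters: a gene with control TPM below the meaningful level
    and stress TPM at or above it is *specifically upregulated* (no ratio is
    reported — a ratio against sub-threshold expression is not meaningful);
    otherwise, with both sides meaningful and stress/control at or above the
    fold threshold, it is *upregulated*; anything else is not called.
    """
    design.validate(matrix)
    meaningful = config.tpm_meaningful
    calls: List[UpregulationCall] = []
    for contrast in design.contrasts:
        stress_col = matrix.df[contrast.stress_condition]
        control_col = matrix.df[contrast.control_condition]
        for gene in matrix.genes:
            stress = float(stress_col.at[gene])
            control = float(control_col.at[gene])
            if control < meaningful:
                category = CATEGORY_SPECIFIC if stress >= meaningful else CATEGORY_NOT
                ratio = None
            else:
                ratio = stress / control
                category = (
                    CATEGORY_UP
                    if stress >= meaningful and ratio >= config.fold_threshold
                    else CATEGORY_NOT
                )
            calls.append(UpregulationCall(gene, contrast, category, ratio))
    return calls


def _called(call: UpregulationCall) -> bool:
    return call.category in (CATEGORY_UP, CATEGORY_SPECIFIC)


def genes_by_group(
    calls: Iterable[UpregulationCall],
    grouping: Optional[Mapping[str, str]] = None,
) -> Dict[str, Set[str]]:
    """Genes called (either category) in at least one contrast of each group.

    ``grouping`` maps contrast id to a group label; by default each
    contrast's stress type is its group.
    """
    groups: Dict[str, Set[str]] = {}
    for call in calls:
        label = (
            grouping[call.contrast.contrast_id]
            if grouping is not None
            else call.contrast.stress_type
        )
        groups.setdefault(label, set())
        if _called(call):
            groups[label].add(call.gene_id)
    return groups


def stress_overlaps(
    calls: Iterable[UpregulationCall],
    grouping: Optional[Mapping[str, str]] = None,
) -> Dict[str, int]:
    """Exclusive-region counts over the power set of stress groups.

    Each gene called anywhere lands in exactly one region — the combination
    of groups it responds to — so the region counts sum to the number of
    genes called in any contrast.  Keys are "|"-joined sorted group labels
    (e.g. ``drought|salt``).
    """
    groups = genes_by_group(calls, grouping)
    labels = sorted(groups)
    membership: Dict[str, FrozenSet[str]] = {}
    for label in labels:
        for gene in groups[label]:
            membership[gene] = membership.get(gene, frozenset()) | {label}
    regions = {
        "|".join(sorted(combo)): 0
        for r in range(1, len(labels) + 1)
        for combo in itertools.combinations(labels, r)
    }
    for gene, combo in membership.items():
        regions["|".join(sorted(combo))] += 1
    return regions


def deduplicate_specific(
    calls: Iterable[UpregulationCall],
    stress_types: Optional[Mapping[str, str]] = None,
) -> Tuple[Dict[str, Set[str]], Set[str]]:
    """Partition responsive genes into per-stress-type exclusive sets plus a
    multi-stress set.

    A gene responsive (either call category) under exactly one stress type
    is exclusive to that type; a gene responsive under two or more types
    joins the multi-stress set.  ``stress_types`` optionally remaps contrast
    ids to types (default: the contrast's own stress type).
    """
    by_type = genes_by_group(calls, stress_types)
    exclusive: Dict[str, Set[str]] = {t: set() for t in by_type}
    multi: Set[str] = set()
    all_genes = set().union(*by_type.values()) if by_type else set()
    for gene in all_genes:
        member_of = [t for t, genes in by_type.items() if gene in genes]
        if len(member_of) == 1:
            exclusive[member_of[0]].add(gene)
        else:
            multi.add(gene)
    return exclusive, multi


@dataclass(frozen=True)
class FamilyResponse:
    family: str
    members: int
    responsive_members: int
    fraction: float
    majority_under_all_types: bool


def family_response_summary(
    calls: Sequence[UpregulationCall],
    assignments: Iterable[FamilyAssignment],
) -> List[FamilyResponse]:
    """Per-family response fractions with a strict-majority-under-every-type flag.

    A family's members are the assigned genes present in the matrix; a
    member is responsive when called in any contrast.  The flag requires a
    strict majority (> 1/2) of members responsive within *each* stress type
    separately.
    """
    family_of = {a.gene_id: a.family for a in assignments if a.family != "unclassified"}
    genes_in_calls = {c.gene_id for c in calls}
    types = []
    for c in calls:
        if c.contrast.stress_type not in types:
            types.append(c.contrast.stress_type)

    responsive_any: Dict[str, Set[str]] = {}
    responsive_by_type: Dict[str, Set[str]] = {t: set() for t in types}
    for call in calls:
        if _called(call):
            responsive_any.setdefault(call.gene_id, set())
            responsive_by_type[call.contrast.stress_type].add(call.gene_id)

    summaries = []
    families = sorted({f for g, f in family_of.items() if g in genes_in_calls})
    for family in families:
        members = [g for g in genes_in_calls if family_of.get(g) == family]
        responsive = [g for g in members if g in responsive_any]
        majority = bool(members) and all(
            sum(g in responsive_by_type[t] for g in members) * 2 > len(members)
            for t in types
        )
        summaries.append(
            FamilyResponse(
                family=family,
                members=len(members),
                responsive_members=len(responsive),
                fraction=len(responsive) / len(members) if members else 0.0,
                majority_under_all_types=majority,
            )
        )
    return summaries
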