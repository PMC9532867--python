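"""Known-family classification and cysteine-class profiling.

The packaged registry lists the 38 known plant SSP families with their
peptide class (PTM, CRP, non-Cys/non-PTM, functional precursor), mode of
action, reported wheat gene count, and a motif used to recognise the family's
conserved C-terminal domain.  Classification scores each motif over the
C-terminal window of the mature sequence; the CEP/PIP pair — which share the
SGPS and GxGH sub-motifs and differ only in the spacer between them — is
resolved by a dedicated spacer rule rather than by score.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import RegistryValidationError
from .motifs import MotifPattern, best_match
from .proteome import ProteinRecord
from .secretion import SignalPeptideCall, mature_sequence

PEPTIDE_CLASSES = ("PTM", "CRP", "NonCysNonPTM", "FunctionalPrecursor")
MODES_OF_ACTION = ("Signal", "Antimicrobial", "PeptidaseInhibitor", "Unknown")
EXPECTED_FAMILY_COUNT = 38


@dataclass(frozen=True)
class FamilyRegistryEntry:
    name: str
    peptide_class: str
    description: str
    mode_of_action: Tuple[str, ...]
    reported_wheat_count: int
    motif: Optional[MotifPattern]

    def __post_init__(self) -> None:
        if self.peptide_class not in PEPTIDE_CLASSES:
            raise RegistryValidationError(
                f"{self.name}: unknown peptide class {self.peptide_class!r}"
            )
        for mode in self.mode_of_action:
            if mode not in MODES_OF_ACTION:
                raise RegistryValidationError(
                    f"{self.name}: unknown mode of action {mode!r}"
                )
        if self.reported_wheat_count < 0:
            raise RegistryValidationError(f"{self.name}: negative gene count")


class FamilyRegistry:
    """Ordered collection of family entries with name lookup."""

    def __init__(self, entries: Sequence[FamilyRegistryEntry]):
        names = [e.name for e in entries]
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise RegistryValidationError(f"duplicate family names: {dupes}")
        self.entries: Tuple[FamilyRegistryEntry, ...] = tuple(entries)
        self._by_name = {e.name: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> FamilyRegistryEntry:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


def _parse_motif(raw, default_identity: float) -> Optional[MotifPattern]:
    if raw is None or raw == "none":
        return None
    if not isinstance(raw, Mapping):
        raise RegistryValidationError(f"malformed motif definition: {raw!r}")
    kind = raw.get("type")
    if kind == "consensus":
        return MotifPattern(
            "consensus",
            consensus=str(raw["sequence"]).upper(),
            min_identity=float(raw.get("min_identity", default_identity)),
        )
    if kind == "regex":
        return MotifPattern("regex", regex=raw["pattern"])
    raise RegistryValidationError(f"unknown motif type {kind!r}")


def load_family_registry(
    path=None,
    expected_families: Optional[int] = EXPECTED_FAMILY_COUNT,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FamilyRegistry:
    """Load the family registry (packaged default when ``path`` is None).

    The packaged registry must hold exactly 38 families; pass
    ``expected_families=None`` to load a custom registry of another size.
    """
    if path is None:
        text = (resources.files("sspmine") / "data" / "families.yaml").read_text()
    else:
        text = open(path).read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "families" not in doc:
        raise RegistryValidationError("registry file must hold a 'families' list")
    entries = []
    for raw in doc["families"]:
        missing = {"name", "peptide_class", "description", "mode_of_action",
                   "reported_wheat_count"} - set(raw)
        if missing:
            raise RegistryValidationError(
                f"family entry {raw.get('name', '?')!r} missing fields {sorted(missing)}"
            )
        if "motif" not in raw:
            raise RegistryValidationError(
                f"family {raw['name']!r} must define a motif or 'motif: none'"
            )
        entries.append(
            FamilyRegistryEntry(
                name=str(raw["name"]),
                peptide_class=str(raw["peptide_class"]),
                description=str(raw["description"]),
                mode_of_action=tuple(raw["mode_of_action"]),
                reported_wheat_count=int(raw["reported_wheat_count"]),
                motif=_parse_motif(raw["motif"], config.min_identity),
            )
        )
    registry = FamilyRegistry(entries)
    if expected_families is not None and len(registry) != expected_families:
        raise RegistryValidationError(
            f"registry holds {len(registry)} families, expected {expected_families}"
        )
    return registry


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RegistrySummary:
    total: int
    per_class_counts: Dict[str, int]
    per_class_shares: Dict[str, int]  # integer percent, round half-up
    per_function_counts: Dict[str, int]
    per_function_families: Dict[str, int]


def registry_summary(registry: FamilyRegistry) -> RegistrySummary:
    """Aggregate reported gene counts by peptide class and mode of action.

    Class shares are integer percentages of the registry total, rounded
    half-up; a family with several modes of action contributes its full gene
    count to each.
    """
    class_counts: Dict[str, int] = {c: 0 for c in PEPTIDE_CLASSES}
    func_counts: Dict[str, int] = {m: 0 for m in MODES_OF_ACTION}
    func_families: Dict[str, int] = {m: 0 for m in MODES_OF_ACTION}
    for entry in registry:
        class_counts[entry.peptide_class] += entry.reported_wheat_count
        for mode in entry.mode_of_action:
            func_counts[mode] += entry.reported_wheat_count
            func_families[mode] += 1
    total = sum(class_counts.values())
    shares = {
        cls: _round_half_up(100 * count / total) if total else 0
        for cls, count in class_counts.items()
    }
    return RegistrySummary(total, class_counts, shares, func_counts, func_families)


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    family: str  # registry name or "unclassified"
    match_span: Optional[Tuple[int, int]] = None  # proprotein coords, 1-based inclusive
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.family != "unclassified" and self.match_span is None:
            raise ValueError("a family assignment requires a match span")


def disambiguate_cep_pip(cterm: str) -> Optional[str]:
    """Distinguish CEP from PIP by the spacer between SGPS and GxGH.

    In the shared C-terminal domain architecture both families carry an SGPS
    sub-motif followed by a GxGH sub-motif.  A single-residue spacer (a
    proline in canonical members) marks CEP; a two-residue spacer marks PIP;
    anything else is neither.  ``cterm`` should be the last <= 25 residues.
    """
    seq = cterm.upper()[-25:] if len(cterm) > 25 else cterm.upper()
    anchor = seq.find("SGPS")
    if anchor == -1:
        return None
    m = re.compile(r"G.GH").search(seq, anchor + 4)
    if m is None:
        return None
    spacer = seq[anchor + 4 : m.start()]
    if len(spacer) == 1:
        if spacer != "P":
            warnings.warn(
                f"single-residue CEP spacer is {spacer!r}, not the canonical proline"
            )
        return "CEP"
    if len(spacer) == 2:
        return "PIP"
    return None


def classify_family(
    record: Union[ProteinRecord, str],
    sp_call: SignalPeptideCall,
    registry: FamilyRegistry,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FamilyAssignment:
    """Assign a secretion-funnel candidate to its best-matching family.

    Motifs are evaluated over the C-terminal ``cterm_window`` residues of the
    mature sequence; the best-scoring family above its threshold wins, with
    ties broken by registry order.  A precursor matching both CEP and PIP is
    resolved by :func:`disambiguate_cep_pip`, never reported as a tie.
    Returns an ``unclassified`` assignment when nothing reaches threshold.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    gene_id = record.gene_id if isinstance(record, ProteinRecord) else "?"
    mature = mature_sequence(seq, sp_call)
    window_start = max(0, len(mature) - config.cterm_window)  # 0-based, in mature
    window = mature[window_start:]

    hits: List[Tuple[float, int, FamilyRegistryEntry, Tuple[int, int]]] = []
    for order, entry in enumerate(registry):
        if entry.motif is None:
            continue
        found = best_match(entry.motif, window)
        if found is None:
            continue
        start, end, score = found
        offset = sp_call.cleavage_after + window_start  # proprotein 0-based
        span = (offset + start + 1, offset + end)  # 1-based inclusive
        hits.append((score, order, entry, span))

    if not hits:
        return FamilyAssignment(gene_id, "unclassified")

    hit_names = {h[2].name for h in hits}
    if {"CEP", "PIP"} <= hit_names:
        resolved = disambiguate_cep_pip(mature[-25:])
        if resolved is not None:
            hits = [h for h in hits if h[2].name not in {"CEP", "PIP"} - {resolved}]

    score, _, entry, span = max(hits, key=lambda h: (h[0], -h[1]))
    return FamilyAssignment(gene_id, entry.name, match_span=span, score=score)


@dataclass(frozen=True)
class CysteineProfile:
    mature_length: int
    cys_count: int

    @property
    def is_even(self) -> bool:
        return self.cys_count % 2 == 0

    def is_crp(self, config: PipelineConfig = DEFAULT_CONFIG) -> bool:
        return self.is_even and config.cys_min <= self.cys_count <= config.cys_max


def cysteine_profile(mature: str) -> CysteineProfile:
    """Count cysteines over the entire mature (signal-peptide-removed) sequence."""
    return CysteineProfile(len(mature), mature.upper().count("C"))


def crp_spectrum(
    profiles: Iterable[CysteineProfile],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Tuple[Dict[int, int], Optional[float]]:
    """Histogram of cysteine counts over CRPs and the share with <= 12 cysteines.

    The share is a percentage of all CRPs; with no CRPs it is None.
    """
    histogram: Dict[int, int] = Counter()
    for profile in profiles:
        if profile.is_crp(config):
            histogram[profile.cys_count] += 1
    total = sum(histogram.values())
    if total == 0:
        return dict(histogram), None
    le12 = sum(count for cys, count in histogram.items() if cys <= 12)
    return dict(sorted(histogram.items())), 100.0 * le12 / total
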