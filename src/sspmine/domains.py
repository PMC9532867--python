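"""Multi-domain repeat scanning and the two manually described novel families.

Single peptide domains usually sit at the C-terminus of the precursor, but a
number of genes carry several tandem domains in the variable region.  The
scanner walks the mature sequence greedily left to right, emitting
non-overlapping motif hits.  Two hand-curated novel families are also
recognised: DYY (a putative tyrosine-sulfated PTM family whose 13-residue
mature peptide begins D-Y) and CRP8CI (a cysteine-rich family whose mature
domain carries exactly eight cysteines, split into three groups by their
inter-cysteine spacing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from collections import Counter

from .config import DEFAULT_CONFIG, PipelineConfig
from .motifs import MotifPattern, match_at, sliding_identity
from .proteome import ProteinRecord
from .secretion import SignalPeptideCall, mature_sequence

#: Packaged consensus of the 13-residue DYY mature peptide (user-overridable).
DYY_CONSENSUS = "DYYKPAGSNRPGH"
DYY_LENGTH = 13

#: Packaged CRP8CI inter-cysteine spacing templates (seven gaps between the
#: eight cysteines), one per group; user-overridable.
CRP8CI_TEMPLATES: Dict[int, Tuple[int, ...]] = {
    1: (2, 4, 6, 3, 2, 5, 3),
    2: (5, 2, 3, 7, 4, 2, 6),
    3: (3, 8, 2, 4, 6, 3, 2),
}


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    family: str
    start: int  # proprotein coordinates, 1-based inclusive
    end: int
    matched_seq: str
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hit start must not exceed end")


def scan_domains(
    record: Union[ProteinRecord, str],
    sp_call: SignalPeptideCall,
    pattern: MotifPattern,
    family: str = "",
    min_gap: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[DomainHit]:
    """Greedy leftmost non-overlapping motif matching over the mature sequence.

    The whole mature sequence is scanned (variable region included, where
    multi-domain repeats live).  After each hit the scan resumes
    ``min_gap`` residues past the hit's end, so consecutive hits are
    separated by at least ``min_gap`` residues.  Hit coordinates are reported
    on the proprotein (1-based inclusive).
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    gene_id = record.gene_id if isinstance(record, ProteinRecord) else "?"
    mature = mature_sequence(seq, sp_call)
    offset = sp_call.cleavage_after  # proprotein 0-based index of mature[0]

    hits: List[DomainHit] = []
    pos = 0
    while pos < len(mature):
        found = match_at(pattern, mature, pos)
        if found is None:
            pos += 1
            continue
        length, score = found
        hits.append(
            DomainHit(
                gene_id=gene_id,
                family=family,
                start=offset + pos + 1,
                end=offset + pos + length,
                matched_seq=mature[pos : pos + length],
                score=score,
            )
        )
        pos += length + min_gap
    return hits


@dataclass(frozen=True)
class MultidomainGene:
    gene_id: str
    n_hits: int
    family_counts: Dict[str, int]

    @property
    def mixed(self) -> bool:
        return len(self.family_counts) > 1


def multidomain_report(
    hits_by_gene: Mapping[str, Sequence[DomainHit]]
) -> List[MultidomainGene]:
    """Genes carrying two or more domain hits, with per-family counts."""
    report = []
    for gene_id, hits in hits_by_gene.items():
        if len(hits) < 2:
            continue
        counts = Counter(h.family for h in hits)
        report.append(MultidomainGene(gene_id, len(hits), dict(counts)))
    return report


def cle_terminal_check(domain_seq: str) -> bool:
    """True iff the domain ends in the residues essential for CLE activity (HN or H)."""
    if len(domain_seq) < 2:
        raise ValueError("domain must hold at least two residues")
    seq = domain_seq.upper()
    return seq.endswith("H") or seq.endswith("HN")


@dataclass(frozen=True)
class DyyHit:
    start: int  # 1-based position in the mature sequence
    matched_seq: str
    score: float


def dyy_scan(
    mature: str,
    consensus: str = DYY_CONSENSUS,
    threshold: float = 0.5,
    search_window: int = 40,
) -> Optional[DyyHit]:
    """Look for the 13-residue DYY mature peptide near the C-terminus.

    Scans the C-terminal ``search_window`` residues for a 13-mer beginning
    ``DY``, scores identity to the consensus, and reports the best-scoring
    window (leftmost on ties) when it reaches ``threshold``.
    """
    if len(mature) < DYY_LENGTH:
        return None
    seq = mature.upper()
    region_start = max(0, len(seq) - search_window)
    best: Optional[DyyHit] = None
    for i in range(region_start, len(seq) - DYY_LENGTH + 1):
        window = seq[i : i + DYY_LENGTH]
        if not window.startswith("DY"):
            continue
        score = sum(a == b for a, b in zip(window, consensus)) / DYY_LENGTH
        if best is None or score > best.score:
            best = DyyHit(i + 1, window, score)
    if best is None or best.score < threshold:
        return None
    return best


@dataclass(frozen=True)
class Crp8ciHit:
    group: int
    cys_positions: Tuple[int, ...]  # 1-based positions in the mature sequence


def crp8ci_scan(
    mature: str,
    templates: Mapping[int, Tuple[int, ...]] = CRP8CI_TEMPLATES,
    max_gap_deviation: int = 1,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Optional[Crp8ciHit]:
    """Recognise the eight-cysteine CRP8CI domain and assign its group.

    A sequence is a candidate iff its C-terminal ``cterm_window`` region
    carries exactly eight cysteines.  The seven inter-cysteine gaps are then
    compared to each group's spacing template; a template is satisfied when
    every gap deviates by at most ``max_gap_deviation`` residues, and the
    best (smallest total deviation, lowest group number on ties) satisfied
    template names the group.
    """
    seq = mature.upper()
    region_start = max(0, len(seq) - config.cterm_window)
    positions = [i + 1 for i in range(region_start, len(seq)) if seq[i] == "C"]
    if len(positions) != 8:
        return None
    gaps = tuple(positions[i + 1] - positions[i] - 1 for i in range(7))
    best: Optional[Tuple[int, int]] = None  # (total deviation, group)
    for group, template in sorted(templates.items()):
        deviations = [abs(g - t) for g, t in zip(gaps, template)]
        if max(deviations) > max_gap_deviation:
            continue
        cand = (sum(deviations), group)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return Crp8ciHit(best[1], tuple(positions))
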