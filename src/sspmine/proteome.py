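"""Proteome ingestion and pre-filters.

Reads a protein FASTA, collapses each gene to its single longest transcript,
applies the precursor-size filter, flags truncated entries, and summarises
how gene loci distribute along chromosomes.  Positions are 1-based inclusive
throughout (protein and genomic).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import HeaderParseError, LocusValidationError, TableParseError

logger = logging.getLogger(__name__)

#: 20 standard residues plus ambiguity (X) and stop (*)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_ENSEMBL_RE = re.compile(r"^(?P<gene>\S+?)\.(?P<iso>\d+)$")


@dataclass(frozen=True)
class GeneLocus:
    """Genomic placement of a gene (1-based inclusive coordinates)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    chrom_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= self.chrom_length):
            raise LocusValidationError(
                f"locus {self.gene_id} ({self.start}-{self.end}) outside "
                f"chromosome {self.chromosome} of length {self.chrom_length}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class ProteinRecord:
    """One proprotein sequence with its gene/transcript identity.

    ``sequence`` is stored uppercase with any terminal stop ``*`` stripped;
    ``had_terminal_stop`` records that a stop was present in the source file
    so FASTA round trips are lossless.
    """

    gene_id: str
    transcript_id: str
    sequence: str
    had_terminal_stop: bool = False
    locus: Optional[GeneLocus] = None

    def __post_init__(self) -> None:
        if not self.transcript_id.startswith(self.gene_id):
            raise ValueError(
                f"transcript_id {self.transcript_id!r} does not begin with "
                f"gene_id {self.gene_id!r}"
            )
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.transcript_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _parse_header(token: str, dialect: str) -> Tuple[str, str]:
    if dialect == "ensembl":
        m = _ENSEMBL_RE.match(token)
        if m is None:
            raise HeaderParseError(
                f"header {token!r} does not match Ensembl '<gene>.<n>' naming"
            )
        return m.group("gene"), token
    if dialect == "generic":
        return token, token
    raise ValueError(f"unknown header dialect {dialect!r}")


def read_proteome(path, dialect: str = "ensembl") -> List[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The first whitespace-delimited token of each header is the transcript id;
    under the ``ensembl`` dialect it must look like ``TraesCS1D02G130700.1``
    (gene id plus ``.n`` isoform suffix), under ``generic`` the whole token
    doubles as the gene id.  File order is preserved and a trailing stop
    codon ``*`` is stripped (flag retained).
    """
    records: List[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        gene_id, transcript_id = _parse_header(entry.id, dialect)
        seq = str(entry.seq).upper()
        had_stop = seq.endswith("*")
        if had_stop:
            seq = seq[:-1]
        records.append(
            ProteinRecord(
                gene_id=gene_id,
                transcript_id=transcript_id,
                sequence=seq,
                had_terminal_stop=had_stop,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path, restore_stop: bool = True) -> None:
    """Write records back to FASTA; terminal stops are restored by default."""
    out = []
    for rec in records:
        seq = rec.sequence + ("*" if restore_stop and rec.had_terminal_stop else "")
        out.append(SeqRecord(Seq(seq), id=rec.transcript_id, description=""))
    SeqIO.write(out, str(path), "fasta")


def select_longest_transcript(records: Sequence[ProteinRecord]) -> List[ProteinRecord]:
    """Keep one transcript per gene: the longest, ties to the lexicographically
    smallest transcript id.  The relative order of genes (first appearance)
    is preserved and the operation is idempotent."""
    best: Dict[str, ProteinRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
        elif (rec.length, _neg_lex(rec.transcript_id)) > (
            cur.length,
            _neg_lex(cur.transcript_id),
        ):
            best[rec.gene_id] = rec
    return list(best.values())


class _neg_lex(str):
    """Order-reversing wrapper so max() prefers the smallest transcript id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def filter_by_length(
    records: Sequence[ProteinRecord], max_length: int = 250
) -> List[ProteinRecord]:
    """Retain records of at most ``max_length`` residues (inclusive bound)."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    kept, rejected = [], []
    for rec in records:
        (kept if rec.length <= max_length else rejected).append(rec)
    for rec in rejected:
        logger.info("length filter rejected %s (%d aa)", rec.transcript_id, rec.length)
    return kept


def is_truncated(sequence: str) -> bool:
    """A sequence counts as truncated if it carries an internal stop ``*``,
    lacks the initiator methionine, or contains any ambiguous residue ``X``."""
    return "*" in sequence or not sequence.startswith("M") or "X" in sequence


def flag_truncated(
    records: Sequence[ProteinRecord],
) -> Tuple[List[ProteinRecord], List[ProteinRecord]]:
    """Partition records into (kept, truncated)."""
    kept, truncated = [], []
    for rec in records:
        (truncated if is_truncated(rec.sequence) else kept).append(rec)
    return kept, truncated


@dataclass(frozen=True)
class ChromosomeSummary:
    chromosome: str
    n_genes: int
    n_end_genes: int

    @property
    def end_ratio(self) -> float:
        return self.n_end_genes / self.n_genes if self.n_genes else 0.0


def read_locus_table(path) -> List[GeneLocus]:
    """Load a TSV with columns gene_id, chromosome, start, end, chrom_length."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "start", "end", "chrom_length"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"locus table missing columns: {sorted(missing)}")
    return [
        GeneLocus(r.gene_id, r.chromosome, int(r.start), int(r.end), int(r.chrom_length))
        for r in df.itertuples(index=False)
    ]


def chromosome_distribution(
    loci: Iterable[GeneLocus], end_fraction: float = 0.2
) -> Dict[str, ChromosomeSummary]:
    """Per-chromosome gene counts and the share of genes near the termini.

    A gene is an "end" gene when its midpoint lies within
    ``end_fraction * chrom_length`` of either chromosome terminus (inclusive
    boundary); a midpoint at exactly half the length is interior.
    """
    if not 0 < end_fraction < 0.5:
        raise ValueError("end_fraction must lie in (0, 0.5)")
    counts: Dict[str, List[int]] = {}
    for locus in loci:
        edge = end_fraction * locus.chrom_length
        at_end = locus.midpoint <= edge or locus.midpoint >= locus.chrom_length - edge
        n, e = counts.setdefault(locus.chromosome, [0, 0])
        counts[locus.chromosome] = [n + 1, e + int(at_end)]
    return {
        chrom: ChromosomeSummary(chrom, n, e) for chrom, (n, e) in counts.items()
    }
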