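"""Secretion funnel: signal peptide, transmembrane exclusion, ER retention.

The funnel orders five screens — precursor size, signal-peptide presence,
transmembrane exclusion on the mature (cleaved) sequence, absence of a
C-terminal K/HDEL ER-retention tail, and sequence integrity — and records the
first stage that rejects each record.

Two prediction routes are supported for the signal-peptide and topology
stages: deterministic built-in classical heuristics (a von-Heijne-style
n/h/c-region rule with a (-3,-1) small-residue cleavage site, and a
Kyte-Doolittle sliding-window hydropathy scan), or adapter-loaded output
tables from external predictors.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import (
    DegenerateCleavageError,
    MissingPredictionError,
    SequenceTooShortError,
    TableParseError,
)
from .proteome import ProteinRecord, is_truncated

#: Kyte-Doolittle hydropathy scale; unknown residues (X, *) score 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Hydrophobic residues accepted in the h-region core.
HYDROPHOBIC = frozenset("AILMFVW")
#: Small residues allowed at the (-3, -1) cleavage-site positions.
SMALL_RESIDUES = frozenset("AGSCTV")

FUNNEL_STAGES = ("length", "signal_peptide", "transmembrane", "er_retention", "truncation")


@dataclass(frozen=True)
class SignalPeptideCall:
    has_sp: bool
    cleavage_after: Optional[int] = None  # last residue of the SP, 1-based
    score: float = 0.0
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.has_sp and self.cleavage_after is None:
            raise ValueError("positive call requires a cleavage position")
        if not self.has_sp and self.cleavage_after is not None:
            raise ValueError("negative call must not carry a cleavage position")


@dataclass(frozen=True)
class TopologyCall:
    has_tm: bool
    best_window: Optional[Tuple[int, int, float]] = None  # (start, end, mean), 1-based
    source: str = "builtin"


@dataclass(frozen=True)
class StageResult:
    stage: str
    passed: Optional[bool]  # None = not evaluated (an earlier stage rejected)


@dataclass(frozen=True)
class SecretionVerdict:
    record: ProteinRecord
    stage_results: Tuple[StageResult, ...]
    sp_call: Optional[SignalPeptideCall] = None
    tm_call: Optional[TopologyCall] = None

    @property
    def rejected_at(self) -> Optional[str]:
        for res in self.stage_results:
            if res.passed is False:
                return res.stage
        return None

    @property
    def is_ssp_candidate(self) -> bool:
        return all(res.passed for res in self.stage_results)


def predict_signal_peptide_builtin(
    sequence: str, config: PipelineConfig = DEFAULT_CONFIG
) -> SignalPeptideCall:
    """Classical n/h/c-region signal-peptide heuristic.

    Within the first ``sp_search_limit`` residues the call is positive iff

    * h-region: some 8-residue window starting at position 3-25 (1-based)
      holds at least 6 hydrophobic residues (A/I/L/M/F/V/W), and
    * c-site: some position ``p`` in 15-35, at least two residues beyond the
      end of such an h-window, has small residues (A/G/S/C/T/V) at both
      ``p`` and ``p - 2`` (the (-3, -1) rule relative to cleavage after
      ``p``).

    The cleavage site is the smallest qualifying ``p``; the score is the
    hydrophobic count of the strongest licensing h-window divided by 8.
    Sequences shorter than 15 residues raise
    :class:`~sspmine.errors.SequenceTooShortError` (a no-call, distinct from
    a negative prediction).
    """
    seq = sequence.upper()
    if len(seq) < 15:
        raise SequenceTooShortError(
            f"sequence of {len(seq)} residues is too short for a signal-peptide call"
        )
    region = seq[: config.sp_search_limit]
    n = len(region)

    # h-region windows: (start, end, hydrophobic count), 1-based inclusive
    windows = []
    for start in range(3, 26):
        end = start + 7
        if end > n:
            break
        count = sum(res in HYDROPHOBIC for res in region[start - 1 : end])
        if count >= 6:
            windows.append((start, end, count))

    best_h = max((w[2] for w in windows), default=0)
    if not windows:
        return SignalPeptideCall(False, score=best_h / 8)

    for p in range(15, 36):
        if p > n:
            break
        licensing = [w for w in windows if p >= w[1] + 2]
        if not licensing:
            continue
        if region[p - 1] in SMALL_RESIDUES and region[p - 3] in SMALL_RESIDUES:
            score = max(w[2] for w in licensing) / 8
            return SignalPeptideCall(True, cleavage_after=p, score=score)
    return SignalPeptideCall(False, score=best_h / 8)


_CS_POS_RE = re.compile(r"(\d+)")


def load_external_sp_calls(path) -> Dict[str, SignalPeptideCall]:
    """Adapter for an external signal-peptide predictor's short-format table.

    Expects tab-separated rows ``id<TAB>label[<TAB>cleavage]``; labels
    beginning ``SP`` are secretory (the cleavage field's first integer is the
    last SP residue, e.g. ``CS pos: 24-25`` -> 24), anything else is a
    negative call.  Duplicate ids with conflicting calls are refused.
    """
    calls: Dict[str, SignalPeptideCall] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            row = [cell.strip() for cell in row if cell.strip() != ""]
            if len(row) < 2:
                raise TableParseError(f"line {lineno}: expected id and label")
            ident, label = row[0], row[1]
            if label.upper().startswith("SP"):
                if len(row) < 3:
                    raise TableParseError(
                        f"line {lineno}: secretory call for {ident} lacks a cleavage position"
                    )
                m = _CS_POS_RE.search(row[2])
                if m is None:
                    raise TableParseError(
                        f"line {lineno}: cannot parse cleavage position from {row[2]!r}"
                    )
                call = SignalPeptideCall(True, cleavage_after=int(m.group(1)),
                                         score=1.0, source="external-file")
            else:
                call = SignalPeptideCall(False, score=0.0, source="external-file")
            if ident in calls and calls[ident] != call:
                raise TableParseError(
                    f"line {lineno}: conflicting duplicate call for id {ident}"
                )
            calls[ident] = call
    return calls


def load_external_tm_calls(path) -> Dict[str, TopologyCall]:
    """Adapter for an external topology predictor: TSV ``id<TAB>predicted_tm_count``."""
    calls: Dict[str, TopologyCall] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            row = [cell.strip() for cell in row if cell.strip() != ""]
            if len(row) < 2:
                raise TableParseError(f"line {lineno}: expected id and TM count")
            try:
                count = int(row[1])
            except ValueError as exc:
                raise TableParseError(
                    f"line {lineno}: non-integer TM count {row[1]!r}"
                ) from exc
            call = TopologyCall(count > 0, source="external-file")
            if row[0] in calls and calls[row[0]] != call:
                raise TableParseError(
                    f"line {lineno}: conflicting duplicate call for id {row[0]}"
                )
            calls[row[0]] = call
    return calls


def mature_sequence(record: Union[ProteinRecord, str], sp_call: SignalPeptideCall) -> str:
    """Residues downstream of the signal-peptide cleavage site."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if not sp_call.has_sp:
        raise ValueError("cannot derive a mature sequence from a negative SP call")
    if sp_call.cleavage_after >= len(seq):
        raise DegenerateCleavageError(
            f"cleavage after residue {sp_call.cleavage_after} of a "
            f"{len(seq)}-residue sequence leaves no mature peptide"
        )
    return seq[sp_call.cleavage_after:]


def detect_tm_builtin(
    mature: str, config: PipelineConfig = DEFAULT_CONFIG
) -> TopologyCall:
    """Kyte-Doolittle sliding-window transmembrane-segment scan.

    The best window is the maximal-mean hydropathy window (leftmost on ties);
    a transmembrane segment is called iff its mean exceeds
    ``hydropathy_cutoff``.  Sequences shorter than the window are negative
    with no window reported.
    """
    w = config.hydropathy_window
    seq = mature.upper()
    if len(seq) < w:
        return TopologyCall(False, None)
    values = np.array([KYTE_DOOLITTLE.get(res, 0.0) for res in seq])
    means = np.convolve(values, np.ones(w) / w, mode="valid")
    best = int(np.argmax(means))  # argmax returns the leftmost maximum
    window = (best + 1, best + w, float(means[best]))
    return TopologyCall(bool(means[best] > config.hydropathy_cutoff), window)


def er_retention(sequence: str, config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """True iff the final four residues equal an ER-retention motif (K/HDEL)."""
    if len(sequence) < 4:
        warnings.warn("sequence shorter than 4 residues cannot carry an ER-retention motif")
        return False
    return sequence[-4:].upper() in config.kdel_motifs


SourceType = Union[str, Mapping[str, SignalPeptideCall], Mapping[str, TopologyCall]]


def _lookup(mapping: Mapping, record: ProteinRecord, missing: str, kind: str):
    for key in (record.gene_id, record.transcript_id):
        if key in mapping:
            return mapping[key]
    if missing == "strict":
        raise MissingPredictionError(
            f"external {kind} map has no call for {record.gene_id}"
        )
    return None


def secretion_pipeline(
    records: Sequence[ProteinRecord],
    sp_source: SourceType = "builtin",
    tm_source: SourceType = "builtin",
    config: PipelineConfig = DEFAULT_CONFIG,
    missing: str = "strict",
) -> Tuple[List[ProteinRecord], List[SecretionVerdict], Dict[str, int]]:
    """Run the full secretion funnel.

    Stages are applied in order length -> signal peptide -> transmembrane
    (on the mature sequence) -> ER retention (C-terminus of the full
    precursor) -> truncation.  ``sp_source``/``tm_source`` are either the
    string ``"builtin"`` or mappings from gene/transcript id to calls loaded
    from external predictor output; a record absent from an external map is a
    hard error under ``missing="strict"`` (default) or a negative call under
    ``missing="negative"``.

    Returns (candidates, per-record verdicts, survivor count after each stage).
    """
    if missing not in ("strict", "negative"):
        raise ValueError("missing must be 'strict' or 'negative'")
    verdicts: List[SecretionVerdict] = []
    candidates: List[ProteinRecord] = []
    counts: Dict[str, int] = {"input": len(records)}
    for stage in FUNNEL_STAGES:
        counts[stage] = 0

    for rec in records:
        results: List[StageResult] = []
        sp_call: Optional[SignalPeptideCall] = None
        tm_call: Optional[TopologyCall] = None
        alive = True

        def run(stage: str, outcome: Optional[bool]) -> bool:
            nonlocal alive
            results.append(StageResult(stage, outcome))
            if outcome:
                counts[stage] += 1
            else:
                alive = False
            return bool(outcome)

        # 1. length
        ok = run("length", rec.length <= config.max_length)

        # 2. signal peptide
        if alive:
            if sp_source == "builtin":
                try:
                    sp_call = predict_signal_peptide_builtin(rec.sequence, config)
                except SequenceTooShortError:
                    sp_call = SignalPeptideCall(False, score=0.0)
            else:
                sp_call = _lookup(sp_source, rec, missing, "signal-peptide")
                if sp_call is None:
                    sp_call = SignalPeptideCall(False, source="external-file")
            run("signal_peptide", sp_call.has_sp and sp_call.cleavage_after < rec.length)
        else:
            results.append(StageResult("signal_peptide", None))

        # 3. transmembrane on the mature sequence
        if alive:
            mature = mature_sequence(rec, sp_call)
            if tm_source == "builtin":
                tm_call = detect_tm_builtin(mature, config)
            else:
                tm_call = _lookup(tm_source, rec, missing, "topology")
                if tm_call is None:
                    tm_call = TopologyCall(False, source="external-file")
            run("transmembrane", not tm_call.has_tm)
        else:
            results.append(StageResult("transmembrane", None))

        # 4. ER retention on the full precursor C-terminus
        if alive:
            run("er_retention", not er_retention(rec.sequence, config))
        else:
            results.append(StageResult("er_retention", None))

        # 5. truncation
        if alive:
            run("truncation", not is_truncated(rec.sequence))
        else:
            results.append(StageResult("truncation", None))

        verdict = SecretionVerdict(rec, tuple(results), sp_call, tm_call)
        verdicts.append(verdict)
        if verdict.is_ssp_candidate:
            candidates.append(rec)

    return candidates, verdicts, counts
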