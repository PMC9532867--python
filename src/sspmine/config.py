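"""Pipeline-wide thresholds and constants.

All thresholds of the identification funnel, the cysteine-class profiler and
the expression caller live in a single immutable :class:`PipelineConfig` so a
run can be reproduced from its manifest.  Defaults encode the standard screen:
precursors of at most 250 residues, K/HDEL ER-retention tails, an even 2-16
cysteine window for CRP calling, TPM >= 1 as "meaningful" expression and a
two-fold stress/control ratio for upregulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet


@dataclass(frozen=True)
class PipelineConfig:
    """Immutable bundle of every tunable threshold in the pipeline.

    Parameters
    ----------
    max_length:
        Maximum precursor length in residues (inclusive) for the size
        pre-filter.
    kdel_motifs:
        C-terminal tetrapeptides that mark ER-retained proteins.
    cys_min, cys_max:
        Inclusive bounds (both even) on the mature-sequence cysteine count
        for a peptide to qualify as cysteine-rich (CRP).
    tpm_meaningful:
        TPM level above which expression is considered meaningful.
    fold_threshold:
        Minimum stress/control TPM ratio for an upregulation call.
    hydropathy_window, hydropathy_cutoff:
        Kyte-Doolittle sliding-window size and mean-hydropathy cutoff for
        transmembrane-segment detection on the mature sequence.
    sp_search_limit:
        Number of N-terminal residues examined by the built-in
        signal-peptide heuristic.
    end_fraction:
        Fraction of a chromosome's length counted as a chromosome "end"
        when summarising gene placement.
    cterm_window:
        Length of the C-terminal window of the mature sequence scanned for
        family motifs.
    min_identity:
        Default consensus-identity threshold for motif matches when a
        registry entry does not specify one.
    """

    max_length: int = 250
    kdel_motifs: FrozenSet[str] = frozenset({"KDEL", "HDEL"})
    cys_min: int = 2
    cys_max: int = 16
    tpm_meaningful: float = 1.0
    fold_threshold: float = 2.0
    hydropathy_window: int = 19
    hydropathy_cutoff: float = 1.6
    sp_search_limit: int = 40
    end_fraction: float = 0.2
    cterm_window: int = 60
    min_identity: float = 0.75

    def __post_init__(self) -> None:
        positive = {
            "max_length": self.max_length,
            "tpm_meaningful": self.tpm_meaningful,
            "fold_threshold": self.fold_threshold,
            "hydropathy_window": self.hydropathy_window,
            "hydropathy_cutoff": self.hydropathy_cutoff,
            "sp_search_limit": self.sp_search_limit,
            "end_fraction": self.end_fraction,
            "cterm_window": self.cterm_window,
            "min_identity": self.min_identity,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.cys_min % 2 or self.cys_max % 2:
            raise ValueError("cys_min and cys_max must both be even")
        if self.cys_min > self.cys_max:
            raise ValueError("cys_min must not exceed cys_max")
        if not 0 < self.end_fraction < 0.5:
            raise ValueError("end_fraction must lie in (0, 0.5)")
        object.__setattr__(
            self, "kdel_motifs", frozenset(m.upper() for m in self.kdel_motifs)
        )
        for motif in self.kdel_motifs:
            if len(motif) != 4:
                raise ValueError(f"ER-retention motifs must be 4-mers, got {motif!r}")

    def with_updates(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = PipelineConfig()
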