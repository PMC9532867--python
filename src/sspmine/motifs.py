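"""Shared motif primitives: consensus identity scoring and regex patterns."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple


@dataclass(frozen=True)
class MotifPattern:
    """A family motif: either a consensus sequence scored by sliding identity,
    or an anchored regular pattern.

    ``kind`` is ``"consensus"`` or ``"regex"``.  Consensus matches score the
    fraction of identical residues over the consensus length; regex matches
    score 1.0.
    """

    kind: str
    consensus: Optional[str] = None
    regex: Optional[str] = None
    min_identity: float = 0.75

    def __post_init__(self) -> None:
        if self.kind == "consensus":
            if not self.consensus:
                raise ValueError("consensus motif requires a sequence")
        elif self.kind == "regex":
            if not self.regex:
                raise ValueError("regex motif requires a pattern")
            re.compile(self.regex)
        else:
            raise ValueError(f"unknown motif kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.consensus) if self.kind == "consensus" else 0


def sliding_identity(consensus: str, window: str) -> List[Tuple[int, float]]:
    """Identity of ``consensus`` against every alignment position of ``window``.

    Returns (0-based offset, identity fraction) for each placement of the
    full consensus inside ``window``; empty when the window is shorter.
    """
    k = len(consensus)
    return [
        (i, sum(a == b for a, b in zip(consensus, window[i : i + k])) / k)
        for i in range(len(window) - k + 1)
    ]


def best_match(pattern: MotifPattern, window: str) -> Optional[Tuple[int, int, float]]:
    """Best placement of a motif in ``window``.

    Returns (start, end, score) with 0-based half-open coordinates, or None
    when nothing reaches the motif's threshold.  Ties go to the leftmost
    placement.
    """
    if pattern.kind == "regex":
        m = re.search(pattern.regex, window)
        if m is None or m.end() == m.start():
            return None
        return m.start(), m.end(), 1.0
    placements = sliding_identity(pattern.consensus, window)
    if not placements:
        return None
    offset, score = max(placements, key=lambda p: (p[1], -p[0]))
    if score < pattern.min_identity:
        return None
    return offset, offset + len(pattern.consensus), score


def match_at(pattern: MotifPattern, window: str, offset: int) -> Optional[Tuple[int, float]]:
    """Test a motif anchored at ``offset``; returns (match length, score) or None."""
    if pattern.kind == "regex":
        m = re.compile(pattern.regex).match(window, offset)
        if m is None or m.end() == m.start():
            return None
        return m.end() - m.start(), 1.0
    k = len(pattern.consensus)
    if offset + k > len(window):
        return None
    score = sum(a == b for a, b in zip(pattern.consensus, window[offset:])) / k
    if score < pattern.min_identity:
        return None
    return k, score
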