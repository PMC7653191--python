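"""Analytic G-quadruplex scorers: the canonical regex and G4Hunter.

The regular expression ``(G{3,}[ATGCN]{1,7}){3,}G{3,}`` calls a sequence
positive when it contains four or more G-tracts of length >= 3 joined by
loops of 1-7 arbitrary bases. G4Hunter scores G-richness/G-skewness: each
base of a maximal G-run of length n contributes +min(n, 4), each base of a
C-run -min(n, 4), A/T/N contribute 0; a sequence's score is the highest
mean over 25-nt sliding windows, floored at 0 when nothing exceeds the
threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import groupby

import numpy as np

__all__ = [
    "G4_REGEX",
    "G4HunterConfig",
    "regex_match",
    "g4hunter_base_scores",
    "g4hunter_score",
]

G4_REGEX = re.compile(r"(?:G{3,}[ATGCN]{1,7}){3,}G{3,}")

_VALID_BASES = frozenset("ACGTN")


def _validate(seq: str) -> None:
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"invalid characters in sequence: {bad}")


@dataclass(frozen=True)
class G4HunterConfig:
    """Sliding-window size and score floor for G4Hunter."""

    window: int = 25
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


def regex_match(seq: str) -> bool:
    """True iff the canonical four-tract G4 motif occurs in ``seq``."""
    _validate(seq)
    return G4_REGEX.search(seq) is not None


def g4hunter_base_scores(seq: str) -> np.ndarray:
    """Per-base G4Hunter scores as an integer vector of len(seq).

    Bases in a maximal run of n Gs score +min(n, 4); runs of Cs score
    -min(n, 4); A, T and N score 0.
    """
    _validate(seq)
    scores = np.empty(len(seq), dtype=np.int64)
    pos = 0
    for base, run in groupby(seq):
        n = sum(1 for _ in run)
        if base == "G":
            val = min(n, 4)
        elif base == "C":
            val = -min(n, 4)
        else:
            val = 0
        scores[pos : pos + n] = val
        pos += n
    return scores


def g4hunter_score(seq: str, config: G4HunterConfig = G4HunterConfig()) -> float:
    """Maximum sliding-window mean of the base scores, floored at 0.

    Windows have length ``config.window`` with stride 1; sequences shorter
    than the window are scored as a single whole-sequence window. The
    result is the best window mean when it strictly exceeds
    ``config.threshold``, otherwise 0. Window sums are integer-exact, so
    the means are reproducible bit-for-bit.
    """
    if len(seq) == 0:
        raise ValueError("cannot score an empty sequence")
    scores = g4hunter_base_scores(seq)
    w = min(config.window, len(scores))
    csum = np.concatenate(([0], np.cumsum(scores)))
    window_sums = csum[w:] - csum[:-w]
    best = int(window_sums.max()) / w
    return best if best > config.threshold else 0.0
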