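"""Count-based inference of the transition structure.

Both agent families learn which initial-stage action commonly leads to
which final-stage state the same way: they count observed transitions
and on each trial adopt whichever of three candidate structures makes
the counts most likely — the two mirrored true structures
(p(s_B|a_A)=0.7 or 0.3) and a flat p=0.5 structure representing
ignorance.  Ties go to the flat structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionCounts",
    "TransitionStructure",
    "CANDIDATES",
    "update_counts",
    "infer_structure",
]

# candidate p(s_B | a1) rows for actions (0, 1); labels for reporting
CANDIDATES: dict[str, np.ndarray] = {
    "a0_common_sB": np.array([0.7, 0.3]),
    "a0_common_sC": np.array([0.3, 0.7]),
    "flat": np.array([0.5, 0.5]),
}

_TIE_TOL = 1e-9


@dataclass
class TransitionCounts:
    """2x2 transition counts: rows = initial action, cols = final state (s_B, s_C)."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionStructure:
    """An inferred p(s2 | s_A, a1) table; one of the three candidates."""

    label: str
    p_sB_given_action: np.ndarray  # length 2

    def prob(self, a1: int, s2: int) -> float:
        p_sB = float(self.p_sB_given_action[a1])
        return p_sB if s2 == 1 else 1.0 - p_sB


def update_counts(counts: TransitionCounts, a1: int, s2: int) -> TransitionCounts:
    """Record one observed (initial action -> final state) transition."""
    if a1 not in (0, 1) or s2 not in (1, 2):
        raise ValueError(f"invalid transition ids a1={a1}, s2={s2}")
    counts.counts[a1, s2 - 1] += 1
    return counts


def infer_structure(counts: TransitionCounts) -> TransitionStructure:
    """Most likely mirrored structure given the counts; flat on ties.

    The two true candidates are scored by the product-Bernoulli log
    likelihood of the observed counts (which reduces to comparing the
    number of transitions each structure would call common).  The flat
    structure represents ignorance and is adopted only when the evidence
    is tied — e.g. before any observations — mirroring participants who
    know the structure is one of the two mirrored options but not which.
    With this rule the correct structure is identified within a handful
    of trials.
    """
    c = counts.counts
    ll_a = float(
        c[0, 0] * np.log(0.7) + c[0, 1] * np.log(0.3)
        + c[1, 0] * np.log(0.3) + c[1, 1] * np.log(0.7)
    )
    ll_b = float(
        c[0, 0] * np.log(0.3) + c[0, 1] * np.log(0.7)
        + c[1, 0] * np.log(0.7) + c[1, 1] * np.log(0.3)
    )
    if abs(ll_a - ll_b) <= _TIE_TOL:
        label = "flat"
    elif ll_a > ll_b:
        label = "a0_common_sB"
    else:
        label = "a0_common_sC"
    return TransitionStructure(label, CANDIDATES[label])
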