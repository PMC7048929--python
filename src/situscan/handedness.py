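"""Exact one-tailed binomial test for elevated left-handedness.

With a population left-handedness rate p0 (10% by default), the evidence
that a group of n subjects containing k natural left-handers is enriched
for left-handedness is the exact upper tail P(X >= k), X ~ Binomial(n, p0),
summed term by term — no normal approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import pandas as pd

from .matching import natural_handedness

log = logging.getLogger(__name__)

POPULATION_LEFT_RATE = 0.10


@dataclass(frozen=True)
class HandednessCount:
    n_left: int
    n_total: int
    p0: float = POPULATION_LEFT_RATE

    def __post_init__(self):
        if not (0 <= self.n_left <= self.n_total):
            raise ValueError(f"need 0 <= n_left <= n_total, got {self}")


def binomial_upper_tail(count: HandednessCount) -> float:
    """Exact one-tailed (greater) binomial probability P(X >= n_left).

    Summed binomial terms: sum_{j=k}^{n} C(n,j) p0^j (1-p0)^(n-j).
    """
    p0, n, k = count.p0, count.n_total, count.n_left
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    if n < 1:
        raise ValueError("n_total must be >= 1")
    total = sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))
    return min(float(total), 1.0)


def tabulate_handedness(
    subjects: pd.DataFrame, p0: float = POPULATION_LEFT_RATE
) -> dict[str, HandednessCount]:
    """Per-group counts of natural left-handers (forced-switch override applied).

    Ambidextrous subjects (|EHI| <= 0.5) are excluded from both numerator
    and denominator; empty groups yield (0, 0) with a warning.
    """
    counts: dict[str, HandednessCount] = {}
    for group, grp in subjects.groupby("group", sort=True):
        hands = [natural_handedness(row) for _, row in grp.iterrows()]
        known = [h for h in hands if h is not None]
        if not known:
            log.warning("group %s has no handedness-classifiable subjects", group)
        counts[group] = HandednessCount(sum(h == "left" for h in known), len(known), p0)
    return counts
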