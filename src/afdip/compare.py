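"""Cross-method protarget comparison: overlaps, background truth, expected
random agreement.

When several orthogonal chemoproteomics screens (e.g. a digestion-kinetics
screen, limited proteolysis, thermal profiling) are run on the same
compound, their agreement is summarized by pairwise protarget overlaps and
by each method's recovery of a consensus "background truth" set — the union
of the most trusted method's calls with the proteins found by both of the
other two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet


@dataclass(frozen=True)
class OverlapSummary:
    """Overlap between two protarget sets."""

    n_a: int
    n_b: int
    n_overlap: int

    @property
    def pct_of_a(self) -> float:
        return 100.0 * self.n_overlap / self.n_a if self.n_a else 0.0

    @property
    def pct_of_b(self) -> float:
        return 100.0 * self.n_overlap / self.n_b if self.n_b else 0.0


def overlap(a: AbstractSet[str], b: AbstractSet[str]) -> OverlapSummary:
    """Pairwise overlap of two protarget sets with percentages of each side."""
    return OverlapSummary(len(a), len(b), len(a & b))


def expected_random_overlap(n_a: int, n_b: int, n_universe: int) -> float:
    """Expected overlap of two random subsets of sizes n_a, n_b drawn from a
    universe of n_universe proteins (hypergeometric mean)."""
    if n_universe <= 0:
        raise ValueError("universe must be nonempty")
    return n_a * n_b / n_universe


def background_truth(
    trusted: AbstractSet[str],
    method_a: AbstractSet[str],
    method_b: AbstractSet[str],
) -> frozenset[str]:
    """Consensus set: the trusted method's protargets plus every protein
    called by both of the other two methods."""
    return frozenset(trusted | (method_a & method_b))
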