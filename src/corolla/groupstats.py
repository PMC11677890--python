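"""Between-species trait comparison with Tukey's HSD.

Pairwise studentized-range tests on a one-way layout, with a compact
letter display (CLD): groups sharing a letter do not differ
significantly at the chosen alpha.  With exactly two groups the HSD is
equivalent to the pooled-variance two-sample t-test (q = sqrt(2)|t|).

Traits are compared on the raw scale.  Petals are treated as independent
observations even though petals from one flower are correlated; the
flower-level non-independence is a documented caveat, not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .aggregate import FlowerSummary
from .geometry import PetalRecord

__all__ = ["PairwiseComparison", "GroupComparisonResult", "tukey_hsd",
           "compare_species_traits"]


@dataclass(frozen=True)
class PairwiseComparison:
    group_1: str
    group_2: str
    mean_diff: float
    q: float          # studentized-range statistic
    p_value: float
    significant: bool


@dataclass
class GroupComparisonResult:
    """HSD outcome for one trait across groups.

    ``letters`` is the compact letter display keyed by group; groups
    sharing any letter are statistically indistinguishable at ``alpha``.
    Letters are assigned in order of descending group mean.
    """

    trait: str
    alpha: float
    means: dict[str, float]
    ns: dict[str, int]
    letters: dict[str, str]
    pairwise: list[PairwiseComparison]

    def significant(self, g1: str, g2: str) -> bool:
        for pc in self.pairwise:
            if {pc.group_1, pc.group_2} == {g1, g2}:
                return pc.significant
        raise KeyError((g1, g2))


def tukey_hsd(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    trait: str = "",
) -> GroupComparisonResult:
    """Tukey's honestly-significant-difference test on a one-way layout.

    For groups i, j with means m_i, m_j and the pooled within-group mean
    square MSW on N - k degrees of freedom,

        q_ij = |m_i - m_j| / sqrt( (MSW / 2) (1/n_i + 1/n_j) )

    and the p-value is the studentized-range tail probability with k
    groups and N - k df (the Tukey-Kramer form for unequal n).

    Raises
    ------
    ValueError
        With fewer than 2 groups or any group of fewer than 2 values.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    k = len(groups)
    ns = {g: int(v.size) for g, v in groups.items()}
    means = {g: float(v.mean()) for g, v in groups.items()}
    n_total = sum(ns.values())
    df = n_total - k
    msw = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values()) / df
    pairwise = []
    for g1, g2 in combinations(groups, 2):
        diff = means[g1] - means[g2]
        if msw == 0:
            q, p = (np.inf, 0.0) if diff != 0 else (0.0, 1.0)
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df))
        pairwise.append(PairwiseComparison(g1, g2, diff, float(q), p,
                                           p < alpha))
    letters = _compact_letter_display(means, pairwise)
    return GroupComparisonResult(trait=trait, alpha=alpha, means=means,
                                 ns=ns, letters=letters, pairwise=pairwise)


def _compact_letter_display(
    means: Mapping[str, float],
    pairwise: Sequence[PairwiseComparison],
) -> dict[str, str]:
    """Insert-and-absorb CLD: split letter sets at each significant pair."""
    sets: list[set[str]] = [set(means)]
    for pc in pairwise:
        if not pc.significant:
            continue
        for s in [s for s in sets if pc.group_1 in s and pc.group_2 in s]:
            sets.remove(s)
            for drop in (pc.group_1, pc.group_2):
                cand = s - {drop}
                if cand and not any(cand <= other for other in sets):
                    sets.append(cand)
    # absorb subsets, then letter sets by descending best member mean
    sets = [s for s in sets
            if not any(s < other for other in sets)]
    sets.sort(key=lambda s: -max(means[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {g: [] for g in means}
    for letter, s in zip(alphabet, sets):
        for g in s:
            out[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in out.items()}


#: trait extractors for the standard petal- and flower-level comparisons
PETAL_TRAITS = {
    "A": lambda p: p.A,
    "L": lambda p: p.L,
    "W": lambda p: p.W,
    "W/L": lambda p: p.W / p.L,
}
FLOWER_TRAITS = {
    "A_T": lambda f: f.A_T,
    "W_KS/L_KS": lambda f: f.W_KS / f.L_KS,
}


def compare_species_traits(
    petals: Sequence[PetalRecord] | None = None,
    flowers: Sequence[FlowerSummary] | None = None,
    alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Run the HSD on the standard trait set, grouped by species.

    Petal-level traits: A, L, W, W/L.  Flower-level: A_T, W_KS/L_KS.
    """
    results = []
    if petals:
        for trait, get in PETAL_TRAITS.items():
            by_group: dict[str, list[float]] = {}
            for p in petals:
                by_group.setdefault(p.species, []).append(get(p))
            results.append(tukey_hsd(by_group, alpha=alpha, trait=trait))
    if flowers:
        for trait, get in FLOWER_TRAITS.items():
            by_group = {}
            for f in flowers:
                by_group.setdefault(f.species, []).append(get(f))
            results.append(tukey_hsd(by_group, alpha=alpha, trait=trait))
    if not results:
        raise ValueError("provide petals and/or flowers")
    return results
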