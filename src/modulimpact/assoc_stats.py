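"""Association statistics for module-level comparisons.

Three families of tests accompany the impact analysis:

* **Disease-ortholog enrichment** — per-module percentages of genes with
  disease-linked human orthologs, compared between selected and
  non-selected modules with the two-sided Wilcoxon--Mann--Whitney
  rank-sum test.
* **RIP-target prevalence** — fractions of altered (DE/AS) transcripts
  that are bound by at least one of the profiled proteins, compared
  between gene groups with the chi-square test of independence (Yates
  continuity correction by default, matching common 2x2 practice).
* **Exact multi-set intersection** — the null distribution of the
  common intersection of k independent uniform fixed-size subsets of an
  N-gene universe, built by chaining hypergeometric laws: the overlap of
  the first two sets is hypergeometric, and each further set thins the
  running intersection by another hypergeometric draw.  The upper tail
  at the observed overlap is the reported p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .module_library import FunctionalModule, ModuleLibrary

__all__ = [
    "WilcoxonResult",
    "Chi2Result",
    "IntersectionTest",
    "disease_fraction",
    "wilcoxon_rank_sum",
    "chi2_independence",
    "multiset_expected",
    "multiset_intersection_distribution",
    "multiset_intersection_p",
    "compare_selected_vs_rest",
    "rip_prevalence",
]

#: Total sample size up to which the Wilcoxon p-value is computed by
#: exact enumeration (when the data contain no ties).
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # Mann-Whitney U of the first sample
    p: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    p: float
    yates: bool


@dataclass(frozen=True)
class IntersectionTest:
    set_sizes: tuple[int, ...]
    universe_size: int
    observed: int
    expected: float
    p_upper: float

    @property
    def fold(self) -> float:
        return self.observed / self.expected if self.expected > 0 else float("inf")


def disease_fraction(module: FunctionalModule, disease: Mapping[str, bool]) -> float:
    """Percentage of module nodes linked to disease.

    Genes absent from the table count as not linked.
    """
    if module.size == 0:
        raise ValueError("module is empty")
    linked = sum(1 for g in module.nodes if disease.get(g, False))
    return 100.0 * linked / module.size


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> WilcoxonResult:
    """Wilcoxon--Mann--Whitney rank-sum test with midranks for ties.

    The p-value is exact (full enumeration of rank assignments) when the
    pooled sample is small (<= 12) and tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.  The
    switch only affects p-value precision, never the direction.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    if len(set(pooled)) == 1:
        # degenerate: every observation identical, no evidence of shift
        return WilcoxonResult(statistic=len(x) * len(y) / 2.0, p=1.0, method="degenerate")
    has_ties = len(set(pooled)) < len(pooled)
    exact = (len(pooled) <= EXACT_WILCOXON_MAX_N) and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p=min(1.0, float(res.pvalue)),
        method="exact" if exact else "asymptotic",
    )


def chi2_independence(
    table: Sequence[Sequence[int]], yates: bool = True
) -> Chi2Result:
    """Chi-square test of independence for a 2x2 contingency table.

    With ``yates`` the classical continuity-corrected statistic
    ``N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2)`` is used, with the
    correction clipped at zero; without it, the textbook
    ``sum (O - E)^2 / E``.  One degree of freedom.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a table margin is zero")
    if yates:
        num = max(abs(a * d - b * c) - n / 2.0, 0.0)
        chi2 = n * num * num / (r1 * r2 * c1 * c2)
    else:
        chi2 = 0.0
        for obs, row, col in ((a, r1, c1), (b, r1, c2), (c, r2, c1), (d, r2, c2)):
            exp = row * col / n
            chi2 += (obs - exp) ** 2 / exp
    return Chi2Result(chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)), yates=yates)


def multiset_expected(universe_size: int, set_sizes: Sequence[int]) -> float:
    """Expected size of the common intersection of independent uniform
    fixed-size subsets: ``N * prod(n_i / N)``."""
    if any(s > universe_size or s < 0 for s in set_sizes):
        raise ValueError("set sizes must lie in [0, universe_size]")
    expected = float(universe_size)
    for s in set_sizes:
        expected *= s / universe_size
    return expected


def multiset_intersection_distribution(
    universe_size: int, set_sizes: Sequence[int]
) -> np.ndarray:
    """Exact pmf of the common-intersection size of k uniform subsets.

    Index ``x`` of the returned array is ``P(|A_1 ∩ ... ∩ A_k| = x)``.
    Built by chained hypergeometric mixing: the running intersection of
    size ``y`` meets the next subset of size ``n_j`` in
    ``Hypergeom(N, y, n_j)`` elements.
    """
    sizes = list(set_sizes)
    if len(sizes) < 2:
        raise ValueError("at least two sets required")
    if any(s > universe_size or s < 0 for s in sizes):
        raise ValueError("set sizes must lie in [0, universe_size]")
    N = universe_size
    support = min(sizes[0], sizes[1])
    dist = stats.hypergeom.pmf(np.arange(support + 1), N, sizes[0], sizes[1])
    for n_j in sizes[2:]:
        new_support = min(support, n_j)
        ys = np.arange(support + 1)
        xs = np.arange(new_support + 1)
        # transition[y, x] = P(next intersection = x | current = y)
        transition = stats.hypergeom.pmf(xs[None, :], N, ys[:, None], n_j)
        dist = dist @ transition
        support = new_support
    dist = np.clip(dist, 0.0, None)
    return dist / dist.sum()


def multiset_intersection_p(
    universe_size: int, set_sizes: Sequence[int], observed: int
) -> IntersectionTest:
    """Upper-tail p-value for an observed multi-set overlap."""
    if observed < 0 or observed > min(set_sizes):
        raise ValueError("observed overlap must lie in [0, min(set sizes)]")
    dist = multiset_intersection_distribution(universe_size, set_sizes)
    if observed == 0:
        p_upper = 1.0
    elif observed <= len(dist) - 1:
        p_upper = float(dist[observed:].sum())
    else:
        p_upper = 0.0
    return IntersectionTest(
        set_sizes=tuple(set_sizes),
        universe_size=universe_size,
        observed=observed,
        expected=multiset_expected(universe_size, set_sizes),
        p_upper=min(1.0, p_upper),
    )


def compare_selected_vs_rest(
    library: ModuleLibrary | Sequence[FunctionalModule],
    selected_ids: Iterable[str],
    disease: Mapping[str, bool],
) -> tuple[WilcoxonResult, list[float], list[float]]:
    """Two-sided Wilcoxon on per-module disease-linked percentages,
    selected modules versus the rest of the library."""
    sel = set(selected_ids)
    x = [disease_fraction(m, disease) for m in library if m.term_id in sel]
    y = [disease_fraction(m, disease) for m in library if m.term_id not in sel]
    if not x or not y:
        raise ValueError("both selected and non-selected groups must be non-empty")
    return wilcoxon_rank_sum(x, y, alternative="two-sided"), x, y


def rip_prevalence(
    groups: Mapping[str, frozenset[str] | set[str]],
    bound: Iterable[str],
) -> tuple[dict[str, float | None], list[tuple[str, str, Chi2Result]]]:
    """Fraction of each gene group bound in any RIP pull-down, plus a
    2x2 chi-square for every group pair.

    ``groups`` partitions altered genes (e.g. in selected modules / in
    non-selected modules / in no module); ``bound`` pools every
    protein/compartment bound set by union.  Empty groups get a missing
    fraction and are excluded from pairwise tests.
    """
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if set(groups[a]) & set(groups[b]):
                raise ValueError(f"groups {a!r} and {b!r} overlap")
    bound_set = frozenset(bound)
    fractions: dict[str, float | None] = {}
    for name in names:
        genes = set(groups[name])
        fractions[name] = 100.0 * len(genes & bound_set) / len(genes) if genes else None
    tests = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ga, gb = set(groups[a]), set(groups[b])
            if not ga or not gb:
                continue
            table = [
                [len(ga & bound_set), len(ga - bound_set)],
                [len(gb & bound_set), len(gb - bound_set)],
            ]
            # a zero column margin (nothing/everything bound in both
            # groups) leaves the test undefined; skip such pairs
            if min(table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
                continue
            tests.append((a, b, chi2_independence(table)))
    return fractions, tests
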