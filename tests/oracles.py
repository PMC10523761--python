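"""Independent brute-force oracles used to validate the analytical
statistics.  Everything here works by explicit enumeration of the
sample space and stays deliberately naive."""

from itertools import combinations


def hypergeom_upper_enum(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating every size-n draw from N items of
    which the first K are marked."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def mannwhitney_u(x, y) -> float:
    """U statistic of sample x (count of pairs where x beats y, ties 0.5)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def wilcoxon_exact_enum(x, y, alternative: str = "two-sided") -> float:
    """Exact rank-sum p-value by enumerating every split of the pooled
    sample into groups of the observed sizes (valid without ties)."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = mannwhitney_u(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        us.append(mannwhitney_u(xs, ys))
    total = len(us)
    p_ge = sum(1 for u in us if u >= u_obs) / total
    p_le = sum(1 for u in us if u <= u_obs) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def multiset_tail_enum(N: int, sizes, m: int) -> float:
    """P(|common intersection| >= m) for independent uniform fixed-size
    subsets, by full enumeration of every subset combination."""
    subset_lists = [list(combinations(range(N), s)) for s in sizes]
    hits, total = _enum_all(subset_lists, m)
    return hits / total


def _enum_all(subset_lists, m):
    hits = total = 0

    def walk(depth, current):
        nonlocal hits, total
        if depth == len(subset_lists):
            total += 1
            if len(current) >= m:
                hits += 1
            return
        for subset in subset_lists[depth]:
            walk(depth + 1, current & set(subset))

    for first in subset_lists[0]:
        walk(1, set(first))
    return hits, total


def multiset_mean_enum(N: int, sizes) -> float:
    """Mean intersection size by the same enumeration."""
    subset_lists = [list(combinations(range(N), s)) for s in sizes]
    acc = cnt = 0

    def walk(depth, current):
        nonlocal acc, cnt
        if depth == len(subset_lists):
            acc += len(current)
            cnt += 1
            return
        for subset in subset_lists[depth]:
            walk(depth + 1, current & set(subset))

    for first in subset_lists[0]:
        walk(1, set(first))
    return acc / cnt


def chi2_textbook(table) -> float:
    """Uncorrected chi-square as sum (O - E)^2 / E."""
    (a, b), (c, d) = table
    n = a + b + c + d
    chi2 = 0.0
    for obs, row, col in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        e = row * col / n
        chi2 += (obs - e) ** 2 / e
    return chi2
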