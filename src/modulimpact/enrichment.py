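"""Term over-representation of a candidate gene set with a
randomization-based false-discovery estimate.

The candidate set (here: nodes of the tissue-filtered network) is tested
against a background (nodes of the unspecific network) one annotation
term at a time with the hypergeometric upper tail.  Because term tests
are strongly dependent — the same genes appear under many terms — the
FDR is estimated empirically: the candidate set is resampled uniformly
at random from the background ``n_rand`` times, all term p-values are
recomputed on each resample, and the FDR at an observed p-value ``t`` is

    fdr(t) = E_null[ #terms with p <= t ] / max(1, #observed terms with p <= t)

made monotone non-decreasing in ``t`` by a cumulative maximum from the
smallest observed p.  A term is flagged enriched when its (monotonized)
FDR is at most the configured threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper",
    "annotation_index",
    "enrich_terms",
    "randomization_fdr",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # annotated genes in candidate set
    K: int  # annotated genes in background
    n: int  # candidate-set size
    N: int  # background size
    p: float  # hypergeometric upper tail P(X >= k)
    fdr: float | None = None
    enriched: bool | None = None


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts annotated genes in a uniform draw of ``n`` genes from a
    universe of ``N`` containing ``K`` annotated ones.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N, got N={N} K={K} n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K,n), got k={k} K={K} n={n}")
    if k == 0:
        return 1.0
    # survival function at k-1; scipy evaluates the tail in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def annotation_index(
    annotations: Iterable[tuple[str, str, str]]
) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Flat annotation records -> (term_id -> name, term_id -> gene set)."""
    names: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for term_id, term_name, gene in annotations:
        names.setdefault(term_id, term_name)
        members.setdefault(term_id, set()).add(gene)
    return names, members


def enrich_terms(
    candidate: Iterable[str],
    background: Iterable[str],
    annotations: Iterable[tuple[str, str, str]],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail test for every annotation term.

    Annotations are restricted to the background before counting; terms
    with no background gene are dropped.  Results are sorted by term id
    and carry no FDR yet (see :func:`randomization_fdr`).
    """
    cand = frozenset(candidate)
    bg = frozenset(background)
    if not cand <= bg:
        raise ValueError("candidate set must be a subset of the background")
    names, members = annotation_index(annotations)
    results = []
    for term_id in sorted(members):
        in_bg = members[term_id] & bg
        if not in_bg:
            continue
        k = len(in_bg & cand)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=names[term_id],
                k=k,
                K=len(in_bg),
                n=len(cand),
                N=len(bg),
                p=hypergeom_upper(len(bg), len(in_bg), len(cand), k),
            )
        )
    return results


def randomization_fdr(
    results: Sequence[EnrichmentResult],
    candidate_size: int,
    background: Iterable[str],
    annotations: Iterable[tuple[str, str, str]],
    n_rand: int = 1000,
    seed: int | np.random.Generator = 0,
    fdr_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """Attach randomization FDR estimates and enrichment flags.

    Each randomization draws a uniform candidate set of ``candidate_size``
    genes from the background and recomputes every term's p-value; term
    sizes and the gene-to-term structure are preserved, only the
    candidate labelling is randomized.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if not results:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg = sorted(set(background))
    N = len(bg)
    n = candidate_size
    idx = {g: i for i, g in enumerate(bg)}
    _, members = annotation_index(annotations)

    terms = [r.term_id for r in results]
    # membership matrix restricted to background
    M = np.zeros((len(terms), N), dtype=np.float32)
    for t, term_id in enumerate(terms):
        for g in members.get(term_id, ()):
            if g in idx:
                M[t, idx[g]] = 1.0
    K = M.sum(axis=1).astype(int)

    # per-term lookup: p-value of the upper tail for each possible overlap k
    lookups = []
    for t in range(len(terms)):
        kmax = min(int(K[t]), n)
        ks = np.arange(kmax + 1)
        lookups.append(stats.hypergeom.sf(ks - 1, N, int(K[t]), n))

    # null overlaps: each column of `pick` is one random candidate set
    null_p = np.empty((n_rand, len(terms)))
    chunk = max(1, int(2e7 // max(N, 1)))  # bound memory of the random matrix
    done = 0
    while done < n_rand:
        r = min(chunk, n_rand - done)
        u = rng.random((r, N))
        order = np.argpartition(u, n - 1, axis=1)[:, :n]
        pick = np.zeros((r, N), dtype=np.float32)
        np.put_along_axis(pick, order, 1.0, axis=1)
        k_null = (pick @ M.T).round().astype(int)  # r x T
        for t in range(len(terms)):
            null_p[done : done + r, t] = lookups[t][np.minimum(k_null[:, t], len(lookups[t]) - 1)]
        done += r

    obs_p = np.array([r.p for r in results])
    flat_null = np.sort(null_p.ravel())
    order = np.argsort(obs_p, kind="stable")
    fdr = np.empty_like(obs_p)
    sorted_obs = np.sort(obs_p)
    for rank, i in enumerate(order):
        t = obs_p[i]
        mean_null = np.searchsorted(flat_null, t, side="right") / n_rand
        n_obs = np.searchsorted(sorted_obs, t, side="right")
        fdr[i] = mean_null / max(1, n_obs)
    # monotonize from the smallest p upward
    running = 0.0
    for i in order:
        running = max(running, fdr[i])
        fdr[i] = running

    return [
        replace(r, fdr=float(fdr[i]), enriched=bool(fdr[i] <= fdr_threshold))
        for i, r in enumerate(results)
    ]
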