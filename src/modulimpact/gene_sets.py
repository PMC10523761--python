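"""Derivation of analysis gene sets from differential-expression,
splicing and RIP enrichment tables.

The calling rules mirror standard transcriptomic practice for a
knockdown study: a gene is differentially expressed (DE) when its
adjusted p-value is strictly below ``alpha`` and its log2 fold change is
non-zero (signed up/down); alternatively spliced (AS) when any splicing
event for the gene has FDR strictly below ``alpha``; bound in a RIP
pull-down when positively enriched (log2fc > 0) at adjusted p strictly
below ``alpha``.  "Altered" for one knockdown condition is the union
DE-up + DE-down + AS.  All boundary comparisons are strict: a gene at
exactly the threshold is not called.

A tissue expression filter (FPKM strictly greater than a threshold,
default 1) defines the neuronal gene universe, to which every derived
set is restricted before network analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "KnockdownProfile",
    "RipProfile",
    "neuronal_universe",
    "call_de",
    "call_as",
    "call_bound",
    "restrict",
    "restrict_profile",
    "profile_from_tables",
]


@dataclass(frozen=True)
class KnockdownProfile:
    """Gene sets altered by one knockdown condition."""

    condition: str
    de_up: frozenset[str]
    de_down: frozenset[str]
    as_set: frozenset[str]

    def __post_init__(self):
        if self.de_up & self.de_down:
            raise ValueError(
                f"{self.condition}: genes cannot be both up- and down-regulated"
            )

    @property
    def altered(self) -> frozenset[str]:
        """DE (either direction) or AS genes, each counted once."""
        return self.de_up | self.de_down | self.as_set


@dataclass(frozen=True)
class RipProfile:
    """Transcripts bound by one protein in one cellular compartment."""

    protein: str
    compartment: str  # "nuclear" or "cytoplasmic"
    bound: frozenset[str]


def neuronal_universe(
    expression: Mapping[str, float], threshold: float = 1.0
) -> frozenset[str]:
    """Genes expressed in the tissue: FPKM strictly greater than ``threshold``."""
    universe = frozenset(g for g, fpkm in expression.items() if fpkm > threshold)
    if not universe:
        warnings.warn(
            f"no gene exceeds the {threshold} FPKM expression threshold",
            stacklevel=2,
        )
    return universe


def call_de(
    dea: Mapping[str, tuple[float, float | None]], alpha: float = 0.05
) -> tuple[frozenset[str], frozenset[str]]:
    """Call significantly up- and down-regulated genes.

    Missing adjusted p-values are non-significant; a log2 fold change of
    exactly zero has no direction and is excluded from both sets.
    """
    up, down = set(), set()
    for gene, (log2fc, padj) in dea.items():
        if padj is None or not padj < alpha:
            continue
        if log2fc > 0:
            up.add(gene)
        elif log2fc < 0:
            down.add(gene)
    return frozenset(up), frozenset(down)


def call_as(
    splicing_tables: Iterable[Mapping[str, float]] | Mapping[str, float],
    alpha: float = 0.05,
) -> frozenset[str]:
    """Union over splicing tables of genes with FDR < alpha.

    Accepts one gene-level FDR table or a sequence of them (one per
    splicing event class); the result pools every event type.
    """
    if isinstance(splicing_tables, Mapping):
        splicing_tables = [splicing_tables]
    called: set[str] = set()
    for table in splicing_tables:
        called.update(g for g, fdr in table.items() if fdr < alpha)
    return frozenset(called)


def call_bound(
    rip: Mapping[str, tuple[float, float | None]], alpha: float = 0.05
) -> frozenset[str]:
    """Transcripts positively enriched over the control pull-down."""
    return frozenset(
        g
        for g, (log2fc, padj) in rip.items()
        if log2fc > 0 and padj is not None and padj < alpha
    )


def restrict(genes: Iterable[str], universe: Iterable[str]) -> frozenset[str]:
    """Intersect a gene set with the expressed-gene universe."""
    return frozenset(genes) & frozenset(universe)


def restrict_profile(
    profile: KnockdownProfile, universe: Iterable[str]
) -> KnockdownProfile:
    u = frozenset(universe)
    return KnockdownProfile(
        condition=profile.condition,
        de_up=profile.de_up & u,
        de_down=profile.de_down & u,
        as_set=profile.as_set & u,
    )


def profile_from_tables(
    condition: str,
    dea: Mapping[str, tuple[float, float | None]],
    splicing: Iterable[Mapping[str, float]] | Mapping[str, float],
    universe: Iterable[str] | None = None,
    de_alpha: float = 0.05,
    as_alpha: float = 0.05,
) -> KnockdownProfile:
    """Build a :class:`KnockdownProfile` from raw tables, optionally
    restricted to the expressed universe."""
    up, down = call_de(dea, de_alpha)
    as_set = call_as(splicing, as_alpha)
    profile = KnockdownProfile(condition, up, down, as_set)
    if universe is not None:
        profile = restrict_profile(profile, universe)
    return profile
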