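"""Functional module extraction from enriched terms.

A functional module is the subgraph of the tissue network induced by the
genes annotated to one enriched term.  Because proteins collaborating in
a process need not all physically interact, a module may consist of
several connected components; however, when the largest component holds
strictly more than a configurable fraction (default 90%) of the induced
nodes, the remaining small "isolated clusters" are discarded and the
module reduces to its largest component.  The library keeps modules
whose final size lies within an inclusive window (default 10 to 100
proteins), chosen to limit term redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import EnrichmentResult, annotation_index

__all__ = [
    "FunctionalModule",
    "ModuleLibrary",
    "extract_module",
    "build_library",
    "redundancy_matrix",
]


@dataclass(frozen=True)
class FunctionalModule:
    term_id: str
    term_name: str
    nodes: frozenset[str]
    #: connected components of the retained induced subgraph,
    #: sorted by decreasing size (ties: smallest node id)
    components: tuple[frozenset[str], ...]

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ModuleLibrary:
    modules: tuple[FunctionalModule, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)

    def by_id(self) -> dict[str, FunctionalModule]:
        return {m.term_id: m for m in self.modules}


def _sorted_components(g: nx.Graph) -> tuple[frozenset[str], ...]:
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return tuple(sorted(comps, key=lambda c: (-len(c), min(c))))


def extract_module(
    term_genes: Iterable[str],
    term_id: str,
    term_name: str,
    net: nx.Graph,
    largest_component_fraction: float = 0.9,
) -> FunctionalModule | None:
    """Induce a term's genes on the tissue network and apply the
    isolated-cluster rule.

    A node without any within-module interaction forms a singleton
    component.  If the largest component covers strictly more than
    ``largest_component_fraction`` of the induced nodes, only the
    largest component is retained; otherwise all components are kept.
    Returns ``None`` when no term gene is present in the network.
    """
    induced_nodes = set(term_genes) & set(net.nodes)
    if not induced_nodes:
        return None
    sub = net.subgraph(induced_nodes)
    comps = _sorted_components(sub)
    largest = comps[0]
    if len(largest) / len(induced_nodes) > largest_component_fraction:
        comps = (largest,)
    nodes = frozenset().union(*comps)
    return FunctionalModule(term_id=term_id, term_name=term_name,
                            nodes=nodes, components=comps)


def build_library(
    enriched: Sequence[EnrichmentResult],
    annotations: Iterable[tuple[str, str, str]],
    net: nx.Graph,
    min_size: int = 10,
    max_size: int = 100,
    largest_component_fraction: float = 0.9,
) -> ModuleLibrary:
    """One module per enriched term, filtered to the inclusive size window.

    The size filter is applied after the isolated-cluster discard, i.e.
    on the retained node count.
    """
    names, members = annotation_index(annotations)
    modules = []
    for res in enriched:
        if not res.enriched:
            continue
        mod = extract_module(
            members.get(res.term_id, set()),
            res.term_id,
            names.get(res.term_id, res.term_name),
            net,
            largest_component_fraction,
        )
        if mod is not None and min_size <= mod.size <= max_size:
            modules.append(mod)
    modules.sort(key=lambda m: m.term_id)
    return ModuleLibrary(
        modules=tuple(modules),
        provenance={
            "min_size": min_size,
            "max_size": max_size,
            "largest_component_fraction": largest_component_fraction,
            "n_enriched_terms": sum(1 for r in enriched if r.enriched),
        },
    )


def redundancy_matrix(
    library: ModuleLibrary | Sequence[FunctionalModule],
) -> list[tuple[str, str, float, float]]:
    """Pairwise module overlap: (term_a, term_b, jaccard, overlap_coef).

    Reported for inspection only; no filtering is applied here.
    """
    modules = list(library)
    if len(modules) < 2:
        raise ValueError("redundancy requires at least two modules")
    rows = []
    for i, a in enumerate(modules):
        for b in modules[i + 1 :]:
            inter = len(a.nodes & b.nodes)
            union = len(a.nodes | b.nodes)
            jaccard = inter / union if union else 0.0
            overlap = inter / min(a.size, b.size)
            rows.append((a.term_id, b.term_id, jaccard, overlap))
    return rows
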