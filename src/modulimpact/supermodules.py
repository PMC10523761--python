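"""Coalescing of selected modules into super-modules.

Selected modules frequently share many genes because related annotation
terms describe overlapping processes.  To obtain a condensed map, the
selected modules are arranged in a weighted overlap graph — edge weight
is the number of commonly altered transcripts, mirroring how such maps
are usually drawn — and modules whose node sets overlap strongly
(Jaccard index at or above a threshold, default 0.2) are merged.
Super-modules are the connected components of the thresholded graph,
which makes the grouping deterministic and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .gene_sets import KnockdownProfile
from .module_library import FunctionalModule

__all__ = [
    "SuperModule",
    "build_overlap_graph",
    "coalesce",
    "supermodule_overlap",
]


@dataclass(frozen=True)
class SuperModule:
    id: str
    member_modules: frozenset[str]
    nodes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.nodes)


def build_overlap_graph(
    selected: Sequence[FunctionalModule],
    profiles: Sequence[KnockdownProfile],
) -> nx.Graph:
    """Weighted overlap graph over the selected modules.

    Every selected module is a vertex.  For each module pair the edge
    carries ``shared_altered`` — the number of genes common to both
    modules and altered in at least one condition — and the node-set
    Jaccard index.  Pairs sharing no altered gene get no edge.
    """
    if not selected:
        raise ValueError("at least one selected module required")
    altered_any = frozenset().union(*(p.altered for p in profiles)) if profiles else frozenset()
    g = nx.Graph()
    for m in selected:
        g.add_node(m.term_id, module=m)
    for i, a in enumerate(selected):
        for b in selected[i + 1 :]:
            common = a.nodes & b.nodes
            shared_altered = len(common & altered_any)
            if shared_altered == 0:
                continue
            jaccard = len(common) / len(a.nodes | b.nodes)
            g.add_edge(a.term_id, b.term_id,
                       shared_altered=shared_altered, jaccard=jaccard)
    return g


def coalesce(graph: nx.Graph, min_jaccard: float = 0.2) -> tuple[SuperModule, ...]:
    """Merge modules into super-modules by thresholded connectivity.

    Edges with Jaccard below ``min_jaccard`` are dropped; the connected
    components of what remains are the super-modules (singletons
    allowed).  A super-module's id derives from its smallest member term
    id, so the output is stable across runs and input orders.
    """
    kept = nx.Graph()
    kept.add_nodes_from(graph.nodes)
    for a, b, data in graph.edges(data=True):
        if data["jaccard"] >= min_jaccard:
            kept.add_edge(a, b)
    supers = []
    for comp in nx.connected_components(kept):
        members = frozenset(comp)
        nodes = frozenset().union(*(graph.nodes[m]["module"].nodes for m in members))
        supers.append(
            SuperModule(id=f"SM:{min(members)}", member_modules=members, nodes=nodes)
        )
    return tuple(sorted(supers, key=lambda s: s.id))


def supermodule_overlap(a: SuperModule, b: SuperModule) -> float:
    """Node overlap between two super-modules, as a percentage of the
    smaller one (overlap coefficient x 100)."""
    if a.id == b.id:
        raise ValueError("overlap is defined between distinct super-modules")
    return 100.0 * len(a.nodes & b.nodes) / min(a.size, b.size)
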