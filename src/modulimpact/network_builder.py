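"""Construction of the unspecific and tissue-filtered interaction networks.

The interactome is an undirected simple graph over gene identifiers:
self-interactions and duplicate pairs are removed on construction, and
nodes left without any interaction partner are dropped.  The
tissue-specific network keeps only interactions where *both* partners
are expressed in the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

__all__ = [
    "EmptyNetworkError",
    "NetworkSummary",
    "build_network",
    "filter_by_universe",
    "network_summary",
]


class EmptyNetworkError(ValueError):
    """Cleaning or filtering left no interaction."""


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    mean_degree: float
    max_degree: int


def build_network(pairs: Iterable[tuple[str, str]], label: str = "unspecific") -> nx.Graph:
    """Build a cleaned simple graph from raw interaction pairs.

    Reversed duplicates collapse because the graph is undirected;
    self-loops are discarded.  Raises :class:`EmptyNetworkError` when no
    proper interaction survives.
    """
    g = nx.Graph(label=label)
    for a, b in pairs:
        if a != b:
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError("no interaction left after removing self-loops")
    return g


def filter_by_universe(net: nx.Graph, universe: Iterable[str], label: str = "tissue") -> nx.Graph:
    """Keep only edges whose both endpoints are expressed.

    Isolated nodes produced by the filtering are dropped, so the result
    satisfies the same cleaning invariants as :func:`build_network`.
    Idempotent, and monotone in the universe.
    """
    u = set(universe)
    g = nx.Graph(label=label)
    for a, b in net.edges:
        if a in u and b in u:
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError("no interaction between expressed genes")
    return g


def network_summary(net: nx.Graph) -> NetworkSummary:
    degrees = [d for _, d in net.degree]
    return NetworkSummary(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        n_components=nx.number_connected_components(net),
        mean_degree=sum(degrees) / len(degrees),
        max_degree=max(degrees),
    )
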