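import networkx as nx
import pytest

from modulimpact.enrichment import EnrichmentResult
from modulimpact.module_library import (
    ModuleLibrary,
    build_library,
    extract_module,
    redundancy_matrix,
)


def chain(nodes):
    g = nx.Graph()
    for a, b in zip(nodes, nodes[1:]):
        g.add_edge(a, b)
    return g


def union(*graphs):
    g = nx.Graph()
    for h in graphs:
        g.add_edges_from(h.edges)
    return g


def component_graph(*sizes):
    """Disjoint path components of the given sizes, nodes 'C<i>N<j>'."""
    graphs = []
    offset = 0
    for i, s in enumerate(sizes):
        names = [f"C{i}N{j}" for j in range(s)]
        if s == 1:
            g = nx.Graph()
            g.add_node(names[0])
            # singleton needs an anchor edge elsewhere so the cleaned
            # network contains it: wire to a dummy hub outside the term
            g.add_edge(names[0], f"HUB{i}")
        else:
            g = chain(names)
        graphs.append(g)
        offset += s
    return union(*graphs)


class TestIsolatedClusterRule:
    def test_over_ninety_percent_keeps_largest_only(self):
        net = component_graph(11, 1)
        genes = {n for n in net.nodes if not n.startswith("HUB")}
        m = extract_module(genes, "T", "t", net)
        assert m.size == 11
        assert len(m.components) == 1

    def test_even_split_keeps_both(self):
        net = component_graph(6, 6)
        genes = {n for n in net.nodes if not n.startswith("HUB")}
        m = extract_module(genes, "T", "t", net)
        assert m.size == 12
        assert len(m.components) == 2

    def test_exactly_ninety_percent_keeps_both(self):
        net = component_graph(9, 1)
        genes = {n for n in net.nodes if not n.startswith("HUB")}
        m = extract_module(genes, "T", "t", net)
        assert m.size == 10  # 9/10 == 0.9 is NOT > 0.9
        assert len(m.components) == 2

    def test_singleton_nodes_count_as_components(self):
        net = union(chain(["A", "B", "C"]), chain(["X", "Y"]))
        m = extract_module({"A", "B", "C", "X"}, "T", "t", net)
        assert len(m.components) == 2
        assert frozenset({"X"}) in m.components

    def test_no_induced_nodes_returns_none(self):
        net = chain(["A", "B"])
        assert extract_module({"Z"}, "T", "t", net) is None

    def test_gene_order_invariance(self):
        net = component_graph(8, 3)
        genes = [n for n in net.nodes if not n.startswith("HUB")]
        a = extract_module(genes, "T", "t", net)
        b = extract_module(list(reversed(genes)), "T", "t", net)
        assert a == b

    def test_post_rule_invariant(self):
        """After the rule, either one component remains or the largest
        covers at most 90% of retained nodes."""
        for sizes in [(11, 1), (9, 1), (6, 6), (20, 2), (18, 2)]:
            net = component_graph(*sizes)
            genes = {n for n in net.nodes if not n.startswith("HUB")}
            m = extract_module(genes, "T", "t", net)
            if len(m.components) > 1:
                assert len(m.components[0]) / m.size <= 0.9


class TestBuildLibrary:
    def make_inputs(self, sizes):
        net = nx.Graph()
        anno = []
        enriched = []
        for i, s in enumerate(sizes):
            nodes = [f"T{i}N{j}" for j in range(s)]
            for a, b in zip(nodes, nodes[1:]):
                net.add_edge(a, b)
            for n in nodes:
                anno.append((f"T{i}", f"term {i}", n))
            enriched.append(
                EnrichmentResult(f"T{i}", f"term {i}", s, s, 1, 1, 0.0,
                                 fdr=0.0, enriched=True)
            )
        return enriched, anno, net

    def test_inclusive_size_window(self):
        enriched, anno, net = self.make_inputs([9, 10, 100, 101])
        lib = build_library(enriched, anno, net)
        assert sorted(m.size for m in lib) == [10, 100]

    def test_no_enriched_terms_empty_library(self):
        enriched, anno, net = self.make_inputs([20])
        enriched = [
            EnrichmentResult("T0", "t", 1, 1, 1, 1, 1.0, fdr=1.0, enriched=False)
        ]
        assert len(build_library(enriched, anno, net)) == 0

    def test_shared_gene_appears_in_several_modules(self):
        net = chain(["A", "B", *(f"N{i}" for i in range(10))])
        anno = [("T1", "x", n) for n in list(net.nodes)[:11]]
        anno += [("T2", "y", n) for n in list(net.nodes)[1:12]]
        enriched = [
            EnrichmentResult("T1", "x", 1, 1, 1, 1, 0.0, fdr=0.0, enriched=True),
            EnrichmentResult("T2", "y", 1, 1, 1, 1, 0.0, fdr=0.0, enriched=True),
        ]
        lib = build_library(enriched, anno, net)
        assert len(lib) == 2
        shared = lib.modules[0].nodes & lib.modules[1].nodes
        assert shared  # overlapping terms coexist in the library


def test_planted_terms_yield_in_bound_modules(default_bundle, default_result):
    lib_ids = {m.term_id for m in default_result.library}
    assert default_bundle.truth.planted_term_ids <= lib_ids
    by_id = default_result.library.by_id()
    for term, core in default_bundle.truth.planted_genes.items():
        assert by_id[term].nodes == core  # satellites discarded, core kept


class TestRedundancy:
    def make(self, nodes_a, nodes_b):
        from modulimpact.module_library import FunctionalModule

        def mod(tid, nodes):
            return FunctionalModule(tid, tid, frozenset(nodes), (frozenset(nodes),))

        return ModuleLibrary((mod("A", nodes_a), mod("B", nodes_b)))

    def test_identical(self):
        lib = self.make({"1", "2"}, {"1", "2"})
        [(a, b, j, o)] = redundancy_matrix(lib)
        assert j == o == 1.0

    def test_disjoint(self):
        lib = self.make({"1"}, {"2"})
        [(_, _, j, o)] = redundancy_matrix(lib)
        assert j == o == 0.0

    def test_arithmetic(self):
        a = {str(i) for i in range(10)}
        b = {str(i) for i in range(5, 25)}
        [(_, _, j, o)] = redundancy_matrix(self.make(a, b))
        assert j == pytest.approx(0.2)
        assert o == pytest.approx(0.5)

    def test_requires_two_modules(self):
        from modulimpact.module_library import FunctionalModule

        lib = ModuleLibrary((FunctionalModule("A", "A", frozenset("x"), (frozenset("x"),)),))
        with pytest.raises(ValueError):
            redundancy_matrix(lib)
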