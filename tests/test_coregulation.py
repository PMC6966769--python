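"""Arc weighting, minimum-weight V-shapes, selection and assembly."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_digraph
from coregnet.coregulation import (
    VShape,
    assign_weights,
    brute_force_min_vshape,
    filter_and_assemble,
    min_weight_vshape,
    optimal_vshape_arcs,
    pvalue_histogram,
    select_coregulatory_arcs,
    weighted_graph,
)


class TestAssignWeights:
    def arcs(self, ps):
        return [(f"s{i}", f"t{i}", p) for i, p in enumerate(ps)]

    def test_eight_arcs_two_per_class(self):
        out = assign_weights(self.arcs([1e-8, 2e-8, 3e-8, 4e-8, 5e-8, 6e-8, 7e-8, 8e-8]))
        assert [a.weight for a in out] == [1, 1, 2, 2, 4, 4, 8, 8]

    def test_four_arcs_one_per_class(self):
        out = assign_weights(self.arcs([4e-8, 3e-8, 2e-8, 1e-8]))
        assert [(a.p_value, a.weight) for a in out] == [
            (1e-8, 1), (2e-8, 2), (3e-8, 4), (4e-8, 8)
        ]

    def test_remainder_goes_to_lowest_p_group(self):
        out = assign_weights(self.arcs([1e-8, 2e-8, 3e-8, 4e-8, 5e-8]))
        assert [a.weight for a in out] == [1, 1, 2, 4, 8]

    def test_weight_nondecreasing_with_p(self):
        rng = np.random.default_rng(0)
        out = assign_weights(self.arcs(rng.uniform(0, 1e-4, size=23)))
        ws = [a.weight for a in out]
        assert ws == sorted(ws)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            assign_weights([])


class TestMinWeightVShape:
    def test_unique_two_arc_vshape(self):
        g = nx.DiGraph()
        g.add_edge("C", "A", weight=1)
        g.add_edge("C", "B", weight=2)
        res = min_weight_vshape(g, "A", "B")
        assert res is not None
        w, shape = res
        assert w == 3 and shape.apex == "C"

    def test_same_target_fatal(self):
        g = nx.DiGraph([("C", "A", {"weight": 1})])
        with pytest.raises(ValueError):
            min_weight_vshape(g, "A", "A")

    def test_shared_middle_node_forces_lower_apex(self):
        # C -> m -> A and C -> m -> B share m: apex C is invalid, m works
        g = nx.DiGraph()
        g.add_edge("C", "m", weight=1)
        g.add_edge("m", "A", weight=1)
        g.add_edge("m", "B", weight=1)
        res = min_weight_vshape(g, "A", "B")
        assert res is not None
        w, shape = res
        assert shape.apex == "m" and w == 2

    def test_no_vshape_returns_none(self):
        g = nx.DiGraph()
        g.add_edge("C", "A", weight=1)
        g.add_node("B")
        assert min_weight_vshape(g, "A", "B") is None

    @pytest.mark.parametrize("seed", range(100))
    def test_flow_equals_enumeration(self, seed):
        """Exhaustive path-pair search agrees with the min-cost flow on
        random digraphs of up to 8 nodes."""
        g = random_weighted_digraph(seed)
        bf = brute_force_min_vshape(g, 0, 1)
        fl = min_weight_vshape(g, 0, 1)
        if bf is None:
            assert fl is None
            return
        assert fl is not None and fl[0] == bf[0]
        fl[1].validate()
        assert optimal_vshape_arcs(g, 0, 1) == bf[1]

    def test_relabeling_invariance(self):
        g = random_weighted_digraph(3)
        res = min_weight_vshape(g, 0, 1)
        mapping = {n: f"node_{n * 7 % 97}" for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        res2 = min_weight_vshape(h, mapping[0], mapping[1])
        assert (res is None) == (res2 is None)
        if res is not None:
            assert res[0] == res2[0]


class TestOptimalVShapeArcs:
    def test_two_disjoint_optima_union(self):
        g = nx.DiGraph()
        for apex in ("C1", "C2"):
            g.add_edge(apex, "A", weight=1)
            g.add_edge(apex, "B", weight=1)
        arcs = optimal_vshape_arcs(g, "A", "B")
        assert arcs == {("C1", "A"), ("C1", "B"), ("C2", "A"), ("C2", "B")}

    def test_unique_optimum_exact_arcs(self):
        g = nx.DiGraph()
        g.add_edge("C", "A", weight=1)
        g.add_edge("C", "B", weight=1)
        g.add_edge("D", "A", weight=4)
        g.add_edge("D", "B", weight=4)
        assert optimal_vshape_arcs(g, "A", "B") == {("C", "A"), ("C", "B")}


class TestSelection:
    def planted(self, seed=0, **kw):
        from coregnet.synthetic_data import plant_network

        net, truth = plant_network(seed=seed, **kw)
        wg = weighted_graph(net.graph)
        cats = {o: set(c) for o, c in truth.categories.items()}
        return wg, cats, truth

    def test_single_operon_category_contributes_nothing(self):
        g = nx.DiGraph()
        g.add_node("F", kind="tf")
        g.add_node("op1", kind="operon")
        g.add_edge("F", "op1", weight=1, p_value=1e-6)
        sel = select_coregulatory_arcs(g, {"op1": {"cat"}})
        assert sel == {}

    def test_shared_pair_provenance_lists_both_categories(self):
        g = nx.DiGraph()
        g.add_node("C", kind="tf")
        for o in ("a", "b"):
            g.add_node(o, kind="operon")
            g.add_edge("C", o, weight=1, p_value=1e-6)
        sel = select_coregulatory_arcs(
            g, {"a": {"s1", "s2"}, "b": {"s1", "s2"}}
        )
        for arc in (("C", "a"), ("C", "b")):
            assert {c for c, _, _ in sel[arc]} == {"s1", "s2"}

    def test_planted_network_recovered_exactly(self):
        wg, cats, truth = self.planted(seed=5)
        sel = set(select_coregulatory_arcs(wg, cats))
        assert sel == set(truth.signal_arcs)

    def test_selected_arcs_subset_of_affinity_arcs(self):
        wg, cats, _ = self.planted(seed=6)
        sel = select_coregulatory_arcs(wg, cats)
        assert set(sel) <= set(wg.edges)

    def test_apex_of_every_vshape_is_tf(self):
        wg, cats, _ = self.planted(seed=7)
        for a in [n for n, d in wg.nodes(data=True) if d["kind"] == "operon"][:3]:
            for b in [n for n, d in wg.nodes(data=True) if d["kind"] == "operon"]:
                if a >= b:
                    continue
                res = min_weight_vshape(wg, a, b)
                if res is not None:
                    assert wg.nodes[res[1].apex]["kind"] == "tf"


class TestFilterAndAssemble:
    def graph(self):
        g = nx.DiGraph()
        g.add_node("F", kind="tf")
        for o, p in (("a", 9e-5), ("b", 9.5e-5)):
            g.add_node(o, kind="operon")
            g.add_edge("F", o, p_value=p, weight=1)
        return g

    def test_threshold_boundary_retained(self):
        g = self.graph()
        sel = {("F", "a"): {("s", "a", "b")}, ("F", "b"): {("s", "a", "b")}}
        net = filter_and_assemble(g, sel, final_arc_p_threshold=9e-5)
        # p = 9e-5 exactly survives; p = 9.5e-5 is removed
        assert set(net.graph.edges) == {("F", "a")}

    def test_family_collapse_merges_parallel_arcs(self):
        g = nx.DiGraph()
        g.add_node("F", kind="tf")
        for o, p in (("op1", 1e-6), ("op2", 1e-7)):
            g.add_node(o, kind="operon")
            g.add_edge("F", o, p_value=p, weight=1)
        sel = {("F", "op1"): {("s", "x", "y")}, ("F", "op2"): {("s", "x", "y")}}
        net = filter_and_assemble(g, sel, family_map={"op1": "G", "op2": "G"})
        assert set(net.graph.edges) == {("F", "G")}
        assert net.graph["F"]["G"]["p_value"] == 1e-7
        assert net.graph.nodes["G"]["kind"] == "tf"

    def test_all_above_threshold_empty(self):
        g = self.graph()
        sel = {("F", "a"): set(), ("F", "b"): set()}
        net = filter_and_assemble(g, sel, final_arc_p_threshold=1e-9)
        assert net.graph.number_of_edges() == 0

    def test_tightening_threshold_never_adds_arcs(self):
        g = self.graph()
        sel = {("F", "a"): set(), ("F", "b"): set()}
        loose = filter_and_assemble(g, sel, final_arc_p_threshold=1e-4)
        tight = filter_and_assemble(g, sel, final_arc_p_threshold=9e-5)
        assert set(tight.graph.edges) <= set(loose.graph.edges)


class TestPvalueHistogram:
    def test_direct_binning(self):
        edges, counts = pvalue_histogram([1e-5, 2e-5, 9e-5], bin_width=2e-5)
        assert list(counts) == [2, 0, 0, 0, 1]
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(1e-4)

    def test_empty(self):
        _, counts = pvalue_histogram([], bin_width=1e-5)
        assert len(counts) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        ps = rng.uniform(1e-8, 1e-4, size=int(rng.integers(1, 60)))
        _, counts = pvalue_histogram(ps, bin_width=7e-6)
        assert counts.sum() == len(ps)
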