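"""Cycles, feedback arc sets, hierarchy levels, tree distance, primaries,
reachability/exclusivity tables and minimal controlling sets."""

from itertools import chain, combinations

import networkx as nx
import numpy as np
import pytest

from coregnet.topology import (
    assign_levels,
    enumerate_cycles,
    exclusivity_table,
    greedy_cover_size,
    hub_report,
    levels_per_fas,
    min_feedback_arc_sets,
    minimal_controlling_sets,
    primary_regulators,
    reachable_operons,
    regulatory_table,
    tree_distance,
)


def random_digraph(seed, n_lo=4, n_hi=8, p=0.3):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g


def brute_force_cycles(g):
    """All simple cycles by rotating-normalized DFS enumeration."""
    cycles = set()
    nodes = list(g.nodes)

    def walk(path):
        u = path[-1]
        for v in g.successors(u):
            if v == path[0] and len(path) > 1:
                k = path.index(min(path))
                cycles.add(tuple(path[k:] + path[:k]))
            elif v not in path:
                walk(path + [v])

    for n in nodes:
        walk([n])
    # 2-cycles and self loops normalized identically by min-rotation
    return {c for c in cycles}


class TestCycles:
    def test_dag_empty(self):
        assert enumerate_cycles(nx.DiGraph([("a", "b"), ("b", "c")])) == []

    def test_two_cycle(self):
        cycles = enumerate_cycles(nx.DiGraph([("X", "Y"), ("Y", "X")]))
        assert len(cycles) == 1 and set(cycles[0]) == {"X", "Y"}

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force(self, seed):
        g = random_digraph(seed, n_hi=8)
        ours = {tuple(c[c.index(min(c)):] + c[: c.index(min(c))])
                for c in enumerate_cycles(g)}
        assert ours == brute_force_cycles(g)

    def test_cap_exceeded_fatal(self):
        g = nx.complete_graph(7, nx.DiGraph())
        with pytest.raises(RuntimeError, match="cycles"):
            enumerate_cycles(g, cap=10)


def brute_force_min_fas(g):
    arcs = list(g.edges)
    for k in range(len(arcs) + 1):
        hits = [
            frozenset(sub) for sub in combinations(arcs, k)
            if nx.is_directed_acyclic_graph(
                g.edge_subgraph([e for e in arcs if e not in sub]).copy()
                if len(arcs) > k else nx.DiGraph()
            )
        ]
        if hits:
            return k, set(hits)
    return 0, {frozenset()}


class TestMinFeedbackArcSets:
    def test_dag(self):
        size, sets = min_feedback_arc_sets(nx.DiGraph([("a", "b")]))
        assert size == 0 and sets == [frozenset()]

    def test_toy_cycle_structure(self, toy_cycle_graph):
        """A 2-cycle plus two cycles sharing a path: every optimum pairs one
        2-cycle arc with one shared-path arc."""
        size, sets = min_feedback_arc_sets(toy_cycle_graph)
        assert size == 2
        expected = {
            frozenset({xy, pq})
            for xy in (("X", "Y"), ("Y", "X"))
            for pq in (("P", "Q"), ("Q", "R"))
        }
        assert set(sets) == expected

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_exhaustive_subset_search(self, seed):
        g = random_digraph(seed, n_lo=3, n_hi=7, p=0.35)

        def residual_acyclic(sub):
            h = g.copy()
            h.remove_edges_from(sub)
            return nx.is_directed_acyclic_graph(h)

        arcs = list(g.edges)
        expected_size, expected = None, set()
        for k in range(len(arcs) + 1):
            found = {
                frozenset(sub)
                for sub in combinations(arcs, k)
                if residual_acyclic(sub)
            }
            if found:
                expected_size, expected = k, found
                break
        size, sets = min_feedback_arc_sets(g)
        assert size == expected_size
        assert set(sets) == expected

    def test_residual_always_acyclic(self, toy_cycle_graph):
        _, sets = min_feedback_arc_sets(toy_cycle_graph)
        for fas in sets:
            h = toy_cycle_graph.copy()
            h.remove_edges_from(fas)
            assert nx.is_directed_acyclic_graph(h)


class TestAssignLevels:
    def test_chain(self):
        lv, n = assign_levels(nx.DiGraph([("a", "b"), ("b", "c")]))
        assert lv == {"a": 1, "b": 2, "c": 3} and n == 3

    def test_longest_path_convention(self):
        lv, n = assign_levels(nx.DiGraph([("a", "c"), ("a", "b"), ("b", "c")]))
        assert lv["c"] == 3 and n == 3

    def test_invalid_fas_fatal(self):
        g = nx.DiGraph([("x", "y"), ("y", "x")])
        with pytest.raises(ValueError, match="cycle"):
            assign_levels(g, frozenset())

    def test_levels_reported_per_fas_choice(self, toy_cycle_graph):
        per = levels_per_fas(toy_cycle_graph)
        assert len(per) == 4
        for entry in per:
            assert entry["n_levels"] >= 1
            # every non-feedback arc strictly increases the level
            fas = set(map(tuple, entry["feedback_arcs"]))
            for u, v in toy_cycle_graph.edges:
                if (u, v) not in fas:
                    assert entry["levels"][u] < entry["levels"][v]


def brute_force_max_branching(g):
    arcs = list(g.edges)
    best = 0
    for r in range(len(arcs), -1, -1):
        if r <= best:
            break
        for sub in combinations(arcs, r):
            h = nx.DiGraph(sub)
            if max((d for _, d in h.in_degree()), default=0) <= 1 and \
               nx.is_directed_acyclic_graph(h):
                best = max(best, r)
                break
    return best


class TestTreeDistance:
    def test_arborescence_needs_no_removal(self):
        g = nx.DiGraph([("r", "a"), ("r", "b"), ("a", "c")])
        assert tree_distance(g) == (0, 0.0)

    def test_in_degree_two_needs_one_removal(self):
        g = nx.DiGraph([("a", "c"), ("b", "c")])
        removals, pct = tree_distance(g)
        assert removals == 1 and pct == 50.0

    def test_empty(self):
        assert tree_distance(nx.DiGraph()) == (0, 0.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_brute_force(self, seed):
        g = random_digraph(seed, n_lo=3, n_hi=7, p=0.3)
        removals, pct = tree_distance(g)
        m = g.number_of_edges()
        assert removals == m - brute_force_max_branching(g)
        if m:
            assert pct == round(100.0 * removals / m, 1)


def net_with(arcs, tf_nodes, op_nodes):
    g = nx.DiGraph()
    for n in tf_nodes:
        g.add_node(n, kind="tf")
    for n in op_nodes:
        g.add_node(n, kind="operon")
    for u, v in arcs:
        g.add_edge(u, v, p_value=1e-6)
    return g


class TestPrimaryRegulators:
    def test_source_tf_is_primary(self):
        g = net_with([("F", "G"), ("F", "op1")], ["F", "G"], ["op1"])
        assert primary_regulators(g) == {"F"}

    def test_two_cycle_has_no_primary(self):
        g = net_with([("F", "G"), ("G", "F")], ["F", "G"], [])
        assert primary_regulators(g) == set()

    def test_all_sources(self):
        g = net_with([("F", "op1"), ("G", "op1")], ["F", "G"], ["op1"])
        assert primary_regulators(g) == {"F", "G"}


class TestRegulatoryTable:
    def test_cascade_counts(self):
        g = net_with([("R", "F"), ("F", "op1")], ["R", "F"], ["op1"])
        tab = regulatory_table(g, {"op1": {"S"}}, ["R"]).set_index("category")
        assert tab.loc["S", "R"] == 1
        assert tab.loc["TOTAL", "Operons"] == 1

    def test_unreachable_operon_is_zero(self):
        g = net_with([("R", "op1")], ["R", "Q"], ["op1", "op2"])
        tab = regulatory_table(g, {"op1": {"S"}, "op2": {"S"}}, ["R", "Q"])
        row = tab.set_index("category").loc["S"]
        assert row["R"] == 1 and row["Q"] == 0 and row["Operons"] == 2

    def test_multi_category_operon_counts_in_both(self):
        g = net_with([("R", "op1")], ["R"], ["op1"])
        tab = regulatory_table(g, {"op1": {"S1", "S2"}}, ["R"]).set_index("category")
        assert tab.loc["S1", "R"] == 1 and tab.loc["S2", "R"] == 1
        assert tab.loc["TOTAL", "Operons"] == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        tfs = [f"T{i}" for i in range(5)]
        ops = [f"o{i}" for i in range(5)]
        g = nx.DiGraph()
        for t in tfs:
            g.add_node(t, kind="tf")
        for o in ops:
            g.add_node(o, kind="operon")
        for u in tfs:
            for v in tfs + ops:
                if u != v and rng.random() < 0.25:
                    g.add_edge(u, v)
        cats = {o: {"S"} for o in ops}
        closure = nx.transitive_closure(g)
        tab = regulatory_table(g, cats, tfs).set_index("category")
        for t in tfs:
            expected = sum(1 for o in ops if closure.has_edge(t, o))
            assert tab.loc["S", t] == expected


class TestExclusivityTable:
    def graph(self):
        # op1 exclusive to P1; op2 reachable from both; op3 exclusive to P2
        return net_with(
            [("P1", "op1"), ("P1", "op2"), ("P2", "op2"), ("P2", "op3")],
            ["P1", "P2"], ["op1", "op2", "op3"],
        )

    def test_shared_operon_excluded_everywhere(self):
        tab = exclusivity_table(self.graph(), {o: {"S"} for o in ("op1", "op2", "op3")})
        row = tab.set_index("category").loc["S"]
        assert row["P1"] == 1 and row["P2"] == 1
        assert row["Total"] == "2 (67%)"

    def test_percentage_rounding(self):
        g = net_with([("P1", "op1"), ("P1", "op2")], ["P1"], ["op1", "op2", "op3"])
        tab = exclusivity_table(g, {o: {"S"} for o in ("op1", "op2", "op3")})
        assert tab.set_index("category").loc["S", "Total"] == "2 (67%)"

    @pytest.mark.parametrize("seed", range(8))
    def test_exclusive_counts_bounded_by_reachability(self, seed):
        rng = np.random.default_rng(seed)
        tfs = [f"P{i}" for i in range(4)]
        ops = [f"o{i}" for i in range(6)]
        g = nx.DiGraph()
        for t in tfs:
            g.add_node(t, kind="tf")
        for o in ops:
            g.add_node(o, kind="operon")
        for t in tfs:
            for o in ops:
                if rng.random() < 0.3:
                    g.add_edge(t, o)
        cats = {o: {"S"} for o in ops}
        prim = primary_regulators(g)
        if not prim:
            return
        excl = exclusivity_table(g, cats, prim).set_index("category")
        reg = regulatory_table(g, cats, prim).set_index("category")
        total_excl = 0
        for p in prim:
            assert excl.loc["S", p] <= reg.loc["S", p]
            total_excl += excl.loc["S", p]
        assert total_excl <= len(ops)


class TestMinimalControllingSets:
    def test_single_covering_regulator(self):
        g = net_with([("R", "o1"), ("R", "o2")], ["R", "Q"], ["o1", "o2"])
        res = minimal_controlling_sets(g, {"o1", "o2"}, ["R", "Q"])
        assert res["min_size"] == 1 and res["sets"] == [frozenset({"R"})]
        assert res["unique"]

    def test_complementary_pair_unique(self):
        g = net_with([("R", "o1"), ("Q", "o2")], ["R", "Q"], ["o1", "o2"])
        res = minimal_controlling_sets(g, {"o1", "o2"}, ["R", "Q"])
        assert res["min_size"] == 2 and res["unique"]

    def test_infeasible_reported_not_fatal(self):
        g = net_with([("R", "o1")], ["R"], ["o1", "o2"])
        res = minimal_controlling_sets(g, {"o1", "o2"}, ["R"])
        assert not res["feasible"] and res["sets"] == []

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_by_greedy_cover(self, seed):
        rng = np.random.default_rng(seed)
        tfs = [f"R{i}" for i in range(5)]
        ops = [f"o{i}" for i in range(6)]
        g = nx.DiGraph()
        for t in tfs:
            g.add_node(t, kind="tf")
        for o in ops:
            g.add_node(o, kind="operon")
        for t in tfs:
            for o in ops:
                if rng.random() < 0.4:
                    g.add_edge(t, o)
        res = minimal_controlling_sets(g, set(ops), tfs)
        greedy = greedy_cover_size(g, set(ops), tfs)
        if res["feasible"]:
            assert greedy is not None and res["min_size"] <= greedy
            for s in res["sets"]:
                covered = set()
                for r in s:
                    covered |= reachable_operons(g, r)
                assert covered >= set(ops)
        else:
            assert greedy is None


class TestHubReport:
    def test_star_out_hub_flagged(self):
        g = net_with([("H", "F"), ("H", "G"), ("F", "op1")], ["H", "F", "G"], ["op1"])
        df = hub_report(g).set_index("node")
        assert df.loc["H", "max_out"]
        assert not df.loc["F", "max_out"]

    def test_total_is_in_plus_out(self):
        g = net_with([("H", "F"), ("F", "H"), ("F", "G")], ["H", "F", "G"], [])
        df = hub_report(g)
        assert (df.total_degree == df.in_degree + df.out_degree).all()

    def test_ties_all_flagged(self):
        g = net_with([("A", "B"), ("B", "A")], ["A", "B"], [])
        df = hub_report(g).set_index("node")
        assert df.max_total.all()
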