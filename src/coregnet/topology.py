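"""Topological analysis of the co-regulatory network.

Covers: exact enumeration of directed simple cycles (Johnson's algorithm),
all minimum feedback arc sets (exact hitting set over the cycles),
longest-path hierarchy levels for each feedback-arc choice, the tree
distance of the TF-TF subgraph (arcs minus a maximum branching), primary
regulators (TF nodes with no incoming regulation), per-regulator pathway
reachability and exclusivity tables, and minimal sets of regulators able to
control an entire pathway category.

Reachability treats TF family nodes and operon nodes uniformly; since
metabolic operons have no outgoing arcs, every regulatory path runs through
TF nodes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd
from networkx.algorithms.tree.branchings import maximum_branching

Arc = tuple[str, str]


# ---------------------------------------------------------------------------
# cycles and feedback arc sets


def enumerate_cycles(graph: nx.DiGraph, cap: int = 10_000) -> list[list[str]]:
    """All directed simple cycles, as node sequences (Johnson enumeration).

    Raises if the count exceeds ``cap`` — such a network is not
    near-hierarchical and the exact FAS machinery would not apply.
    """
    cycles: list[list[str]] = []
    for cyc in nx.simple_cycles(graph):
        cycles.append(list(cyc))
        if len(cycles) > cap:
            raise RuntimeError(
                f"more than {cap} directed cycles; raise the cap only if an "
                "exact minimum feedback arc set is still wanted"
            )
    return cycles


def _cycle_arcs(cycle: list[str]) -> frozenset[Arc]:
    return frozenset(
        (cycle[i], cycle[(i + 1) % len(cycle)]) for i in range(len(cycle))
    )


def min_feedback_arc_sets(
    graph: nx.DiGraph, max_sets: int = 1_000
) -> tuple[int, list[frozenset[Arc]]]:
    """Exact minimum feedback arc sets: smallest arc sets hitting every
    directed simple cycle.

    Branch-and-bound on an uncovered cycle (branching over its arcs); all
    optima are returned, truncated at ``max_sets``. A DAG yields (0, [{}]).
    """
    cycles = [_cycle_arcs(c) for c in enumerate_cycles(graph)]
    if not cycles:
        return 0, [frozenset()]

    best_size = len(cycles)  # hitting one arc per cycle always works
    solutions: set[frozenset[Arc]] = set()

    def extend(chosen: frozenset[Arc], remaining: list[frozenset[Arc]]) -> None:
        nonlocal best_size, solutions
        if not remaining:
            if len(chosen) < best_size:
                best_size = len(chosen)
                solutions = {chosen}
            elif len(chosen) == best_size:
                solutions.add(chosen)
            return
        if len(chosen) + 1 > best_size:
            return
        # branch on the uncovered cycle with the fewest arcs
        pivot = min(remaining, key=len)
        for arc in sorted(pivot):
            nxt = [c for c in remaining if arc not in c]
            extend(chosen | {arc}, nxt)

    extend(frozenset(), cycles)
    out = sorted(solutions, key=sorted)
    if len(out) > max_sets:
        out = out[:max_sets]
    return best_size, out


# ---------------------------------------------------------------------------
# hierarchy levels


def assign_levels(
    graph: nx.DiGraph, fas: frozenset[Arc] | set[Arc] = frozenset()
) -> tuple[dict[str, int], int]:
    """Longest-path layering after removing the feedback arcs.

    level(v) = 1 for sources; otherwise 1 + max level over non-feedback
    in-neighbors. Every non-feedback arc runs from a strictly lower to a
    strictly higher level. Returns (level per node, number of levels).
    """
    g = graph.copy()
    g.remove_edges_from(fas)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("graph minus the feedback arc set still has a cycle")
    level: dict[str, int] = {}
    for v in nx.topological_sort(g):
        preds = list(g.predecessors(v))
        level[v] = 1 + max((level[u] for u in preds), default=0)
    n_levels = max(level.values(), default=0)
    for u, v in g.edges:
        assert level[u] < level[v]
    return level, n_levels


def levels_per_fas(graph: nx.DiGraph) -> list[dict]:
    """Level assignment and level count for every minimum feedback arc set.

    The level count can differ between equally small feedback-arc choices,
    so it is reported per choice rather than as a single number.
    """
    size, sets = min_feedback_arc_sets(graph)
    out = []
    for fas in sets:
        level, n = assign_levels(graph, fas)
        out.append({"feedback_arcs": sorted(fas), "n_levels": n, "levels": level})
    return out


# ---------------------------------------------------------------------------
# tree distance of the TF-TF subgraph


def tree_distance(tf_subgraph: nx.DiGraph) -> tuple[int, float]:
    """Minimum number of arcs to remove so the TF-TF subgraph becomes a
    branching (acyclic, every in-degree <= 1), and that number as a
    percentage of the arcs (1 decimal).

    Equals |arcs| minus the size of a maximum branching (Edmonds, unit
    weights). An n-node graph keeps at most n - 1 arcs, so a spanning
    branching is the best case.
    """
    m = tf_subgraph.number_of_edges()
    if m == 0:
        return 0, 0.0
    branching = maximum_branching(tf_subgraph, attr="__unit__", default=1)
    removals = m - branching.number_of_edges()
    return removals, round(100.0 * removals / m, 1)


def tf_subgraph(graph: nx.DiGraph) -> nx.DiGraph:
    tf = [n for n, d in graph.nodes(data=True) if d.get("kind") == "tf"]
    return graph.subgraph(tf).copy()


# ---------------------------------------------------------------------------
# primary regulators and reachability tables


def primary_regulators(graph: nx.DiGraph) -> set[str]:
    """TF family nodes with in-degree 0: regulators controlled by no other
    regulator inside the network."""
    return {
        n for n, d in graph.nodes(data=True)
        if d.get("kind") == "tf" and graph.in_degree(n) == 0
    }


def reachable_operons(graph: nx.DiGraph, regulator: str) -> set[str]:
    """Operon nodes reachable from a regulator by a directed path
    (direct binding or chain regulatory cascades)."""
    if regulator not in graph:
        return set()
    reach = nx.descendants(graph, regulator)
    return {n for n in reach if graph.nodes[n].get("kind") == "operon"}


def _category_members(
    graph: nx.DiGraph, categories: dict[str, set[str]]
) -> dict[str, set[str]]:
    by_cat: dict[str, set[str]] = {}
    for node, cats in categories.items():
        if node in graph and graph.nodes[node].get("kind") == "operon":
            for cat in cats:
                by_cat.setdefault(cat, set()).add(node)
    return by_cat


def _order_categories(by_cat: dict[str, set[str]]) -> list[str]:
    # ascending operon count, then name: the ordering used for the report
    return sorted(by_cat, key=lambda c: (len(by_cat[c]), c))


def regulatory_table(
    graph: nx.DiGraph,
    categories: dict[str, set[str]],
    regulators: list[str] | set[str],
) -> pd.DataFrame:
    """Category x regulator counts of reachable operons.

    Cell (S, R) = number of category-S operons reachable from regulator R;
    the "Operons" column holds the per-category operon count in the network
    (an operon in two categories counts in both rows). A TOTAL row sums
    every column. Columns are ordered by descending total, rows by ascending
    category size.
    """
    by_cat = _category_members(graph, categories)
    cat_order = _order_categories(by_cat)
    reach = {r: reachable_operons(graph, r) for r in regulators}
    reg_order = sorted(
        regulators, key=lambda r: (-len(reach[r]), r)
    )
    rows = []
    for cat in cat_order:
        members = by_cat[cat]
        row = {"category": cat, "Operons": len(members)}
        for r in reg_order:
            row[r] = len(members & reach[r])
        rows.append(row)
    total = {"category": "TOTAL", "Operons": sum(r["Operons"] for r in rows)}
    for r in reg_order:
        total[r] = sum(row[r] for row in rows)
    rows.append(total)
    return pd.DataFrame(rows, columns=["category", "Operons", *reg_order])


def exclusivity_table(
    graph: nx.DiGraph,
    categories: dict[str, set[str]],
    primaries: set[str] | None = None,
) -> pd.DataFrame:
    """Operons controlled exclusively by a single primary regulator.

    An operon counts under primary P iff P is the only primary regulator
    from which it is reachable. The "Total" column holds the per-category
    exclusive count formatted "n (p%)" with the percentage of the category
    size rounded to the nearest integer.
    """
    if primaries is None:
        primaries = primary_regulators(graph)
    by_cat = _category_members(graph, categories)
    cat_order = _order_categories(by_cat)
    reach = {p: reachable_operons(graph, p) for p in primaries}
    reg_order = sorted(primaries, key=lambda r: (-len(reach[r]), r))

    exclusive_of: dict[str, str] = {}
    for op in {o for members in by_cat.values() for o in members}:
        controlling = [p for p in reg_order if op in reach[p]]
        if len(controlling) == 1:
            exclusive_of[op] = controlling[0]

    rows = []
    for cat in cat_order:
        members = by_cat[cat]
        counts = {
            p: sum(1 for op in members if exclusive_of.get(op) == p)
            for p in reg_order
        }
        n_excl = sum(counts.values())
        pct = int(round(100.0 * n_excl / len(members))) if members else 0
        row = {
            "category": cat,
            "Operons": len(members),
            "Total": f"{n_excl} ({pct}%)",
        }
        row.update(counts)
        rows.append(row)
    return pd.DataFrame(rows, columns=["category", "Operons", "Total", *reg_order])


# ---------------------------------------------------------------------------
# minimal controlling sets


def minimal_controlling_sets(
    graph: nx.DiGraph,
    category_operons: set[str],
    candidate_regulators: list[str] | set[str],
) -> dict:
    """Smallest regulator subsets whose joint reachability covers the whole
    category; exhaustive search in increasing cardinality.

    Returns {"min_size", "sets", "unique", "feasible"}; infeasible coverage
    (even using every candidate) is reported, not raised.
    """
    candidates = sorted(candidate_regulators)
    if len(candidates) > 20:
        raise ValueError("exhaustive search bounded at 20 candidate regulators")
    targets = {
        o for o in category_operons
        if o in graph and graph.nodes[o].get("kind") == "operon"
    }
    if not targets:
        return {"min_size": 0, "sets": [frozenset()], "unique": True, "feasible": True}
    reach = {r: reachable_operons(graph, r) & targets for r in candidates}
    full = set().union(*reach.values()) if reach else set()
    if full != targets:
        return {"min_size": None, "sets": [], "unique": False, "feasible": False}
    for k in range(1, len(candidates) + 1):
        found = [
            frozenset(combo)
            for combo in combinations(candidates, k)
            if set().union(*(reach[r] for r in combo)) == targets
        ]
        if found:
            return {
                "min_size": k,
                "sets": found,
                "unique": len(found) == 1,
                "feasible": True,
            }
    raise AssertionError("unreachable: full coverage was verified above")


def greedy_cover_size(
    graph: nx.DiGraph, category_operons: set[str], candidates: list[str]
) -> int | None:
    """Greedy set-cover upper bound on the minimal controlling set size
    (cross-check for the exhaustive search)."""
    targets = {
        o for o in category_operons
        if o in graph and graph.nodes[o].get("kind") == "operon"
    }
    reach = {r: reachable_operons(graph, r) & targets for r in candidates}
    uncovered = set(targets)
    size = 0
    while uncovered:
        best = max(candidates, key=lambda r: (len(reach[r] & uncovered), r))
        gain = len(reach[best] & uncovered)
        if gain == 0:
            return None
        uncovered -= reach[best]
        size += 1
    return size


# ---------------------------------------------------------------------------
# hubs and the assembled report


def hub_report(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-TF degree table with the maxima flagged (ties all flagged)."""
    tf = sorted(n for n, d in graph.nodes(data=True) if d.get("kind") == "tf")
    rows = [
        {
            "node": n,
            "in_degree": graph.in_degree(n),
            "out_degree": graph.out_degree(n),
            "total_degree": graph.in_degree(n) + graph.out_degree(n),
        }
        for n in tf
    ]
    df = pd.DataFrame(rows, columns=["node", "in_degree", "out_degree", "total_degree"])
    if df.empty:
        for col in ("max_in", "max_out", "max_total"):
            df[col] = []
        return df
    for col, flag in (
        ("in_degree", "max_in"), ("out_degree", "max_out"), ("total_degree", "max_total"),
    ):
        df[flag] = df[col] == df[col].max()
    return df.sort_values(["total_degree", "node"], ascending=[False, True]).reset_index(drop=True)


@dataclass
class TopologyReport:
    """Every derived topology table for one co-regulatory network."""

    cycles: list[list[str]]
    min_fas_size: int
    min_feedback_arc_sets: list[frozenset[Arc]]
    levels_by_fas: list[dict]
    tf_tree_removals: int
    tf_tree_removal_pct: float
    n_tf_tf_arcs: int
    primary_regulators: set[str]
    regulatory_table: pd.DataFrame
    exclusivity_table: pd.DataFrame
    controlling_sets: dict[str, dict] = field(default_factory=dict)
    controlling_sets_all_tfs: dict[str, dict] = field(default_factory=dict)
    hub_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze(graph: nx.DiGraph, categories: dict[str, set[str]]) -> TopologyReport:
    """Run the full topology suite on a co-regulatory network."""
    size, sets = min_feedback_arc_sets(graph)
    cycles = enumerate_cycles(graph)
    lv = levels_per_fas(graph)
    tfs = tf_subgraph(graph)
    removals, pct = tree_distance(tfs)
    primaries = primary_regulators(graph)
    reg_tab = regulatory_table(graph, categories, primaries)
    excl_tab = exclusivity_table(graph, categories, primaries)
    by_cat = _category_members(graph, categories)
    all_tfs = sorted(n for n, d in graph.nodes(data=True) if d.get("kind") == "tf")
    ctrl = {
        cat: minimal_controlling_sets(graph, members, primaries)
        for cat, members in sorted(by_cat.items())
    }
    ctrl_all = {
        cat: minimal_controlling_sets(graph, members, all_tfs[:20])
        for cat, members in sorted(by_cat.items())
        if len(all_tfs) <= 20
    }
    return TopologyReport(
        cycles=cycles,
        min_fas_size=size,
        min_feedback_arc_sets=sets,
        levels_by_fas=lv,
        tf_tree_removals=removals,
        tf_tree_removal_pct=pct,
        n_tf_tf_arcs=tfs.number_of_edges(),
        primary_regulators=primaries,
        regulatory_table=reg_tab,
        exclusivity_table=excl_tab,
        controlling_sets=ctrl,
        controlling_sets_all_tfs=ctrl_all,
        hub_table=hub_report(graph),
    )
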