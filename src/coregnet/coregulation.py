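"""Confident co-regulation arc selection by minimum-weight V-shapes.

A V-shape for a pair of target nodes (A, B) is the union of two directed
paths that start at a common apex C and end at A and B respectively,
sharing no node other than C. If a V-shape exists, its apex is a candidate
common regulator of A and B. Parsimony prefers V-shapes that use few arcs
and arcs with small binding p-values; both criteria combine by giving each
arc an integer weight from its p-value quantile (1, 2, 4, 8 by default;
weight 1 for the lowest p-values) and selecting V-shapes of minimum total
weight.

The co-regulatory network is the union, over every unordered pair of
metabolic operons sharing a pathway category, of the arcs appearing in at
least one minimum-weight V-shape for the pair, followed by a final p-value
filter and TF-family collapsing.

Minimum-weight V-shapes are found exactly: for each candidate apex, two
units of min-cost flow on the node-split transformation (every node other
than the apex and the two targets has throughput capacity 1) yield the
cheapest pair of node-disjoint paths. Arc membership in *some* optimal
V-shape is decided by re-optimizing with the arc forced to carry flow. An
explicit enumerator over simple-path pairs is provided for small graphs as
an independent oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Arc = tuple[str, str]


@dataclass(frozen=True)
class WeightedArc:
    source: str
    target: str
    p_value: float
    weight: int


@dataclass
class VShape:
    """Two node-disjoint directed paths from one apex to two targets."""

    apex: str
    path_a: list[Arc]  # ends at target a
    path_b: list[Arc]  # ends at target b
    total_weight: int

    @property
    def arcs(self) -> frozenset[Arc]:
        return frozenset(self.path_a) | frozenset(self.path_b)

    def validate(self) -> None:
        for path in (self.path_a, self.path_b):
            if not path:
                raise ValueError("V-shape paths need at least one arc")
            if path[0][0] != self.apex:
                raise ValueError("path does not start at the apex")
            for (u1, v1), (u2, v2) in zip(path, path[1:]):
                if v1 != u2:
                    raise ValueError("path arcs are not consecutive")
        na = {v for arc in self.path_a for v in arc} - {self.apex}
        nb = {v for arc in self.path_b for v in arc} - {self.apex}
        if na & nb:
            raise ValueError("paths share a node other than the apex")


# ---------------------------------------------------------------------------
# arc weights


def assign_weights(
    arcs: list[tuple[str, str, float]],
    weight_classes: tuple[int, ...] = (1, 2, 4, 8),
) -> list[WeightedArc]:
    """Split arcs into len(weight_classes) groups of (as near as possible)
    equal size by ascending p-value and assign the class weights in order.

    Ties and non-divisible counts: stable sort by (p_value, source, target);
    when the count is not divisible by the class count the remainder goes to
    the lowest-p groups (sizes differ by at most one, larger groups first).
    """
    if not arcs:
        raise ValueError("assign_weights requires at least one arc")
    k = len(weight_classes)
    ordered = sorted(arcs, key=lambda a: (a[2], a[0], a[1]))
    n = len(ordered)
    base, rem = divmod(n, k)
    out: list[WeightedArc] = []
    idx = 0
    for j, w in enumerate(weight_classes):
        size = base + (1 if j < rem else 0)
        for _ in range(size):
            s, t, p = ordered[idx]
            out.append(WeightedArc(source=s, target=t, p_value=p, weight=w))
            idx += 1
    return out


def weighted_graph(graph: nx.DiGraph, weight_classes=(1, 2, 4, 8)) -> nx.DiGraph:
    """Copy of ``graph`` with integer ``weight`` attributes assigned from the
    p-value quantile classes (computed over the whole network)."""
    arcs = [(u, v, d["p_value"]) for u, v, d in graph.edges(data=True)]
    g = graph.copy()
    for wa in assign_weights(arcs, weight_classes):
        g[wa.source][wa.target]["weight"] = wa.weight
    return g


# ---------------------------------------------------------------------------
# minimum-weight V-shapes (exact, min-cost flow)


def _candidate_apexes(graph: nx.DiGraph, a: str, b: str) -> list[str]:
    # An apex needs two distinct out-arcs (paths share only the apex).
    return [
        n for n in graph.nodes
        if n not in (a, b) and graph.out_degree(n) >= 2
    ]


def _flow_network(
    graph: nx.DiGraph, apex: str, a: str, b: str
) -> nx.DiGraph:
    """Node-split flow network: 2 units from the apex to targets a and b,
    every other node with throughput 1, arc costs = weights."""
    f = nx.DiGraph()
    f.add_node(("out", apex), demand=-2)
    f.add_node(("in", a), demand=1)
    f.add_node(("in", b), demand=1)
    for v in graph.nodes:
        if v in (apex, a, b):
            continue
        f.add_edge(("in", v), ("out", v), capacity=1, weight=0)
    for u, v, d in graph.edges(data=True):
        if u in (a, b):       # targets are endpoints only
            continue
        if v == apex:         # the apex is a pure source
            continue
        f.add_edge(("out", u), ("in", v), capacity=1, weight=int(d["weight"]))
    return f


def _min_flow_cost(graph: nx.DiGraph, apex: str, a: str, b: str):
    """(cost, flow dict) of the cheapest 2-unit node-disjoint flow from
    ``apex`` to {a, b}, or None if infeasible."""
    f = _flow_network(graph, apex, a, b)
    if ("out", apex) not in f or ("in", a) not in f or ("in", b) not in f:
        return None
    try:
        flow = nx.min_cost_flow(f)
    except (nx.NetworkXUnfeasible, nx.NetworkXUnbounded):
        return None
    cost = nx.cost_of_flow(f, flow)
    return cost, flow


def _walk_paths(flow: dict, apex: str, a: str, b: str) -> dict[str, list[Arc]]:
    """Decompose a 2-unit node-capacitated flow into its two paths.

    Node capacities make the decomposition unique: each intermediate node
    carries at most one unit, so following positive flow out of the apex
    twice traces the two node-disjoint paths."""
    residual = {u: dict(vs) for u, vs in flow.items()}
    paths: dict[str, list[Arc]] = {}
    for _ in range(2):
        path: list[Arc] = []
        node = ("out", apex)
        while True:
            nxt = next(v for v, units in residual[node].items() if units > 0)
            residual[node][nxt] -= 1
            if node[0] == "out" and nxt[0] == "in":
                path.append((node[1], nxt[1]))
            if nxt in (("in", a), ("in", b)):
                paths[nxt[1]] = path
                break
            node = nxt
    return paths


def _dijkstra_to(graph: nx.DiGraph, target: str) -> dict[str, int]:
    """Weighted distance from every node to ``target``."""
    return nx.single_source_dijkstra_path_length(
        graph.reverse(copy=False), target, weight="weight"
    )


def min_weight_vshape(
    graph: nx.DiGraph, a: str, b: str
) -> tuple[int, VShape] | None:
    """Exact minimum total weight over all apexes and node-disjoint path
    pairs; returns (weight, one optimal V-shape) or None when no V-shape
    connects a and b. Edges must carry integer ``weight`` attributes."""
    if a == b:
        raise ValueError("V-shape targets must be distinct")
    if a not in graph or b not in graph:
        return None
    dist_a = _dijkstra_to(graph, a)
    dist_b = _dijkstra_to(graph, b)

    best: tuple[int, str, dict] | None = None
    apexes = _candidate_apexes(graph, a, b)
    # Lower bound: two independent shortest paths ignoring disjointness.
    ranked = sorted(
        (
            (dist_a[c] + dist_b[c], c)
            for c in apexes
            if c in dist_a and c in dist_b
        ),
    )
    for lb, c in ranked:
        if best is not None and lb >= best[0]:
            break
        res = _min_flow_cost(graph, c, a, b)
        if res is None:
            continue
        cost, flow = res
        if best is None or cost < best[0]:
            best = (cost, c, flow)
    if best is None:
        return None
    cost, apex, flow = best
    paths = _walk_paths(flow, apex, a, b)
    shape = VShape(
        apex=apex, path_a=paths[a], path_b=paths[b], total_weight=cost
    )
    shape.validate()
    return cost, shape


def optimal_vshape_arcs(graph: nx.DiGraph, a: str, b: str) -> set[Arc]:
    """All arcs belonging to >= 1 minimum-weight V-shape for (a, b).

    Implemented by forced-arc re-optimization: arc e is in some optimum iff,
    for some apex achieving the global optimum W*, the cheapest flow forced
    through e still costs W*. Explicit enumeration (see
    :func:`enumerate_vshapes`) can be exponential and is kept as an oracle.
    """
    opt = min_weight_vshape(graph, a, b)
    if opt is None:
        return set()
    w_star, _ = opt
    dist_a = _dijkstra_to(graph, a)
    dist_b = _dijkstra_to(graph, b)

    optimal_apexes = []
    for c in _candidate_apexes(graph, a, b):
        lb = dist_a.get(c, math.inf) + dist_b.get(c, math.inf)
        if lb > w_star:
            continue
        res = _min_flow_cost(graph, c, a, b)
        if res is not None and res[0] == w_star:
            optimal_apexes.append(c)

    arcs: set[Arc] = set()
    for c in optimal_apexes:
        reach = nx.descendants(graph, c) | {c}
        for u, v, d in graph.edges(data=True):
            if (u, v) in arcs:
                continue
            if u in (a, b) or v == c:
                continue
            if u not in reach:
                continue
            if _forced_cost(graph, c, a, b, (u, v), int(d["weight"])) == w_star:
                arcs.add((u, v))
    return arcs


def _forced_cost(
    graph: nx.DiGraph, apex: str, a: str, b: str, arc: Arc, arc_weight: int
) -> int | None:
    """Min cost of the 2-unit flow from ``apex`` forced through ``arc``."""
    f = _flow_network(graph, apex, a, b)
    u, v = arc
    u_out, v_in = ("out", u), ("in", v)
    if not f.has_edge(u_out, v_in):
        return None
    # lower-bound transformation: ship one unit across the arc up front
    f.remove_edge(u_out, v_in)
    f.nodes[u_out]["demand"] = f.nodes[u_out].get("demand", 0) + 1
    f.nodes[v_in]["demand"] = f.nodes[v_in].get("demand", 0) - 1
    try:
        flow = nx.min_cost_flow(f)
    except (nx.NetworkXUnfeasible, nx.NetworkXUnbounded):
        return None
    return nx.cost_of_flow(f, flow) + arc_weight


# ---------------------------------------------------------------------------
# explicit enumeration oracle (small graphs only)


def enumerate_vshapes(graph: nx.DiGraph, a: str, b: str, max_nodes: int = 12):
    """Yield every V-shape connecting a and b by explicit enumeration of
    simple-path pairs. Exponential; intended as a test oracle (n <= 12)."""
    if graph.number_of_nodes() > max_nodes:
        raise ValueError("enumerate_vshapes is an oracle for small graphs only")
    for c in graph.nodes:
        if c in (a, b):
            continue
        paths_a = [
            [(u, v) for u, v in path]
            for path in nx.all_simple_edge_paths(graph, c, a)
        ]
        paths_b = [
            [(u, v) for u, v in path]
            for path in nx.all_simple_edge_paths(graph, c, b)
        ]
        for pa in paths_a:
            if any(b in arc for arc in pa):
                continue
            na = {x for arc in pa for x in arc} - {c}
            for pb in paths_b:
                if any(a in arc for arc in pb):
                    continue
                nb = {x for arc in pb for x in arc} - {c}
                if na & nb:
                    continue
                w = sum(graph[u][v]["weight"] for u, v in pa) + sum(
                    graph[u][v]["weight"] for u, v in pb
                )
                yield VShape(apex=c, path_a=pa, path_b=pb, total_weight=w)


def brute_force_min_vshape(graph: nx.DiGraph, a: str, b: str):
    """(min weight, set of arcs in >= 1 optimum) by explicit enumeration."""
    best_w: int | None = None
    arcs: set[Arc] = set()
    for shape in enumerate_vshapes(graph, a, b):
        if best_w is None or shape.total_weight < best_w:
            best_w = shape.total_weight
            arcs = set(shape.arcs)
        elif shape.total_weight == best_w:
            arcs |= shape.arcs
    if best_w is None:
        return None
    return best_w, arcs


# ---------------------------------------------------------------------------
# selection over same-category operon pairs


def select_coregulatory_arcs(
    graph: nx.DiGraph, categories: dict[str, set[str]]
) -> dict[Arc, set[tuple[str, str, str]]]:
    """Union of optimal V-shape arcs over every unordered same-category
    operon pair; returns arc -> provenance set of (category, a, b) triples.

    ``graph`` must carry ``weight`` edge attributes (see
    :func:`weighted_graph`); ``categories`` maps operon node -> categories.
    Pairs with no connecting V-shape contribute nothing (logged).
    """
    by_cat: dict[str, list[str]] = {}
    for node, cats in categories.items():
        if node not in graph:
            continue
        for cat in cats:
            by_cat.setdefault(cat, []).append(node)

    provenance: dict[Arc, set[tuple[str, str, str]]] = {}
    for cat in sorted(by_cat):
        members = sorted(by_cat[cat])
        for a, b in combinations(members, 2):
            arcs = optimal_vshape_arcs(graph, a, b)
            if not arcs:
                logger.info("no V-shape connects %s and %s (category %s)", a, b, cat)
                continue
            for arc in arcs:
                provenance.setdefault(arc, set()).add((cat, a, b))
    return provenance


# ---------------------------------------------------------------------------
# final network assembly


@dataclass
class CoRegulatoryNetwork:
    """The selected co-regulatory sub-network with pathway categories."""

    graph: nx.DiGraph
    categories: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[Arc, set[tuple[str, str, str]]] = field(default_factory=dict)

    @property
    def tf_family_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "tf"}

    @property
    def metabolic_operon_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "operon"}

    def counts(self) -> dict[str, int]:
        tf = self.tf_family_nodes
        ops = self.metabolic_operon_nodes
        tf_tf = sum(1 for _, v in self.graph.edges if v in tf)
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_tf_family_nodes": len(tf),
            "n_metabolic_operon_nodes": len(ops),
            "n_arcs": self.graph.number_of_edges(),
            "n_tf_tf_arcs": tf_tf,
            "n_tf_operon_arcs": self.graph.number_of_edges() - tf_tf,
        }


def filter_and_assemble(
    affinity_graph: nx.DiGraph,
    selected: dict[Arc, set[tuple[str, str, str]]],
    final_arc_p_threshold: float = 9e-5,
    family_map: dict[str, str] | None = None,
    categories: dict[str, set[str]] | None = None,
) -> CoRegulatoryNetwork:
    """Assemble the co-regulatory network from the selected arcs.

    Arcs whose original p-value exceeds the threshold are removed (a p equal
    to the threshold is retained). Nodes present in ``family_map`` (operons
    coding for transcription factors) are replaced by their family node;
    parallel arcs created by the collapse merge keeping the minimum p-value.
    Isolated nodes are dropped. Provenance and categories follow the
    relabeling.
    """
    family_map = family_map or {}
    categories = categories or {}

    def rename(n: str) -> str:
        return family_map.get(n, n)

    g = nx.DiGraph()
    provenance: dict[Arc, set[tuple[str, str, str]]] = {}
    dropped = 0
    for (u, v), prov in sorted(selected.items()):
        p = affinity_graph[u][v]["p_value"]
        if p > final_arc_p_threshold:
            dropped += 1
            continue
        ru, rv = rename(u), rename(v)
        ku = "tf" if (affinity_graph.nodes[u].get("kind") == "tf" or u in family_map) else "operon"
        kv = "tf" if (affinity_graph.nodes[v].get("kind") == "tf" or v in family_map) else "operon"
        g.add_node(ru, kind=ku)
        g.add_node(rv, kind=kv)
        if g.has_edge(ru, rv):
            g[ru][rv]["p_value"] = min(g[ru][rv]["p_value"], p)
        else:
            g.add_edge(ru, rv, p_value=p, selected=True)
        if "weight" in affinity_graph[u][v]:
            w = affinity_graph[u][v]["weight"]
            g[ru][rv]["weight"] = min(g[ru][rv].get("weight", w), w)
        provenance.setdefault((ru, rv), set()).update(prov)
    if dropped:
        logger.info("final p filter removed %d selected arcs", dropped)
    if g.number_of_edges() == 0:
        logger.warning("co-regulatory network is empty after filtering")
    cats = {
        rename(n): set(c) for n, c in categories.items() if rename(n) in g
    }
    return CoRegulatoryNetwork(graph=g, categories=cats, provenance=provenance)


# ---------------------------------------------------------------------------
# diagnostics


def pvalue_histogram(p_values, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Right-closed binned counts of p-values over (0, max p].

    Bin i covers (i*bin_width, (i+1)*bin_width]; a p-value of exactly a bin
    edge falls in the lower bin (so 2e-5 with width 2e-5 is in bin 0).
    Returns (bin_edges, counts); counts sum to the number of p-values.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    ps = np.asarray(sorted(p_values), dtype=float)
    if ps.size == 0:
        return np.array([0.0]), np.array([], dtype=int)
    n_bins = max(1, int(math.ceil(ps.max() / bin_width - 1e-12)))
    idx = np.ceil(ps / bin_width - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return edges, counts
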