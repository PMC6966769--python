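"""PSSM scanning with exact match p-values, and affinity-network assembly.

The scanner mirrors FIMO's model: a position-specific scoring matrix is
converted to integer-scaled log-odds scores against a 0-order background,
and the null distribution of the total score is computed *exactly* by
dynamic programming (convolution of the per-position score distributions
under the background). A match is any window, on either strand, whose score
has tail probability P(S >= s) at or below the scan threshold.

An affinity relation TF family -> operon holds when the family's motif has
at least one match in a promoter region of the operon. Families collapse:
however many genes encode members of a family, the network carries a single
family node, and an operon containing a gene of family G is represented by
the node G on the target side (so TF->TF arcs arise from binding sites
upstream of TF-coding operons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from coregnet.operon_promoter import Operon, PromoterRegion

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int64)  # A<->T, C<->G, N->N


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N, ambiguity codes) -> 4."""
    out = np.full(len(seq), 4, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class PSSM:
    """Per-position nucleotide probabilities of a binding motif."""

    family: str
    probs: np.ndarray  # shape (width, 4), rows sum to 1

    @classmethod
    def from_rows(cls, family: str, rows) -> "PSSM":
        probs = np.asarray(rows, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"motif {family}: matrix must be width x 4, width >= 1")
        sums = probs.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError(f"motif {family}: column with zero total probability")
        return cls(family=family, probs=probs / sums[:, None])

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.family}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def information_content(self, background=None) -> float:
        """Total information in bits relative to the background."""
        bg = np.array(
            [0.25] * 4 if background is None else [background[b] for b in _BASES]
        )
        p = np.clip(self.probs, 1e-12, None)
        return float(np.sum(p * np.log2(p / bg)))


@dataclass
class ScoreModel:
    """Integer-scaled log-odds matrix with an exact score -> p-value table."""

    family: str
    width: int
    entries: np.ndarray        # (width, 4) int64 scaled log-odds
    n_scores: np.ndarray       # (width,) int64: expected score for an N base
    background: np.ndarray     # (4,) probabilities
    scale: int
    min_score: int
    tail: np.ndarray           # tail[s - min_score] = P(S >= s) under background

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.tail) - 1

    def pvalue(self, score) -> np.ndarray | float:
        """Exact P(S >= score) under the background; 1 below the support,
        0 above it."""
        s = np.asarray(score, dtype=np.int64)
        idx = np.clip(s - self.min_score, 0, len(self.tail) - 1)
        out = self.tail[idx]
        out = np.where(s <= self.min_score, 1.0, out)
        out = np.where(s > self.max_score, 0.0, out)
        return float(out) if np.isscalar(score) else out

    def score_sequence(self, codes: np.ndarray) -> int:
        """Score one window of length ``width`` (codes 0..4)."""
        ext = np.concatenate([self.entries, self.n_scores[:, None]], axis=1)
        return int(ext[np.arange(self.width), codes].sum())


def build_score_model(
    pssm: PSSM,
    background: dict[str, float] | None = None,
    pseudocount: float = 0.01,
    scale: int = 1000,
) -> ScoreModel:
    """Construct the integer log-odds score model and its exact p-value table.

    entry(i, a) = round(scale * log2((p_ia + c*bg_a) / ((1+c)*bg_a))) and the
    null distribution of the window score is the exact convolution of the
    per-position score distributions under the 0-order background. The table
    is non-increasing, with p = 1 at (and below) the minimum achievable
    score and p = 0 above the maximum.
    """
    bg = np.array(
        [0.25] * 4 if background is None else [background[b] for b in _BASES]
    )
    if np.any(bg <= 0):
        raise ValueError("background probabilities must be strictly positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = pssm.probs
    if pseudocount == 0 and np.any(p == 0):
        raise ValueError(
            f"motif {pssm.family}: zero probability with zero pseudocount "
            "gives an infinite log-odds score"
        )
    adjusted = (p + pseudocount * bg[None, :]) / (1.0 + pseudocount)
    entries = np.rint(scale * np.log2(adjusted / bg[None, :])).astype(np.int64)

    # N bases contribute the background-expected score of the position.
    n_scores = np.rint(entries @ bg).astype(np.int64)

    w = pssm.width
    col_min = entries.min(axis=1)
    col_max = entries.max(axis=1)
    min_score = int(col_min.sum())
    max_score = int(col_max.sum())
    size = max_score - min_score + 1

    # DP convolution: dist over achievable totals, offset by running minimum.
    dist = np.zeros(1, dtype=float)
    dist[0] = 1.0
    for i in range(w):
        width_i = int(col_max[i] - col_min[i])
        new = np.zeros(len(dist) + width_i, dtype=float)
        for a in range(4):
            off = int(entries[i, a] - col_min[i])
            new[off : off + len(dist)] += bg[a] * dist
        dist = new
    assert len(dist) == size
    tail = np.cumsum(dist[::-1])[::-1]
    tail = np.minimum(tail, 1.0)  # guard rounding just above 1

    return ScoreModel(
        family=pssm.family,
        width=w,
        entries=entries,
        n_scores=n_scores,
        background=bg,
        scale=scale,
        min_score=min_score,
        tail=tail,
    )


def reverse_complement_entries(model: ScoreModel) -> np.ndarray:
    """Score matrix equivalent to scoring the reverse complement window."""
    return model.entries[::-1, [3, 2, 1, 0]]


@dataclass
class MotifMatch:
    """One significant occurrence of a motif in a promoter region."""

    family: str
    promoter_id: str
    offset: int  # 0-based within the forward-strand promoter sequence
    strand: str  # strand of the match
    score: int
    p_value: float
    confident: bool = False


def scan_promoter(
    model: ScoreModel,
    region: PromoterRegion,
    p_threshold: float = 1e-4,
    confident_p_threshold: float = 1e-5,
) -> list[MotifMatch]:
    """Scan both strands of a promoter at every offset; emit every window
    whose exact p-value is <= ``p_threshold`` (a p equal to the threshold is
    a match). Regions shorter than the motif yield no matches."""
    w = model.width
    codes = encode(region.sequence)
    L = len(codes)
    if L < w:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    pos = np.arange(w)

    fwd_ext = np.concatenate([model.entries, model.n_scores[:, None]], axis=1)
    rc = reverse_complement_entries(model)
    rc_n = np.rint(rc @ model.background).astype(np.int64)
    rc_ext = np.concatenate([rc, rc_n[:, None]], axis=1)

    matches: list[MotifMatch] = []
    for strand, ext in (("+", fwd_ext), ("-", rc_ext)):
        scores = ext[pos, windows].sum(axis=1)
        pvals = model.pvalue(scores)
        hits = np.nonzero(pvals <= p_threshold)[0]
        for off in hits:
            pv = float(pvals[off])
            matches.append(
                MotifMatch(
                    family=model.family,
                    promoter_id=region.promoter_id,
                    offset=int(off),
                    strand=strand,
                    score=int(scores[off]),
                    p_value=pv,
                    confident=pv <= confident_p_threshold,
                )
            )
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


# ---------------------------------------------------------------------------
# affinity network


@dataclass
class AffinityNetwork:
    """Directed graph of affinity relations.

    Nodes carry attribute ``kind`` in {"tf", "operon"}: one node per TF
    family (however many genes encode it), one node per regulated operon
    that codes no TF. Edges carry ``p_value`` = the best (minimum) match
    p-value supporting the arc.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def tf_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "tf"}

    @property
    def operon_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "operon"}

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def validate(self, p_threshold: float | None = None) -> None:
        for u, v, d in self.graph.edges(data=True):
            if self.graph.nodes[u].get("kind") != "tf":
                raise ValueError(f"arc source {u} is not a TF family node")
            if p_threshold is not None and d["p_value"] > p_threshold:
                raise ValueError(f"arc {u}->{v} p={d['p_value']} above threshold")


def build_affinity_network(
    matches: list[MotifMatch],
    operons: list[Operon],
    promoters: list[PromoterRegion],
    tf_gene_map: dict[str, str],
) -> AffinityNetwork:
    """Assemble the affinity network from scan matches.

    ``tf_gene_map`` maps gene id -> TF family for every TF-candidate gene.
    An arc F -> X exists iff some match of F's motif lies in a promoter of
    an operon represented by X, where X is a family node G for operons
    containing a gene of family G and the operon node itself otherwise.
    Parallel evidence collapses to one arc with the minimum p-value.
    """
    promoter_by_id = {p.promoter_id: p for p in promoters}
    operon_by_id = {op.operon_id: op for op in operons}

    def targets_of(operon: Operon) -> list[tuple[str, str]]:
        fams = sorted({tf_gene_map[g] for g in operon.gene_ids if g in tf_gene_map})
        if fams:
            return [(f, "tf") for f in fams]
        return [(operon.operon_id, "operon")]

    net = AffinityNetwork()
    g = net.graph
    for m in matches:
        if m.promoter_id not in promoter_by_id:
            raise KeyError(f"match references unknown promoter {m.promoter_id}")
        prom = promoter_by_id[m.promoter_id]
        g.add_node(m.family, kind="tf")
        for oid in prom.downstream_operon_ids:
            for target, kind in targets_of(operon_by_id[oid]):
                g.add_node(target, kind=kind)
                if g.has_edge(m.family, target):
                    if m.p_value < g[m.family][target]["p_value"]:
                        g[m.family][target]["p_value"] = m.p_value
                else:
                    g.add_edge(m.family, target, p_value=m.p_value)
    return net


def degree_stats(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node in/out/total degree table, sorted by total degree descending."""
    rows = [
        {
            "node": n,
            "kind": d.get("kind", "operon"),
            "in_degree": graph.in_degree(n),
            "out_degree": graph.out_degree(n),
            "total_degree": graph.in_degree(n) + graph.out_degree(n),
        }
        for n, d in graph.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node", "kind", "in_degree", "out_degree", "total_degree"])
    if not df.empty:
        df = df.sort_values(["total_degree", "node"], ascending=[False, True]).reset_index(drop=True)
    return df


def degree_histogram(graph: nx.DiGraph, which: str = "total") -> dict[int, int]:
    getter = {
        "in": graph.in_degree, "out": graph.out_degree,
        "total": lambda n: graph.in_degree(n) + graph.out_degree(n),
    }[which]
    hist: dict[int, int] = {}
    for n in graph.nodes:
        k = getter(n) if which == "total" else getter(n)
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))
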