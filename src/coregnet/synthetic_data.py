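"""Synthetic genomes, motifs and networks with known ground truth.

No real genome ships with the package, so every pipeline stage is
exercised against generated inputs whose truth is known by construction: operon structure is fixed by the gap distribution
(intra-operon gaps uniform on [1, 49] bp, inter-operon on [60, 500] bp),
binding sites are sampled from the emitting PSSM and verified to pass the
scan threshold before planting, and planted networks carry designated
primaries, an exact number of cycles, category-labelled operon leaves,
signal arcs (p log-uniform on [1e-8, 1e-5]) and decoy arcs (p log-uniform
on [1e-5, 1e-4]) that no minimum-weight V-shape should use.

All generators take an explicit seed; there is no global RNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from coregnet.config import DEFAULT_CATEGORIES, PipelineConfig
from coregnet.operon_promoter import (
    GeneRecord,
    Operon,
    PromoterRegion,
    call_operons,
    extract_promoters,
    reverse_complement,
)
from coregnet.pssm_affinity import PSSM, AffinityNetwork, build_score_model, encode

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedSite:
    family: str
    promoter_id: str
    offset: int
    strand: str
    site: str


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    rng_seed: int
    planted_sites: list[PlantedSite] = field(default_factory=list)
    signal_arcs: list[tuple[str, str]] = field(default_factory=list)
    decoy_arcs: list[tuple[str, str]] = field(default_factory=list)
    tf_arcs: list[tuple[str, str]] = field(default_factory=list)
    primaries: list[str] = field(default_factory=list)
    operon_genes: list[list[str]] = field(default_factory=list)
    categories: dict[str, list[str]] = field(default_factory=dict)  # node -> cats
    n_cycles: int = 0

    def to_json(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, default=list)


def _random_seq(rng: np.random.Generator, n: int, background=None) -> str:
    p = [0.25] * 4 if background is None else [background[b] for b in "ACGT"]
    return "".join(rng.choice(_BASES, size=n, p=p))


def random_pssm(
    family: str, width: int, rng: np.random.Generator, dominant: float = 0.88
) -> PSSM:
    """Information-rich random motif: one dominant base per column with
    probability ``dominant`` (0.88 gives ~1.2 bits per column, so width-10
    motifs clear 10 bits of total information)."""
    rows = []
    rest = (1.0 - dominant) / 3.0
    for _ in range(width):
        row = [rest] * 4
        row[int(rng.integers(4))] = dominant
        rows.append(row)
    return PSSM.from_rows(family, rows)


# ---------------------------------------------------------------------------
# genomes


def generate_genome(
    n_genes: int,
    n_contigs: int = 1,
    seed: int = 0,
    intra_gap: tuple[int, int] = (1, 49),
    inter_gap: tuple[int, int] = (60, 500),
    gene_length: tuple[int, int] = (300, 900),
    p_operon_continue: float = 0.5,
    background: dict[str, float] | None = None,
) -> tuple[dict[str, str], list[GeneRecord], list[list[str]]]:
    """Random genome with known operon structure.

    Consecutive genes continue the current operon (same strand, gap drawn
    from ``intra_gap``) with probability ``p_operon_continue``, otherwise a
    new operon starts (random strand, gap from ``inter_gap``). Returns
    (contig sequences, sorted GeneRecords, true operon gene-id lists).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1

    sequences: dict[str, str] = {}
    genes: list[GeneRecord] = []
    true_operons: list[list[str]] = []
    gid = 0
    for ci, count in enumerate(per_contig):
        contig = f"contig_{ci + 1}"
        pos = 1 + int(rng.integers(inter_gap[0], inter_gap[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        current: list[str] = []
        for gi in range(count):
            if gi > 0:
                if current and rng.random() < p_operon_continue:
                    gap = int(rng.integers(intra_gap[0], intra_gap[1] + 1))
                else:
                    gap = int(rng.integers(inter_gap[0], inter_gap[1] + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    true_operons.append(current)
                    current = []
                pos += gap
            gid += 1
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            gene = GeneRecord(
                gene_id=f"gene_{gid:04d}",
                contig_id=contig,
                start=pos,
                end=pos + length - 1,
                strand=strand,
            )
            genes.append(gene)
            current.append(gene.gene_id)
            pos = gene.end + 1
        if current:
            true_operons.append(current)
        tail = int(rng.integers(inter_gap[0], inter_gap[1] + 1))
        sequences[contig] = _random_seq(rng, pos - 1 + tail, background)
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return sequences, genes, true_operons


# ---------------------------------------------------------------------------
# motif planting


def sample_site(pssm: PSSM, rng: np.random.Generator) -> str:
    idx = [int(rng.choice(4, p=col / col.sum())) for col in pssm.probs]
    return "".join("ACGT"[i] for i in idx)


def plant_motifs(
    sequences: dict[str, str],
    promoters: list[PromoterRegion],
    operons: list[Operon],
    pssms: dict[str, PSSM],
    truth_arcs: list[tuple[str, str]],
    seed: int = 0,
    scan_p_threshold: float = 1e-4,
    background: dict[str, float] | None = None,
    max_resample: int = 100,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write one verified binding site per planted arc (family -> operon)
    into a promoter of that operon.

    Sites are sampled from the family's PSSM, rejected (up to
    ``max_resample`` times) until their exact p-value passes the scan
    threshold, placed at a random free offset on a random strand, and
    spliced into the contig sequence. Returns the mutated contig sequences
    and the updated promoter sequences alongside the site list; promoter
    objects are updated in place.
    """
    rng = np.random.default_rng(seed)
    models = {
        fam: build_score_model(p, background=background) for fam, p in pssms.items()
    }
    prom_by_id = {p.promoter_id: p for p in promoters}
    op_by_id = {op.operon_id: op for op in operons}
    mutable = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    occupied: dict[str, list[tuple[int, int]]] = {p.promoter_id: [] for p in promoters}
    sites: list[PlantedSite] = []

    for family, operon_id in truth_arcs:
        pssm = pssms[family]
        model = models[family]
        op = op_by_id[operon_id]
        if not op.promoter_ids:
            raise ValueError(f"operon {operon_id} has no promoter to plant into")
        prom = prom_by_id[op.promoter_ids[0]]
        w = pssm.width
        if len(prom) <= w:
            raise ValueError(
                f"promoter {prom.promoter_id} shorter than motif {family}"
            )
        site = None
        for _ in range(max_resample):
            cand = sample_site(pssm, rng)
            score = model.score_sequence(encode(cand))
            if model.pvalue(score) <= scan_p_threshold:
                site = cand
                break
        if site is None:
            raise RuntimeError(
                f"could not sample a significant site for {family} in "
                f"{max_resample} draws; motif information content is only "
                f"{pssm.information_content():.1f} bits"
            )
        free = [
            off
            for off in range(len(prom) - w + 1)
            if all(off + w <= s or off >= e for s, e in occupied[prom.promoter_id])
        ]
        if not free:
            raise RuntimeError(f"promoter {prom.promoter_id} has no free offset left")
        offset = int(free[int(rng.integers(len(free)))])
        strand = "+" if rng.random() < 0.5 else "-"
        written = site if strand == "+" else reverse_complement(site)
        lo = prom.interval[0] - 1 + offset  # 0-based contig coordinate
        mutable[prom.contig_id][lo : lo + w] = written.encode("ascii")
        occupied[prom.promoter_id].append((offset, offset + w))
        sites.append(
            PlantedSite(
                family=family,
                promoter_id=prom.promoter_id,
                offset=offset,
                strand=strand,
                site=site,
            )
        )

    out = {c: s.decode("ascii") for c, s in mutable.items()}
    for prom in promoters:
        lo, hi = prom.interval
        prom.sequence = out[prom.contig_id][lo - 1 : hi]
    return out, sites


# ---------------------------------------------------------------------------
# planted abstract networks


def _draw_p(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def plant_network(
    n_tf_families: int = 12,
    n_metabolic_operons: int = 18,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    n_primaries: int = 4,
    n_cycles: int = 0,
    seed: int = 0,
    signal_p: tuple[float, float] = (1e-8, 1e-5),
    decoy_p: tuple[float, float] = (1e-5, 1e-4),
) -> tuple[AffinityNetwork, SyntheticGroundTruth]:
    """Planted affinity network emulating a near-hierarchical regulator
    cascade with category-labelled operon leaves.

    TF families form a DAG whose first ``n_primaries`` nodes have in-degree
    0; exactly ``n_cycles`` back-arcs are added (each verified to create one
    new cycle); each category gets a dedicated apex TF wired to all of its
    operons (signal arcs); one decoy arc per signal arc points from a random
    TF to a random operon with a high p-value, so no minimum-weight V-shape
    should use it.
    """
    if n_primaries > n_tf_families:
        raise ValueError("n_primaries cannot exceed n_tf_families")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i + 1:02d}" for i in range(n_tf_families)]
    primaries = tfs[:n_primaries]
    g = nx.DiGraph()
    for t in tfs:
        g.add_node(t, kind="tf")

    truth = SyntheticGroundTruth(rng_seed=seed, primaries=list(primaries), n_cycles=n_cycles)

    # hierarchy: every non-primary TF gets 1-2 parents among earlier TFs
    for i in range(n_primaries, n_tf_families):
        n_par = int(rng.integers(1, min(2, i) + 1))
        parents = rng.choice(i, size=n_par, replace=False)
        for pi in parents:
            g.add_edge(tfs[pi], tfs[i], p_value=_draw_p(rng, *signal_p))
            truth.tf_arcs.append((tfs[pi], tfs[i]))

    # exact number of cycles: add back-arcs one at a time, verifying each
    # raises the simple-cycle count by exactly one
    added = 0
    tree_arcs = list(truth.tf_arcs)
    rng.shuffle(tree_arcs)
    for u, v in tree_arcs:
        if added == n_cycles:
            break
        if u in primaries or g.has_edge(v, u):
            continue  # a back-arc must not give a primary an in-arc
        g.add_edge(v, u, p_value=_draw_p(rng, *signal_p))
        if sum(1 for _ in nx.simple_cycles(g)) == added + 1:
            added += 1
            truth.tf_arcs.append((v, u))
        else:
            g.remove_edge(v, u)
    if added < n_cycles:
        raise RuntimeError(
            f"could only realize {added} of {n_cycles} planted cycles"
        )

    # category-labelled operon leaves with dedicated apexes
    ops = [f"op{i + 1:03d}" for i in range(n_metabolic_operons)]
    cats = list(categories)
    apex_pool = [t for t in tfs if t not in primaries] or tfs
    for j, cat in enumerate(cats):
        members = [o for i, o in enumerate(ops) if i % len(cats) == j]
        apex = apex_pool[j % len(apex_pool)]
        for o in members:
            g.add_node(o, kind="operon")
            truth.categories.setdefault(o, []).append(cat)
            g.add_edge(apex, o, p_value=_draw_p(rng, *signal_p))
            truth.signal_arcs.append((apex, o))

    # decoys: as many as all signal-range arcs combined, so the p-value
    # quartiles put every signal arc in the low-weight half and every decoy
    # in the high-weight half (decoy-bearing V-shapes then always lose)
    n_decoys = len(truth.signal_arcs) + len(truth.tf_arcs)
    guard = 0
    while len(truth.decoy_arcs) < n_decoys and guard < 100 * n_decoys:
        guard += 1
        t = tfs[int(rng.integers(n_tf_families))]
        o = ops[int(rng.integers(n_metabolic_operons))]
        if g.has_edge(t, o):
            continue
        g.add_edge(t, o, p_value=_draw_p(rng, *decoy_p))
        truth.decoy_arcs.append((t, o))

    net = AffinityNetwork(graph=g)
    net.validate()
    return net, truth


# ---------------------------------------------------------------------------
# full dataset on disk (end-to-end pipeline input)


@dataclass
class SyntheticDataset:
    sequences: dict[str, str]
    genes: list[GeneRecord]
    operons: list[Operon]
    promoters: list[PromoterRegion]
    pssms: dict[str, PSSM]
    gene_categories: dict[str, set[str]]
    truth: SyntheticGroundTruth


def generate_dataset(
    seed: int = 0,
    n_tf_families: int = 8,
    n_primaries: int = 3,
    n_metabolic_operons: int = 12,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    motif_width: int = 12,
    genes_per_operon: tuple[int, int] = (1, 3),
    config: PipelineConfig | None = None,
) -> SyntheticDataset:
    """A complete genome + motifs + categories bundle with planted sites.

    Transcription units are laid out on one contig: one single-gene unit per
    TF family, then multi-gene metabolic operons, in shuffled order, all
    separated by promoter-sized gaps. A binding site is planted for every
    designed regulatory arc (TF hierarchy arcs and category apex -> operon
    arcs), so scanning the genome should recover the designed network.
    """
    cfg = config or PipelineConfig(rng_seed=seed)
    rng = np.random.default_rng(seed)
    fams = [f"Fam{i + 1:02d}" for i in range(n_tf_families)]
    pssms = {f: random_pssm(f, motif_width, rng) for f in fams}

    # designed regulation (family-level)
    design_tf_arcs: list[tuple[str, str]] = []
    for i in range(n_primaries, n_tf_families):
        parent = fams[int(rng.integers(i))]
        design_tf_arcs.append((parent, fams[i]))
    cats = list(categories)
    op_names = [f"M{i + 1:02d}" for i in range(n_metabolic_operons)]
    op_category = {
        o: cats[i % len(cats)] for i, o in enumerate(op_names)
    }
    apex_pool = fams[n_primaries:] or fams
    apex_of_cat = {c: apex_pool[j % len(apex_pool)] for j, c in enumerate(cats)}
    design_op_arcs = [
        (apex_of_cat[op_category[o]], o) for o in op_names
    ]

    # genome layout: shuffled transcription units, all on '+' for TF units
    units: list[dict] = [
        {"name": f, "kind": "tf", "n_genes": 1, "strand": "+"} for f in fams
    ] + [
        {
            "name": o,
            "kind": "met",
            "n_genes": int(rng.integers(genes_per_operon[0], genes_per_operon[1] + 1)),
            "strand": "+" if rng.random() < 0.5 else "-",
        }
        for o in op_names
    ]
    rng.shuffle(units)

    contig = "contig_1"
    genes: list[GeneRecord] = []
    gene_categories: dict[str, set[str]] = {}
    unit_first_gene: dict[str, str] = {}
    pos = 1 + int(rng.integers(150, 400))
    gid = 0
    for unit in units:
        member_ids = []
        for k in range(unit["n_genes"]):
            gid += 1
            gene_id = f"gene_{gid:04d}"
            length = int(rng.integers(300, 900))
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=pos,
                    end=pos + length - 1,
                    strand=unit["strand"],
                    product=("transcription factor" if unit["kind"] == "tf" else "enzyme"),
                    tf_family=unit["name"] if unit["kind"] == "tf" else None,
                    categories=(
                        frozenset([op_category[unit["name"]]])
                        if unit["kind"] == "met"
                        else frozenset()
                    ),
                )
            )
            if unit["kind"] == "met":
                gene_categories[gene_id] = {op_category[unit["name"]]}
            member_ids.append(gene_id)
            pos = pos + length + (
                int(rng.integers(1, cfg.operon_max_gap)) if k + 1 < unit["n_genes"] else 0
            )
        # '-' units list genes 5'->3' right to left; first positional gene marks the unit
        unit_first_gene[unit["name"]] = member_ids[0]
        pos += int(rng.integers(150, 400))

    sequences = {contig: _random_seq(rng, pos + 200, cfg.background_model)}
    operons = call_operons(genes, cfg.operon_max_gap)
    promoters = extract_promoters(operons, genes, sequences, cfg.operon_max_gap)

    op_of_gene = {g: op.operon_id for op in operons for g in op.gene_ids}
    unit_operon = {name: op_of_gene[g] for name, g in unit_first_gene.items()}

    # planted arcs at operon resolution
    planted: list[tuple[str, str]] = []
    truth = SyntheticGroundTruth(
        rng_seed=seed, primaries=fams[:n_primaries],
        operon_genes=[op.gene_ids for op in operons],
    )
    for u, v in design_tf_arcs:
        planted.append((u, unit_operon[v]))
        truth.tf_arcs.append((u, v))
    for u, o in design_op_arcs:
        planted.append((u, unit_operon[o]))
        truth.signal_arcs.append((u, unit_operon[o]))
        truth.categories.setdefault(unit_operon[o], []).append(op_category[o])

    sequences, sites = plant_motifs(
        sequences, promoters, operons, pssms, planted,
        seed=seed + 1, scan_p_threshold=cfg.confident_p_threshold,
        background=cfg.background_model,
    )
    truth.planted_sites = sites

    return SyntheticDataset(
        sequences=sequences,
        genes=genes,
        operons=operons,
        promoters=promoters,
        pssms=pssms,
        gene_categories=gene_categories,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write a dataset in the dialects the readers consume; returns paths."""
    import os

    from coregnet import genome_io

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "annotation": os.path.join(outdir, "genes.gff3"),
        "motifs": os.path.join(outdir, "motifs.meme"),
        "categories": os.path.join(outdir, "categories.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    genome_io.write_fasta(ds.sequences, paths["genome"])
    genome_io.write_genes(ds.genes, paths["annotation"])
    genome_io.write_motifs(list(ds.pssms.values()), paths["motifs"])
    genome_io.write_pathway_categories(ds.gene_categories, paths["categories"])
    ds.truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# closed-loop recovery experiments


def site_recovery_experiment(
    seed: int,
    n_families: int = 10,
    motif_width: int = 10,
    n_promoters: int = 10,
    promoter_len: int = 300,
    scan_p_threshold: float = 1e-5,
) -> dict:
    """Plant one verified site per family into its own random promoter, scan
    everything, and report recovery and false-positive counts.

    Returns planted/recovered counts, the number of off-site matches, and
    the exact expected number of background matches (sum over models of
    2 * windows * realized p at the score threshold), for a Poisson check.
    """
    from coregnet.pssm_affinity import scan_promoter

    rng = np.random.default_rng(seed)
    fams = [f"R{i + 1:02d}" for i in range(n_families)]
    pssms = {f: random_pssm(f, motif_width, rng) for f in fams}
    for f in fams:
        assert pssms[f].information_content() >= motif_width  # >= 1 bit/col

    sequences = {}
    promoters = []
    operons = []
    for i, f in enumerate(fams[:n_promoters]):
        contig = f"c{i + 1}"
        sequences[contig] = _random_seq(rng, promoter_len)
        prom = PromoterRegion(
            promoter_id=f"p{i + 1:02d}", contig_id=contig,
            interval=(1, promoter_len), sequence=sequences[contig],
            downstream_operon_ids=[f"o{i + 1:02d}"],
        )
        promoters.append(prom)
        operons.append(
            Operon(operon_id=f"o{i + 1:02d}", contig_id=contig, strand="+",
                   gene_ids=[f"g{i + 1:02d}"], span=(promoter_len + 1, promoter_len + 2),
                   promoter_ids=[prom.promoter_id])
        )
    arcs = [(f, f"o{i + 1:02d}") for i, f in enumerate(fams[:n_promoters])]
    sequences, sites = plant_motifs(
        sequences, promoters, operons, pssms, arcs,
        seed=seed + 1, scan_p_threshold=scan_p_threshold,
    )

    models = {f: build_score_model(p) for f, p in pssms.items()}
    planted_by_key = {(s.family, s.promoter_id): s for s in sites}
    recovered = 0
    false_positives = 0
    for s in sites:
        model = models[s.family]
        hits = scan_promoter(model, next(p for p in promoters
                                         if p.promoter_id == s.promoter_id),
                             p_threshold=scan_p_threshold)
        if any(h.offset == s.offset and h.strand == s.strand for h in hits):
            recovered += 1

    expected_fp = 0.0
    for f in fams:
        model = models[f]
        # realized match probability at the threshold (discrete tail)
        in_tail = model.tail[model.tail <= scan_p_threshold]
        p_star = float(in_tail.max()) if in_tail.size else 0.0
        for prom in promoters:
            hits = scan_promoter(model, prom, p_threshold=scan_p_threshold)
            planted = planted_by_key.get((f, prom.promoter_id))
            for h in hits:
                if planted is not None and abs(h.offset - planted.offset) < motif_width:
                    continue  # overlaps the planted site
                false_positives += 1
            expected_fp += 2 * (len(prom) - motif_width + 1) * p_star

    return {
        "planted": len(sites),
        "recovered": recovered,
        "false_positives": false_positives,
        "expected_false_positives": expected_fp,
    }


def vshape_recovery_experiment(seed: int, n_cycles: int = 0, **plant_kwargs) -> dict:
    """Plant a network, run weighting + V-shape selection, and report the
    fraction of signal arcs recovered and of decoy arcs selected."""
    from coregnet.coregulation import select_coregulatory_arcs, weighted_graph

    net, truth = plant_network(seed=seed, n_cycles=n_cycles, **plant_kwargs)
    wg = weighted_graph(net.graph)
    cats = {o: set(c) for o, c in truth.categories.items()}
    selected = set(select_coregulatory_arcs(wg, cats))
    signal = set(truth.signal_arcs)
    decoys = set(truth.decoy_arcs)
    return {
        "signal_total": len(signal),
        "signal_recovered": len(selected & signal),
        "decoy_total": len(decoys),
        "decoy_selected": len(selected & decoys),
        "extra_selected": len(selected - signal - decoys),
    }
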