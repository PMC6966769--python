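"""Select the co-regulatory network by minimum-weight V-shapes.

Two runs: (i) the genome-derived affinity network from 02, selecting arcs
that connect same-category metabolic operons, then the final p filter; and
(ii) the planted abstract network from 01, scoring selection against its
signal/decoy ground truth. Writes results/coregulation/.
"""

import json
import os
import sys
from collections import defaultdict

SEED = 11
ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def load_operon_categories(path):
    cats = defaultdict(set)
    with open(path) as fh:
        next(fh)
        for line in fh:
            oid, cat = line.rstrip("\n").split("\t")
            cats[oid].add(cat)
    return dict(cats)


def main() -> int:
    from coregnet import genome_io
    from coregnet.config import PipelineConfig
    from coregnet.coregulation import (
        filter_and_assemble,
        pvalue_histogram,
        select_coregulatory_arcs,
        weighted_graph,
    )

    outdir = os.path.join(ROOT, "coregulation")
    os.makedirs(outdir, exist_ok=True)
    cfg = PipelineConfig(rng_seed=SEED)

    # (i) genome-derived network
    aff = genome_io.read_network(os.path.join(ROOT, "affinity", "affinity_network.tsv"))
    cats = load_operon_categories(
        os.path.join(ROOT, "affinity", "operon_categories.tsv")
    )
    wg = weighted_graph(aff, cfg.weight_classes)
    selected = select_coregulatory_arcs(wg, cats)
    print(f"V-shape selection: {len(selected)} of {aff.number_of_edges()} "
          f"affinity arcs selected")
    ps = [wg[u][v]["p_value"] for (u, v) in selected]
    edges, counts = pvalue_histogram(ps, bin_width=2e-5)
    with open(os.path.join(outdir, "selected_p_histogram.tsv"), "w") as fh:
        fh.write("bin_low\tbin_high\tcount\n")
        for lo, hi, n in zip(edges, edges[1:], counts):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{n}\n")
    coreg = filter_and_assemble(
        wg, selected, cfg.final_arc_p_threshold, categories=cats
    )
    genome_io.write_network(
        coreg.graph, os.path.join(outdir, "coregulatory_network.tsv")
    )
    genome_io.write_network(
        coreg.graph, os.path.join(outdir, "coregulatory_network.graphml"),
        dialect="graphml",
    )
    c = coreg.counts()
    print(f"co-regulatory network: {c['n_nodes']} nodes "
          f"({c['n_tf_family_nodes']} TF families + "
          f"{c['n_metabolic_operon_nodes']} metabolic operons), "
          f"{c['n_arcs']} arcs ({c['n_tf_tf_arcs']} TF-TF + "
          f"{c['n_tf_operon_arcs']} TF-operon)")
    with open(os.path.join(outdir, "operon_categories.tsv"), "w") as fh:
        fh.write("operon_id\tcategory\n")
        for oid in sorted(coreg.categories):
            for cat in sorted(coreg.categories[oid]):
                fh.write(f"{oid}\t{cat}\n")

    # (ii) planted benchmark
    planted = genome_io.read_network(
        os.path.join(ROOT, "synthetic", "planted_affinity.tsv")
    )
    truth = json.load(open(os.path.join(ROOT, "synthetic", "planted_truth.json")))
    pcats = {o: set(cs) for o, cs in truth["categories"].items()}
    wg2 = weighted_graph(planted, cfg.weight_classes)
    sel2 = set(select_coregulatory_arcs(wg2, pcats))
    signal = {tuple(a) for a in truth["signal_arcs"]}
    decoys = {tuple(a) for a in truth["decoy_arcs"]}
    print(f"planted benchmark: recovered {len(sel2 & signal)}/{len(signal)} "
          f"signal arcs, selected {len(sel2 & decoys)}/{len(decoys)} decoys")
    with open(os.path.join(outdir, "benchmark.json"), "w") as fh:
        json.dump({
            "signal_total": len(signal),
            "signal_recovered": len(sel2 & signal),
            "decoy_total": len(decoys),
            "decoy_selected": len(sel2 & decoys),
        }, fh, indent=1)
    return 0


if __name__ == "__main__":
    sys.exit(main())
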