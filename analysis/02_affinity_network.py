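"""Build the affinity transcriptional regulatory network.

Reads the synthetic genome from results/synthetic/, predicts operons
(<50 bp rule), extracts promoter intergenic regions, scans them with every
TF family's PSSM at the exact-p-value threshold, assembles the affinity
network, and reports how many of the planted sites the scan rediscovered.
Writes results/affinity/.
"""

import json
import os
import sys

SEED = 11
ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> int:
    from coregnet import genome_io
    from coregnet.cli_pipeline import operon_categories
    from coregnet.config import PipelineConfig
    from coregnet.operon_promoter import call_operons, extract_promoters
    from coregnet.pssm_affinity import (
        build_affinity_network,
        build_score_model,
        degree_stats,
        scan_promoter,
    )

    indir = os.path.join(ROOT, "synthetic")
    outdir = os.path.join(ROOT, "affinity")
    os.makedirs(outdir, exist_ok=True)
    cfg = PipelineConfig(rng_seed=SEED)

    genes = genome_io.read_genes(
        os.path.join(indir, "genes.gff3"), os.path.join(indir, "genome.fasta")
    )
    sequences = genome_io.read_fasta(os.path.join(indir, "genome.fasta"))
    pssms = genome_io.read_motifs(os.path.join(indir, "motifs.meme"))
    gene_cats = genome_io.read_pathway_categories(
        os.path.join(indir, "categories.tsv"), cfg
    )

    operons = call_operons(genes, cfg.operon_max_gap)
    promoters = extract_promoters(operons, genes, sequences, cfg.operon_max_gap)
    genome_io.write_operons(operons, os.path.join(outdir, "operons.tsv"))
    genome_io.write_promoters_fasta(promoters, os.path.join(outdir, "promoters.fasta"))
    print(f"{len(operons)} operons, {len(promoters)} promoter regions")

    matches = []
    for pssm in pssms:
        model = build_score_model(pssm, background=cfg.background_model)
        for region in promoters:
            matches.extend(scan_promoter(
                model, region, cfg.scan_p_threshold, cfg.confident_p_threshold
            ))
    genome_io.write_matches(matches, os.path.join(outdir, "matches.tsv"))
    confident = sum(1 for m in matches if m.confident)
    print(f"{len(matches)} motif matches at p <= {cfg.scan_p_threshold} "
          f"({confident} confident at p <= {cfg.confident_p_threshold})")

    truth = json.load(open(os.path.join(indir, "truth.json")))
    planted = {(s["family"], s["promoter_id"], s["offset"], s["strand"])
               for s in truth["planted_sites"]}
    got = {(m.family, m.promoter_id, m.offset, m.strand) for m in matches}
    rec = len(planted & got)
    print(f"planted-site recovery: {rec}/{len(planted)} "
          f"({100.0 * rec / len(planted):.1f}%)")

    tf_gene_map = {g.gene_id: g.tf_family for g in genes if g.tf_family}
    net = build_affinity_network(matches, operons, promoters, tf_gene_map)
    genome_io.write_network(net.graph, os.path.join(outdir, "affinity_network.tsv"))
    stats = degree_stats(net.graph)
    stats.to_csv(os.path.join(outdir, "degree_stats.tsv"), sep="\t", index=False)
    print(f"affinity network: {net.graph.number_of_nodes()} nodes "
          f"({len(net.tf_nodes)} TF families), {net.graph.number_of_edges()} arcs")
    top = stats.head(3)
    print("highest-degree nodes:\n" + top.to_string(index=False))

    op_cats = operon_categories(operons, gene_cats)
    with open(os.path.join(outdir, "operon_categories.tsv"), "w") as fh:
        fh.write("operon_id\tcategory\n")
        for oid in sorted(op_cats):
            for cat in sorted(op_cats[oid]):
                fh.write(f"{oid}\t{cat}\n")
    return 0


if __name__ == "__main__":
    sys.exit(main())
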