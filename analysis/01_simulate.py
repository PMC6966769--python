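"""Generate the synthetic study inputs.

Writes a genome (FASTA + GFF3) with planted binding sites, the motif models
(MEME minimal), the pathway-category table, the generator's ground truth,
and a separately planted abstract affinity network used for the selection
benchmark. Everything downstream (02-04) reads from results/synthetic/.
"""

import json
import os
import sys

SEED = 11
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "synthetic")


def main() -> int:
    from coregnet import genome_io
    from coregnet.synthetic_data import generate_dataset, plant_network, write_dataset

    os.makedirs(OUT, exist_ok=True)
    ds = generate_dataset(seed=SEED)
    paths = write_dataset(ds, OUT)
    print(f"genome: {len(ds.sequences)} contig(s), {len(ds.genes)} genes, "
          f"{len(ds.operons)} operons, {len(ds.promoters)} promoter regions")
    print(f"planted {len(ds.truth.planted_sites)} binding sites for "
          f"{len(ds.pssms)} TF families "
          f"({len(ds.truth.tf_arcs)} TF-TF arcs, {len(ds.truth.signal_arcs)} "
          f"TF-operon arcs)")

    net, truth = plant_network(seed=SEED, n_cycles=2)
    genome_io.write_network(net.graph, os.path.join(OUT, "planted_affinity.tsv"))
    truth.to_json(os.path.join(OUT, "planted_truth.json"))
    print(f"planted abstract network: {net.graph.number_of_nodes()} nodes, "
          f"{net.graph.number_of_edges()} arcs "
          f"({len(truth.signal_arcs)} signal, {len(truth.decoy_arcs)} decoys, "
          f"{truth.n_cycles} cycles)")
    with open(os.path.join(OUT, "paths.json"), "w") as fh:
        json.dump(paths, fh, indent=1)
    return 0


if __name__ == "__main__":
    sys.exit(main())
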