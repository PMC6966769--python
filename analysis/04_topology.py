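"""Topological analysis of the co-regulatory network.

Cycles and minimum feedback arc sets, hierarchy levels per feedback-arc
choice, the tree distance of the TF-TF subgraph, primary regulators, the
reachability and exclusivity tables, minimal controlling regulator sets,
and the hub degree table. Writes results/topology/.
"""

import json
import os
import sys
from collections import defaultdict

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> int:
    from coregnet import genome_io
    from coregnet.topology import analyze

    outdir = os.path.join(ROOT, "topology")
    os.makedirs(outdir, exist_ok=True)
    coreg = genome_io.read_network(
        os.path.join(ROOT, "coregulation", "coregulatory_network.tsv")
    )
    cats = defaultdict(set)
    with open(os.path.join(ROOT, "coregulation", "operon_categories.tsv")) as fh:
        next(fh)
        for line in fh:
            oid, cat = line.rstrip("\n").split("\t")
            cats[oid].add(cat)

    report = analyze(coreg, dict(cats))
    print(f"directed cycles: {len(report.cycles)}; "
          f"minimum feedback arc set size: {report.min_fas_size} "
          f"({len(report.min_feedback_arc_sets)} optimal sets)")
    levels = sorted({e["n_levels"] for e in report.levels_by_fas})
    print(f"hierarchy levels per feedback-arc choice: {levels}")
    print(f"TF-TF tree distance: {report.tf_tree_removals} of "
          f"{report.n_tf_tf_arcs} arcs ({report.tf_tree_removal_pct}%)")
    print(f"primary regulators ({len(report.primary_regulators)}): "
          f"{', '.join(sorted(report.primary_regulators))}")
    print("\nreachability table:")
    print(report.regulatory_table.to_string(index=False))
    print("\nexclusivity table:")
    print(report.exclusivity_table.to_string(index=False))
    for cat, res in report.controlling_sets.items():
        if res["feasible"]:
            uniq = "unique" if res["unique"] else f"{len(res['sets'])} optima"
            sets = " | ".join("{" + ",".join(sorted(s)) + "}" for s in res["sets"])
            print(f"minimal controlling set, {cat}: size {res['min_size']} "
                  f"({uniq}): {sets}")
        else:
            print(f"minimal controlling set, {cat}: not coverable by primaries")

    # the planted abstract network carries cycles, so its TF hierarchy
    # exercises the feedback-arc and layering machinery non-trivially
    planted = genome_io.read_network(
        os.path.join(ROOT, "synthetic", "planted_affinity.tsv")
    )
    truthc = defaultdict(set)
    truth = json.load(open(os.path.join(ROOT, "synthetic", "planted_truth.json")))
    for o, cs in truth["categories"].items():
        truthc[o] = set(cs)
    planted_report = analyze(planted, dict(truthc))
    plevels = sorted({e["n_levels"] for e in planted_report.levels_by_fas})
    print(f"\nplanted network: {len(planted_report.cycles)} cycles, "
          f"minimum feedback arc set size {planted_report.min_fas_size} "
          f"({len(planted_report.min_feedback_arc_sets)} optima), "
          f"levels per choice {plevels}, "
          f"TF-TF tree distance {planted_report.tf_tree_removals} of "
          f"{planted_report.n_tf_tf_arcs} ({planted_report.tf_tree_removal_pct}%)")

    report.regulatory_table.to_csv(
        os.path.join(outdir, "regulatory_table.tsv"), sep="\t", index=False
    )
    report.exclusivity_table.to_csv(
        os.path.join(outdir, "exclusivity_table.tsv"), sep="\t", index=False
    )
    report.hub_table.to_csv(
        os.path.join(outdir, "hub_table.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump({
            "n_cycles": len(report.cycles),
            "min_fas_size": report.min_fas_size,
            "n_min_fas": len(report.min_feedback_arc_sets),
            "levels_per_fas": [e["n_levels"] for e in report.levels_by_fas],
            "tf_tree_removals": report.tf_tree_removals,
            "tf_tree_removal_pct": report.tf_tree_removal_pct,
            "primary_regulators": sorted(report.primary_regulators),
            "controlling_sets": {
                cat: {
                    "min_size": res["min_size"],
                    "unique": res["unique"],
                    "feasible": res["feasible"],
                    "sets": [sorted(s) for s in res["sets"]],
                }
                for cat, res in report.controlling_sets.items()
            },
        }, fh, indent=1)
    return 0


if __name__ == "__main__":
    sys.exit(main())
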