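"""Readers and writers for all external formats; no science here.

Formats: FASTA (Biopython SeqIO), GFF3 (gffutils, in-memory), MEME minimal
motif format (Bio.motifs), TSV tables (pandas; tab, header row, '.' for
missing), GraphML (networkx), YAML config. Coordinates are 1-based
inclusive everywhere, as in GFF3; nothing converts them downstream.
"""

from __future__ import annotations

import logging
import os
from typing import TYPE_CHECKING

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from coregnet.config import PipelineConfig
from coregnet.operon_promoter import GeneRecord, Operon, PromoterRegion

if TYPE_CHECKING:  # pragma: no cover
    from coregnet.pssm_affinity import PSSM, MotifMatch

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violated its declared format."""


# ---------------------------------------------------------------------------
# genome + annotation


def read_fasta(path) -> dict[str, str]:
    """Contig id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genes(annotation_file, genome_file) -> list[GeneRecord]:
    """Parse a GFF3 annotation against its FASTA; returns genes sorted by
    (contig, start).

    Recognized attributes: ``ID`` (gene id), ``product``, ``tf_family``
    (TF-candidate family tag) and ``category`` (comma-separated pathway
    categories). A feature on a contig absent from the FASTA is fatal.
    """
    sequences = read_fasta(genome_file)
    db = gffutils.create_db(
        str(annotation_file), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneRecord] = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        if feat.seqid not in sequences:
            raise FormatError(
                f"gene {feat.id}: contig {feat.seqid!r} not present in FASTA"
            )
        if feat.end < feat.start:
            raise FormatError(f"gene {feat.id}: end {feat.end} < start {feat.start}")
        attrs = feat.attributes
        cats = []
        for raw in attrs.get("category", []):
            cats.extend(c.strip() for c in raw.split(",") if c.strip())
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=(attrs.get("product") or [""])[0],
                tf_family=(attrs.get("tf_family") or [None])[0],
                categories=frozenset(cats),
            )
        )
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes


def write_genes(genes: list[GeneRecord], path) -> None:
    """Write genes as GFF3 (inverse of read_genes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.tf_family:
                attrs.append(f"tf_family={g.tf_family}")
            if g.categories:
                attrs.append("category=" + ",".join(sorted(g.categories)))
            fh.write(
                "\t".join(
                    [g.contig_id, "coregnet", "gene", str(g.start), str(g.end),
                     ".", g.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# motifs


def read_motifs(motif_file) -> list["PSSM"]:
    """Read MEME minimal-format motifs (alphabet ACGT only).

    Columns are renormalized to sum to exactly 1; the motif name is the TF
    family name.
    """
    from coregnet.pssm_affinity import PSSM  # cycle guard

    with open(motif_file) as fh:
        text = fh.read()
    if "MOTIF" not in text:
        logger.warning("motif file %s contains no motifs", motif_file)
        return []
    try:
        with open(motif_file) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
    except Exception as exc:  # Biopython raises bare ValueError/Exception
        raise FormatError(f"cannot parse MEME minimal file {motif_file}: {exc}") from exc

    out: list[PSSM] = []
    for m in parsed:
        if sorted(m.alphabet) != ["A", "C", "G", "T"]:
            raise FormatError(f"motif {m.name}: alphabet must be ACGT")
        if m.length == 0:
            raise FormatError(f"motif {m.name}: zero-width motif")
        probs = [[m.pwm[base][i] for base in "ACGT"] for i in range(m.length)]
        out.append(PSSM.from_rows(m.name, probs))
    return out


def write_motifs(pssms: list["PSSM"], path, background=None) -> None:
    """Write PSSMs in MEME minimal format (version 4 header)."""
    bg = background or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.5f}" for b in "ACGT") + "\n\n")
        for p in pssms:
            fh.write(f"MOTIF {p.family}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# pathway categories


def read_pathway_categories(table, config: PipelineConfig) -> dict[str, set[str]]:
    """gene id -> set of pathway category names.

    Two tab-separated columns with a header row. Unknown category names are
    fatal; duplicated (gene, category) rows are deduplicated with a warning.
    """
    df = pd.read_csv(table, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("pathway table needs two columns: gene id, category")
    mapping: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    allowed = set(config.category_names)
    for row in df.itertuples(index=False):
        gene, cat = str(row[0]), str(row[1])
        if cat not in allowed:
            raise FormatError(f"unknown pathway category {cat!r} for gene {gene}")
        if (gene, cat) in seen:
            logger.warning("duplicate pathway row (%s, %s) ignored", gene, cat)
            continue
        seen.add((gene, cat))
        mapping.setdefault(gene, set()).add(cat)
    return mapping


def write_pathway_categories(mapping: dict[str, set[str]], path) -> None:
    rows = [
        {"gene_id": g, "category": c}
        for g in sorted(mapping) for c in sorted(mapping[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "category"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks

_NET_COLUMNS = ["source", "target", "arc_kind", "p_value", "weight", "selected_flag"]


def network_to_frame(graph: nx.DiGraph) -> pd.DataFrame:
    rows = []
    for u, v, data in graph.edges(data=True):
        kind = "tf-tf" if graph.nodes[v].get("kind") == "tf" else "tf-operon"
        rows.append(
            {
                "source": u,
                "target": v,
                "arc_kind": kind,
                "p_value": data.get("p_value", "."),
                "weight": data.get("weight", "."),
                "selected_flag": int(bool(data.get("selected", False))),
            }
        )
    rows.sort(key=lambda r: (r["source"], r["target"]))
    return pd.DataFrame(rows, columns=_NET_COLUMNS)


def write_network(graph: nx.DiGraph, path, dialect: str = "tsv-edgelist") -> None:
    """Write a network (affinity or co-regulatory) as TSV edge list or GraphML.

    TSV columns: source, target, arc_kind, p_value, weight, selected_flag.
    """
    if dialect == "tsv-edgelist":
        network_to_frame(graph).to_csv(path, sep="\t", index=False)
    elif dialect == "graphml":
        g = nx.DiGraph()
        for n, d in graph.nodes(data=True):
            g.add_node(n, kind=str(d.get("kind", "operon")))
        for u, v, d in graph.edges(data=True):
            attrs = {}
            if "p_value" in d:
                attrs["p_value"] = float(d["p_value"])
            if "weight" in d:
                attrs["weight"] = int(d["weight"])
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path, dialect: str = "tsv-edgelist") -> nx.DiGraph:
    """Inverse of write_network (graph structure + attributes)."""
    if dialect == "graphml":
        return nx.read_graphml(str(path))
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        attrs = {}
        if not pd.isna(row.p_value) and row.p_value != ".":
            attrs["p_value"] = float(row.p_value)
        if not pd.isna(row.weight) and row.weight != ".":
            attrs["weight"] = int(float(row.weight))
        attrs["selected"] = bool(int(row.selected_flag))
        g.add_edge(row.source, row.target, **attrs)
        g.nodes[row.source]["kind"] = "tf"
        g.nodes[row.target]["kind"] = "tf" if row.arc_kind == "tf-tf" else "operon"
    return g


# ---------------------------------------------------------------------------
# tabular artifacts


def write_operons(operons: list[Operon], path) -> None:
    rows = [
        {
            "operon_id": op.operon_id,
            "contig": op.contig_id,
            "strand": op.strand,
            "genes": ",".join(op.gene_ids),
            "span_start": op.span[0],
            "span_end": op.span[1],
        }
        for op in operons
    ]
    pd.DataFrame(
        rows, columns=["operon_id", "contig", "strand", "genes", "span_start", "span_end"]
    ).to_csv(path, sep="\t", index=False)


def write_promoters_fasta(promoters: list[PromoterRegion], path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=f"{p.promoter_id}|{','.join(p.downstream_operon_ids)}",
            description="",
        )
        for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def write_matches(matches: list["MotifMatch"], path) -> None:
    rows = [
        {
            "family": m.family,
            "promoter": m.promoter_id,
            "offset": m.offset,
            "strand": m.strand,
            "score": m.score,
            "p_value": m.p_value,
        }
        for m in matches
    ]
    pd.DataFrame(
        rows, columns=["family", "promoter", "offset", "strand", "score", "p_value"]
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
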