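"""Operon prediction by intergenic distance and promoter-region extraction.

An operon is a maximal run of consecutive same-strand genes on one contig
in which every internal intergenic gap is shorter than a threshold
(default < 50 bp). Any intergenic region strictly longer than that
threshold that lies immediately upstream of an operon's 5'-most gene is a
putative promoter region. A region between divergently transcribed operons
serves both; a region between convergent operons serves neither and is not
emitted (it is logged instead). A gap of exactly the threshold splits the
operon yet is not a promoter: the two literal rules ("< 50" to join,
"> 50" to be a promoter) leave it unassigned, and we follow both literally.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """A coding sequence with optional TF-family and pathway annotations."""

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'
    product: str = ""
    tf_family: str | None = None
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.categories = frozenset(self.categories)

    @property
    def is_tf(self) -> bool:
        return bool(self.tf_family)


@dataclass
class Operon:
    """A run of co-transcribed consecutive same-strand genes."""

    operon_id: str
    contig_id: str
    strand: str
    gene_ids: list[str]
    span: tuple[int, int]
    promoter_ids: list[str] = field(default_factory=list)


@dataclass
class PromoterRegion:
    """An intergenic region upstream of one or two operons."""

    promoter_id: str
    contig_id: str
    interval: tuple[int, int]  # 1-based inclusive, forward strand
    sequence: str
    downstream_operon_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.interval[1] - self.interval[0] + 1


def intergenic_gap(prev: GeneRecord, nxt: GeneRecord) -> int:
    """Bases strictly between two consecutive genes (may be negative on overlap)."""
    return nxt.start - prev.end - 1


def call_operons(genes: list[GeneRecord], max_gap: int = 50) -> list[Operon]:
    """Partition genes into operons.

    Two consecutive genes share an operon iff they lie on the same contig
    and strand and the gap between them is < ``max_gap``. Overlapping
    same-strand genes (negative gap) merge trivially. Input must be sorted
    by (contig, start).
    """
    key = [(g.contig_id, g.start) for g in genes]
    if key != sorted(key):
        raise ValueError("genes must be sorted by (contig, start)")

    operons: list[Operon] = []
    run: list[GeneRecord] = []

    def flush() -> None:
        if not run:
            return
        oid = f"operon_{len(operons) + 1:04d}"
        operons.append(
            Operon(
                operon_id=oid,
                contig_id=run[0].contig_id,
                strand=run[0].strand,
                gene_ids=[g.gene_id for g in run],
                span=(min(g.start for g in run), max(g.end for g in run)),
            )
        )
        run.clear()

    for gene in genes:
        if run:
            prev = run[-1]
            same = (
                gene.contig_id == prev.contig_id
                and gene.strand == prev.strand
                and intergenic_gap(prev, gene) < max_gap
            )
            if not same:
                flush()
        run.append(gene)
    flush()
    return operons


def extract_promoters(
    operons: list[Operon],
    genes: list[GeneRecord],
    genome_sequences: dict[str, str],
    max_gap: int = 50,
) -> list[PromoterRegion]:
    """Emit every promoter intergenic region (> ``max_gap`` bp, upstream of
    an operon 5' end), including contig-end flanks.

    The sequence is always reported on the forward strand. Regions between
    convergent operons (no 5' end adjacent) are logged and skipped, as are
    regions of exactly ``max_gap`` bp.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    op_of_gene = {gid: op.operon_id for op in operons for gid in op.gene_ids}
    op_by_id = {op.operon_id: op for op in operons}

    by_contig: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
        by_contig.setdefault(g.contig_id, []).append(g)

    promoters: list[PromoterRegion] = []

    def emit(contig: str, lo: int, hi: int, downstream: list[str]) -> None:
        seq = genome_sequences[contig]
        if lo < 1 or hi > len(seq):
            raise ValueError(
                f"promoter interval [{lo},{hi}] outside contig {contig} bounds"
            )
        pid = f"promoter_{len(promoters) + 1:04d}"
        region = PromoterRegion(
            promoter_id=pid,
            contig_id=contig,
            interval=(lo, hi),
            sequence=seq[lo - 1 : hi],
            downstream_operon_ids=list(downstream),
        )
        promoters.append(region)
        for oid in downstream:
            op_by_id[oid].promoter_ids.append(pid)

    for contig, cgenes in by_contig.items():
        if contig not in genome_sequences:
            raise KeyError(f"contig {contig} absent from genome sequences")
        clen = len(genome_sequences[contig])

        # contig-start flank
        first = cgenes[0]
        flank = first.start - 1
        if flank > max_gap:
            downstream = [op_of_gene[first.gene_id]] if first.strand == "+" else []
            if downstream:
                emit(contig, 1, first.start - 1, downstream)
                logger.info("contig-end promoter at %s:1-%d", contig, first.start - 1)

        # internal intergenic regions
        for prev, nxt in zip(cgenes, cgenes[1:]):
            gap = intergenic_gap(prev, nxt)
            if gap == max_gap:
                logger.info(
                    "unassigned %d bp region between %s and %s (exactly at the "
                    "operon/promoter boundary)", gap, prev.gene_id, nxt.gene_id,
                )
                continue
            if gap <= max_gap:
                continue
            downstream = []
            if nxt.strand == "+":
                downstream.append(op_of_gene[nxt.gene_id])
            if prev.strand == "-":
                downstream.append(op_of_gene[prev.gene_id])
            if not downstream:
                logger.info(
                    "convergent intergenic region between %s and %s (%d bp) "
                    "serves no operon; skipped", prev.gene_id, nxt.gene_id, gap,
                )
                continue
            emit(contig, prev.end + 1, nxt.start - 1, downstream)

        # contig-end flank
        last = cgenes[-1]
        flank = clen - last.end
        if flank > max_gap and last.strand == "-":
            emit(contig, last.end + 1, clen, [op_of_gene[last.gene_id]])
            logger.info("contig-end promoter at %s:%d-%d", contig, last.end + 1, clen)

    # deterministic dedup guard: operon promoter lists unique
    for op in operons:
        op.promoter_ids = list(dict.fromkeys(op.promoter_ids))
    return promoters
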