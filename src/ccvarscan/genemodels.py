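"""Gene architecture and protein → CDS → genome coordinate projection.

All coordinates are 1-based fully-closed intervals (GenBank convention).
BED output converts to 0-based half-open.  One transcript per gene;
alternative isoforms are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .clusters import ChargeCluster

Interval = Tuple[int, int]

#: the four nested sequence contexts compared for variant density
REGION_TAGS = ("cluster_exonic", "cluster_exonic_plus_intronic", "full_mRNA", "gene")


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


@dataclass
class GeneModel:
    """Exon/CDS architecture of one transcript on one chromosome strand."""

    gene_id: str
    chrom: str
    strand: str
    gene_span: Interval
    exons: List[Interval]
    cds_exons: List[Interval]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for ivs in (self.exons, self.cds_exons):
            for (a, b) in ivs:
                if a > b:
                    raise ValueError(f"malformed interval ({a}, {b})")
            for prev, cur in zip(ivs, ivs[1:]):
                if cur[0] <= prev[1]:
                    raise ValueError("intervals must be ascending and disjoint")
        lo, hi = self.gene_span
        if self.exons and (self.exons[0][0] < lo or self.exons[-1][1] > hi):
            raise ValueError("exons extend outside gene_span")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(interval_len(iv) for iv in self.cds_exons)

    def cds_genomic_positions(self) -> List[int]:
        """Genomic position of each CDS base, in translation order.

        On the − strand, CDS position 1 is the highest genomic coordinate.
        """
        pos = [p for a, b in self.cds_exons for p in range(a, b + 1)]
        return pos[::-1] if self.strand == "-" else pos

    def spliced_cds(self, genome_seq: str) -> str:
        """CDS nucleotide sequence in translation order (strand-oriented)."""
        forward = "".join(genome_seq[a - 1 : b] for a, b in self.cds_exons)
        if self.strand == "-":
            return str(Seq(forward).reverse_complement())
        return forward

    def translate(self, genome_seq: str) -> str:
        """Protein sequence encoded by the model (stop codon stripped)."""
        prot = str(Seq(self.spliced_cds(genome_seq)).translate())
        return prot[:-1] if prot.endswith("*") else prot


@dataclass
class Region:
    """An interval set with its total nucleotide length."""

    tag: str
    intervals: List[Interval]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        self.length = sum(interval_len(iv) for iv in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.intervals)


@dataclass
class MappedCluster:
    """A charge cluster projected onto the genome, with its context regions."""

    cluster: ChargeCluster
    gene_id: str
    cds_interval: Interval
    genomic_blocks: List[Interval]
    exon_span: int
    context_regions: Dict[str, Region]


def protein_interval_to_cds(start_aa: int, end_aa: int) -> Interval:
    """Map a 1-based inclusive residue interval to CDS nucleotide coordinates."""
    if not 1 <= start_aa <= end_aa:
        raise ValueError(f"invalid residue interval ({start_aa}, {end_aa})")
    return (3 * start_aa - 2, 3 * end_aa)


def cds_to_genomic(cds_interval: Interval, model: GeneModel) -> List[Interval]:
    """Project a CDS interval through the exon map to genomic blocks.

    Blocks partition the image of the interval and are reported in
    ascending genomic order regardless of strand.
    """
    lo, hi = cds_interval
    total = model.cds_length
    if not 1 <= lo <= hi <= total:
        raise ValueError(
            f"CDS interval ({lo}, {hi}) outside [1, {total}]"
        )
    positions = sorted(model.cds_genomic_positions()[lo - 1 : hi])
    blocks: List[Interval] = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
        else:
            blocks.append((start, prev))
            start = prev = p
    blocks.append((start, prev))
    return blocks


def genomic_to_cds(pos: int, model: GeneModel) -> Optional[int]:
    """1-based CDS coordinate of a genomic position, or None outside the CDS."""
    cds_pos = model.cds_genomic_positions()
    try:
        return cds_pos.index(pos) + 1
    except ValueError:
        return None


def exon_span_count(genomic_blocks: Sequence[Interval], model: GeneModel) -> int:
    """Number of distinct exons intersected by the blocks."""
    hit = set()
    for (a, b) in genomic_blocks:
        covered = False
        for idx, (ea, eb) in enumerate(model.exons):
            if a <= eb and ea <= b:
                hit.add(idx)
                covered = True
        if not covered:
            raise ValueError(f"block ({a}, {b}) lies outside all exons")
    return len(hit)


def context_regions(
    genomic_blocks: Sequence[Interval], model: GeneModel
) -> Dict[str, Region]:
    """The four nested regions compared for variant density.

    cluster_exonic: the cluster's genomic blocks themselves;
    cluster_exonic_plus_intronic: the contiguous span from the first to the
    last block, so any interleaved introns are included;
    full_mRNA: the union of all exons; gene: the full gene span.
    """
    blocks = sorted(genomic_blocks)
    span = (blocks[0][0], blocks[-1][1])
    return {
        "cluster_exonic": Region("cluster_exonic", list(blocks)),
        "cluster_exonic_plus_intronic": Region(
            "cluster_exonic_plus_intronic", [span]
        ),
        "full_mRNA": Region("full_mRNA", list(model.exons)),
        "gene": Region("gene", [model.gene_span]),
    }


def map_cluster(cluster: ChargeCluster, model: GeneModel) -> MappedCluster:
    """Project a cluster's protein coordinates to the genome."""
    cds_iv = protein_interval_to_cds(cluster.start_aa, cluster.end_aa)
    blocks = cds_to_genomic(cds_iv, model)
    return MappedCluster(
        cluster=cluster,
        gene_id=model.gene_id,
        cds_interval=cds_iv,
        genomic_blocks=blocks,
        exon_span=exon_span_count(blocks, model),
        context_regions=context_regions(blocks, model),
    )


# ---------------------------------------------------------------------------
# GFF3 / BED12 I/O

def write_gff3(models: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.gene_span
            gid = m.gene_id
            fh.write(
                f"{m.chrom}\tccvarscan\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID=gene:{gid}\n"
            )
            fh.write(
                f"{m.chrom}\tccvarscan\tmRNA\t{m.exons[0][0]}\t{m.exons[-1][1]}\t.\t"
                f"{m.strand}\t.\tID=mrna:{gid};Parent=gene:{gid};"
                f"protein_id={m.protein_id}\n"
            )
            for i, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tccvarscan\texon\t{a}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID=exon:{gid}.{i};Parent=mrna:{gid}\n"
                )
            for i, (a, b) in enumerate(m.cds_exons, 1):
                fh.write(
                    f"{m.chrom}\tccvarscan\tCDS\t{a}\t{b}\t.\t{m.strand}\t0\t"
                    f"ID=cds:{gid}.{i};Parent=mrna:{gid}\n"
                )


def read_gff3(path: str) -> List[GeneModel]:
    """Load gene models from a GFF3 file (gene/mRNA/exon/CDS features)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        gid = gene.id.split(":", 1)[-1]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                gene_span=(gene.start, gene.end),
                exons=exons,
                cds_exons=cds,
                protein_id=mrna.attributes.get("protein_id", [""])[0],
            )
        )
    return models


def write_bed12(mapped: Sequence[MappedCluster], models: Dict[str, GeneModel], path: str) -> None:
    """Write cluster genomic blocks as BED12 (0-based half-open)."""
    with open(path, "w") as fh:
        for mc in mapped:
            m = models[mc.gene_id]
            blocks = mc.genomic_blocks
            chrom_start = blocks[0][0] - 1
            chrom_end = blocks[-1][1]
            sizes = ",".join(str(interval_len(b)) for b in blocks)
            starts = ",".join(str(b[0] - 1 - chrom_start) for b in blocks)
            name = f"{mc.cluster.protein_id}:{mc.cluster.sign}:{mc.cluster.start_aa}-{mc.cluster.end_aa}"
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            m.chrom,
                            chrom_start,
                            chrom_end,
                            name,
                            0,
                            m.strand,
                            chrom_start,
                            chrom_end,
                            0,
                            len(blocks),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )
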