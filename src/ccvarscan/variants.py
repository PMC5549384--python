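"""Variant records: overlap with regions and classification.

Each variant is classified four ways, as in dbSNP/ClinVar-style summaries:
nucleotide type (SNV / insertion / deletion / MNV), molecular consequence
on the encoded protein, clinical-significance class, and minor-allele-
frequency bin per population source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

from .aachanges import ProteinChange
from .genemodels import GeneModel, Interval, Region, genomic_to_cds

log = logging.getLogger(__name__)

MAF_SOURCES = ("1000G", "GO-ESP", "ExAC")
MAF_BIN_EDGES = (0.005, 0.01, 0.05)
MAF_BINS = ("lt_0.005", "0.005_to_0.01", "0.01_to_0.05", "ge_0.05", "unspecified")

VAR_TYPES = ("SNV", "insertion", "deletion", "MNV")

CONSEQUENCES = (
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "frameshift",
    "inframe_insertion",
    "inframe_deletion",
    "splice_region",
    "intronic",
    "non_coding",
)

CLINICAL_CLASSES = ("pathogenic_spectrum", "benign_spectrum", "unspecified")

_PATHOGENIC_LABELS = {
    "pathogenic",
    "probably pathogenic",
    "likely pathogenic",
    "risk factor",
}
_BENIGN_LABELS = {"benign", "likely benign", "probably benign"}

#: intronic nucleotides on each side of an exon counted as splice region
SPLICE_WINDOW = 2


class ClassificationError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One normalized variant (single alt allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    clinical_raw: Optional[str] = None
    maf: Dict[str, float] = field(default_factory=dict)
    var_id: str = "."

    def __post_init__(self) -> None:
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"ref/alt must be non-empty and differ: {self.ref}>{self.alt}")
        for src, f in self.maf.items():
            if not 0.0 <= f <= 0.5:
                raise ValueError(f"MAF {f} for {src} outside [0, 0.5]")


def normalize_alleles(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim shared suffix then prefix to the minimal VCF representation.

    At least one base is kept on each allele (the VCF anchor convention);
    the position advances past any trimmed prefix.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_variant_type(ref: str, alt: str) -> str:
    """Nucleotide-level type from normalized alleles."""
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    if len(ref) == len(alt):
        return "MNV"
    raise ClassificationError(f"unnormalizable allele pair {ref}>{alt}")


def variants_in_region(
    variants: Iterable[VariantRecord], intervals: Sequence[Interval]
) -> List[VariantRecord]:
    """Variants whose position falls in any 1-based inclusive interval."""
    return [v for v in variants if any(a <= v.pos <= b for a, b in intervals)]


def maf_bin(frequency: Optional[float], source: str = "ExAC") -> str:
    """Assign a minor-allele frequency to one of four half-open bins.

    [0, 0.005) < [0.005, 0.01) < [0.01, 0.05) < [0.05, 0.5]; an absent
    frequency maps to 'unspecified'.
    """
    if frequency is None:
        return "unspecified"
    if not 0.0 <= frequency <= 0.5:
        raise ValueError(f"MAF {frequency} outside [0, 0.5]")
    for edge, name in zip(MAF_BIN_EDGES, MAF_BINS):
        if frequency < edge:
            return name
    return "ge_0.05"


def clinical_class(raw: Optional[str]) -> str:
    """Collapse a free-text clinical-significance label into three classes."""
    if not raw:
        return "unspecified"
    label = raw.strip().lower().replace("_", " ").replace("-", " ")
    if label in _PATHOGENIC_LABELS:
        return "pathogenic_spectrum"
    if label in _BENIGN_LABELS:
        return "benign_spectrum"
    return "unspecified"


# ---------------------------------------------------------------------------
# molecular consequence

def _splice_sites(model: GeneModel) -> List[int]:
    sites: List[int] = []
    for (_, prev_end), (next_start, _) in zip(model.exons, model.exons[1:]):
        sites.extend(range(prev_end + 1, prev_end + 1 + SPLICE_WINDOW))
        sites.extend(range(next_start - SPLICE_WINDOW, next_start))
    return sites


def _affected_span(variant: VariantRecord) -> Tuple[int, int]:
    """Genomic positions whose bases the variant touches."""
    return variant.pos, variant.pos + len(variant.ref) - 1


def molecular_consequence(
    variant: VariantRecord, model: GeneModel, genome_seq: str
) -> Tuple[str, Optional[ProteinChange]]:
    """Protein-level consequence of a variant on one gene model.

    Coding substitutions are resolved by mutating the affected codon(s) and
    translating; indels are frameshift when the length change is not a
    multiple of 3, inframe otherwise.  When several labels could apply the
    precedence is splice_region > stop_gained > stop_lost > frameshift >
    inframe > missense > synonymous.  The second return value carries the
    implied protein change for coding substitutions.
    """
    if variant.chrom != model.chrom:
        raise ValueError(f"variant on {variant.chrom}, model on {model.chrom}")
    lo, hi = _affected_span(variant)
    observed = genome_seq[lo - 1 : hi]
    if observed.upper() != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} ref {variant.ref!r} != genome {observed!r}"
        )

    splice = set(_splice_sites(model))
    if any(p in splice for p in range(lo, hi + 1)):
        return "splice_region", None

    vtype = classify_variant_type(variant.ref, variant.alt)
    in_exon = lambda p: any(a <= p <= b for a, b in model.exons)
    in_cds = lambda p: genomic_to_cds(p, model) is not None

    if vtype in ("SNV", "MNV"):
        positions = list(range(lo, hi + 1))
        if all(in_cds(p) for p in positions):
            return _substitution_consequence(variant, model, genome_seq)
        if any(in_exon(p) for p in positions):
            return "non_coding", None
        return "intronic", None

    # indel: the changed bases sit after the anchor base
    if vtype == "insertion":
        touched = [variant.pos, variant.pos + 1]
        delta = len(variant.alt) - len(variant.ref)
    else:
        touched = list(range(variant.pos + 1, variant.pos + len(variant.ref)))
        delta = len(variant.ref) - len(variant.alt)
    if any(in_cds(p) for p in touched):
        if delta % 3 != 0:
            return "frameshift", _first_codon_change(variant, model, genome_seq, "frameshift")
        return ("inframe_insertion" if vtype == "insertion" else "inframe_deletion"), None
    if any(in_exon(p) for p in touched):
        return "non_coding", None
    return "intronic", None


def _strand_base(base: str, strand: str) -> str:
    return str(Seq(base).complement()) if strand == "-" else base


def _substitution_consequence(
    variant: VariantRecord, model: GeneModel, genome_seq: str
) -> Tuple[str, Optional[ProteinChange]]:
    cds_seq = model.spliced_cds(genome_seq)
    mutated = list(cds_seq)
    first_cds_pos = None
    for offset in range(len(variant.ref)):
        gpos = variant.pos + offset
        cpos = genomic_to_cds(gpos, model)
        mutated[cpos - 1] = _strand_base(variant.alt[offset], model.strand)
        if first_cds_pos is None or cpos < first_cds_pos:
            first_cds_pos = cpos
    ref_prot = str(Seq(cds_seq).translate())
    alt_prot = str(Seq("".join(mutated)).translate())
    aa_pos = (first_cds_pos - 1) // 3 + 1
    ref_aa, alt_aa = ref_prot[aa_pos - 1], alt_prot[aa_pos - 1]
    # MNVs can span two codons; report the first differing residue
    if ref_aa == alt_aa and ref_prot != alt_prot:
        aa_pos = next(i + 1 for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b)
        ref_aa, alt_aa = ref_prot[aa_pos - 1], alt_prot[aa_pos - 1]
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained", ProteinChange(aa_pos, ref_aa, "*", "stop_gained")
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost", ProteinChange(aa_pos, "*", alt_aa, "stop_lost")
    if ref_prot == alt_prot:
        return "synonymous", ProteinChange(aa_pos, ref_aa, ref_aa, "synonymous")
    return "missense", ProteinChange(aa_pos, ref_aa, alt_aa, "substitution")


def _first_codon_change(
    variant: VariantRecord, model: GeneModel, genome_seq: str, kind: str
) -> Optional[ProteinChange]:
    cpos = genomic_to_cds(variant.pos, model) or genomic_to_cds(variant.pos + 1, model)
    if cpos is None:
        return None
    aa_pos = (cpos - 1) // 3 + 1
    prot = str(Seq(model.spliced_cds(genome_seq)).translate())
    if aa_pos > len(prot):
        return None
    return ProteinChange(aa_pos, prot[aa_pos - 1], "", kind)


# ---------------------------------------------------------------------------
# VCF I/O (pysam)

_INFO_KEYS = {"1000G": "MAF_1000G", "GO-ESP": "MAF_ESP", "ExAC": "MAF_EXAC"}


def read_vcf(path: str) -> List[VariantRecord]:
    """Read a VCF (v4.x), splitting multi-allelic records per alt allele."""
    import pysam

    out: List[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            clnsig = rec.info.get("CLNSIG")
            if isinstance(clnsig, tuple):
                clnsig = clnsig[0]
            maf = {}
            for src, key in _INFO_KEYS.items():
                val = rec.info.get(key)
                if isinstance(val, tuple):
                    val = val[0]
                if val is not None:
                    maf[src] = float(val)
            for alt in rec.alts or ():
                pos, ref, a = normalize_alleles(rec.pos, rec.ref, alt)
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=a,
                        clinical_raw=clnsig,
                        maf=dict(maf),
                        var_id=rec.id or ".",
                    )
                )
    return out


def write_vcf(
    variants: Sequence[VariantRecord], path: str, contigs: Dict[str, int]
) -> None:
    """Write variants to an uncompressed VCF with the package's INFO keys."""
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("CLNSIG", 1, "String", "Clinical significance label")
    header.info.add("MAF_1000G", 1, "Float", "1000 Genomes minor allele frequency")
    header.info.add("MAF_ESP", 1, "Float", "GO-ESP minor allele frequency")
    header.info.add("MAF_EXAC", 1, "Float", "ExAC minor allele frequency")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.var_id
            )
            if v.clinical_raw:
                rec.info["CLNSIG"] = v.clinical_raw.replace(" ", "_")
            for src, key in _INFO_KEYS.items():
                if src in v.maf:
                    rec.info[key] = v.maf[src]
            vcf.write(rec)


# ---------------------------------------------------------------------------
# annotation table

def annotate_variants(
    variants: Sequence[VariantRecord],
    regions: Dict[str, Region],
    model: GeneModel,
    genome_seq: str,
    cluster_id: str = "",
) -> pd.DataFrame:
    """One row per (variant, region containing it): full classification."""
    rows = []
    for tag, region in regions.items():
        for v in variants_in_region(variants, region.intervals):
            try:
                cons, pchange = molecular_consequence(v, model, genome_seq)
            except ReferenceMismatchError as exc:
                log.warning("skipping variant with reference mismatch: %s", exc)
                continue
            row = {
                "cluster_id": cluster_id,
                "region_tag": tag,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "var_type": classify_variant_type(v.ref, v.alt),
                "consequence": cons,
                "clinical_class": clinical_class(v.clinical_raw),
                "protein_change": (
                    "" if pchange is None else f"{pchange.ref_res}{pchange.position}{pchange.alt_res}"
                ),
            }
            for src in MAF_SOURCES:
                row[f"maf_bin_{src}"] = maf_bin(v.maf.get(src), src)
            rows.append(row)
    return pd.DataFrame(rows)
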