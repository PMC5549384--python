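"""Synthetic cohorts with planted ground truth.

Generates proteins carrying planted charge clusters, gene models whose
clusters span a configurable number of exons, genomes, variant sets with a
configurable type / MAF / clinical mixture, and HGVS.p-style protein-change
sets — everything the pipeline consumes — together with a truth record per
generated object, so every stage can be validated by parameter recovery
without any database download.

Defaults encode the study conditions the analysis was designed around:
negative-cluster lengths 24.2 ± 3.9 aa and positive 27.8 ± 7.6 aa (truncated
to [20, 75]); clusters on one exon 67% of the time, two 31%, three 2%; SNVs
80% of variants with deletions outnumbering insertions 3:2 at the
nucleotide level; 78% of specified ExAC frequencies below 0.005 for
negative clusters (85% for positive); protein-level change mix 55%
substitution / 28% synonymous / 17% indels split 3:1 deletion:insertion;
Glu affected in 34.5% of mutated residues and Asp in 22%; and 54% of
insertions inserting a single residue.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from . import clusters as cl
from .aachanges import GROUP_OF, GROUPS, to_three_letter
from .genemodels import GeneModel, Interval, map_cluster
from .variants import MAF_SOURCES, VariantRecord

UNCHARGED = sorted(set(GROUP_OF) - set("DEKR"))
_STOPS = ("TAA", "TAG", "TGA")

_CODONS_FOR: Dict[str, List[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()


class ConfigError(ValueError):
    pass


def _check_mixture(name: str, probs: Sequence[float]) -> None:
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigError(f"{name} probabilities sum to {sum(probs)}, not 1")
    if any(p < 0 for p in probs):
        raise ConfigError(f"{name} has a negative probability")


def _default_insertion_spectrum() -> Tuple[float, ...]:
    # 54% single-residue insertions; the remaining mass decays
    # geometrically over lengths 2..12
    tail = np.array([0.46 ** (k - 2) for k in range(2, 13)])
    tail = 0.46 * tail / tail.sum()
    return tuple([0.54] + list(tail))


def _default_residue_weights() -> Dict[str, float]:
    # Glu and Asp dominate inside negative clusters; the remainder is
    # split evenly between the polar and hydrophobic groups; basic
    # residues are absent from opposite-charge-free negative clusters
    weights = {"E": 0.345, "D": 0.22}
    polar = [aa for aa in GROUP_OF if GROUP_OF[aa] == "polar"]
    hydro = [aa for aa in GROUP_OF if GROUP_OF[aa] == "hydrophobic"]
    for aa in polar:
        weights[aa] = 0.22 / len(polar)
    for aa in hydro:
        weights[aa] = 0.215 / len(hydro)
    return weights


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_genes: int = 50
    protein_length: int = 400

    # cluster planting
    sign_mix: Dict[str, float] = field(
        default_factory=lambda: {cl.NEGATIVE: 0.75, cl.POSITIVE: 0.25}
    )
    cluster_length_by_sign: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {cl.NEGATIVE: (24.2, 3.9), cl.POSITIVE: (27.8, 7.6)}
    )
    cluster_length_bounds: Tuple[int, int] = (20, 75)
    cluster_charge_density: float = 0.55
    background_charge_freq: float = 0.025  # per charged residue D, E, K, R

    # gene architecture
    exon_span_mix: Tuple[float, float, float] = (0.67, 0.31, 0.02)  # 1, 2, 3+ exons
    intron_length_range: Tuple[int, int] = (60, 400)
    utr5_len: int = 50
    utr3_len: int = 100
    flank_len: int = 150
    gene_pad: int = 50
    extra_intron_prob: float = 0.5

    # variants: density per disjoint stratum (variants per nt)
    density_cluster_exonic: float = 0.25
    density_cluster_intron: float = 0.08
    density_mrna_other: float = 0.10
    density_gene_other: float = 0.05
    variant_type_mix: Dict[str, float] = field(
        default_factory=lambda: {"SNV": 0.80, "deletion": 0.12, "insertion": 0.08}
    )
    indel_length_range: Tuple[int, int] = (1, 6)
    maf_bin_mix_by_sign: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            cl.NEGATIVE: (0.78, 0.10, 0.07, 0.05),
            cl.POSITIVE: (0.85, 0.07, 0.05, 0.03),
        }
    )
    maf_unspecified_share: float = 0.20
    clinical_mix_by_sign: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            # specified labels are half the mass; benign spectrum is 46% of
            # the specified mass for negative clusters, pathogenic 34% for
            # positive ones
            cl.NEGATIVE: {
                "Pathogenic": 0.15,
                "Likely pathogenic": 0.08,
                "risk factor": 0.04,
                "Benign": 0.13,
                "Likely benign": 0.10,
                "Uncertain significance": 0.25,
                "": 0.25,
            },
            cl.POSITIVE: {
                "Pathogenic": 0.10,
                "Likely pathogenic": 0.05,
                "risk factor": 0.02,
                "Benign": 0.18,
                "Likely benign": 0.15,
                "Uncertain significance": 0.25,
                "": 0.25,
            },
        }
    )

    # protein-change sets (negative-cluster conditions)
    change_category_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "substitution": 0.55,
            "synonymous": 0.28,
            "deletion": 0.1275,
            "insertion": 0.0425,
        }
    )
    affected_residue_weights: Dict[str, float] = field(
        default_factory=_default_residue_weights
    )
    substitution_dest_group_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "polar": 0.42,
            "acidic": 0.23,
            "basic": 0.23,
            "hydrophobic": 0.12,
        }
    )
    insertion_length_spectrum: Tuple[float, ...] = field(
        default_factory=_default_insertion_spectrum
    )
    inserted_group_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "acidic": 0.90,
            "polar": 0.05,
            "hydrophobic": 0.025,
            "basic": 0.025,
        }
    )

    def __post_init__(self) -> None:
        _check_mixture("sign_mix", list(self.sign_mix.values()))
        _check_mixture("exon_span_mix", self.exon_span_mix)
        _check_mixture("variant_type_mix", list(self.variant_type_mix.values()))
        for sign, mix in self.maf_bin_mix_by_sign.items():
            _check_mixture(f"maf_bin_mix[{sign}]", mix)
        for sign, mix in self.clinical_mix_by_sign.items():
            _check_mixture(f"clinical_mix[{sign}]", list(mix.values()))
        _check_mixture("change_category_mix", list(self.change_category_mix.values()))
        _check_mixture(
            "affected_residue_weights", list(self.affected_residue_weights.values())
        )
        _check_mixture(
            "substitution_dest_group_mix",
            list(self.substitution_dest_group_mix.values()),
        )
        _check_mixture("insertion_length_spectrum", self.insertion_length_spectrum)
        _check_mixture("inserted_group_mix", list(self.inserted_group_mix.values()))
        lo, hi = self.cluster_length_bounds
        if not 1 <= lo <= hi:
            raise ConfigError("invalid cluster length bounds")
        if hi + 2 > self.protein_length:
            raise ConfigError("protein too short to hold a planted cluster")
        for d in (
            self.density_cluster_exonic,
            self.density_cluster_intron,
            self.density_mrna_other,
            self.density_gene_other,
        ):
            if not 0.0 <= d <= 1.0:
                raise ConfigError(f"variant density {d} outside [0, 1]")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# helpers

def _choice(rng: np.random.Generator, mix: Dict[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    """Rejection-sampled integer from a truncated normal."""
    while True:
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# proteins

def simulate_protein(
    config: SimulationConfig,
    rng: np.random.Generator,
    sign: Optional[str] = None,
    protein_id: str = "prot1",
) -> Tuple[str, List[Dict]]:
    """A protein with one planted charge cluster.

    Background residues are i.i.d. from a low-charge composition; the
    planted segment draws only same-sign and uncharged residues at the
    configured charge density, starts and ends charged, and is isolated by
    one opposite-charge residue on each side so it cannot extend or merge
    with background runs.
    """
    if sign is None:
        sign = _choice(rng, config.sign_mix)
    same = sorted(cl.NEGATIVE_RESIDUES if sign == cl.NEGATIVE else cl.POSITIVE_RESIDUES)
    opposite = sorted(cl.POSITIVE_RESIDUES if sign == cl.NEGATIVE else cl.NEGATIVE_RESIDUES)
    length = config.protein_length
    mean, sd = config.cluster_length_by_sign[sign]
    lo, hi = config.cluster_length_bounds
    clen = _truncated_normal(rng, mean, sd, lo, hi)

    # background composition
    charged = list("DEKR")
    p_bg = np.array(
        [config.background_charge_freq] * 4
        + [(1 - 4 * config.background_charge_freq) / len(UNCHARGED)] * len(UNCHARGED)
    )
    alphabet = charged + UNCHARGED
    seq = list(rng.choice(alphabet, size=length, p=p_bg))

    start = int(rng.integers(2, length - clen))  # 1-based; leaves room for blockers
    for i in range(start, start + clen):
        if rng.random() < config.cluster_charge_density:
            seq[i - 1] = same[rng.integers(len(same))]
        else:
            seq[i - 1] = UNCHARGED[rng.integers(len(UNCHARGED))]
    seq[start - 1] = same[rng.integers(len(same))]
    seq[start + clen - 2] = same[rng.integers(len(same))]
    # isolation blockers
    seq[start - 2] = opposite[rng.integers(len(opposite))]
    seq[start + clen - 1] = opposite[rng.integers(len(opposite))]

    truth = [
        {
            "protein_id": protein_id,
            "sign": sign,
            "start_aa": start,
            "end_aa": start + clen - 1,
            "length_aa": clen,
        }
    ]
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# gene models

def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    ]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def simulate_gene_model(
    protein: str,
    truth_cluster: Dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str = "gene1",
    chrom: str = "chr1",
) -> Tuple[GeneModel, str, Dict]:
    """A gene model and chromosome sequence encoding the protein.

    The protein is back-translated with uniform synonymous codon choice;
    introns are inserted so the planted cluster spans 1, 2 or 3 exons per
    the configured mixture (optionally with extra introns outside the
    cluster); UTR exon padding and intergenic flanks are added.  The
    spliced CDS re-translates to the protein exactly.
    """
    cds = _back_translate(protein, rng)
    cds_len = len(cds)
    c1, c2 = 3 * truth_cluster["start_aa"] - 2, 3 * truth_cluster["end_aa"]

    span = 1 + int(rng.choice(3, p=np.array(config.exon_span_mix)))
    # cuts inside the cluster interrupt it; each cut sits after CDS base j
    inside = sorted(rng.choice(np.arange(c1, c2), size=span - 1, replace=False)) if span > 1 else []
    cuts = [int(j) for j in inside]
    if c1 > 2 and rng.random() < config.extra_intron_prob:
        cuts.append(int(rng.integers(1, c1 - 1)))
    if c2 < cds_len - 1 and rng.random() < config.extra_intron_prob:
        cuts.append(int(rng.integers(c2 + 1, cds_len)))
    cuts = sorted(set(cuts))

    pieces = []
    prev = 0
    for j in cuts + [cds_len]:
        pieces.append(cds[prev:j])
        prev = j

    utr5 = _random_dna(rng, config.utr5_len)
    utr3 = _random_dna(rng, config.utr3_len)
    ilo, ihi = config.intron_length_range

    # assemble pre-mRNA in transcription order; track 0-based offsets
    segments: List[Tuple[str, int, int]] = []  # (kind, start, end) half-open
    parts: List[str] = []
    off = 0

    def _push(kind: str, s: str) -> None:
        nonlocal off
        parts.append(s)
        segments.append((kind, off, off + len(s)))
        off += len(s)

    for i, piece in enumerate(pieces):
        if i == 0:
            _push("utr5", utr5)
        else:
            n_int = int(rng.integers(ilo, ihi + 1))
            _push("intron", "GT" + _random_dna(rng, n_int - 4) + "AG")
        _push("cds", piece)
    _push("utr3", utr3)

    pre = "".join(parts)
    flank5 = _random_dna(rng, config.flank_len)
    flank3 = _random_dna(rng, config.flank_len)
    strand = "+" if rng.random() < 0.5 else "-"

    P, F = len(pre), config.flank_len
    if strand == "+":
        genome = flank5 + pre + flank3
        to_genomic = lambda a, b: (F + a + 1, F + b)  # 0-based half-open -> 1-based closed
    else:
        genome = flank5 + str(Seq(pre).reverse_complement()) + flank3
        to_genomic = lambda a, b: (F + P - b + 1, F + P - a)

    exon_ivs: List[Interval] = []
    cds_ivs: List[Interval] = []
    cur_exon: Optional[List[int]] = None
    for kind, a, b in segments:
        if kind == "intron":
            exon_ivs.append(tuple(cur_exon))  # type: ignore[arg-type]
            cur_exon = None
            continue
        if cur_exon is None:
            cur_exon = [a, b]
        else:
            cur_exon[1] = b
        if kind == "cds":
            cds_ivs.append((a, b))
    exon_ivs.append(tuple(cur_exon))  # type: ignore[arg-type]

    exons = sorted(to_genomic(a, b) for a, b in exon_ivs)
    cds_exons = sorted(to_genomic(a, b) for a, b in cds_ivs)
    gene_span = (
        max(exons[0][0] - config.gene_pad, 1),
        min(exons[-1][1] + config.gene_pad, len(genome)),
    )
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        gene_span=gene_span,
        exons=exons,
        cds_exons=cds_exons,
        protein_id=truth_cluster["protein_id"],
    )
    truth = dict(truth_cluster)
    truth.update({"gene_id": gene_id, "chrom": chrom, "strand": strand, "exon_span": span})
    return model, genome, truth


# ---------------------------------------------------------------------------
# variants

_MAF_BIN_RANGES = ((0.0, 0.005), (0.005, 0.01), (0.01, 0.05), (0.05, 0.5))
_MAF_BIN_NAMES = ("lt_0.005", "0.005_to_0.01", "0.01_to_0.05", "ge_0.05")


def _stratum_positions(model: GeneModel, blocks: Sequence[Interval]) -> Dict[str, List[int]]:
    in_blocks = {p for a, b in blocks for p in range(a, b + 1)}
    span = range(min(a for a, _ in blocks), max(b for _, b in blocks) + 1)
    in_exons = {p for a, b in model.exons for p in range(a, b + 1)}
    glo, ghi = model.gene_span
    gene = set(range(glo, ghi + 1))
    return {
        "cluster_exonic": sorted(in_blocks),
        "cluster_intron": sorted(set(span) - in_blocks),
        "mrna_other": sorted(in_exons - in_blocks),
        "gene_other": sorted(gene - in_exons - set(span)),
    }


def simulate_variants(
    model: GeneModel,
    genome_seq: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    sign: str = cl.NEGATIVE,
    cluster_blocks: Optional[Sequence[Interval]] = None,
) -> Tuple[List[VariantRecord], List[Dict]]:
    """Variants over the gene with planted type, MAF and clinical mixtures.

    The gene is partitioned into four disjoint strata (cluster exonic
    blocks, introns interrupting the cluster, the rest of the mRNA, the
    rest of the gene); within each, the variant count is Binomial(stratum
    length, stratum density) and positions are drawn without collision.
    Alleles are realized against the genome sequence, so every emitted ref
    matches the reference.
    """
    if cluster_blocks is None:
        raise ConfigError("cluster_blocks required: pass the mapped cluster's blocks")
    strata = _stratum_positions(model, cluster_blocks)
    densities = {
        "cluster_exonic": config.density_cluster_exonic,
        "cluster_intron": config.density_cluster_intron,
        "mrna_other": config.density_mrna_other,
        "gene_other": config.density_gene_other,
    }
    bin_mix = config.maf_bin_mix_by_sign[sign]
    clin_mix = config.clinical_mix_by_sign[sign]
    max_del = config.indel_length_range[1]

    records: List[VariantRecord] = []
    truths: List[Dict] = []
    serial = 0
    for tag, positions in strata.items():
        if not positions:
            continue
        n = int(rng.binomial(len(positions), densities[tag]))
        n = min(n, len(positions))
        chosen = sorted(
            int(p)
            for p in rng.choice(np.array(positions), size=n, replace=False)
            if p + max_del + 1 < len(genome_seq)
        )
        for pos in chosen:
            vtype = _choice(rng, config.variant_type_mix)
            ref_base = genome_seq[pos - 1]
            if vtype == "SNV":
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                ref = ref_base
            elif vtype == "insertion":
                ilen = int(rng.integers(config.indel_length_range[0], config.indel_length_range[1] + 1))
                ref = ref_base
                alt = ref_base + _random_dna(rng, ilen)
            else:
                dlen = int(rng.integers(config.indel_length_range[0], config.indel_length_range[1] + 1))
                ref = genome_seq[pos - 1 : pos + dlen]
                alt = ref_base
            maf: Dict[str, float] = {}
            maf_bins: Dict[str, str] = {}
            for src in MAF_SOURCES:
                if rng.random() < config.maf_unspecified_share:
                    maf_bins[src] = "unspecified"
                    continue
                b = int(rng.choice(4, p=np.array(bin_mix)))
                lo, hi = _MAF_BIN_RANGES[b]
                maf[src] = float(rng.uniform(lo, hi))
                maf_bins[src] = _MAF_BIN_NAMES[b]
            label = _choice(rng, clin_mix)
            serial += 1
            rec = VariantRecord(
                chrom=model.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                clinical_raw=label or None,
                maf=maf,
                var_id=f"{model.gene_id}_v{serial}",
            )
            records.append(rec)
            truths.append(
                {
                    "var_id": rec.var_id,
                    "chrom": model.chrom,
                    "pos": pos,
                    "stratum": tag,
                    "type": vtype,
                    "maf_bins": maf_bins,
                    "clinical_raw": label,
                }
            )
    return records, truths


# ---------------------------------------------------------------------------
# protein changes

def simulate_protein_changes(
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
    max_position: int = 400,
) -> Tuple[List[str], List[Dict]]:
    """HGVS.p-style change strings with the configured category mixture.

    Every string round-trips through the parser to its truth record.
    """
    strings: List[str] = []
    truths: List[Dict] = []
    res_keys = list(config.affected_residue_weights)
    res_p = np.array([config.affected_residue_weights[r] for r in res_keys])
    spectrum = np.array(config.insertion_length_spectrum)
    for _ in range(n):
        kind = _choice(rng, config.change_category_mix)
        ref = res_keys[rng.choice(len(res_keys), p=res_p)]
        pos = int(rng.integers(1, max_position + 1))
        if kind == "substitution":
            group = _choice(rng, config.substitution_dest_group_mix)
            pool = [aa for aa in GROUP_OF if GROUP_OF[aa] == group and aa != ref]
            alt = pool[rng.integers(len(pool))]
            text = f"{to_three_letter(ref)}{pos}{to_three_letter(alt)}"
            truth = {"kind": kind, "position": pos, "ref": ref, "alt": alt}
        elif kind == "synonymous":
            text = f"{to_three_letter(ref)}{pos}{to_three_letter(ref)}"
            truth = {"kind": kind, "position": pos, "ref": ref, "alt": ref}
        elif kind == "deletion":
            text = f"{to_three_letter(ref)}{pos}del"
            truth = {"kind": kind, "position": pos, "ref": ref}
        else:  # insertion
            ilen = 1 + int(rng.choice(len(spectrum), p=spectrum))
            inserted = []
            for _i in range(ilen):
                group = _choice(rng, config.inserted_group_mix)
                pool = [aa for aa in GROUP_OF if GROUP_OF[aa] == group]
                inserted.append(pool[rng.integers(len(pool))])
            ins = "".join(inserted)
            ref2 = res_keys[rng.choice(len(res_keys), p=res_p)]
            text = (
                f"{to_three_letter(ref)}{pos}_{to_three_letter(ref2)}{pos + 1}ins"
                + "".join(to_three_letter(a) for a in ins)
            )
            truth = {"kind": kind, "position": pos, "inserted": ins}
        strings.append(text)
        truths.append(truth)
    return strings, truths


# ---------------------------------------------------------------------------
# cohort orchestration

def simulate_cohort(
    config: SimulationConfig,
    seed: int,
    out_dir: Optional[str] = None,
    n_changes: int = 0,
) -> Dict:
    """Generate a full cohort; optionally write all files to ``out_dir``.

    Returns an in-memory bundle: proteins, gene models, genome contigs,
    variants, protein changes and the truth records, all keyed by gene.
    Identical (config, seed) produce byte-identical output files.
    """
    rng = np.random.default_rng(seed)
    bundle: Dict = {
        "proteins": {},
        "models": {},
        "genomes": {},
        "variants": {},
        "truth": {"clusters": [], "genes": [], "variants": [], "changes": []},
        "changes": [],
    }
    for i in range(1, config.n_genes + 1):
        pid, gid, chrom = f"P{i:04d}", f"G{i:04d}", f"chr{i}"
        seq, truth_clusters = simulate_protein(config, rng, protein_id=pid)
        tc = truth_clusters[0]
        model, genome, gene_truth = simulate_gene_model(
            seq, tc, config, rng, gene_id=gid, chrom=chrom
        )
        cluster = cl.ChargeCluster(
            protein_id=pid,
            sign=tc["sign"],
            start_aa=tc["start_aa"],
            end_aa=tc["end_aa"],
            length_aa=tc["length_aa"],
            charged_count=0,
            p_value=0.0,
        )
        mapped = map_cluster(cluster, model)
        recs, vtruth = simulate_variants(
            model, genome, config, rng, sign=tc["sign"],
            cluster_blocks=mapped.genomic_blocks,
        )
        bundle["proteins"][pid] = seq
        bundle["models"][gid] = model
        bundle["genomes"][chrom] = genome
        bundle["variants"][gid] = recs
        bundle["truth"]["clusters"].append(tc)
        bundle["truth"]["genes"].append(gene_truth)
        bundle["truth"]["variants"].extend(vtruth)
    if n_changes:
        strings, ctruth = simulate_protein_changes(config, rng, n_changes)
        bundle["changes"] = strings
        bundle["truth"]["changes"] = ctruth
    if out_dir is not None:
        _write_cohort(bundle, config, out_dir)
    return bundle


def _write_cohort(bundle: Dict, config: SimulationConfig, out_dir: str) -> None:
    from .genemodels import write_gff3
    from .variants import write_vcf

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "proteins.fasta"), "w") as fh:
        for pid, seq in bundle["proteins"].items():
            fh.write(f">{pid}\n{seq}\n")
    with open(os.path.join(out_dir, "genome.fasta"), "w") as fh:
        for chrom, seq in bundle["genomes"].items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gff3(list(bundle["models"].values()), os.path.join(out_dir, "genes.gff3"))
    contigs = {chrom: len(seq) for chrom, seq in bundle["genomes"].items()}
    all_variants = [v for recs in bundle["variants"].values() for v in recs]
    write_vcf(all_variants, os.path.join(out_dir, "variants.vcf"), contigs)
    if bundle["changes"]:
        with open(os.path.join(out_dir, "protein_changes.tsv"), "w") as fh:
            fh.write("cluster_id\tprotein_change\n")
            for i, text in enumerate(bundle["changes"]):
                fh.write(f"cc{i % max(config.n_genes, 1) + 1}\t{text}\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(bundle["truth"], fh, indent=1, sort_keys=True)
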