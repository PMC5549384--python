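"""End-to-end orchestration: detect → map → annotate → aachange → report.

Every stage reads and writes plain files with documented schemas; a run
manifest records the configuration digest, the seed, input digests and the
produced outputs, so identical manifests reproduce identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .aachanges import (
    affected_residue_counts,
    exchange_matrix,
    insertion_spectrum,
    kind_counts,
    parse_protein_change,
    variation_type_by_group,
)
from .clusters import DEFAULT_ALPHA, DEFAULT_P0_FLOOR, NEGATIVE, POSITIVE, ChargeCluster, find_charge_clusters
from .genemodels import GeneModel, map_cluster, read_gff3, write_bed12
from .statstests import chi_square_homogeneity, density_report, fraction_table
from .variants import annotate_variants, read_vcf, variants_in_region

log = logging.getLogger(__name__)

CLUSTER_TSV_COLUMNS = [
    "protein_id", "sign", "start_aa", "end_aa", "length_aa", "charged_count", "p_value",
]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_detect(
    protein_fasta: str,
    alpha: float = DEFAULT_ALPHA,
    p0_floor: float = DEFAULT_P0_FLOOR,
) -> pd.DataFrame:
    """Detect clusters of both signs in every FASTA record."""
    rows = []
    for rec in SeqIO.parse(protein_fasta, "fasta"):
        for sign in (NEGATIVE, POSITIVE):
            for c in find_charge_clusters(
                str(rec.seq), sign, alpha=alpha, p0_floor=p0_floor, protein_id=rec.id
            ):
                rows.append(
                    [c.protein_id, c.sign, c.start_aa, c.end_aa, c.length_aa,
                     c.charged_count, c.p_value]
                )
    return pd.DataFrame(rows, columns=CLUSTER_TSV_COLUMNS)


def stage_map(clusters_df: pd.DataFrame, gff3_path: str):
    """Project detected clusters through their gene models.

    Returns (mapped clusters, models by gene id, region-length table).
    Clusters whose protein has no gene model are skipped with a warning.
    """
    models = read_gff3(gff3_path)
    by_protein: Dict[str, GeneModel] = {m.protein_id: m for m in models}
    mapped = []
    rows = []
    for _, r in clusters_df.iterrows():
        model = by_protein.get(r.protein_id)
        if model is None:
            log.warning("no gene model for protein %s; cluster skipped", r.protein_id)
            continue
        c = ChargeCluster(
            protein_id=r.protein_id, sign=r.sign, start_aa=int(r.start_aa),
            end_aa=int(r.end_aa), length_aa=int(r.length_aa),
            charged_count=int(r.charged_count), p_value=float(r.p_value),
        )
        mc = map_cluster(c, model)
        mapped.append(mc)
        for tag, region in mc.context_regions.items():
            rows.append(
                [_cluster_id(mc), model.gene_id, tag, region.length, mc.exon_span]
            )
    lengths = pd.DataFrame(
        rows, columns=["cluster_id", "gene_id", "region_tag", "length_nt", "exon_span"]
    )
    return mapped, {m.gene_id: m for m in models}, lengths


def _cluster_id(mc) -> str:
    c = mc.cluster
    return f"{c.protein_id}:{c.sign}:{c.start_aa}-{c.end_aa}"


def stage_annotate(
    mapped: Sequence, models: Dict[str, GeneModel], vcf_path: str, genomes: Dict[str, str]
) -> pd.DataFrame:
    """Classify every variant within each cluster's context regions."""
    variants = read_vcf(vcf_path)
    by_chrom: Dict[str, List] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    frames = []
    for mc in mapped:
        model = models[mc.gene_id]
        chrom_variants = by_chrom.get(model.chrom, [])
        frames.append(
            annotate_variants(
                chrom_variants, mc.context_regions, model,
                genomes[model.chrom], cluster_id=_cluster_id(mc),
            )
        )
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def stage_aachange(changes_tsv: str) -> Dict[str, pd.DataFrame]:
    """Parse protein changes and compute the residue-group statistics."""
    df = pd.read_csv(changes_tsv, sep="\t")
    changes = [parse_protein_change(t) for t in df["protein_change"]]
    em = exchange_matrix(changes)
    gain_loss = pd.DataFrame({"loss": em.loss, "gain": em.gain})
    return {
        "exchange_matrix": em.counts,
        "gain_loss": gain_loss,
        "type_by_group": variation_type_by_group(changes),
        "insertion_spectrum": insertion_spectrum(changes),
        "affected_residues": affected_residue_counts(changes).to_frame("count"),
        "kind_counts": kind_counts(changes).to_frame("count"),
    }


def stage_report(
    annotations: pd.DataFrame, lengths: pd.DataFrame,
    aachange_tables: Optional[Dict[str, pd.DataFrame]] = None,
) -> Dict:
    """Fraction table, ANOVA/Tukey across regions, category chi-squares."""
    report: Dict = {}
    if annotations.empty:
        counts = pd.DataFrame(columns=["cluster_id", "region_tag", "variant_count"])
    else:
        counts = (
            annotations.groupby(["cluster_id", "region_tag"])
            .size()
            .reset_index(name="variant_count")
        )
    merged = lengths.merge(counts, on=["cluster_id", "region_tag"], how="left")
    merged["variant_count"] = (
        merged["variant_count"].astype("float").fillna(0.0).astype(int)
    )
    fractions = fraction_table(
        list(
            merged[["cluster_id", "region_tag", "variant_count", "length_nt"]]
            .itertuples(index=False, name=None)
        )
    )
    report["fractions"] = fractions
    if fractions.empty or annotations.empty:
        report["density"] = {"degenerate": True, "reason": "no variants annotated"}
    else:
        report["density"] = density_report(fractions)
        cc = annotations[annotations.region_tag == "cluster_exonic"]
        report["tallies"] = {
            "var_type": cc["var_type"].value_counts().to_dict(),
            "consequence": cc["consequence"].value_counts().to_dict(),
            "clinical_class": cc["clinical_class"].value_counts().to_dict(),
            "maf_bin_ExAC": cc["maf_bin_ExAC"].value_counts().to_dict(),
        }
    if aachange_tables is not None:
        table = aachange_tables["type_by_group"]
        kept = table.loc[(table.sum(axis=1) > 0), table.sum(axis=0) > 0]
        if kept.shape[0] >= 2 and kept.shape[1] >= 2:
            stat, df_, p = chi_square_homogeneity(kept)
            report["type_by_group_chi2"] = {"statistic": stat, "df": df_, "p_value": p}
    return report


def run_pipeline(config: Dict, out_dir: str, seed: Optional[int] = None) -> Dict:
    """Execute every stage from one configuration dict; write the bundle.

    ``config['inputs']`` names the protein FASTA, genome FASTA, GFF3, VCF
    and (optionally) protein-change TSV; ``config['params']`` may override
    alpha and p0_floor.  Raises with the stage name on any stage failure.
    """
    os.makedirs(out_dir, exist_ok=True)
    inputs = config["inputs"]
    params = config.get("params", {})
    alpha = float(params.get("alpha", DEFAULT_ALPHA))
    p0_floor = float(params.get("p0_floor", DEFAULT_P0_FLOOR))

    stage = "detect"
    try:
        clusters_df = stage_detect(inputs["proteins"], alpha=alpha, p0_floor=p0_floor)
        clusters_df.to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)

        stage = "map"
        mapped, models, lengths = stage_map(clusters_df, inputs["gff3"])
        lengths.to_csv(os.path.join(out_dir, "region_lengths.tsv"), sep="\t", index=False)
        write_bed12(mapped, models, os.path.join(out_dir, "clusters.bed"))

        stage = "annotate"
        genomes = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(inputs["genome"], "fasta")
        }
        annotations = stage_annotate(mapped, models, inputs["vcf"], genomes)
        annotations.to_csv(os.path.join(out_dir, "annotations.tsv"), sep="\t", index=False)

        stage = "aachange"
        aachange_tables = None
        if inputs.get("changes"):
            aachange_tables = stage_aachange(inputs["changes"])
            for name, tbl in aachange_tables.items():
                tbl.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t")

        stage = "report"
        report = stage_report(annotations, lengths, aachange_tables)
        report["fractions"].to_csv(
            os.path.join(out_dir, "fractions.tsv"), sep="\t", index=False
        )
        summary = {k: v for k, v in report.items() if k != "fractions"}
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "params": {"alpha": alpha, "p0_floor": p0_floor},
        "config_digest": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_digests": {
            k: _sha256(v) for k, v in inputs.items() if v and os.path.exists(v)
        },
        "outputs": sorted(
            f for f in os.listdir(out_dir) if f != "manifest.json"
        ),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"report": summary, "manifest": manifest, "annotations": annotations}
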