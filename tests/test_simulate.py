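"""Generator properties: determinism, planted structure, mixture recovery."""

import filecmp
import json

import numpy as np
import pytest

from ccvarscan.clusters import NEGATIVE, POSITIVE, ChargeCluster, find_charge_clusters
from ccvarscan.genemodels import map_cluster
from ccvarscan.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_cohort,
    simulate_gene_model,
    simulate_protein,
    simulate_protein_changes,
    simulate_variants,
)


def test_config_mixtures_must_sum_to_one():
    with pytest.raises(ConfigError):
        SimulationConfig(variant_type_mix={"SNV": 0.5, "deletion": 0.1, "insertion": 0.1})
    with pytest.raises(ConfigError):
        SimulationConfig(exon_span_mix=(0.5, 0.5, 0.5))


def test_planted_cluster_lengths_within_bounds(rng):
    cfg = SimulationConfig()
    for _ in range(200):
        _, truth = simulate_protein(cfg, rng)
        t = truth[0]
        assert 20 <= t["length_aa"] <= 75
        assert t["end_aa"] - t["start_aa"] + 1 == t["length_aa"]


def test_planted_segment_is_opposite_free(rng):
    cfg = SimulationConfig()
    for _ in range(100):
        seq, truth = simulate_protein(cfg, rng)
        t = truth[0]
        seg = seq[t["start_aa"] - 1 : t["end_aa"]]
        opp = set("KR") if t["sign"] == NEGATIVE else set("DE")
        same = set("DE") if t["sign"] == NEGATIVE else set("KR")
        assert not (set(seg) & opp)
        assert seg[0] in same and seg[-1] in same


def test_planted_length_mean_matches_truncated_normal(rng):
    cfg = SimulationConfig()
    lengths = []
    for _ in range(1000):
        _, truth = simulate_protein(cfg, rng, sign=NEGATIVE)
        lengths.append(truth[0]["length_aa"])
    # expectation of the configured truncated normal by direct simulation
    draws = rng.normal(24.2, 3.9, size=200_000)
    draws = np.round(draws)
    draws = draws[(draws >= 20) & (draws <= 75)]
    se = draws.std() / np.sqrt(len(lengths))
    assert abs(np.mean(lengths) - draws.mean()) < 3 * se + 0.1


def test_negative_control_no_planted_cluster(rng):
    """Background-only proteins yield ~no detections at alpha = 0.01."""
    cfg = SimulationConfig()
    alphabet = list("DEKR") + sorted(set("ACDEFGHIKLMNPQRSTVWY") - set("DEKR"))
    p = np.array([cfg.background_charge_freq] * 4 + [(1 - 0.1) / 16] * 16)
    hits = sum(
        bool(find_charge_clusters("".join(rng.choice(alphabet, size=400, p=p)), NEGATIVE))
        for _ in range(200)
    )
    assert hits / 200 < 0.2


def test_detector_recall_on_planted_clusters(rng):
    """Planted clusters are recovered with >= 95% overlap-based recall."""
    cfg = SimulationConfig()
    hits = 0
    n = 300
    for _ in range(n):
        seq, truth = simulate_protein(cfg, rng)
        t = truth[0]
        for c in find_charge_clusters(seq, t["sign"]):
            ov = min(c.end_aa, t["end_aa"]) - max(c.start_aa, t["start_aa"]) + 1
            if ov >= 0.5 * t["length_aa"]:
                hits += 1
                break
    assert hits / n >= 0.95


def test_gene_model_translation_round_trip(rng):
    cfg = SimulationConfig()
    for _ in range(30):
        seq, truth = simulate_protein(cfg, rng)
        model, genome, gt = simulate_gene_model(seq, truth[0], cfg, rng)
        assert model.translate(genome) == seq
        assert gt["exon_span"] in (1, 2, 3)


def test_single_exon_cluster_context_lengths_equal(rng):
    cfg = SimulationConfig(exon_span_mix=(1.0, 0.0, 0.0), extra_intron_prob=0.0)
    seq, truth = simulate_protein(cfg, rng)
    t = truth[0]
    model, genome, _ = simulate_gene_model(seq, t, cfg, rng)
    c = ChargeCluster("p", t["sign"], t["start_aa"], t["end_aa"], t["length_aa"], 1, 0.0)
    mc = map_cluster(c, model)
    assert mc.exon_span == 1
    regions = mc.context_regions
    assert regions["cluster_exonic"].length == regions["cluster_exonic_plus_intronic"].length


def test_exon_span_mixture_recovered(rng):
    cfg = SimulationConfig()
    spans = []
    for _ in range(600):
        seq, truth = simulate_protein(cfg, rng)
        _, _, gt = simulate_gene_model(seq, truth[0], cfg, rng)
        spans.append(gt["exon_span"])
    frac1 = np.mean([s == 1 for s in spans])
    se = np.sqrt(0.67 * 0.33 / len(spans))
    assert abs(frac1 - 0.67) < 3 * se


def test_variants_match_reference_and_density(rng):
    cfg = SimulationConfig()
    counts, total_len = 0, 0
    for _ in range(10):
        seq, truth = simulate_protein(cfg, rng, sign=NEGATIVE)
        t = truth[0]
        model, genome, _ = simulate_gene_model(seq, t, cfg, rng)
        c = ChargeCluster("p", NEGATIVE, t["start_aa"], t["end_aa"], t["length_aa"], 1, 0.0)
        mc = map_cluster(c, model)
        recs, truths = simulate_variants(
            model, genome, cfg, rng, sign=NEGATIVE, cluster_blocks=mc.genomic_blocks
        )
        for v in recs:
            assert genome[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref
        in_cc = [
            tr for tr in truths if tr["stratum"] == "cluster_exonic"
        ]
        counts += len(in_cc)
        total_len += mc.context_regions["cluster_exonic"].length
    # planted density 0.25 per nt in the cluster's exonic blocks
    se = np.sqrt(0.25 * 0.75 * total_len)
    assert abs(counts - 0.25 * total_len) < 3 * se + 1


def test_zero_density_yields_no_variants(rng):
    cfg = SimulationConfig(
        density_cluster_exonic=0.0, density_cluster_intron=0.0,
        density_mrna_other=0.0, density_gene_other=0.0,
    )
    seq, truth = simulate_protein(cfg, rng, sign=NEGATIVE)
    t = truth[0]
    model, genome, _ = simulate_gene_model(seq, t, cfg, rng)
    c = ChargeCluster("p", NEGATIVE, t["start_aa"], t["end_aa"], t["length_aa"], 1, 0.0)
    mc = map_cluster(c, model)
    recs, _ = simulate_variants(
        model, genome, cfg, rng, sign=NEGATIVE, cluster_blocks=mc.genomic_blocks
    )
    assert recs == []


def test_all_substitution_mixture(rng):
    cfg = SimulationConfig(
        change_category_mix={"substitution": 1.0, "synonymous": 0.0,
                             "deletion": 0.0, "insertion": 0.0}
    )
    strings, truths = simulate_protein_changes(cfg, rng, 200)
    assert all(t["kind"] == "substitution" for t in truths)


def test_change_category_mixture_recovered(rng):
    cfg = SimulationConfig()
    _, truths = simulate_protein_changes(cfg, rng, 5000)
    frac = np.mean([t["kind"] == "substitution" for t in truths])
    se = np.sqrt(0.55 * 0.45 / 5000)
    assert abs(frac - 0.55) < 3 * se


def test_cohort_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(n_genes=3)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_cohort(cfg, seed=42, out_dir=str(d1), n_changes=30)
    simulate_cohort(cfg, seed=42, out_dir=str(d2), n_changes=30)
    for name in ("proteins.fasta", "genome.fasta", "genes.gff3", "variants.vcf",
                 "protein_changes.tsv", "truth.json"):
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name


def test_truth_index_consistency(small_cohort):
    bundle = small_cohort["bundle"]
    truth = json.loads((small_cohort["dir"] / "truth.json").read_text())
    assert len(truth["clusters"]) == len(bundle["models"])
    emitted = {v.var_id for recs in bundle["variants"].values() for v in recs}
    assert emitted == {t["var_id"] for t in truth["variants"]}
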