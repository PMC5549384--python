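"""Variant typing, region overlap, consequence calling, MAF and clinical bins."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from ccvarscan.genemodels import GeneModel, genomic_to_cds
from ccvarscan.simulate import SimulationConfig, simulate_gene_model, simulate_protein
from ccvarscan.variants import (
    ClassificationError,
    ReferenceMismatchError,
    VariantRecord,
    classify_variant_type,
    clinical_class,
    maf_bin,
    molecular_consequence,
    normalize_alleles,
    variants_in_region,
)


@pytest.mark.parametrize(
    "ref,alt,vtype",
    [
        ("A", "G", "SNV"),
        ("A", "AGA", "insertion"),
        ("TTC", "T", "deletion"),
        ("AT", "GC", "MNV"),
    ],
)
def test_classify_variant_type(ref, alt, vtype):
    assert classify_variant_type(ref, alt) == vtype


def test_classify_rejects_unnormalizable():
    with pytest.raises(ClassificationError):
        classify_variant_type("ACG", "TT")


def test_normalize_alleles_trims_to_minimal():
    assert normalize_alleles(100, "CAT", "CGT") == (101, "A", "G")
    assert normalize_alleles(100, "ATT", "AT") == (100, "AT", "A")
    assert normalize_alleles(100, "TTC", "T") == (100, "TTC", "T")


def test_variants_in_region_inclusive_bounds():
    vs = [VariantRecord("chr1", p, "A", "G") for p in (5, 10, 11, 20, 21)]
    got = variants_in_region(vs, [(10, 20)])
    assert [v.pos for v in got] == [10, 11, 20]
    assert variants_in_region(vs, []) == []


def test_variants_in_region_matches_brute_force(rng):
    vs = [VariantRecord("chr1", int(p), "A", "G") for p in rng.integers(1, 500, 80)]
    ivs = [(50, 120), (200, 200), (300, 420)]
    got = {id(v) for v in variants_in_region(vs, ivs)}
    want = {id(v) for v in vs if any(a <= v.pos <= b for a, b in ivs)}
    assert got == want


def test_region_count_additivity(rng):
    """cluster_exonic counts + intronic-remainder counts = exonic+intronic counts."""
    blocks = [(100, 150), (400, 430)]
    span = [(100, 430)]
    remainder = [(151, 399)]
    vs = [VariantRecord("chr1", int(p), "A", "G") for p in rng.integers(50, 500, 200)]
    n_blocks = len(variants_in_region(vs, blocks))
    n_rem = len(variants_in_region(vs, remainder))
    n_span = len(variants_in_region(vs, span))
    assert n_blocks + n_rem == n_span


@pytest.mark.parametrize(
    "freq,binname",
    [
        (0.001, "lt_0.005"),
        (0.0, "lt_0.005"),
        (0.005, "0.005_to_0.01"),
        (0.0099, "0.005_to_0.01"),
        (0.03, "0.01_to_0.05"),
        (0.05, "ge_0.05"),
        (0.5, "ge_0.05"),
        (None, "unspecified"),
    ],
)
def test_maf_bin(freq, binname):
    assert maf_bin(freq) == binname


def test_maf_bin_rejects_out_of_range():
    with pytest.raises(ValueError):
        maf_bin(-0.01)
    with pytest.raises(ValueError):
        maf_bin(0.6)


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
def test_maf_bins_partition(freq):
    """Every frequency in [0, 0.5] falls in exactly one of the four bins."""
    edges = [(0.0, 0.005), (0.005, 0.01), (0.01, 0.05), (0.05, 0.5 + 1e-12)]
    member = [lo <= freq < hi or (freq == 0.5 and hi > 0.5) for lo, hi in edges]
    assert sum(member) == 1
    assert maf_bin(freq) != "unspecified"


@pytest.mark.parametrize(
    "raw,cls",
    [
        ("Pathogenic", "pathogenic_spectrum"),
        ("probably pathogenic", "pathogenic_spectrum"),
        ("Likely_pathogenic", "pathogenic_spectrum"),
        ("risk factor", "pathogenic_spectrum"),
        ("Benign", "benign_spectrum"),
        ("likely benign", "benign_spectrum"),
        ("Uncertain significance", "unspecified"),
        (None, "unspecified"),
        ("", "unspecified"),
    ],
)
def test_clinical_class(raw, cls):
    assert clinical_class(raw) == cls


# ---------------------------------------------------------------------------
# molecular consequence


def single_exon_model(cds: str, start=101):
    """One-exon + strand gene whose CDS is the given string."""
    end = start + len(cds) - 1
    return (
        GeneModel("g", "chr1", "+", (1, end + 100), [(start - 50, end + 50)],
                  [(start, end)]),
        "T" * (start - 1 - 50) + "A" * 50 + cds + "A" * 50 + "T" * 50,
    )


def _genome_for(model, cds, start):
    n_before = model.exons[0][0] - 1
    pre = "T" * n_before
    utr5 = ""
    return pre


def make_coding_genome(cds: str):
    """chrom with UTR(50) + CDS + UTR(50) in a single exon starting at 101."""
    genome = "T" * 50 + "C" * 50 + cds + "G" * 50 + "T" * 50
    model = GeneModel(
        "g", "chr1", "+", (1, len(genome)),
        [(51, 100 + len(cds) + 50)], [(101, 100 + len(cds))],
    )
    return model, genome


def test_synonymous_third_position():
    model, genome = make_coding_genome("ATGGAAGGCTAA")  # Met Glu Gly Ter
    v = VariantRecord("chr1", 106, "A", "G")  # GAA -> GAG, still Glu
    cons, pc = molecular_consequence(v, model, genome)
    assert cons == "synonymous"
    assert pc.ref_res == "E" and pc.position == 2


def test_missense_glu_to_lys():
    model, genome = make_coding_genome("ATGGAAGGCTAA")
    v = VariantRecord("chr1", 104, "G", "A")  # GAA -> AAA, Glu -> Lys
    cons, pc = molecular_consequence(v, model, genome)
    assert cons == "missense"
    assert (pc.ref_res, pc.alt_res, pc.position) == ("E", "K", 2)


def test_stop_gained_arg_to_ter():
    model, genome = make_coding_genome("ATGCGAGGCTAA")  # Met Arg Gly Ter
    v = VariantRecord("chr1", 104, "C", "T")  # CGA -> TGA
    cons, pc = molecular_consequence(v, model, genome)
    assert cons == "stop_gained"
    assert pc.ref_res == "R" and pc.alt_res == "*"


def test_stop_lost():
    model, genome = make_coding_genome("ATGCGAGGCTAA")
    v = VariantRecord("chr1", 110, "T", "C")  # TAA -> CAA
    cons, pc = molecular_consequence(v, model, genome)
    assert cons == "stop_lost"


def test_single_nt_deletion_is_frameshift():
    model, genome = make_coding_genome("ATGCGAGGCTAA")
    v = VariantRecord("chr1", 103, "GC", "G")
    cons, _ = molecular_consequence(v, model, genome)
    assert cons == "frameshift"


def test_inframe_deletion():
    model, genome = make_coding_genome("ATGCGAGGCTAA")
    v = VariantRecord("chr1", 103, "GCGA", "G")
    cons, _ = molecular_consequence(v, model, genome)
    assert cons == "inframe_deletion"


def test_reference_mismatch_raises():
    model, genome = make_coding_genome("ATGCGAGGCTAA")
    with pytest.raises(ReferenceMismatchError):
        molecular_consequence(VariantRecord("chr1", 104, "A", "T"), model, genome)


def test_splice_region_and_intronic():
    model = GeneModel(
        "g", "chr1", "+", (1, 400),
        [(51, 110), (211, 400)], [(60, 110), (211, 339)],
    )
    rng = np.random.default_rng(5)
    genome = "".join(rng.choice(list("ACGT"), size=400))
    for pos in (111, 112, 209, 210):
        v = VariantRecord("chr1", pos, genome[pos - 1], "A" if genome[pos - 1] != "A" else "C")
        assert molecular_consequence(v, model, genome)[0] == "splice_region"
    v = VariantRecord("chr1", 160, genome[159], "A" if genome[159] != "A" else "C")
    assert molecular_consequence(v, model, genome)[0] == "intronic"
    # UTR position: inside mRNA, outside CDS
    v = VariantRecord("chr1", 55, genome[54], "A" if genome[54] != "A" else "C")
    assert molecular_consequence(v, model, genome)[0] == "non_coding"


def test_consequence_matches_translate_and_diff_oracle(rng):
    """Coding SNVs agree with re-translating a mutated chromosome."""
    cfg = SimulationConfig()
    checked = 0
    while checked < 300:
        seq, truth = simulate_protein(cfg, rng)
        model, genome, _ = simulate_gene_model(seq, truth[0], cfg, rng)
        cds_positions = set(model.cds_genomic_positions())
        pool = sorted(cds_positions)
        for pos in rng.choice(pool, size=10, replace=False):
            pos = int(pos)
            ref = genome[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            v = VariantRecord(model.chrom, pos, ref, alt)
            cons, _ = molecular_consequence(v, model, genome)
            mutated = genome[: pos - 1] + alt + genome[pos:]
            p_ref = str(Seq(model.spliced_cds(genome)).translate())
            p_alt = str(Seq(model.spliced_cds(mutated)).translate())
            if p_ref == p_alt:
                expected = "synonymous"
            else:
                diffs = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
                a, b = diffs[0]
                if b == "*":
                    expected = "stop_gained"
                elif a == "*":
                    expected = "stop_lost"
                else:
                    expected = "missense"
            assert cons == expected, (pos, ref, alt, cons, expected)
            checked += 1


def test_indel_consequence_matches_length_rule(rng):
    """Coding indels: frameshift iff length change not divisible by 3."""
    cfg = SimulationConfig()
    checked = 0
    while checked < 200:
        seq, truth = simulate_protein(cfg, rng)
        model, genome, _ = simulate_gene_model(seq, truth[0], cfg, rng)
        splice = set()
        for (_, pe), (ns, _) in zip(model.exons, model.exons[1:]):
            splice.update(range(pe + 1, pe + 3))
            splice.update(range(ns - 2, ns))
        interior = [
            p for a, b in model.cds_exons for p in range(a + 1, b - 7)
        ]
        for pos in rng.choice(interior, size=8, replace=False):
            pos = int(pos)
            dlen = int(rng.integers(1, 7))
            if rng.random() < 0.5:
                ref = genome[pos - 1 : pos + dlen]
                alt = genome[pos - 1]
                touched = set(range(pos + 1, pos + dlen + 1))
            else:
                ref = genome[pos - 1]
                alt = ref + "".join(rng.choice(list("ACGT"), size=dlen))
                touched = {pos, pos + 1}
            v = VariantRecord(model.chrom, pos, ref, alt)
            cons, _ = molecular_consequence(v, model, genome)
            if touched & splice:
                assert cons == "splice_region"
            elif dlen % 3:
                assert cons == "frameshift"
            else:
                assert cons in ("inframe_insertion", "inframe_deletion")
            checked += 1
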