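# ccvarscan

Analysis of genetic variation in the genomic regions that encode protein
**charge clusters** — runs of 20–75 residues with a high concentration of
same-charge amino acids (Asp/Glu for negative clusters, NCCs; Lys/Arg for
positive clusters, PCCs), free of any residue of the opposite charge.
Charge clusters mediate protein–protein and protein–nucleic-acid binding,
and variants disrupting them are candidates for disease involvement; this
package is for computational biologists who want to quantify how variant
density and variant character inside cluster-coding sequence compare with
the surrounding gene.

The pipeline has five stages:

1. **detect** — find significant, disjoint charge clusters in protein
   sequences. A candidate window of length *w* ∈ [20, 75] that starts and
   ends on a same-sign residue and contains none of the opposite sign is
   scored by the binomial tail probability
   *P*(X ≥ k), X ~ Binomial(*w*, *p₀*), where *k* is its same-sign residue
   count and *p₀* is the protein-wide frequency of that sign (floored at
   0.05). Windows with *p* ≤ α = 0.01 enter a greedy disjoint selection
   (smallest *p* first; ties to the longest, then leftmost window).
2. **map** — project each cluster through its gene model: residues
   [a, b] → CDS nucleotides [3a−2, 3b] → genomic blocks via the per-base
   exon map (strand-aware). Four nested context regions are derived for
   density comparisons: the cluster's exonic blocks, the contiguous
   exonic + intronic span, the full mRNA (exon union) and the gene.
3. **annotate** — overlap VCF records with each region and classify every
   variant by nucleotide type (SNV / insertion / deletion / MNV), molecular
   consequence (codon mutation + translation: synonymous, missense,
   stop gained/lost, frameshift, inframe indel, splice region, intronic,
   non-coding), clinical-significance class and minor-allele-frequency bin
   (< 0.005, [0.005, 0.01), [0.01, 0.05), ≥ 0.05) per source
   (1000 Genomes, GO-ESP, ExAC).
4. **aachange** — parse HGVS.p-style protein-change strings and tally
   exchanges between the four physicochemical residue groups
   (hydrophobic, polar, acidic, basic), per-residue gain/loss counts, and
   insertion-length spectra.
5. **report** — the variant fraction (variant count / region length in nt)
   per cluster and region, compared across regions with one-way ANOVA and
   Tukey HSD; category distributions compared with Pearson's chi-square.

A synthetic-data module generates proteins with planted clusters, gene
models, genomes, VCFs and protein-change sets with configurable planted
mixtures, so every stage is validated by parameter recovery without any
database access.

## Worked example

Detecting the negative cluster in a toy protein:

```python
from ccvarscan import find_charge_clusters

seq = "MSTA" * 10 + "EEDNEEGSDEEFDDLEELDEMMEED" + "GQLR" * 10
for c in find_charge_clusters(seq, "negative", protein_id="demo"):
    print(c)
```

```
ChargeCluster(protein_id='demo', sign='negative', start_aa=41, end_aa=65,
              length_aa=25, charged_count=17, p_value=1.038e-08)
```

The 25-residue acidic run is reported with tight boundaries (positions
41–65), 17 of its residues are Asp/Glu, and the binomial tail probability
of that enrichment against the protein's overall acidic frequency is
about 10⁻⁸.

Running the whole pipeline on a simulated 20-gene cohort:

```python
from ccvarscan.simulate import SimulationConfig, simulate_cohort
from ccvarscan.pipeline import run_pipeline

simulate_cohort(SimulationConfig(n_genes=20), seed=3, out_dir="demo", n_changes=500)
inputs = {"proteins": "demo/proteins.fasta", "genome": "demo/genome.fasta",
          "gff3": "demo/genes.gff3", "vcf": "demo/variants.vcf",
          "changes": "demo/protein_changes.tsv"}
res = run_pipeline({"inputs": inputs}, "demo_run", seed=3)
print(res["report"]["density"]["group_means"])
print(res["report"]["density"]["anova"])
```

```
{'cluster_exonic': 0.2607, 'cluster_exonic_plus_intronic': 0.2265,
 'full_mRNA': 0.1111, 'gene': 0.1001}
{'F': 47.92, 'df_between': 3, 'df_within': 76, 'p_value': 1.72e-17,
 'degenerate': False}
```

The cluster-coding sequence carries about one variant every 4 nt
(fraction 0.26) versus one every 10 nt gene-wide, and the ANOVA across
the four nested regions rejects equality of densities decisively — the
enrichment that was planted by the generator is recovered by the
analysis. The same run writes `clusters.tsv`, `clusters.bed`,
`annotations.tsv`, `fractions.tsv`, the exchange-matrix tables and a
`manifest.json` recording digests of every input.

The same stages are available from a shell:

```sh
ccvarscan simulate --seed 3 --out-dir demo --n-changes 500
ccvarscan detect demo/proteins.fasta -o clusters.tsv
ccvarscan run --config pipeline.yaml --out-dir demo_run
```

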