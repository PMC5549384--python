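# Methods

## Cluster detection model

A charge cluster of sign *s* (negative = Asp/Glu, positive = Lys/Arg) is a
segment of 20–75 residues that (i) contains no residue of the opposite
sign, (ii) starts and ends on a residue of sign *s* (so boundaries are not
padded by uncharged flanks), and (iii) is significantly enriched in
sign-*s* residues relative to the protein's overall composition.

Enrichment is scored with a binomial tail: for a window of length *w*
containing *k* sign-*s* residues, *p* = P(X ≥ k) with
X ~ Binomial(*w*, *p₀*), where *p₀* is the protein-wide frequency of
sign-*s* residues, floored at `p0_floor = 0.05`. The floor prevents
trivially significant windows in proteins almost devoid of charge, where
the empirical frequency would make any short charged run look
extraordinary. Windows with *p* ≤ `alpha = 0.01` are candidates; the
returned set is the greedy disjoint selection — repeatedly accept the
window with the smallest *p* (ties broken by longest, then leftmost) and
discard everything overlapping it. The greedy rule is deterministic and
reproduces "significant and disjoint" without solving a weighted
interval-scheduling problem whose optimum would be harder to reason about.

The score function of the original cluster-finding literature is not
restated anywhere we could implement from; the binomial tail is this
package's own scoring choice with the same qualitative definition
(high same-sign density relative to the protein's composition, no
opposite-sign residue). All detector tests therefore validate against a
brute-force re-implementation of *this* definition, not against any
external tool's output.

Two consequences worth knowing:

- **Family-wise false positives.** `alpha` is a per-window threshold. A
  300-residue protein contributes thousands of overlapping windows, so on
  i.i.d. background sequences (≈5% same-sign residues) the per-*protein*
  discovery rate is roughly 5–8% per sign — about an order of magnitude
  above `alpha`, as expected without multiplicity correction. The property
  test bounds it at 10×alpha. Users comparing cluster *counts* across
  protein sets should treat `alpha` as a ranking knob, not an error rate.
- Mixed-charge clusters (high total charge, both signs) are out of scope;
  only single-sign clusters are detected.

Non-standard residue codes (B, Z, X, U, `*`) score as uncharged and never
block a window; each occurrence is logged.

## Coordinate projection

Coordinates are 1-based fully closed throughout (GenBank convention); the
BED12 writer converts to 0-based half-open. Residues [a, b] map to CDS
nucleotides [3a−2, 3b]; the CDS interval maps to genomic blocks through a
per-base exon map, which handles codons straddling exon junctions without
special cases. On the − strand, CDS position 1 is the highest genomic
coordinate of the CDS. One transcript per gene; isoforms are out of scope.

The four context regions compared for variant density are nested:
cluster exonic blocks ⊆ exonic + intronic span ⊆ gene, with the full mRNA
(exon union) as the fourth comparison group. "Exonic + intronic" is read
as the contiguous genomic span from the first to the last cluster block —
for clusters spanning two or three exons this equals "the cluster plus the
introns interrupting it", which is the case that occurs.

## Variant classification

Alleles are trimmed to the minimal VCF representation (shared suffix, then
shared prefix, keeping the anchor base) before typing. Molecular
consequence is resolved by mutating the spliced CDS and translating with
the standard code; indels are frameshift iff the length change is not a
multiple of 3. When several labels could apply the precedence is
splice_region > stop_gained > stop_lost > frameshift > inframe > missense
> synonymous, giving one label per variant. The splice region is the 2
intronic nt at each donor/acceptor — the minimal canonical definition.

MAF bins are half-open on the right: [0, 0.005), [0.005, 0.01),
[0.01, 0.05), [0.05, 0.5]. A closed-interval reading would double-count
the shared edges; the half-open partition keeps every frequency in exactly
one bin. An absent frequency is "unspecified" and excluded from
proportions, as is an unrecognized clinical label. Clinical labels
collapse to a pathogenic spectrum (pathogenic, probably/likely pathogenic,
risk factor), a benign spectrum (benign, likely benign), or unspecified.

## Residue-group statistics

The 20 residues partition into hydrophobic (A, V, L, I, M, F, W, P), polar
(G, S, T, C, Y, N, Q, H), acidic (E, D) and basic (K, R). The exchange
matrix tallies only true substitutions; stop-involving changes have no
group and are kept in a side tally; synonymous changes and indels are
tallied separately. Deletions are attributed per deleted residue,
symmetric with insertions. Range deletions name only their endpoint
residues in HGVS.p short strings, so interior residues of a range deletion
cannot be attributed; the generator emits single-residue deletions and the
parser marks unknown interior residues.

## Statistical tests

Chi-square is Pearson's Σ(O−E)²/E without continuity correction (2×2
included); expected counts below 5 trigger a logged warning, not an error.
ANOVA observations are per-cluster variant fractions, not pooled counts,
so long genes do not dominate; the F statistic uses the standard one-way
decomposition, and a cohort where every region of every cluster has the
same fraction is reported as degenerate instead of producing 0/0. Tukey
HSD uses the studentized range with the Tukey–Kramer adjustment for
unequal group sizes (delegated to scipy). No multiple-testing control is
applied across the report's chi-square tests.

Because the four regions are nested, their fractions are positively
dependent and have unequal binomial variances (variance ∝ 1/length); the
ANOVA is used descriptively, as in the analysis it reproduces. The type-I
calibration test therefore uses exchangeable null groups — equal planted
density and the same region-length distribution in every group — where
the nominal 5% level is exact in expectation.

## Synthetic cohorts

The generator's defaults are the study conditions, fixed once:

| parameter | default | meaning |
|---|---|---|
| cluster length (NCC) | truncated normal 24.2 ± 3.9 aa on [20, 75] | planted segment length |
| cluster length (PCC) | truncated normal 27.8 ± 7.6 aa on [20, 75] | idem |
| sign mix | 75% negative / 25% positive | NCCs ~3× more prevalent |
| in-cluster charge density | 0.55 | P(same-sign) per planted position |
| background charge | 2.5% per charged residue | low-charge background composition |
| exon-span mix | 0.67 / 0.31 / 0.02 | cluster on 1 / 2 / 3 exons |
| intron length | uniform 60–400 nt | GT…AG introns |
| variant densities | 0.25 / 0.08 / 0.10 / 0.05 per nt | cluster exonic / its introns / rest of mRNA / rest of gene |
| variant type mix | 0.80 SNV / 0.12 del / 0.08 ins | nucleotide level |
| ExAC rare-bin share | 0.78 (NCC), 0.85 (PCC) | of specified frequencies |
| MAF unspecified share | 0.20 per source | frequencies left absent |
| change category mix | 0.55 sub / 0.28 syn / 0.1275 del / 0.0425 ins | protein level; deletions:insertions = 3:1 |
| affected residues | Glu 0.345, Asp 0.22, polar 0.22, hydrophobic 0.215 | weights for mutated residues |
| insertion lengths | 0.54 at length 1, geometric (r = 0.46) over 2–12 | inserted residue count |
| inserted residues | acidic 0.90 / polar 0.05 / hydrophobic 0.025 / basic 0.025 | per inserted residue |

Remaining free choices, fixed as follows: the in-cluster charge density
(0.55) gives planted clusters comfortably beyond the detection threshold
while keeping realistic uncharged interruptions; proteins are 400 aa so a
cluster plus isolation flanks always fits; codon choice at back-translation
is uniform over synonymous codons (codon-usage bias is irrelevant to every
statistic tested); non-cluster variant densities descend with distance
from the cluster so the planted enrichment ordering matches the analysed
one; the exon-span "3+" class is realized as exactly 3 exons; clinical
label mixtures put half the mass on specified labels with the benign
spectrum at 46% of specified for NCC cohorts and the pathogenic spectrum
at 34% for PCC cohorts. Truncated normals are sampled by rejection.
Planted clusters are isolated by one opposite-charge residue on each side,
so a plant can never extend into, or merge with, a background charge run.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage and population structure among
variants, mutation-rate heterogeneity along the genome (CpG effects,
indel hotspots in repeats), codon-usage bias, alternative isoforms,
multi-allelic sites, structural variants, and any correlation between a
variant's frequency, clinical label and consequence (the generator draws
them independently). Recovery tests demonstrate that the pipeline measures
planted structure correctly, not that real cluster-coding regions have
that structure.

## Problem sizes

The validation suite runs entirely on simulated data: detector-vs-oracle
equivalence on random sequences up to 300 aa; coordinate round trips on
1000 random gene models on both strands; consequence calls against a
translate-and-diff oracle on 1000 coding variants; mixture-recovery
cohorts of 2000 genes or ≥ 3000–5000 records per target, which puts three
binomial standard errors at roughly 1–3 percentage points; ANOVA type-I
calibration over 500 null replicates. These sizes make every recovered
proportion's sampling error small relative to the differences under test.

## Known limitations

- The detector's significance is per window; genome-scale screens should
  add their own multiplicity control.
- Consequence calling assumes the variant lies entirely within one gene
  model's span and one chromosome; overlapping genes are not handled.
- HGVS.p parsing covers the short forms the cohort generator emits plus
  stop/frameshift/range forms; extensions ("dup", "delins", "ext") are
  rejected with a parse error naming the token.
- The ANOVA's independence assumption is violated by nested regions, as
  noted above; Tukey p-values inherit the caveat.
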