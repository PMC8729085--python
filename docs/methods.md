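# Methods

This note records the statistical models, parameter choices and numerical
conventions behind `pistilgrn`, and what the synthetic benchmark does and
does not demonstrate.

## Study design and containers

The pipeline assumes a two-sex (F/M), four-stage (S1 primordium, S2/S3
meiosis, S4 mitosis) pistil development design with three replicates per
pistil group and one leaf group per sex with two replicates — 28 samples in
10 groups. Expression lives in an `ExpressionMatrix` (genes × samples with
sample metadata and a counts/FPKM unit flag); group means live in a
`GroupProfile` with `sex:stage` columns. FPKM is
`count · 10⁹ / (length · library size)`; gene lengths default to 1 kb in the
generator so the conversion is a pure per-sample scaling.

## Stage-specificity (SS) scoring

`SS(i,j) = 1 − max_{s≠j} E_s / E_j` on group-mean FPKM over the 10 groups,
with preferential expression called at a strict `SS > 0.3`. Conventions:
`E_j = 0` yields a −∞ sentinel and is never preferential; a gene expressed
only in the focal group scores exactly 1. The preferential call is computed
in the algebraically equivalent ratio form `max_other < (1 − t)·E_j`, which
avoids the `1 − x/y` floating-point rounding that would misclassify profiles
lying exactly on the threshold. Z-scores standardize each gene's group means
with the sample (n−1) standard deviation; constant genes are masked rather
than erroring. PCA operates on log2(FPKM+1), gene-centered, via SVD.

## Differential expression

Two deliberately different negative-binomial tests per stage contrast, both
parameterized by mean and dispersion α with `var = μ + αμ²`:

* **Size factors.** DESeq-style median-of-ratios by default (geometric-mean
  reference over genes positive everywhere); a TMM-like alternative (30%
  log-ratio / 5% abundance trim against the depth-median sample) is
  available.
* **Dispersion.** The per-gene method-of-moments estimate solves
  `var(y) = μ·mean(1/s) + αμ²` on normalized counts pooled within groups.
  The trend is the binned **mean** raw estimate over 20 equal-count bins of
  log mean, interpolated. Means, not medians: with 4 residual degrees of
  freedom the raw estimator is strongly right-skewed, so binned medians sit
  ~20% below the truth and inflate the type-I error of everything downstream
  (observed ~0.09 at nominal 0.05); binned means — negative estimates
  included — are close to unbiased and restore calibration (~0.065 measured
  on planted-null simulations). The final dispersion blends per-gene and
  trend on the log scale with weight 0.15 on the per-gene value (little
  per-gene information at n = 3), floored at 1e-8.
* **Method A (Wald).** log2FC from normalized group means with pseudo-count
  0.5; delta-method standard error from the NB variance at the estimated
  means; two-sided normal p.
* **Method B (conditional exact).** Counts are scaled to a common library
  (size factors normalized to geometric mean 1, group pseudo-sums rounded).
  The sum of n i.i.d. NB(μ, α) is NB(nμ, α/n); conditional on the total, the
  split probability is the renormalized product of the two sum pmfs, and the
  p-value doubles the smaller tail, capped at 1. A gene with total 0 has
  p = 1.
* **Significance.** BH-adjusted p < 0.05 **and** |log2FC| > 1, both strict;
  BH is the classic step-up, implemented directly and checked against a
  brute-force recursion. "Shared DEGs" are the per-contrast intersection of
  the two methods; totals count a gene once per contrast.

## Co-expression and mutual rank

Correlations are computed once over the union of shared DEGs, on the
**log2(FPKM+1) group-mean profile across all 10 groups**. Two choices to
note:

* Log scale: on linear FPKM a single extreme group dominates the Pearson
  covariance and co-regulated genes with identical log-profiles can fail the
  0.95 threshold through replicate noise alone.
* All 10 groups rather than per-sex 5-group profiles: a 5-point correlation
  has a null `P(|r| ≥ 0.95) ≈ 1.6%`, which floods the mutual-rank
  neighborhood of every gene with spurious partners; at 10 points the null
  rate is ~2·10⁻⁵. The per-sex character of the six networks comes from the
  expression rule at assembly (below), not from sex-restricted profiles.

`rank_AB` is B's position in A's partners sorted by decreasing (signed) PCC,
self excluded, ties averaged; `MR_raw = √(rank_AB·rank_BA)`. The raw mutual
rank is ≥ 1 while the thresholding scale is 0–1 with 1 best, so the score is
the linear rescale `MR_score = 1 − (MR_raw − 1)/(N − 2)` (mutual best
partners ↦ 1; clipped to [0, 1]); a reciprocal variant `1/MR_raw` is
selectable and the choice is recorded in the run metadata. Edges require
|PCC| ≥ 0.95 and MR_score ≥ 0.95, both inclusive. A practical consequence of
the linear rescale: with N candidate genes the admissible raw rank is
`1 + 0.05(N − 2)`, so meaningful regulons require N of at least ~20× the
module size — the synthetic defaults respect this.

## Promoters, scanning, enrichment

Promoters are the 2 kb upstream of the annotated TSS: `[TSS−2000, TSS)` on
the plus strand, `(TSS, TSS+2000]` reverse-complemented on the minus strand,
truncated and flagged at contig edges; provenance is stored 0-based
half-open. JASPAR PFM and minimal MEME motifs parse through Biopython into
4×L probability matrices with pseudocount 0.01.

Scanning scores every window on both strands with log2 odds against the
background base composition **estimated from the promoter set itself**
(assuming a uniform background on AT-rich plant promoters raised the
realized false-hit rate from the intended ~33% per 2 kb promoter to ~70% and
destroyed enrichment contrast). The hit threshold is the smallest score
whose exact upper-tail probability under that background — computed by
dynamic programming over the per-position score distribution, scores
discretized to 1e-3 log-odds units — is ≤ 1e-4 per window (configurable
`scan_p`; the observed hit/miss calls compare scores on the same discretized
grid as the threshold). If no achievable score is that improbable (e.g. a
near-uniform matrix) the threshold is +∞ and the motif can never hit. N
bases score 0; promoters above 50% N are excluded.

Enrichment is AME-flavored: for each TF with an assigned motif, foreground =
its called co-expression partners, background = the remaining DEG universe;
one-tailed Fisher exact p via the hypergeometric upper tail; Bonferroni
across motifs only; enriched at adjusted p < 0.001.

## Networks, hubs, sex specificity

A directed edge TF→G requires (i) the pair passed co-expression calling,
(ii) the TF's motif is enriched, and (iii) G's promoter has a hit for that
motif; TF–TF pairs may yield both directions; no self-loops. Each of the six
(sex × {S1, S2-3, S4}) networks restricts nodes to that stage's shared DEGs
**that are expressed in that sex at that stage** (group-mean FPKM ≥ 1;
exactly 1 counts as expressed, consistent with the "low" bin's lower edge).

Topology is computed on the undirected projection: average degree 2E/N; mean
local clustering (degree < 2 contributes 0); mean shortest path over
reachable pairs within components; "average connectivity" is interpreted as
the mean over nodes of the mean degree of their neighbors, and that
interpretation is recorded in the outputs. Hubs are the top
`ceil(0.10 · N)` nodes by degree with deterministic (degree desc, gene id
asc) tie-breaking. Sex-specific calls apply the FPKM ≥ 1 rule per
(sex, stage); a gene female-expressed and male-silent at a stage is
female-specific there, genes qualifying in both directions at different
stages are reported as shared. The subnetwork around seed TFs is the union
of first-order neighborhoods across the six networks with stage/sex-tagged
(multi-)edges; seeds default to the sex-specific hub TFs and fall back to
all hub TFs when none is fully sex-specific — on synthetic data the
opposite-sex arm of a module is reduced only at its dominant stage, not
silenced, so fully sex-specific TFs are not typically planted.

## ORA

Flat hypergeometric upper tail per annotated term with K ≥ 1 universe genes;
raw p ≤ 0.05 is the headline criterion and BH-adjusted values are reported
alongside. The default universe is the set of expressed genes (FPKM ≥ 1
anywhere in the relevant groups); term-hierarchy propagation is out of
scope.

## Synthetic-data generator

One `numpy` generator seeded once drives everything in a fixed order, so a
fixed seed gives byte-identical artifacts. Defaults define the standard
study: 2000 genes; per-gene baseline lognormal(ln 100, 1) count means; NB
dispersion α = 0.1 shared across genes; 20 stage-preferential genes per
pistil group at fold 5; 50 standalone sex-differential genes per stage
contrast at |log2FC| = 3 (signs alternating); 10 TF-led modules of 12 genes.

Module members share a latent group profile — lognormal with log-sd 2 around
a 200-count baseline, i.e. strongly stage-modulated regulons — times
per-gene×group lognormal noise (sd 0.05). The latent profile is redrawn
until its realized log-sd across the four pistil stages is ≥ 1.2: with only
four draws, an unlucky module would otherwise realize a near-flat profile
and the planted "high within-module correlation" property would fail for
that module rather than merely on average. The opposite sex receives the
same profile except at the module's most-expressed (dominant) stage, where
it is divided by 2^3, making members sex-differential exactly there; the
ground truth records stage-preferential genes as DE at their own stage too
(fold 5 ⇒ |log2FC| ≈ 2.32 > 1), since they genuinely are.

Promoters are i.i.d. sequences at GC = 0.35 (order-0; a Markov background is
a non-goal); each module TF gets a 10-bp motif with 85/5/5/5 column counts,
and one consensus instance is planted per true target at rate 1.0, at a
uniform offset on a random strand, recorded in the truth. The toy genome
places each gene on its own contig (promoter + 1 kb body, alternating
strands) so the GFF3/FASTA extraction path reproduces the generated
promoters exactly.

What the generator does **not** emulate: batch effects, gene-length
variation, isoform structure, correlated background genes, GC bias,
sequencing-depth composition beyond library-size scaling, or TFs silenced
outright in one sex. Passing recovery tests therefore demonstrates that the
chain of estimators is correct and calibrated under its own model
assumptions — not that those assumptions hold for any particular real
dataset.

## Problem sizes and tolerances

The standard benchmark is three seeded replicates of the 2000-gene study
(~10 s per replicate end-to-end); unit tests use a 600-gene version of the
same design. Null calibration of both DE tests is asserted inside
[0.03, 0.07] at nominal 0.05 on a planted-null 2000-gene study. Oracle
comparisons (SS, mutual rank, Fisher, BH, ORA) are exact to 1e-12.
Recovery floors on the standard study: ≥ 90% of planted stage-preferential
genes called, ≤ 5% background false calls, shared-DEG sensitivity ≥ 0.85 at
empirical FDR ≤ 0.10, ≥ 85% of planted TF→target edges recovered, every
planted motif enriched at Bonferroni p < 0.001, and a repeated run is
byte-identical.

## Known limitations

* The two DE tests are internally specified; they are not numerical
  replicas of any external package, and agreement with such packages is not
  claimed.
* The mutual-rank [0, 1] normalization is a modeling choice (linear rescale
  by default); network size is sensitive to it, so it is surfaced in the
  output metadata rather than hidden.
* The AME-style enrichment depends on the foreground definition (a TF's
  co-expression partners); small regulons (< ~8 targets) cannot reach
  Bonferroni p < 0.001 against a ~30% background hit rate at the default
  scan p-value.
* Sample sizes of n = 3 per group leave Wald inference approximate even
  after dispersion shrinkage; the exact test is the more reliable of the two
  at very low counts.
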