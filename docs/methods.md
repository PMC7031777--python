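# Methods

This note documents the models, statistics and numerical choices behind
`subreg`, what the synthetic cohorts do and do not emulate, and the
problem sizes used by the test suite and acceptance script.

## The discovery pipeline

### Signature expansion

A subtype's extended signature (ESG) is built from a seed list by a
cross-dataset coexpression search. Within each expression dataset
(genes × samples, log scale), the score of a non-seed gene is the mean
Fisher-z-transformed Pearson correlation with the present seeds,
rank-normalized to [0, 1] (ties averaged). Rank normalization makes the
aggregate invariant to any strictly monotone per-dataset transform of
expression, which is what allows microarray and RNA-seq cohorts to be
combined. Each dataset is weighted by seed self-consistency: the mean
leave-one-out rank score of each seed against the others (≈1 when seeds
are mutually coexpressed, ≈0.5 when they are unrelated; datasets with
fewer than two measured seeds are dropped). The genome-wide aggregate is
the weight-weighted mean over the datasets covering each gene; the top
k = 200 genes (ties broken by gene id) form the ESG, seeds excluded.
Empirical coexpression p-values compare a gene's aggregate against
uniformly resampled genes, p = (1 + #{random ≥ observed})/(n_perm + 1).

### ChIP-seq binding scores

Peak signal values are normalized by the experiment's 75th-percentile
signal (linear interpolation between order statistics) times a base
score of 500, so scores are invariant to sequencing depth. A peak
overlaps a gene when it intersects the gene's TSS ± 50 kb window by at
least 1 bp; the peak's normalized score is split evenly over the n(f)
genes it touches and the per-gene binding score is

    g = sum over peaks f near g of p_norm(f) / n(f).

This conserves signal mass: the sum of all gene scores equals the total
normalized signal of window-overlapping peaks (a test invariant).
Experiment prioritization sums g over an ESG and compares against
size-matched gene sets sampled uniformly without replacement
(permutation p with the +1 correction); factors matching an editable
exclusion list (CTCF, RAD21, POLR2A/POL2, H2*/H3*/H4*) are dropped
before testing, and results are summarized per cell line (best p,
count of significant experiments).

### Enrichment statistics

The rank-based enrichment statistic is the minimum hypergeometric
(mHG): for a ranked list of N genes containing K members of a target
set, mHG = min over prefixes n of P(X ≥ k_n), X ~ Hypergeom(N, K, n).
Its exact p-value is computed by dynamic programming over the (n, k)
lattice: a ranking is a monotone path from (0,0) to (N,K); the p-value
is one minus the probability that a random path avoids every cell whose
tail probability is ≤ the observed statistic, accumulated with the
hypergeometric walk's conditional step probabilities. The DP is O(N·K)
in floating point and matches exhaustive enumeration over all orderings
for all N ≤ 10, K ≤ 4 to 1e-9. For N > 50 000 a conservative bound
(statistic × number of prefixes) is available. Ties in caller rankings
are always broken by gene id before membership construction.

Welch's unequal-variance t-test (Satterthwaite df) and the one-sample
t-test are two-sided throughout; direction labels (hyper/hypo, gain/
loss) come from the sign of the difference afterwards. Degenerate
zero-variance cases return t = 0, p = 1 for equal means and p = 0 with a
warning otherwise. Multiple testing uses Storey q-values: π0 estimated
on λ = 0.05…0.95 with a cubic-polynomial smoother evaluated at λ = 0.95,
forced to 1 for batches under 100 tests (where the estimator is
unstable, and the procedure reduces to Benjamini–Hochberg), with
step-up monotonicity enforcement.

### Deregulation scoring

Copy-number segments carry log-ratios in [−1, +1]. A gene belongs to a
segment when its body midpoint lies inside it (default; an any-overlap
mode exists — note a gene spanning a breakpoint can then belong to two
segments). Per sample, gain(g) sums cna(f)/len(f) over containing
segments with positive ratio, loss(g) over negative ones; len(f) is the
segment's gene count under the same rule. Per subtype, one-sample
t-tests against zero flag genes associated with gains and with losses.
Because gain and loss are censored at zero, their tests are one-sided
screens and are anti-conservative under a pure-noise segment model; the
signed net value gain+loss is symmetric under that null and is the
quantity whose type-I rate is calibrated (reported as `p_net`).

CpG beta values are summed per gene and sample over promoter CpGs;
Welch tests of each subtype's tumors against the shared normal group
call hyper-/hypomethylated genes at P < 0.01 (configurable).

For the subtype-aberration enrichment (the pipeline's central readout),
genes are ranked by the magnitude of their subtype-mean deregulation —
|gain| + |loss| for CNA (a max mode exists), |tumor − normal| gene-level
difference for methylation — and each TF set is tested with exact mHG
against the TF universe as background (ESG-level sets use the
whole-genome background). q-values are computed across the batch of
(subtype × aberration × set) tests.

### Networks, lineages, knockdown validation

A ChIP'd TF gains a directed edge to an ESG gene when the gene's
binding score exceeds the experiment's genome-wide 95th percentile of
nonzero scores ("higher than expected"; mean+2sd and absolute modes
exist; multiple experiments per TF are averaged before thresholding).
The TF–TF network restricts targets to TF-flagged genes; targets are
partitioned by their exact in-neighbor sets.

Lineage decomposition intersects two assignments over the
substantially-bound ESG subset (score > 0 in ≥ 3 experiments):
(1) per-gene Welch tests of binding scores between an epithelial and a
stem experiment group, labeling by direction at p < 0.05;
(2) open-chromatin log fold-changes per cell line (each line vs the mean
of the others, pseudocount 1), hierarchically clustered
(average linkage, Euclidean) into 3 clusters, each labeled by the line
with maximal mean LFC (≥ 0.1, else ambiguous). Before clustering, LFC
rows are scaled to unit norm: the lineage signal is the *direction* of
the LFC vector, and raw magnitudes (accessibility depth) otherwise
chain the linkage into one mixed cluster. A final epithelial/stem label
requires agreement of both routes; mesenchymal is observable only
through chromatin and is assigned when binding is ambiguous.

Knockdown validation calls a gene perturbed when its linear fold-change
between knockdown and control means exceeds 1.5 in either direction
(expression is log2); the ESG's perturbed proportion is compared with
size-matched random gene sets by permutation.

## The synthetic cohorts

`PlantedModel` plants, on an n-gene genome with an n_TF TF subset: per
subtype, a set of regulator TFs with target modules; module coexpression
through a one-factor model (target = baseline + effect·1[own subtype] +
λ·z_sample + N(0, σ²), with the factor active in all samples so the
within-module correlation has the closed form λ²/(λ²+σ²), ≈ 0.33 at the
defaults λ = 0.7, σ = 1); regulators track their module factor tightly
(loading 1, residual sd 0.3). ChIP-seq experiments put peaks uniformly
over the genome plus, for planted regulators, peaks inside target TSS
windows at 5× the background density with doubled tag means. CNA
segments tile chromosomes with a geometric number of genes (mean 5);
segments covering a basal regulator (or a planted half of its targets)
get log-ratio ±0.5 (alternating sign per regulator) in basal samples,
N(0, 0.05) elsewhere, clipped to [−1, 1]. Methylation plants a −0.2
beta shift at luminal-A regulators (and half their targets) in
luminal-A tumors, with Beta-distributed CpG noise around per-gene
baselines in TSS ± 1.5 kb promoters. Open chromatin gives every basal
module gene a promoter peak, amplified 4× in its own lineage's cell
line, plus enriched peaks near own-lineage genes. A genome FASTA
(capped at 100 Mb) can plant a motif consensus into a stated fraction
of a regulator's peaks.

Defaults follow the study-scale magnitudes (17 000 genes, 1000 TFs,
5 regulators × 40 targets per subtype, 50 tumors/subtype + 30 normals);
gene spacing is exponential with mean 30 kb so ±50 kb windows overlap
and peaks are genuinely shared between genes.

What the generator does **not** emulate: read-level noise, peak-caller
artifacts, segmentation breakpoint realism, array probe effects,
correlated CNA/methylation at the same loci, tumor purity, or
biologically structured backgrounds (e.g. CpG islands). Passing
recovery tests therefore demonstrates correctness and calibration of
the pipeline's statistics under its stated model, not performance on
real cohorts.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the planted conditions
at desk scale: a 2000-gene genome with a 200-TF background, 5
regulators × 40 targets per subtype, 5–10 datasets × 30–50 samples,
2000 background peaks per experiment, 50 tumors/subtype + 30 normals,
and 20 replicate seeds for the multi-seed properties. These sizes keep
the full suite around a minute while leaving all planted effect sizes
and thresholds at their defaults.

Other numerical choices: percentile computations use linear
interpolation; Fisher z is capped at |r| = 1 − 1e−6; PWM log-odds use a
1e−3 pseudocount against the background composition (note a consensus
PWM's score distribution is nearly discrete, so quantile-calibrated
thresholds are only exact for soft matrices); permutation p-values use
the (1 + hits)/(1 + n) estimator and are deterministic under a fixed
seed; all generator streams derive from a single root seed via fixed
sub-stream ids, so every output is reproducible byte-for-byte.

## Known limitations

The original analysis' headline numbers (real-cohort q-values, TF
counts, lineage gene counts, open-chromatin overlap percentages) depend
on external data (TCGA, METABRIC, OSLO2, ENCODE, GEO) and are out of
scope; this package establishes the machinery and its calibration on
planted cohorts. The motif route treats the motif→TF-family map as an
explicit input rather than shipping a TFBS database. Gene-set
enrichment against a real ontology is replaced by a generic term-table
test. The one-factor coexpression model cannot express nested or
overlapping modules with distinct factors per regulator.
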