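# Methods

This note documents the models, defaults and numerical choices behind
`amniowave`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic time course

`generate_time_course` emulates a triplicate bulk RNA-seq experiment over
the grid 0, 0.5, 1, 3, 6, 12, 24, 48 hr after a signaling trigger. Gene
counts are negative binomial with the standard RNA-seq parameterization
var = μ + α·μ² (`nb_dispersion` α, default 0.05; α = 0 degrades to
Poisson). Baseline means are log-normal (`baseline_mean_log_mu` = 4,
`baseline_mean_log_sigma` = 1 in natural log, i.e. a median of ~55 counts
with a realistic right tail). Five planted waves of 100 genes each switch
from baseline to `activation_fold` × baseline (default 8) at onset hours
{immediate: 1, early: 3, intermediate-1: 12, intermediate-2: 24, late: 48};
the remaining 1500 genes are flat background. Activation is a step by
default because the classifier's semantics is "first significant
upregulation relative to the previous timepoint"; a logistic option
(`activation_shape="sigmoid"`, half-time at the onset hour) is available
for smoother dynamics. Per-sample library sizes are log-normal with zero
log-mean (`libsize_log_sigma` = 0.15, ~±15% depth variation) so the
expected geometric mean is 1 and median-of-ratios estimates are directly
comparable to truth. All randomness flows from one integer seed.

What the generator does *not* model: isoforms, batch effects, mean-variance
trends beyond the single global dispersion, gene-gene correlation, or
read-level artifacts. Passing recovery benchmarks on these data therefore
demonstrates the pipeline's statistical machinery under a faithful noise
model, not robustness to every artifact of real sequencing.

## Filtering and normalization

Two count filters are applied in order: drop genes with no sample reaching
10 reads, then drop genes whose maximum is ≤ 30 reads. Both use strict
conventions (max ≥ 10 keeps; max > 30 keeps) and each logs its removal
count. Size factors are median-of-ratios: the per-gene reference is the
geometric mean across samples computed in log space, restricted to genes
positive in every sample (genes with any zero are excluded from the
reference set, the DESeq2 convention); the factor is the median ratio to
that reference. Note a structural property: scaling one sample's counts by
c rescales its factor by c^((n−1)/n) and every other factor by c^(−1/n),
because the geometric-mean reference absorbs c^(1/n); only factor *ratios*
are exactly scale-equivariant, and the tests assert exactly that. Log
views use log2(value + 1); the pseudocount keeps zeros at zero.

## Differential expression

Tests run on log2(normalized + 1). The default `moderated_t` pools the
two group variances per gene (df = n_A + n_B − 2) and shrinks them toward
a scaled inverse chi-square prior fitted across genes by moment matching
on log-variances (digamma/trigamma equations solved by Newton iteration);
the statistic divides the mean difference by the posterior standard error
and is referred to a t distribution with df = d_gene + d_prior. The
motivation is quantitative: at triplicate scale a per-gene variance
estimate has 2–4 df, so a normal reference is anticonservative (measured
type-I ≈ 0.12 at α = 0.05 on a simulated null) while a plain Welch-t
reference, though calibrated (≈ 0.034), cannot clear BH-corrected
thresholds even for eightfold changes (stage recovery ≈ 50%). Variance
moderation — standard practice for small-n RNA-seq — restores both
properties simultaneously (measured type-I ≈ 0.045, power ≈ 100% at fold
8). The unmoderated Welch statistic (`welch_t`) and its normal-reference
variant (`z_log2`) remain available for comparison. A variance floor of
1e-8 makes zero-variance genes yield statistic 0 and p = 1 rather than
NaN. No exact reimplementation of any commercial or NB-Wald pipeline is
claimed.

BH FDR is the step-up procedure computed per contrast over the filtered
gene universe, matching per-comparison selection. Significance is the
joint rule FDR < 0.05 and |fold| > 2, both strict, mirroring the printed
inequalities; the volcano classification deliberately uses the raw
p-value, as volcano displays conventionally do.

## Wave assignment

One contrast per adjacent timepoint pair, later group as group B, so
positive fold change means activation over time. A gene's wave is set by
the earliest contrast with FDR < 0.05 and log2 fc > 1; the later timepoint
of that contrast maps through the `StageMap`. The default map assigns 0.5
and 1 hr to *immediate* and 3 and 6 hr to *early* (the map is a config
object, so grouping 6 hr with 12 hr into intermediate-1 — an alternative
convention for these data — is a one-line change). Only upregulation
defines a wave; downregulation is reported in the contrast tables but not
staged. Tightening the FDR threshold can only move genes to later waves or
to `unassigned`, never earlier — this monotonicity is property-tested.

The optional stringent filter (`sustained` mode, off by default and
recorded in output metadata when applied) keeps a staged gene only if its
mean log2 expression at every timepoint from first activation onward stays
at least 1 log2 unit above its pre-activation baseline mean. This is an
explicit, documented heuristic for suppressing transient spikes; no
published procedure is claimed for it.

## Synthetic reference atlas and projection

`generate_reference_atlas` builds a 5-cluster, 1500-cell reference along a
differentiation trajectory. Expression programs share a log-normal
background; each cluster additionally expresses an exclusive 100-gene
marker block (zero mean elsewhere, weight 5× the mean background gene) —
roughly 25% of a cell's reads — and per-cell counts are NB (α = 0.1)
around the program scaled to a log-normal depth (mean 5000). Embedding
coordinates are synthesized, not fitted: cluster centers sit on a line at
`cluster_separation` (default 10) spacing and cells jitter around them
with SD `within_cluster_sd` (default 0.5). Keeping the embedding synthetic
removes any stochastic embedding algorithm from the test path; the
package likewise consumes real reference embeddings as given and never
refits them.

Projection of a bulk sample proceeds: (1) multinomial downsampling into
`n_cells` = 100 pseudo-single-cells at `depth` = the reference's median
per-cell total (so pseudo-cells are statistically comparable to reference
cells), pseudo-cell i drawing from the stream seeded seed + i; (2) LSI
transform — TF = count/column total, IDF = log(1 + N/(1 + N_expressing)),
X = log1p(TF·IDF·10⁴), projected on the top 30 right singular vectors of
the reference's X (deterministic dense SVD with sign fixed by the
largest-magnitude loading; the chromatin-analysis convention of dropping
component 1 is available as a flag but off by default, since these are
expression data and component 1 carries real signal); (3) embedding
transfer by inverse-distance-weighted average of the 15 nearest reference
cells in LSI space, with exact matches copying coordinates; (4) medoid of
the 100 transferred points (ties to lowest index); (5) label and distance
from the Euclidean-nearest reference cell in embedding space. Query gene
universes are reconciled by intersection: model genes missing from the
query are zero-filled, extra query genes dropped. TF normalization makes
coordinates invariant to scaling a query column.

## Problem sizes and determinism

Benchmarks run at the design sizes above (2000 genes × 24 samples;
1500-cell atlas; 20 cluster-derived bulks of 10⁶ reads), which complete in
seconds on one core. Identical configs and seeds reproduce outputs
bit-identically; the pipeline manifest records a config hash and SHA-256
of every file to make this checkable. Sub-seeds for independent stages are
derived as small fixed offsets (atlas seed + 1, projection seed + 2,
per-sample pseudo-cell streams seed + 100003·j).

## Known limitations

- The moderated test assumes exchangeable variances around a single prior;
  a strong mean-variance trend would call for a trended prior, not modeled
  here.
- Wave assignment keys on consecutive contrasts only; a gene rising slowly
  but monotonically may never clear fold 2 between neighbors and end
  `unassigned` (cumulative contrasts against 0 hr are not implemented).
- The projection assumes the reference embedding is locally smooth in LSI
  space; label transfer degrades for query states absent from the
  reference, which distance magnitudes (reported per sample) help flag.
- Biotype-based gene filtering (e.g. protein-coding only) requires an
  annotation source and is out of scope; the gene universe is whatever the
  input provides.
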