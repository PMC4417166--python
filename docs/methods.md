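# Methods

## The quantity being modeled

The package studies how well local epigenetic state predicts quantitative
transcription-factor (TF) occupancy, position by position around regulatory
anchors. An *anchor* is a transcription start site (TSS, strand-aware), a
transcription termination site, or an enhancer midpoint (strandless). The
8-kb window centered on each anchor is tiled with 80 disjoint 100-bp bins
indexed −40..−1 upstream and +1..+40 downstream (there is no bin 0; bins
−1/+1 flank the anchor). For a minus-strand gene the indices follow
transcription direction, so "+k" always means k·100 bp downstream. Genes
shorter than 4 kb from TSS to TTS are excluded so the downstream flank is
fully intragenic; a gene of exactly 4 kb is retained. Anchors whose window
would leave the chromosome are dropped rather than truncated, so every
retained anchor contributes a complete 80-bin profile, and anchors sharing
(chrom, strand, position) are collapsed to avoid duplicated design rows.

## Per-bin signals

For each sequencing experiment the per-base coverage is the number of read
intervals containing that base. A bin's raw signal is the arithmetic mean of
its 100 per-base coverages, scaled to reads per million (RPM) by
10⁶ / library size, where the library size is the experiment-wide mapped-read
total supplied by the manifest (never recomputed from a window). Replicates
are RPM-normalized first and averaged second. Histone-mark and
histone-variant features stay on the RPM scale; the TF target additionally
takes log₂(RPM + 1). A bin into which no TF read at all maps (pooled across
replicates) receives the sentinel −1 instead of log₂(0 + 1) = 0, keeping
truly read-free bins strictly below every covered bin, including
low-but-nonzero ones. Rows with y = −1 are retained in training; no
exclusion or weighting is applied.

DNA methylation enters as the mean level of the CpGs whose position falls in
the bin. A CpG-free bin is *missing*; the default policy writes 0.0 and
records the fact in a missingness mask, so the models always receive
complete matrices. The alternative `mask_only` policy leaves NaN for the
caller. Methylation levels outside [0, 1] are rejected at load time, and
duplicated positions (strand pairs, assay overlap) are averaged.

The default feature panel has 12 entries: H2az, H3K4me1/2/3, H3K9ac,
H3K9me3, H3K27ac, H3K27me3, H3K36me3, H3K79me2, H4K20me1 and DNAmeth.

## Models and evaluation

Each bin is modeled independently: the anchors × 12 matrix of that bin's
feature levels predicts that bin's TF affinity. Two model families are
fitted. Multiple linear regression (ordinary least squares; a rank-deficient
design is an error naming the collinear columns) and a bagged random-forest
regression with the classical regression defaults: 500 trees, floor(p/3) = 4
candidate features per split, terminal nodes of ≥ 5 rows. The forest is a
bootstrap ensemble of CART trees built here rather than taken from a library
forest because permutation importance needs each tree's genuine out-of-bag
(OOB) rows; the tree learner itself is scikit-learn's.

Accuracy is estimated by repeated random splits: 2/3 of anchors train, 1/3
test, 50 repeats by default (smaller studies use fewer; each states its
size). Scores are the Pearson correlation (PCC) between predicted and
observed affinities on the test anchors, and R². The default R² is the
squared PCC of predicted vs observed; the 1 − SS_res/SS_tot variant is also
computed and reported alongside, since the two diverge for miscalibrated but
correlated predictions. A repeat whose test target (or prediction) is
constant has no defined correlation; it is skipped and counted, and a bin
errs out if more than 20% of repeats skip.

Feature contributions use %IncMSE-style permutation importance: per tree,
the MSE on that tree's OOB rows is computed before and after permuting one
feature's values; the importance is the mean increase over trees divided by
its standard error across trees (the scaled variant; the raw mean is
config-selectable). Permuting a column that is constant is a no-op, so such
features score exactly 0. Because the magnitude of %IncMSE is not comparable
across bins, scores are converted to within-bin ranks 1..12 (1 = most
important, ties broken by canonical feature order and flagged), and the rank
profiles are what cross-bin comparisons use.

## Transfer

A model fitted in one context (cell line, or coding promoters) is applied to
the *same bin index* of another context, using the target's feature levels
as inputs; applying across bin indices is an error. Transfer models train on
the full source anchor set by default — the target set is disjoint, so
nothing leaks — with a split-trained variant available for strict
comparability with CV numbers. The report table gives per-bin
Δ = same-context CV PCC − cross-context PCC plus column means.
Coding→non-coding transfer reuses the same machinery with the gene class as
the context label; enhancer runs are ordinary same-context runs on
enhancer-midpoint anchors.

## Synthetic data generator

The generator emulates all four input classes with a known link:

* **Annotation** — genes in disjoint 20-kb slots with jittered starts and
  50/50 strands; a configurable fraction of sub-4-kb decoys exercises the
  length filter with an exact retained count; enhancers sit ≥ 10 kb from
  every TSS.
* **Latent feature levels** — L[a, f, b] = exp(μ_{f,b} + ε) with
  μ ~ N(0, 0.3) per (feature, bin) and ε ~ N(0, 0.5) per anchor. Baselines
  μ are shared by all cell lines (they are properties of the genomic
  position); only the anchor-level ε and, optionally, the weights are
  cell-line-specific, which makes matched-weight cell lines statistically
  exchangeable. The methylation latent passes through a logistic so it lives
  in [0, 1].
* **Affinity** — latents are z-scored per (feature, bin) before weighting,
  so each feature's share of signal variance is its squared weight and the
  ground-truth importance order is well defined. y* = link(Σ_f w z) +
  N(0, noise_sd) with link ∈ {linear, multiplicative, saturating}. The
  multiplicative link multiplies the two half-sums of the weighted features:
  it has no linear component (a linear fit scores ≈ 0) yet remains
  tree-learnable. The default weights put a fixed pattern (1.0, 0.8, 0.5,
  0.3) on H3K4me3, H3K9ac, H3K27ac, H3K4me1 — the top two marks carry 83% of
  signal variance — scaled by 1.6·exp(−|bin|/30) so contributions decay away
  from the anchor.
* **Reads** — per bin, counts ~ Poisson(L · read_depth), placed uniformly
  inside the bin (36 bp; boundary-straddling reads are an option), two
  replicates, library size = reads drawn. The TF rate is
  tf_depth · (2^(y*−min y*) − 1): exactly zero at the lowest latent
  affinity, so read-free bins (the −1 path) arise precisely where binding is
  weakest, and the observed log₂(RPM+1) is a monotone noisy image of y*.
* **Methylome** — CpG counts per bin ~ Poisson around a density profile
  peaking at the anchor (≈ 8/bin) and decaying to ≈ 1/bin distally, so
  CpG-free bins occur naturally; levels jitter (σ = 0.05) around the bin's
  latent and are clipped to [0, 1].

All randomness flows from one master seed through named child streams
(annotation, mu:feature, latents:cell:feature, weights:cell, noise:cell,
tracks:cell:feature:replicate, tf:cell, methylome:cell), and latent draws
cover all 80 bins even when a run restricts to a subset — so partial
regeneration and bin subsetting never change the values of what is kept.

**Calibration of the reference scenario.** With a linear link, the latent
PCC of bin b is A(b)/√(A(b)² + σ²) with A(b) = 1.6·exp(−|b|/30), σ = 0.45:
≈ 0.96 at bin ±1, ≈ 0.68 at ±40, mean ≈ 0.85 over the 80 bins. The default
depth (read_depth 50, tf_depth 8, ≈ 60 reads/bin/replicate) keeps observed
RPM and log₂(RPM+1) correlated with their latents at r > 0.98, so the
generative latent PCC is a meaningful ceiling for the pipeline.

**What the generator does not emulate.** Fragment-length and GC models,
mappability, duplicated reads, input/background enrichment, peak structure,
inter-feature correlation beyond the shared target, and biological
covariation between methylation and chromatin state. Passing tests
demonstrate that the *procedure* recovers known structure under realistic
counting noise, not that real epigenomes are this predictable.

## Reference experiments and problem sizes

The studies in `epibind.experiments` (also run by `scripts/acceptance.py`)
use desk-scale sizes chosen so each completes in minutes on one core:

* **Recovery** — the read-level pipeline end to end: 1000 anchors, bins
  ±{1, 2, 10, 20, 40}, RF with 200 trees, 10 CV repeats. Expected: mean CV
  PCC within 0.1 of the mean latent PCC of those bins, and proximal
  (|b| ≤ 2) above distal (|b| ≥ 20). The residual gap (≈ 0.05–0.08) is
  dominated by forest estimation error at n = 1000, not by counting noise.
* **Link non-linearity** — latent matrices, n = 1000, 5 generator draws,
  bin +1: RF beats MLR by ≥ 0.05 under the multiplicative link; MLR is
  within 0.05 of RF under the linear link (it is the true model class
  there, since y* is linear in the raw feature levels).
* **Importance recovery** — 20 draws × 6 bins at n = 800, 150 trees: the
  %IncMSE top-2 set matches the generative top-2 in ≥ 90% of bins.
* **Transfer** — two cell lines, n = 800, bins {+1, +10}, 10 draws per arm:
  matched weights give |Δ| < 0.05; independently drawn weight directions
  drop cross-context PCC by ≥ 0.1 (in practice far more).
* **Permutation null** — shuffling y collapses CV PCC to |PCC| < 0.1 and
  the importance spread (max − median %IncMSE) to a small fraction of its
  value on the true target.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; 1-based dialects convert at
  the reader boundary.
* Bins follow transcription direction for genes (strand-aware) and genomic
  order for enhancers; both behaviors are selectable per scheme.
* RPM-then-average replicate order follows the operational definition above;
  the reverse order is a config option for sensitivity checks.
* Read-free TF bins are judged on pooled replicate coverage: a bin has zero
  reads iff its pooled per-base coverage sums to zero.
* Rank ties (exactly equal importance scores) break by canonical feature
  order and set a flag rather than passing silently.
* Pearson correlation on a constant vector raises rather than returning NaN;
  callers decide whether that means "skip the repeat" or "record undefined".
* The %IncMSE scale divides by the across-tree standard error; a feature
  with zero spread but nonzero mean increase maps to ±inf by convention.
* Forest determinism: bootstrap indices and tree seeds derive from one
  integer seed, so fit/predict/importance are pure functions of
  (data, config, seed); per-(bin, repeat) child streams make bins and
  repeats order- and parallelism-independent.

## Known limitations

* The bagged forest fits trees in a Python loop; it is fast enough for
  desk-scale studies (≈ 0.3 s per 200-tree fit at n = 1000) but not tuned
  for ENCODE-scale anchor sets.
* bedGraph coverage tracks are supported as inputs, but bigWig/BAM readers
  are not wired into the manifest loader; convert upstream.
* The multiplicative link's ground-truth importance order is defined from
  squared weights as in the linear case; this is an approximation when the
  interaction dominates (the importance-recovery study uses the linear
  link).
* `coefficient_of_determination`'s two modes can disagree strongly on
  transferred models (correlated but shifted predictions); tables report
  the squared-PCC variant unless stated.
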