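# Methods

## Overview

`windowdb` detects differential binding (DB) between conditions in
ChIP-seq data without pre-defined peaks.  Reads are directionally
extended to the average fragment length, counted into sliding windows
tiling the genome, filtered against a global background estimate,
normalized, and tested per window with negative-binomial (NB)
quasi-likelihood (QL) F-tests.  Windows are then merged into regions and
the region-level false discovery rate (FDR) is controlled by combining
window p-values with Simes' method and applying Benjamini–Hochberg (BH)
across regions.  Testing windows but reporting regions is what makes the
FDR interpretable: a single binding event spans many correlated windows,
so window-level BH would control the wrong error rate.

## Coordinates and read filtering

All internal coordinates are 0-based half-open; every user-facing table
and log message is 1-based inclusive, converted only at the presentation
layer.  Reads are used when their mapping quality is at least `minq`
(default 50, appropriate for short single-end reads), their chromosome is
in the optional restriction set, and their 5' position does not fall in a
blacklisted interval.  Blacklist membership is judged by the 5' base, not
by any-overlap of the extended fragment: the rule is cheap, deterministic
and independent of the fragment-length estimate; the alternative
(any-overlap) would discard a few extra reads at blacklist margins.
Duplicate-flagged reads are kept everywhere except cross-correlation,
where they exaggerate the read-length phantom peak.

## Fragment length

The average fragment length is the delay maximizing the Pearson
correlation between forward- and reverse-strand 5'-position count vectors
(multiple reads at one base contribute their count, not a 0/1 indicator).
Correlations are computed per chromosome with FFT cross-products and
exact sliding means/variances, then averaged across chromosomes and
libraries weighted by read count; read count rather than chromosome
length is used because empty stretches of genome carry no information
about the fragment-size distribution.  `max_delay` defaults to 1000 bp,
generously above any sonication fragment size.  Ties break toward the
smaller delay.  On simulated bimodal reads the estimate is within a few
bp of truth for fragment lengths 100–200.

## Counting

Windows of `width` bp start every `spacing` bp from position 0 of each
chromosome; the final partial window is kept, clipped at the chromosome
end.  An extended fragment adds one count to every window it overlaps by
at least one base (implemented with difference arrays, O(reads +
windows)).  Windows whose count sum across libraries is below
`min_total` (default 10) are dropped immediately — a memory filter, not
the statistical one.  Bins are the disjoint case: each fragment is
counted once, into the bin containing its midpoint, so bin counts are
conserved per library; this single-assignment property is what the TMM
composition logic requires.  The midpoint convention (vs the 5' base) was
chosen because it is symmetric in strand.

## Abundance filter

The average abundance of a window is
`log2(1e6 * mean_i((count_i + p_i)/N_i))` with a prior count specified
per million reads (`p_i = prior * N_i / 1e6`, default prior 2).  This
form is exactly invariant to rescaling any library's counts together
with its total and strictly monotone in counts.  The background estimate
is the median abundance of large bins (2 kbp for broad marks) minus
`log2(bin_width / window_width)`; a window is kept when its abundance
exceeds background by more than `log2(min_fc)` (default 3-fold,
strictly).  The width rescaling uses nominal widths by default; an
`effective_widths` flag uses `width + ext − 1`, which shifts the
statistic by a constant that the fold-change threshold absorbs.

## Normalization

Two mutually exclusive schemes, matching the two failure modes of
ChIP-seq depth scaling:

* **Loess offsets** (trended biases, e.g. efficiency differences in
  histone-mark data): per library, M-values `log2(count+0.5)` minus the
  window row mean are smoothed against average abundance by locally
  linear lowess (span 0.3, 3 robustness iterations); fitted values,
  converted to natural log and row-centred to mean zero, become the GLM
  offset matrix.  Requires abundance-filtered input and assumes most
  windows are non-differential at every abundance (balanced DB).
* **Binned TMM factors** (composition bias, e.g. global loss of binding
  in a knock-out): the trimmed mean of M-values is computed on large
  unfiltered bins (10 kbp for TF data), where background dominates.
  Reference library: upper-quartile CPM closest to the mean upper
  quartile.  Trim fractions 0.3 (M) and 0.05 (A), rank-based with stable
  ties; weights are the inverse delta-method variances
  `(N−y)/(Ny)` summed over the pair.  Factors are rescaled to geometric
  mean 1.

`effective_offsets` unifies both as natural-log GLM offsets
`log(N_i) + offset` or `log(N_i f_i)`.  Offsets are stored in natural log
(the GLM-native scale) and divided by `log(2)` only for display.

## Statistical model

Counts are NB GLMs with log link: `log mu_gi = x_i' beta_g + o_gi`.
Fitting is damped iteratively reweighted least squares, vectorized across
windows (one design matrix; per-window step-halving whenever a step
increases the deviance; convergence at score norm < 1e-6 or 50
iterations).  The NB deviance uses the analytic y = 0 and phi = 0
(Poisson) limits.

**NB dispersion trend.**  The Cox–Reid adjusted profile likelihood
(APL = log-likelihood − ½ log det X'WX) is evaluated on a 41-point
log-spaced grid of dispersions in [1e-4, 1], refitting the GLMs at each
grid point (warm-started from the previous one).  Windows are pooled into
20 abundance bins; each bin's APL-maximizing dispersion (with quadratic
interpolation in log-dispersion) is smoothed by loess over bin abundance
(span 0.5) and interpolated back to windows.  Only this trend is used
downstream; per-window ("tagwise") dispersions are deliberately not
estimated, as window-level variability is handled by the QL dispersion.
Residual df uses plain n − p; windows with many fitted zeros may be
slightly anticonservative, which the abundance filter makes rare.

**QL dispersions and empirical Bayes.**  The raw quasi-dispersion is
deviance over residual df at the trended NB dispersion.  Its abundance
trend is estimated by lowess on the log scale *without* robustness
iterations — the heavy left skew of log chi-squared is expected, and
robust iterations would bias the conditional mean upward (about +20% in
our null simulations, visibly deflating type-I error).  Exact-zero
deviances (identical counts within groups, an atom the continuous theory
does not cover) are floored at the smallest positive value before taking
logs.  The prior degrees of freedom d0 are estimated by moment-matching
`log(s2_raw/s2_trend)` to a log-F(df_res, d0) distribution via the
trigamma inverse; the trend is bias-corrected by the corresponding
digamma terms.  Shrunken values are
`s2_post = (d0 s2_trend + df_res s2_raw)/(d0 + df_res)`, which always
lies between the raw value and the trend.

With `robust=True` (the pipeline default) the moment matching uses
residuals winsorized at their empirical 5%/95% quantiles, solving for the
d0 whose theoretical winsorized log-F variance (by probability-integral
quadrature) matches the observed one.  Windows above the upper
winsorization limit then receive an individually reduced prior df, chosen
so their observed dispersion ratio is exactly as extreme under their
personal prior as the winsorization limit is under the global one; such
outlier windows are therefore shrunk less and cannot borrow significance
from the trend.

**QL F-test.**  For a contrast of rank r, the statistic is the deviance
difference between the full fit and the null-constrained fit (design
post-multiplied by a null-space basis of the contrast), divided by
r·s2_post; p-values come from F(r, d0 + df_res), degenerating to the
scaled chi-squared form when d0 is infinite.  logFC is the contrast
applied to the coefficients divided by log 2.

## Region-level inference

Sorted windows merge transitively when the gap `start_{i+1} − end_i` is
strictly below `tol` (default 100: "fewer than 100 intervening bases" in
half-open coordinates — off-by-one conventions differ between tools, so
this is pinned by tests).  Clusters spanning more than `max_width`
(default 5 kbp) split into `ceil(span/max_width)` contiguous subclusters
of near-equal span, windows assigned by midpoint — deterministic and
order-free.  Per cluster, Simes' combined p-value
`min_i(m p_(i) / i)` tests the global null over member windows (valid
under the positive dependence of overlapping windows); `logFC.up` /
`logFC.down` count members beyond ±0.5 log2 units; BH across clusters
controls the region-level FDR.  The best-window summary reports the most
significant member (ties to the leftmost), Bonferroni-adjusted within the
cluster (Holm would differ only beyond the minimum p-value, which
dominates here).  Feature-directed combination (e.g. promoters) applies
Simes over the windows overlapping each feature; features sharing windows
each use their own member set, and featureless promoters get NA rows.

## Annotation

Genes touching a region are reported as `SYMBOL|FEATURES|STRAND`:
promoter = 0, exons numbered 5'→3' in gene orientation over the merged
exon set (the per-transcript convention is not defined for merged
models), intron = `I` at most once per gene, runs compressed (`0-1`,
`0,2`).  Flanking strings list promoter/exon features wholly outside the
region within 5 kbp, with the intervening distance appended; introns
never flank.  Promoters default to 3 kbp upstream / 1 kbp downstream of
the TSS.

## Synthetic data

`simulate_reads` emulates the statistical structure the workflow relies
on: uniform background fragments plus strand-bimodal site reads (forward
5' ends at `position − frag_len/2`, reverse mirrored, Gaussian jitter of
SD `frag_len/10` plus a uniform shift within the site width), NB
replicate variability of site yields (phi = 0.05), optional per-library
depth, composition, trended-bias and duplicate parameters.  The default
experiment is two 500 kbp chromosomes, four libraries in two conditions,
90 sites of which 50 are differential at 8-fold, balanced up/down so the
loess normalization assumption (balanced DB) holds; ~45k reads per
library.  It does **not** model base calls, mappability, GC bias, or
irregular background, so passing tests demonstrate correctness of the
computation, not robustness to every artefact of real data.
`simulate_counts` is the count-level twin: log-uniform baseline means
(30–300 reads, typical of abundance-filtered windows), a log2 fold change
applied to the last design column, and per-window dispersions
`phi · d0/chi2(d0)` to mimic QL variability.  All randomness flows
through one seeded generator per call in a documented stream order.

## Numerical choices

* IRLS: score-norm tolerance 1e-6, max 50 iterations, 15 step-halvings,
  ridge 1e-8 on the normal equations; means floored at 1e-10 in deviance
  and likelihood evaluations.
* Dispersion grid [1e-4, 1] with 41 points covers biological coefficients
  of variation from 1% to 100%.
* p-values are clipped into (0, 1]; BED scores `-10 log10(FDR)` are
  capped at 3000.
* Problem sizes in the test-suite simulations (e.g. 1e5 null windows, 20
  FDR replicates, 2×10^5-read end-to-end experiments) were chosen as the
  smallest sizes at which the Monte-Carlo error is comfortably below the
  tolerances being checked.

## Known limitations

* Single-end reads only; paired-end fragment inference is out of scope.
* No consolidation across multiple window sizes.
* The loess normalization assumes balanced DB; strongly one-sided changes
  require the TMM path (the `tf` preset).
* The robust EB outlier rule is a deliberate simplification of
  established robust hyperparameter estimation; it reduces, never
  increases, per-window prior df.
* Region FDR control relies on Simes' validity under positive
  dependence; adversarial negative dependence between member windows is
  not covered.
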