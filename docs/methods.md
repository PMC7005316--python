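# Methods

## Data model

The pipeline operates on a feature × sample matrix of nonnegative integer
counts (ATAC-seq reads in peaks, or RNA-seq reads in genes) and a sample
table with age (integer years), sex (two labels), batch and library size.
Counts for feature *i* in sample *j* are modeled as negative binomial with
mean μᵢⱼ and dispersion αᵢ (variance μ + αμ²).

## Quality control

Peaks are kept when their maximum raw count strictly exceeds 20 in at least
one sample and their maximum counts-per-million never exceeds 500 (an
artifact cap; note CPM scales inversely with the number of features, so the
500 value presumes a genome-scale peak set — toy matrices should raise it),
and when they do not overlap blacklist intervals (0-based half-open BED, any
≥ 1 bp overlap).

*Benchmark peaks* are approximately invariant, strong, ubiquitously called
peaks: |log₂ fold change| between the age groups within the bottom quartile
(CPM + 0.5 pseudocount), maximum normalized count within the top decile, and
call rate ≥ 90 %. Quantile boundaries are inclusive. A sample passes QC iff
it calls ≥ 92.5 % of the benchmark set (inclusive). When no external call
matrix is supplied, calls default to count > 0 (logged). The size of the
benchmark set is roughly 0.1 × (fraction of features with near-zero fold
change) × n features; the flagging power against a dropout rate *d* is
1 − (1 − d)^|benchmark|, so cohorts need enough strong invariant features for
the sample QC to have teeth.

## Normalization and differential testing

TMM scaling factors follow the trimmed-mean-of-M-values definition: the
reference library is the one whose upper-quartile CPM is closest to the mean
upper-quartile; for every other library the factor is the precision-weighted
mean of log₂ count ratios after removing the 30 % most extreme M-values and
5 % most extreme A-values (rank-based double trim), exponentiated and
rescaled to geometric mean one.

The differential test fits, per feature, a negative-binomial GLM (log link)
on the user's covariates (sex, age group, log₂ effective library size,
batch, surrogate covariates). Dispersions are method-of-moments estimates
from Poisson fits (Pearson-residual form), smoothed by a lowess trend on log
mean abundance, and shrunk toward the trend with a fixed weight of 0.5 in
log space — a deliberately simple moderation scheme standing in for
common/trended/tagwise empirical-Bayes machinery. Significance is a
likelihood-ratio χ² test of the contrast column, BH-adjusted; the default
FDR threshold is 5 % for accessibility data and 10 % for expression data.
Under a null NB simulation (2000 features, 40 samples, lognormal abundances
and library sizes) the raw-p rejection rate at α = 0.05 is ≈ 0.055 (the
acceptance script recomputes it).

Model-adjusted values are log₂ CPM minus the OLS fit of a nuisance-only
design (intercept, batch, library size, surrogate covariates); being a
projection, adjusting twice equals adjusting once, and the factors of
interest must never appear in the null design (guarded by `protect`).
Surrogate covariates are the top principal components of the residuals of
log₂ CPM on the known design — orthogonal to it by construction; the number
of surrogate variables is a configuration value, not auto-selected.

PC1 marker selection treats samples as observations; the PC1 sign is pinned
so that the loading vector correlates positively with mean feature
abundance, making the positive/negative marker sets reproducible.

## Chronological trend discovery

Adjusted values are averaged within (sex, age in years) and treated as an
equally spaced ordered series (age gaps are not modeled — the series index
is the rank of the age). The differencing order D is chosen by successive
KPSS level-stationarity tests at α = 0.05 (difference until non-rejection,
D ≤ 2). Given D, a greedy ±1 neighborhood search over (p, q) runs from each
of the starting orders (0,0), (1,0), (0,1), (2,2), accepting strictly better
AIC; the best endpoint wins. Models are ML-estimated (statsmodels state
space); a constant is included for D = 0 and a drift term for D = 1 —
without drift the differenced series of a trending feature has an unmodeled
mean and sensitivity collapses. Candidates are rejected when the optimizer
does not converge or when an AR root nearly cancels an MA root (within 0.05
in the complex plane): both produce spurious likelihoods from redundant
parameterizations.

A feature carries a significant chronological trend iff D > 0 and at least
one AR or MA coefficient is present (p + q > 0). On simulated series of
length 60 this rule selects ≈ 5 % of white-noise series and essentially all
series with a linear trend of one noise-SD per year. A greedy stepwise
search does not guarantee the global AIC minimum: against an exhaustive
(p, q) ≤ (5, 5) grid the chosen model is occasionally (≈ 6 % of white-noise
series) more than 2 AIC units above the grid minimum, because the exhaustive
minimum over ~36 nested models rides a χ² order statistic; this mirrors the
documented behavior of stepwise ARIMA selection generally.

Fitted trajectories of selected features are z-scored per feature and
clustered with k-means (best of `nstart` random initializations, default
1000, ≤ 100 Lloyd iterations each; lowest within-cluster sum of squares
wins; scikit-learn handles empty clusters by relocation). Features trending
in both sexes can be clustered on the concatenation of their female and male
fitted series, z-scored over the concatenation, which lets sex-opposed
trajectories (rising in one sex, falling in the other) form their own
cluster. The number of clusters is chosen by scanning k = 2…15, computing
each cluster's hypergeometric enrichment signature against a user-supplied
feature-set collection (background = all trending features), collapsing
clusters with identical significant-set signatures, and recommending the
smallest k whose collapsed signature set equals that of k + 1.

## Breakpoint detection

For one cluster of features, adjusted values are reduced by PCA to n = 3
subject-level score dimensions. For a window span w and every integer age t
from (youngest + w) to (oldest − w), donors in [t − w, t) are compared with
donors in (t, t + w] by one-way MANOVA using the Pillai trace with the
standard F approximation (exact for two groups); the donor at exactly age t
belongs to neither side, and ages where either side holds fewer than
n_pcs + 2 donors are skipped (logged). The spans w = 10…20 years (step 1)
are scanned.

Each per-span −log₁₀ p curve is LOESS-smoothed under bandwidths 0.25, 0.30,
…, 0.75 (11 values). The smoother is a local **quadratic** tricube-weighted
regression: local-linear smoothing flattens peaks near the curve boundaries,
and early-life breakpoints necessarily sit within a few grid points of the
first tested age (youngest + w), where degree-2 fits preserve them (measured
on the synthetic benchmark: early-breakpoint recovery 0.63 with a
local-linear smoother vs ≥ 0.95 with local-quadratic). Smoothed curves are
back-transformed to p-values (clipped into (0, 1]; clipping logged) and
combined per age by Fisher's method, X² = −2 Σ ln pᵢ with df = 22. The
combined −log₁₀ p curve is smoothed once more at the smallest grid bandwidth
(0.25 — the least aggressive choice, so nearby breakpoints are not merged)
and classified into maxima/minima by sign changes of the first finite
difference.

A maximum is a *candidate breakpoint* when (i) its Fisher-combined χ²
p-value is ≤ α (default 0.01) and (ii) its prominence — the smoothed value
at the maximum minus the value at the nearest minimum (curve endpoints count
as minima when no interior minimum exists) — is at least 25 % of the global
maximum of the smoothed curve. Candidates pooled over all window spans are
grouped by a one-dimensional Gaussian mixture over their ages (component
count 1–4 by BIC; variance floor 1 year², matching the integer test grid);
each component is reported as a breakpoint interval with the median and
range of its member ages and the smallest member p-value.

**False-positive behavior.** The per-age MANOVA p-values are well calibrated
(verified against uniform by simulation), but Fisher's combination treats
the 11 bandwidth-smooths of the *same* curve as independent, so the combined
scale is strongly inflated, and a scan tests ~40 ages under 11 overlapping
window spans. Consequently a stationary cluster yields at least one
candidate in the majority of simulated cohorts at α = 0.01: the screen
controls per-age significance on the inflated scale, not scan-wise error.
Reported intervals should therefore be read jointly with the magnitude of
their combined −log₁₀ p (planted transitions of ~2 within-age SD reach
12–150; stationary chance patterns stay below ~13) and, ideally, replicated
across clusters, as in the independent per-cluster scans the pipeline
performs.

## Synthetic cohorts

The generator draws integer ages uniformly over the configured range for
each sex, lognormal library-size scales, and NB counts with mean
libsize_scale × 2^(baseline + trend(age, sex) + batch shift). Trends are
continuous piecewise-linear log₂ trajectories; `sex_opposed` mirrors the
trajectory around the baseline for males. Corrupted samples zero a
configurable fraction of high-signal (above-median mean) features.

What it emulates: age-uniform cohort composition, overdispersed counts,
composition effects (trending features shift library totals — the
benchmark cohorts pair up- and down-going clusters at each breakpoint age so
normalization cannot imprint one cluster's transition onto another),
batch shifts, and poor-quality libraries. What it does not emulate: genomic
coordinates and peak structure, subject-level random effects and repeated
technical replicates, irregular recruitment densities, cell-composition
drift as a latent confounder, and read-level artifacts. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the stated generative model, not robustness to every artifact of real
libraries.

The standard validation cohorts (`epichron.cohorts`) use 60 donors per sex
over ages 22–90, NB dispersion 0.08, baseline log₂ abundance 6, and
five-year rapid-change ramps of 1 log₂ unit (≈ 2 within-age SD at this depth)
centered at ages 40 and 66 — one up- and one down-going cluster of 100
features per breakpoint age plus 200 stationary features.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run, per replicate, 100–600
feature cohorts with 40–120 samples; ARIMA benchmarks use series of length
60 and 500 replicates per condition; breakpoint benchmarks use 20 cohort
replicates. These sizes are the package's standard validation settings.
Other fixed numerical choices: CPM pseudocount 0.5 for log transforms and
fold changes; dispersion bounds [1e-6, 10]; −log₁₀ p capped at 300;
KPSS with automatic lag selection; k-means and GMM seeded via a counter-based
child-seed scheme so stages are reproducible in isolation.
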