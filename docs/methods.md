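# Methods

## Problem and model

Single-subject spatial ICA of resting-state fMRI yields `N_src` components
per subject, each a spatial map with an associated time course (a column of
the mixing matrix in the linear model *x = A·s*).  The filter decides, from
the time course alone, whether a component is an *obvious artifact* or a
candidate resting-state network (RSN).  It is a two-feature rule, not a
full classifier: components that survive are candidates, not confirmed
networks.

### Criterion I — motion coupling

An OLS fit of the component time course on an intercept plus the six
rigid-body motion parameters produces a prediction; `r_moco` is the Pearson
correlation between time course and prediction (non-negative by
construction of least squares with an intercept), and `p_moco` its
two-sided significance via `t = r·sqrt((T−2)/(1−r²))` with `T−2` degrees of
freedom.  Two caveats are deliberate properties of this construction:

* The prediction is fit to the same data it is correlated with, so `r_moco`
  is a multiple-correlation coefficient and the t formula is
  anti-conservative under the null.  No correction is applied: the
  thresholds are *trained jointly* on the same statistic, which absorbs the
  bias.  The circular-shift permutation oracle in the test suite therefore
  checks the t formula as a p-value calculator for a *fixed* pair of
  series, not the refit statistic.
* If the time course is (numerically) orthogonal to the design the
  prediction is constant and the correlation undefined; the fit then
  reports `r_moco = 0, p_moco = 1` (no evidence of motion coupling).

Constant motion columns are dropped from the design with a warning; the
corresponding coefficient is reported as zero.

### Criterion II — out-of-band spectral power

The spectral estimator is the plain periodogram of the full record on the
grid `f_k = k/(T·TR)`, `k = 1..floor(T/2)`: the DC bin is excluded, the
Nyquist bin included when `T` is even, and bins are scaled so the total
power equals `T × variance` (Parseval; variance in the population, ddof=0,
convention — the same convention `normalize_timecourse` uses, so normalized
components have total power exactly `T`).  A Welch estimator is available
behind the `estimator` switch for sensitivity analyses; the periodogram is
the default because it keeps the bin count deterministic and
parameter-free.

The band-restricted spectrum zeroes all power outside the *open* interval
(0.009, 0.08) Hz — a bin exactly at an edge is outside.  Both spectra are
normalized to unit total power over the grid and compared by the maximal
absolute difference `D` of their cumulative curves.  The p-value uses the
asymptotic Kolmogorov distribution in its two-sample form with equal
effective counts, `n_eff = n_bins/2`, with the standard small-sample
correction `λ = (√n_eff + 0.12 + 0.11/√n_eff)·D`.  What the "two samples"
of the KS comparison are is a genuine design choice: treating the
normalized spectra as discrete distributions over the frequency grid gives
a deterministic, parameter-free rule that sends broadband components to
tiny p-values and band-limited components to p ≈ 1, which is the behavior
the filter needs.  Both the estimator and the KS construction are exposed
as configuration so alternatives can be compared.

### Classification

`ARTIFACT` if `p_moco < p_moco_crit` (reason `MOTION`) **or**
`p_pow < p_pow_crit` (reason `POWER`); both reasons are recorded when both
fire.  Degenerate components are artifacts by fiat with reason
`DEGENERATE`: a zero-variance time course (motion scores reported as NaN —
no finite p-value is meaningful there) or a spectrum with no in-band power
at all (`D = 1, p = 0`).  All scores are invariant under sign flip and
affine rescaling of the time course, as the sign/scale ambiguity of ICA
requires.

## Threshold training

Both thresholds are scanned on a log10 grid over `[10^-50, 10^-1]`, default
step 0.5 (99 × 99 points).  Component p-values are computed once; each grid
point costs only threshold comparisons.  The objective is the mean over
subjects of the subject-wise accuracy against reference labels — not the
pooled global accuracy, which would let subjects with many components
dominate.  Tie-breaking is deterministic: the grid is scanned from the most
stringent thresholds (`10^-50`) upward, p_moco outer and p_pow inner, and
the first maximum is kept.  On well-separated cohorts the optimum is a
broad plateau; the returned pair is then the plateau's most stringent
corner, and the surface is exported so users can see the full region.

## Evaluation

The positive class is `ARTIFACT` (the filter's detection target): `sens`
is the fraction of reference artifacts flagged, `spec` the fraction of
reference candidates spared.  Undefined metrics (zero denominators) are
NaN and excluded pairwise from means and rank tests with a logged count.
Distributions of metrics are compared by the two-sided
Mann–Whitney–Wilcoxon rank-sum test: exact null when the smaller sample has
at most 8 values and no ties occur, otherwise the normal approximation with
midranks and tie correction; two identical pooled samples give p = 1.

## Synthetic cohorts

The generator's defaults are the study conditions the filter targets:
T = 270 (training) or 300 (held-out) volumes at TR = 1.98 s; per-subject
class counts drawn uniformly around 14 RSN-like, 15 motion and 15
high-frequency components (±3), giving ~29–53 components per subject and an
artifact fraction near 2/3.  Motion traces are Gaussian random walks
(increment sd 0.02; translations in mm, rotations scaled ×0.01 in rad) plus
a slow sinusoidal drift (period 200–600 s, amplitude 0.25) plus
Poisson-placed spike transients (0.5 per 100 volumes, amplitude sd 0.3,
~3-volume decay).  Component classes:

* `RSN`: white noise spectrally masked to the open band (0.009, 0.08) Hz —
  the *same* edge rule as the scorer — plus a broadband noise floor
  (`noise_floor = 0.1`), then residualized against the motion design;
* `MOTION_ART`: `alpha_motion` (default 0.95) times a random positive
  combination of the six motion channels plus `1 − alpha_motion` times
  band-limited noise;
* `POWER_ART`: noise masked to f > 0.1 Hz plus the noise floor.

Sub-seeds are `master_seed + i·10007 (mod 2^31)` so extending a cohort
never reshuffles earlier subjects.  Effect sizes are deliberately strong:
trained thresholds separate the classes essentially perfectly, which is the
point — the synthetic cohorts validate the machinery (formulas,
invariances, grid search, end-to-end plumbing), not the filter's accuracy
on real data.  Real decompositions have mixed-cause components,
physiological noise, and raters; none of that is modelled, so the measured
accuracies here say nothing about out-of-sample accuracy on real fMRI.

Spatial-map fixtures live on a 1-D voxel lattice (the group algorithm is
dimension-agnostic): per subject, K Gaussian-blob templates with fixed
evenly-spaced centers plus noise (sd 0.3) represent RSN maps, one
high-amplitude edge-concentrated pattern mimics a brain-boundary motion
artifact, and the remaining maps are pure noise.

## Group stage

Retained maps are row z-scored and concatenated along the component axis
("time" for the second-level decomposition).  The secondary ICA is a
standard FastICA — tanh contrast, symmetric decorrelation — on data
mean-centered and PCA-whitened to the requested order; a probabilistic-ICA
engine is intentionally not re-implemented, because the claim being
exercised is the effect of artifact removal, not the ICA flavor.  FastICA's
fixed-point iteration can settle in local optima, so five restarts with
derived seeds are run and the solution with the largest log-cosh negentropy
objective is kept; results are deterministic under the seed.  Recovered
maps are matched to templates by maximizing summed absolute Pearson
correlation (Hungarian assignment), absorbing sign and permutation
ambiguity.

Model order is pluggable: `fixed`, a broken-stick eigenvalue rule, or the
Laplace (Minka) approximation to the Bayesian evidence of a
probabilistic-PCA model.  The Laplace estimate floors eigenvalues at
`1e-12` of the leading one and restricts candidate orders to the numerical
rank so the noiseless low-rank limit is well defined; it is known to be
unreliable on large noisy concatenations, which is why the demonstrations
fix the order at the planted template count.

## Problem sizes and numerical choices

The acceptance workflow trains on 6 subjects (T = 270), evaluates on a
disjoint 29-subject cohort (T = 300), and runs the group stage on ten
29-subject map cohorts (10 components × 400 voxels each) — sizes chosen to
mirror the training/held-out regime the filter is meant for while keeping a
full run in seconds.  Tolerances: Parseval and whitening identities to
1e-8; invariance checks to 1e-10; exact equality for confusion tallies.
Degenerate inputs (constant components, empty bands, rank-deficient
designs, all-filtered subjects) raise typed errors or flagged results
rather than silent defaults.

## Known limitations

* The two criteria capture only time-course evidence; spatially obvious
  artifacts with clean time courses pass the filter by design.
* The t-based `p_moco` is anti-conservative (see above) and meaningful only
  relative to thresholds trained with the same statistic.
* The KS p-value treats spectral bins as independent observations, which
  they are only approximately; it is a ranking device, not a calibrated
  tail probability.
* The synthetic generator produces single-cause components with strong
  effects; measured accuracies on it are upper bounds of a sanity check,
  not performance claims.
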