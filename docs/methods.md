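# Methods

This note documents the models implemented in `srtpipe`, the parameter
choices that matter, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## SC mapping and stimulus scaling

The visual field maps to SC tissue coordinates (mm) by the log-polar form

    X = 1.1 · ln(√(R² + 1.8 R cosθ + 0.81) / 0.9)
    Y = 1.8 · atan2(R sinθ, R cosθ + 0.9)

with eccentricity R in dva and polar angle θ accepted in degrees and
converted to radians internally. Y uses the two-argument arctangent so
points straddling θ = 90° behave continuously (all stimuli handled here lie
on the horizontal meridian, θ = 0, where X collapses to
1.1 ln((R+0.9)/0.9) and the local magnification is 1.1/(R+0.9) mm/dva).

*Scaled* target diameters are found by exact extent matching: d solves
X(R + d/2) − X(R − d/2) = reference extent, by bracketed root-finding
(Brent, xtol 1e-9) on d ∈ (0, 2R), rather than dividing the reference
extent by the local magnification. The linear approximation agrees to
better than 1e-3 dva for these target sizes, and rounding the exact
solutions to two decimals reproduces the experimental diameter series
0.10/0.13/0.17/0.20/0.24/0.31/0.38 dva at 2–10 dva from the reference
(2 dva, 0.1 dva).

`slope_to_collicular_speed` converts an SRT-eccentricity slope (ms/dva)
into a tissue speed. The conversion convention is genuinely open — local
derivative at a reference point versus fovea-to-target chord, and the
averaging order, give answers from ~10 to ~47 cm/s — so the function
declares its convention in its output. The default is the fovea-to-target
chord (X(R) divided by slope·R, averaged arithmetically over the target
set); a "local" convention (dX/dR divided by the slope) is selectable.
This quantity is reported for interpretation only and is not checked
against any fixed value.

## Contrast conventions

Weber contrast (L−Lb)/Lb and Michelson contrast (L−Lb)/(L+Lb) are plain
arithmetic. "Log units above the background" is implemented as log10 of
the Weber contrast, which reproduces the printed 0.84 for the
243.7/30.7 cd/m² pair; log10 of the luminance ratio (which would give
0.90) is available behind a convention flag.

## Ex-Gaussian distribution and its summaries

SRT distributions are modelled as Gaussian(μ, σ) + Exponential(τ). The
log-density is evaluated with the scaled complementary error function
(`erfcx`) for z ≥ 0 and plain `erfc` for z < 0, keeping both tails finite;
it matches `scipy.stats.exponnorm` to machine precision (exponnorm serves
as the independent oracle in the tests, not as the implementation — the
hand-written density makes tens of thousands of bootstrap refits
affordable).

Fitting is by maximum likelihood (Nelder-Mead on (μ, log σ, log τ)),
initialised from sample moments with a skewness-based τ start floored at
1 ms. Warm starts (used for bootstrap replicates, initialised at the
full-data fit) run with looser stopping tolerances, since the
replicate-to-replicate spread dominates any optimiser noise. The minimum
accepted sample size is 50 trials: the experimental design collects >200
per condition, and 50 keeps small-scale use honest while rejecting
degenerate inputs; zero-variance samples are rejected at the fit level
(so a bootstrap over degenerate data aborts with a diagnostic rather than
returning a width-0 interval).

Mode and FWHM are computed numerically: bounded scalar minimisation of
−log f on [μ, μ+τ] (the mode of this family always lies strictly inside
that interval), then bisection for the two half-maximum crossings with
outward-expanding brackets. Tolerances are 0.02 ms (mode) and 0.05 ms
(FWHM) against dense-grid brute force. In the τ → 0 limit the mode
approaches μ from above at distance ~τ, and FWHM approaches 2.3548 σ.

## Saccade detection and trial inclusion

Velocity is the 5-sample symmetric difference
v_n = (p_{n+2} + p_{n+1} − p_{n−1} − p_{n−2}) / (6Δt) at 500 Hz
(Δt = 2 ms); the two samples at each trace boundary are undefined. The
per-axis threshold is η = λ·√(median(v²) − median(v)²) with λ = 10,
estimated per trial from the trial's full trace (the median estimator is
robust to the saccade samples; the spread equals 0.6745× the Gaussian
noise SD). A saccade is a run of samples with
(v_x/η_x)² + (v_y/η_y)² > 1 sustained for ≥3 samples (6 ms); runs
separated by a single sample are merged first. Onset/offset are the run's
first/last sample; amplitude is the onset→offset displacement. Analysis is
monocular on a designated eye (configurable).

SRT is the onset of the first saccade after fixation-dot offset, minus the
offset time. Inclusion applies, in order: a response saccade exists; SRT ∈
[100, 500) ms; landing error (offset sample to target centre) ≤ 1.0 dva;
and in flash trials the saccade onset must not fall within 100 ms after
flash onset. The first failed rule is recorded as the exclusion reason, so
reasons partition the excluded trials.

## Regression and resampling inference

Each condition contributes one point (its fitted mode or FWHM) to OLS on
the centred predictor (eccentricity − 2): a simple model per scaling group
and an interaction model `y ~ β0 + β1·x + β2·x·isScaled` on both groups
(no main scaling effect — both groups share the identical 2-dva reference
target, so the intercept is common by design). OLS is solved by `lstsq`
and is checked against the normal equations and statsmodels in the tests.
Condition points enter unweighted; per-condition trial counts are balanced
by design.

Permutation p-values shuffle the regressor the coefficient belongs to:
eccentricity labels across points for β1, is_scaled labels within each
eccentricity for β2 (preserving the eccentricity margin). p uses the
add-one estimator (1 + #{|β*| ≥ |β̂|})/(N+1), so p ∈ [1/(N+1), 1]. Note
that with 7 eccentricities the β2 scheme has only 2⁷ distinct label
patterns, so its p-values bottom out near 2/128 rather than 1/(N+1).
Degenerate permuted designs (possible on very small designs) are redrawn.

Bootstrap CIs resample trials with replacement within each condition,
refit the ex-Gaussian per condition (warm-started), recompute the summary,
and refit the regression; the interval is the percentile interval of the
coefficient across replicates (the percentile/basic/BCa choice is not
fixed by the analysis being reproduced; percentile is the default). More
than 5% replicate failures abort with a diagnostic.

The percent-per-dva conversion divides the raw slope by the fitted value
at 2 dva (the model intercept) and multiplies by 100.

Across subjects, inference is a fixed effect: the plain mean of
per-subject coefficients, with its CI formed by averaging the per-subject
bootstrap streams replicate-by-replicate and its p by comparing |mean|
against the averaged per-subject permutation streams. No population-level
random-effects claim is made.

## Point-image activity model

Stimulus discs are projected onto a uniform 1-D SC axis (default spacing
0.005 mm, extending 1.5 mm beyond X(15 dva) so peripheral profile tails
and their half-max crossings stay on the grid). The afferent image is a
unit-height indicator on [X(ecc−d/2), X(ecc+d/2)], rasterized with
fractional cell coverage: the smallest images are only ~8 cells long, and
point sampling would quantize image mass by ±1 cell (~12%), destroying the
equal-peak property the construction exists to demonstrate. Population
activity is the convolution with a unit-mass Gaussian connectivity kernel
(default σ = 0.5 mm, configurable; homogeneous tissue kernels correspond
to receptive fields growing with eccentricity in visual space). The
afferent input is luminance-independent by design; no quantitative
contrast-response function is modelled. Profile summaries are the peak and
the FWHM by linear interpolation between grid samples.

For the scaled-set predictions the *unrounded* extent-matched diameters
are used: the 2-dp rounding of the experimental stimulus table perturbs
image length by up to ~4%, which is a property of the printed table, not
of the constant-point-image construction being illustrated.

## Synthetic data generator

The generator defines the conditions under which the pipeline is
validated. Trial tables follow the task structure: Step (fixation 800–1500
ms, then offset + target onset in one frame) and Delayed (fixation 800–
1000 ms, target on for 800–1500 ms before the fixation-offset Go; 50% of
trials carry a 30 ms foveal flash 100 ms after Go). Targets sit at
{2,3,4,5,6,8,10} dva on the right horizontal meridian, 250
trials/condition by default, Equal (0.1 dva) and Scaled (2-dp table)
diameters.

SRTs are drawn from ex-Gaussians parameterised by target mode and FWHM:
mode = base_mode + slope·(ecc−2) (+ flash delay), fwhm = base_fwhm +
fwhm_slope·(ecc−2), with τ/σ = 0.8 mimicking the right skew of empirical
SRT distributions. Defaults: base mode 160 ms, Equal slope 5 ms/dva,
Scaled slope 0, base FWHM 60 ms, FWHM slope 2 ms/dva — the effect
structure the analysis is designed to detect. The flash adds 30 ms to the
mode (the flash demonstrably delays SRT; no printed value exists, and a
few tens of ms matches the reported distribution shifts). Solving (mode,
FWHM, ratio) → (μ, σ, τ) exploits scale equivariance: at fixed τ/σ both
mode−μ and FWHM are proportional to σ, so one reference evaluation at
σ = 1 suffices.

Gaze traces are built on top at 500 Hz: white Gaussian fixational jitter
(SD 0.05 dva per sample), a minimum-jerk saccade toward a landing point
scattered around the target (SD 0.3 dva per axis), then a stationary hold.
Saccade duration follows a main sequence of 15 ms + 2 ms/dva of amplitude
(19–35 ms over this amplitude range — the fast end of plausible primate
values, chosen so the velocity-threshold detector can resolve onsets of
the smallest targets to within the closure tolerance; the generator's
stated requirement is detection accuracy, not oculomotor realism). The
scheduled onset is snapped to the 2 ms sample grid and the snapped time is
the trace-level ground truth — the sampled eye cannot move between
samples — while the drawn SRT is kept alongside as `scheduled_srt_ms`.

What the generator does *not* emulate: glissades and dynamic overshoot,
drift and smooth pursuit, blinks, binocular disconjugacy, saccadic
inhibition by the flash, and any contrast dependence of SRT. Passing
closure tests therefore shows that the detection and inference machinery
is correct under idealised oculomotor noise, not that it is robust to
every artifact of real recordings.

## Power analysis

The scenario is an ex-Gaussian with mode 200 ms and SD 38 ms, shifted by
10 ms, compared by a two-sided Mann-Whitney U test at α = 0.05. The
mode/SD pair leaves the σ/τ split free; the declared default is σ = 30 ms,
τ = √(38²−30²) ≈ 23.32 ms, with μ solved so the mode is 200 ms (the
target power of 0.80 is likewise a declared default). Power is the
rejection fraction over 2000 simulated pairs per candidate n, scanned over
n = 100…400 in steps of 25; the p-value is the tie-free normal
approximation with continuity correction, vectorized over replicates and
exactly equal to scipy's asymptotic Mann-Whitney p for continuous data. At
these settings the minimal n for 80% power is 225 — consistent with the
design requirement of more than 200 trials per condition. Because the
σ/τ split and target power are assumptions, this reproduction is
assumption-dependent by construction.

## Problem sizes used in the test suite

The acceptance-level tests run the pipeline at sizes chosen to make their
statistical bands reliable: detection closure on ~500 gaze trials plus 100
fixation-only traces; permutation calibration on 600 null datasets of 7
conditions × 60 trials at reduced N_perm = 300 (600 rather than 200
datasets keeps the binomial error small against the [0.03, 0.08]
acceptance band); bootstrap coverage over 50 replicates of 7 conditions ×
80 trials at N_boot = 150. The power criterion runs at its full stated
size (2000 simulations per grid point).

## Known limitations

- A single canonical SC mapping; no inter-individual magnification
  differences, no upper/lower-field asymmetries, no 3-D geometry.
- The activity model is 1-D, binary-input, and stops at activity profiles;
  no activity-to-SRT transfer function is claimed.
- The tissue-speed conversion is convention-dependent and reported as
  such.
- Fixed-effect inference describes the tested subjects only.
- Ex-Gaussian only; no shifted-Wald or lognormal alternatives, no Bayesian
  fitting.
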