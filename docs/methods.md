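# Methods

## Scope and data model

The package analyses epoch-level wrist-actigraphy activity counts (AC;
non-negative integers every 30 s) from two groups of subjects, together with
a covariate table (age, sex, education, binary group status). All rhythm
analyses operate on `ln(AC + 1)` — the natural logarithm throughout — which
symmetrises the count distribution; days are calendar days midnight-to-
midnight in local clock time, and bins are half-open `[start, start + Δ)`
intervals of 30 min (48/day) or 60 min (24/day, the sensitivity resolution).

A subject's **mean profile** is the per-bin average of binned log activity
over valid days; the **SD profile** is the per-bin sample SD (n−1) across
those days, measuring day-to-day irregularity at each clock time. A day is
valid when at most half of its bins are missing (off-wrist); subjects with
fewer than three valid days are flagged and excluded from rhythm analyses.
Both thresholds are configurable; the wear-fraction rule is this package's
own operationalisation of "valid day", since only the three-day rule is
standard. Missing cells are excluded rather than zero-filled (zero-filling
would bias log activity downward).

## Standard metrics

**Cosinor.** Ordinary least squares of the binned log values (all valid
days pooled, time = bin-midpoint clock hour) on
`{1, cos(2πt/24), sin(2πt/24)}`. MESOR is the intercept; amplitude is the
cosine coefficient `A = √(β_c² + β_s²)` — *half* the peak-to-trough
excursion, the standard convention; some reports gloss amplitude as the full
peak-to-trough difference, which is `2A`, so cross-study comparisons should
check the convention. The acrophase is `atan2(β_s, β_c)·24/2π` mapped into
[0, 24) so the fitted curve peaks there; it is reported as undefined (not an
arbitrary angle) when the amplitude is numerically zero.

**Nonparametric.** IS = `[N·Σ_h (x̄_h − x̄)²] / [p·Σ_i (x_i − x̄)²]` over
the valid-day matrix (listwise-complete bins); IV is the normalised mean
squared successive difference, computed within days and pooled by default so
that midnight discontinuities between consecutive days do not count as
fragmentation (the fully concatenated variant is a switch — on a single
contiguous sequence both reduce to the textbook
`[N·Σ(x_i − x_{i−1})²]/[(N−1)·Σ(x_i − x̄)²]`); RA = (M10 − L5)/(M10 + L5)
with M10/L5 the best 10-h/5-h circular window means of the mean profile,
ties broken by earliest clock onset. All three are computed on log-binned
data for consistency with the rest of the pipeline; this differs from parts
of the literature that use raw counts (RA in particular is not invariant to
the transform), and raw-mode is available by passing raw-binned values.

**Sleep.** The scorer marks an epoch wake when a weighted sum of counts in a
symmetric ±2-min window (central weight 1.0, neighbours 0.2) exceeds a
threshold (default 40, a "medium" sensitivity). These weights are a
documented stand-in for proprietary vendor scorers, not a claim of
equivalence — published tables produced by such software are therefore not
bit-reproducible by construction. Within a supplied in-bed interval, sleep
onset is the start of the first ≥10-min run of sleep epochs; SOL, TST, WASO,
SE and average wake bout length follow from the scored epochs, and
`TST + WASO = interval − SOL` holds exactly. Nightly values are averaged per
subject before group comparison.

## Function-on-scalar regression

For outcome profiles `Y_i(t)` (mean or SD profile) and covariates
`x_i = (1, age, sex, education, group)`:

`Y_i(t) = Σ_j x_ij β_j(t) + ε_i(t)`,  `β_j(t) = B(t)ᵀθ_j`,

with `B` eight cubic B-splines on [0, 24] (evenly spaced knots, clamped
ends). Eight basis functions resolve features of roughly 3 h and wider while
keeping the coefficient space small relative to the subjects. The basis is
non-periodic by default — the two ends of the day are not tied together,
which costs some power around midnight; `periodic=True` switches to wrapped
cardinal B-splines (circular difference penalty), and a Fourier family is
available. All non-intercept covariates are mean-centered (sex: 1 = female,
group: 1 = positive), so the intercept function is the sample-average
profile and `β₄(t)` the adjusted positive-minus-negative contrast at clock
time t; centering the binary columns keeps them orthogonal to the intercept,
so smoothing bias of the large mean curve cannot leak into the contrast
functions.

**Estimation** is penalized GLS in three steps:

1. Penalized OLS (working independence) with a second-difference penalty on
   each `θ_j` and a single smoothing parameter λ shared across coefficient
   functions, selected by GCV over a log-spaced grid (1e−2 … 1e8).
2. Residual covariance estimation. The default (`cov_structure="basis"`) is
   structured: an unrestricted K×K covariance `Σ_K` of the residuals'
   basis-coefficient scores, plus an isotropic variance for the off-span
   remainder. The rationale: with T = 48 bins and m = n − q ≈ 54 residual
   functions, inverting a raw (or diagonally shrunk) T×T sample covariance
   is dominated by Marchenko–Pastur sampling noise — its smallest
   eigenvalues are near zero, the GLS weights explode, and (more subtly)
   eigenvector error of the dominant subject-level variance component
   inflates the true variance of the weighted estimator by roughly
   (1 + T/m), which no plug-in standard error can see. Restricting the
   weighting to the K-dimensional span (K = 8 ≪ m) makes the estimate
   well-conditioned and the calibration verifiable. A diagonally shrunk
   full-grid estimate (`"shrunk_diagonal"`, factor 0.1) and `"identity"` are
   retained as options.
3. Penalized GLS with weight `Σ̂⁻¹` (block form: `Σ_K⁻¹` within the span,
   `1/σ̂⊥²` off-span), λ re-selected by weighted GCV.

The coefficient covariance is the robust sandwich
`A⁻¹ [XᵀX ⊗ BᵀW S W B] A⁻¹`, with `S` the raw final-pass residual
covariance, multiplied by the Wishart small-sample factor `m/(m − K − 1)`
(capped at 2) that compensates for plugging in an estimated weight. Under a
null group effect at the study design (n = 59, T = 48), simulation places
the pointwise non-coverage at ≈ 0.04 per bin and the simultaneous
family-wise error at ≈ 0.045 at α = 0.05 (the calibration is re-verified at
500 replicates by the test suite on every run).

**Inference.** Pointwise band: `β̂_j(t) ± z_{1−α/2}·SE_j(t)`. Simultaneous
band: the (1−α) quantile `q*` of `max_t |G(t)|/SE_j(t)` over draws
`G ~ N(0, Ĉov(β̂_j(·)))`, floored at the pointwise z so nesting holds by
construction; seeded, hence reproducible. Global test per covariate:
`F = [(RSS_reduced − RSS_full)/Δedf] / [RSS_full/(nT − edf_full)]` with RSS
summed over the grid, and a permutation p-value from shuffling that
covariate's column (λ and the GLS weight held at their observed values
during permutation); the permutation reference avoids leaning on an
asymptotic F distribution whose behaviour in small functional samples is
poorly established. Windows are maximal runs of bins whose band excludes
zero, merged across the midnight wrap, reported as `[bin start, bin end]`
clock times with the effect sign.

The SD-profile analysis runs through the identical engine with
`Y = sd_profile`.

## Synthetic cohort generator

The generator emulates the screening-cohort design the package targets: 26
positive and 33 negative subjects, 2–6 days each (weights 0.02/0.02/0.04/
0.12/0.80, mean ≈ 5.7 days of a mostly complete week), 30-s epochs. Counts
arise from a Gaussian latent log-process

`x = μ(t − J_d) + b_i + δ(t)·1[pos] + ε`,  `AC = max(0, round(eˣ − 1))`,

with μ a cosinor baseline (MESOR 3.2, amplitude 2.3 log counts, acrophase
14.7 h, one second-order harmonic of 0.35 — values chosen to mimic typical
older-adult log-activity profiles), subject intercepts `b_i ~ N(0, 0.3²)`,
day-level phase jitter `J_d ~ N(0, 0.5² h²)` applied to the baseline only
(the group effect δ stays anchored to clock time, so the group contrast at
clock time t is exactly δ(t)), and epoch noise ε with SD 0.6, multiplied
inside configurable clock windows for the positive group. Default effects
mirror the time-localised pattern the method targets: Gaussian mean bumps
(SD 1.5 h) of −0.5 log units at 01:15 and +0.5 at 06:30 and 15:00, and
across-day SD multipliers ×1.5 in 21:30–01:00 and 04:30–08:30 and ×0.6 in
02:30–03:30.

Ground truth (μ, δ, σ per group on the bin grid) is returned with the data,
so bin-averaging noiseless draws reproduces the latent curves up to count
discretisation (exact against the discretised oracle; within 0.2 log units
of μ at the trough where counts are ~1–2), and stochastic draws match to
Monte-Carlo error.

What the generator does *not* emulate: device-specific count noise (the
latent-Gaussian construction is an analysis-scale stand-in, not an
accelerometer model), realistic rhythm fragmentation (simulated IS ≈ 0.98
and IV ≈ 0.02 are far smoother than the ≈ 0.75 / 0.4 typical of real older
adults, because the only within-day noise is epoch-level and averages out in
30-min bins), naps, off-wrist gaps (off-wrist flags are supported but not
generated), or realistic sleep architecture (the simulated nights are too
efficient). Consequently, passing tests demonstrate correctness of the
estimators and calibration of the inference under a plausible signal
structure — not that real recordings are this easy. One designed property
worth noting: the phase-jitter component of the across-day SD is common to
both groups and is largest where the profile is steep (morning/evening), so
it dilutes the windowed SD multipliers there; sign recovery of the SD
effects at the default design is therefore reliable on average but not in
every replicate, unlike the mean-bump localisation which is near-certain.

## Numerical and interface choices

- Penalized normal equations are solved by Cholesky factorisation of
  `XᵀX ⊗ BᵀWB + λ(I ⊗ P)` (size qK = 40 by default); singularity raises an
  error carrying the condition number.
- Zero-amplitude cosinor fits and zero-variance IS/IV inputs return missing
  values with warnings rather than arbitrary numbers; IS is clipped to
  [0, 1] only for floating error ≤ 1e−12.
- Acrophases and window bounds format as `HH:MM`, rounding to the nearest
  minute and wrapping at midnight.
- The t-test defaults to pooled variance (Welch optional); the Fisher exact
  p-value uses the minimum-likelihood two-sided convention; no
  multiple-testing adjustment is applied across the scalar outcomes, and the
  window reports carry no multiplicity control beyond the simultaneous band
  itself.
- Pipeline outputs are written with fixed float formatting and seeded
  randomness only, so identical configuration + seed reproduces every file
  byte-for-byte.
- Problem sizes in the validation suite: coverage at 500 null replicates of
  the full study size (59 × 48, 800 max-statistic draws per band), recovery
  at 100 replicates of the default cohort, oracle equivalence at 20 random
  instances; the acceptance script uses 10 000 band draws and 1999
  permutations.

## Known limitations

- Non-periodic default basis loses power at the midnight seam (periodic mode
  provided).
- The global F-test pools the whole day and is insensitive to effects
  confined to a few hours — exactly the situation the bands are for.
- The sleep scorer is a stand-in; its absolute parameter values should not
  be compared against vendor-scored datasets without recalibration.
- With fewer than ~15 subjects per group the within-span covariance estimate
  (m ≈ n − 5 samples of an 8-vector) becomes noisy; the df-correction keeps
  intervals honest but wide.
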