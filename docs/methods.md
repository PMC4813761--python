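# Methods

This note documents the models implemented in `countermand`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data do and do not establish about real recordings.

## The race model and the task

Behavior on each trial is an independent horse race. The go process
finishes at an ex-Gaussian time `T = N(μ, σ²) + Exp(τ)` (defaults
μ = 0.35 s, σ = 0.05 s, τ = 0.15 s, giving a median go RT near 0.46 s and
mean 0.50 s, in the range of published stop-signal work). On signal
trials a stop process of duration SSRT (default 0.20 s, constant across
trials by default) starts at the SOA; stopping succeeds iff
`T > SOA + SSRT`. With a constant stop duration the inhibition function
in RT-corrected coordinates has its midpoint exactly at the stop
duration, which is what makes the psychometric estimator interpretable.
Optional Gaussian trial-to-trial jitter of the stop duration
(`ssrt_sd`) is available for robustness studies. In change mode the
winning stop is followed by a press of the opposite button
`change_extra` (default 0.25 s) after the stop process finishes, so
successful change trials have an RT while successful stop trials do not.

The SOA staircase uses two independent threads starting at 0 and 0.300 s,
moving ±0.050 s (up after success, down after failure, floored at 0); a
signal trial samples one thread uniformly and updates only it. Upward RT
drift ("waiting" for the signal) is linear in trial index
(`drift_slope`). Sessions default to two blocks of 78 trials (~155
presented trials, ~4 minutes per block at ~3 s per trial), with signal
probability 0.5 applied exactly per block. The contextual-complexity
manipulation adds `complexity_effect` (default 0.03 s) to μ in the two
complex task variants (arrow/stop and bar/change), where the correct
action requires combining two cue elements instead of one.

Lapses (`lapse_prob`) become unclassifiable errors (wrong-direction or
double presses); on signal trials the staircase treats them as failures,
since a press occurred.

## SSRT estimators and their biases

* **Average-difference**: `mean(go RT) − mean(SOA)` over all presented
  signal trials. Under tracking the mean SOA settles near
  `median(T) − SSRT`, so this estimator carries a structural bias of
  roughly `mean(T) − median(T)` minus the staircase's equilibrium
  overshoot. For the default ex-Gaussian (mean−median ≈ 0.044 s,
  overshoot ≈ 0.013 s) it overestimates by ≈ 0.03 s. This is a property
  of the method, not a defect of the implementation; the test suite pins
  it down quantitatively.
* **Integration**: the `p`-th quantile of the sorted go RTs
  (1-based index `ceil(p·n)`) minus the mean SOA, with `p` the fail
  fraction. Near-unbiased under tracking (the two staircase-related
  biases cancel to first order); recovery within ±0.02 s at 2,000 signal
  trials.
* **Inhibition-function midpoint**: Bernoulli regression of success on
  `z = predicted go RT − SOA` with a lapse-logistic
  `λ/2 + (1−λ)σ(β(z−α))`. Priors: `α ~ N(SSRTav, 0.05 s)`, log-uniform β
  on [1, 500] s⁻¹, `λ ~ Beta(1, 19)` truncated at 0.1. Four random-walk
  Metropolis chains of 5,000 iterations, first half discarded; split-R̂
  on α above 1.1 flags non-convergence without raising. Posterior means
  are reported.

**Drift model.** The predicted go RT is a cubic regression spline of
go-only RT on trial index with interior knots every ~75 go trials, kept
only when BIC prefers it to a straight line (always available as the
fallback below 30 points), plus the *median* of the fit residuals. Two
deliberate choices: (i) the small knot budget — a generalized
cross-validated smoothing spline undersmooths badly under skewed,
heavy-tailed RT noise (on drift-free sessions its fitted curve wanders
with SD ≈ 0.07 s, which leaks into the corrected SOA and inflates the
psychometric deviance several-fold); (ii) the median offset — session
summaries are medians, and predicting the running median makes the
inhibition-function midpoint equal the true stop duration exactly when
the stop duration is constant. A mean-RT correction would inherit the
full ex-Gaussian skew bias.

**Deviance.** Goodness of fit is the binned binomial deviance
`2(LL_saturated − LL_model)` over quantile bins of `z` (sparse bins
merged, ≥5 trials each). The bin count scales with the number of signal
trials (~12 per bin, between 4 and 10 bins): with that granularity a
correctly specified fit has expected deviance of a few (χ² with a handful
of degrees of freedom), which is the scale on which the published
exclusion threshold of 7.5 operates (printed session deviances 0.6–7.9,
one rejection). A fixed decile binning would put even perfect fits above
the threshold in roughly a third of ~80-trial sessions.

**Screening.** Sessions are excluded if the median success SOA exceeds
the median fail SOA (race-model ordering), if the fail fraction is below
0.28, or — only when both behavioral rules pass, since rejected sessions
never get a psychometric fit — if the deviance exceeds 7.5.

## Source simulation and forward model

Each source is 1/f-amplitude background noise (flat below 1 Hz, unit
RMS) plus unit-RMS band-limited carriers multiplied by event-locked
Hanning envelopes: a theta/alpha (2–12 Hz) burst of 0.4 s at the
stop/change signal; gamma (55–75 Hz) sustained over the trial (1.6 s from
fixation onset — short enough to keep inter-trial dips, otherwise the
effect would be a block-wide DC offset that the 0.25 Hz high-pass removes
by construction) with amplitude proportional to the variant's complexity
level; post-signal beta (15–25 Hz) whose amplitude depends on
success × response mode; and a press-locked envelope dip of the ongoing
beta rhythm at the motor source. Because carriers have unit RMS, the
injected amplitudes are directly the expected band-RMS increments (in
quadrature with the background), which the tests exploit as an oracle.

The forward model is the analytic current-dipole solution for a
homogeneous conducting sphere, sampled by radial magnetometers; radial
dipoles are silent and the radial field equals the primary-dipole
Biot–Savart term, which the tests use as an independent oracle. This is a
deliberate simplification of realistic single-shell head models: no BEM,
no head movement, no physiological artifacts.

## Beamformer, spectral, and deconvolution stages

The LCMV filter `w = C⁻¹l/(lᵀC⁻¹l)` uses the sample covariance of an
entire block plus a ridge of 0.01% of its mean diagonal; filters are per
block and never shared. The max-power orientation is the minimum
eigenvector of `LᵀC⁻¹L`, restricted to the numerically non-silent column
space of `L` (the sphere model leaves a silent radial direction that
would otherwise win spuriously; rank < 2 raises). Filter similarity
(squared Pearson correlation of raw weight vectors) is reported as the
separability diagnostic. Standardization uses segment-median moments
(10 s segments); for Gaussian input the median-of-squares underestimates
the variance by the median-of-χ²₁ factor (≈0.455), so standardized
series have second moment ≈ 2.2 rather than 1 — a consistent scale is
all downstream stages need, and the medians buy insensitivity to brief
artifacts.

Multitaper analysis uses unit-energy DPSS tapers in 0.4 s windows
stepped by 0.05 s, half-bandwidth 2.5 Hz up to 25 Hz, 0.1·f between 25
and 50 Hz, 5 Hz above, with `K = max(1, ⌊2TW⌋ − 1)` tapers; windows are
computed only where they fit entirely inside the block, and the square
root of power (RMS amplitude) is returned so that responses combine
approximately linearly.

The convolution GLM convolves per-event-type impulse trains (snapped to
the 0.05 s grid) with a Fourier basis over −0.5…+1.5 s. The basis
harmonics take the 41-point grid as one full period, making the columns
exactly orthogonal; default order is 11 for standalone use (23 columns)
and 6 in the end-to-end study driver (13 columns, enough for the smooth
injected envelopes at a third of the cost). Parametric modulators (the
predicted go RT on go events) are mean-centered within event type.
"Filtering below 0.25 Hz" is implemented as projection onto the
complement of a DCT subspace, applied identically to data and design —
the reading that removes time-on-task drifts. Rank-deficient designs
fall back to the minimum-norm solution with a warning. OLS is
mass-univariate across frequencies; no autocorrelation correction is
attempted (a known limitation: standard errors of single-subject
coefficients are optimistic, which is why inference happens at the group
level).

## Group inference

Per-subject condition images are combined with contrast weights
(complexity = the stimulus × response interaction, weights +1/−1/−1/+1);
the group test is a one-sample t image thresholded at the 1−α quantile
of the max-|t| distribution over random per-subject sign flips
(two-tailed, default 2,000 flips, α = 0.05). This replaces
random-field-theory FWE with non-sphericity correction: the sign-flip
test is exact under per-subject sign symmetry at small n and assumes no
smoothness. Band courses average the response over 2–12 Hz (theta/alpha)
or 15–25 Hz (beta); the peak rate of rise is the maximum centered first
difference in −0.2…0.5 s, computed after averaging the successful and
unsuccessful courses. The source × SSRT-group analysis permutes group
labels across sessions (sessions grouped short/long relative to the mean
SSRT) and runs post hoc per-source contrasts only when the interaction is
significant.

## The end-to-end study driver

`StudyConfig` defaults define the synthetic study: 8 subjects × 4 task
variants × 100 trials (the real design had 8 analyzable subjects and
~155 presented trials per variant; trials are scaled to one third with
the injected effects kept at amplitudes a clean MEG study would show),
28 sensors at 160 Hz, three sources (theta burst amplitude 1.2/1.0 at
the two frontal sources, gamma 0.4 per complexity level at the medial
source only, background RMS 1, sensor noise SD 1), and ten analyzed
frequencies covering the theta/alpha, beta, a mid control, and gamma
ranges. The complexity contrast is evaluated on the trial-onset-locked
reconstruction because the injected gamma is a "set" effect that begins
at trial onset. With these defaults the pipeline localizes the gamma
effect to its injected source and the theta/alpha burst to its two
sources (and not to the control source) in 20/20 seeded replicates while
keeping the whole suite within a desk-scale compute budget.

## What passing tests do and do not show

The generator emulates the statistical structure the analyses rely on —
event-locked band-limited amplitude changes, linear instantaneous mixing,
stationary backgrounds — but not volume-conduction realism, artifacts,
inter-subject anatomical variability, or non-stationary noise. Passing
the suite demonstrates that each stage recovers what it is designed to
recover under its own assumptions and that the pipeline's inferences are
calibrated (FWE within its binomial band, permutation p-values uniform
under the null); it does not validate the assumptions themselves on real
recordings. The printed-table recomputation checks transcription and the
screening/summary logic against published numbers, not the MEG stages.

## Known limitations

* The mean (average-difference) SSRT method is structurally biased
  upward under skewed go RT distributions (≈ +0.03 s at the defaults);
  it is reported because it is standard, and its mean with the
  integration estimate (SSRTav) cancels most of the bias.
* The spherical forward model makes source depth and orientation only
  qualitatively realistic.
* Single-subject GLM errors ignore temporal autocorrelation of RMS
  amplitude.
* Block-mean amplitude differences between conditions are invisible by
  construction (high-pass); only trial-locked modulation is analyzed.
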