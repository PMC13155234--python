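# Methods

This note records what the package computes, the conventions and defaults it
adopts where the field leaves room, and what its synthetic data can and
cannot establish.

## Outcome measures

### Percent coefficient of variation

For a stride-parameter sequence (stride time in s, stride length in m),
%CV = (sample SD / sample mean) × 100 with the n−1 denominator. The bilateral
value is, by default, the arithmetic mean of the two per-leg %CVs
(`mode="mean"`). Because per-leg summary exports sometimes provide SDs and
means rather than raw strides, an alternate order — mean of per-leg SDs over
mean of per-leg means, ×100 (`mode="pooled"`) — is selectable; the two differ
only through between-leg mean asymmetry and agree to within a few percent on
realistic data. Both are tested. %CV requires n ≥ 2 strides and a positive
mean, is non-negative, scale-invariant, and ignores stride order.

### Short-term local divergence exponent

The estimator is the divergence-curve (Rosenstein-style) route used
throughout trunk-accelerometry work on local dynamic stability:

1. **Segmentation** — stride starts from dominant peaks of the band-passed
   vertical lumbar acceleration (2nd-order Butterworth band-pass,
   0.3–5 × the expected stride frequency, zero-phase; minimum peak distance
   0.6 expected stride times; peak prominence at least half the filtered
   signal's SD). Detection is vertical-axis by default with an
   anterior-posterior fallback, because vertical lumbar acceleration carries
   the most reliable stride periodicity in level walking.
2. **Bouts** — non-overlapping runs of 8 consecutive strides, 11 per trial
   by default, assigned earliest-first. Taking bouts from the start of the
   trial is a determinism choice; placement elsewhere in a stationary trial
   is statistically equivalent.
3. **Time normalization** — each stride is linearly resampled to 100
   samples; a bout is then an 800 × 3 record in normalized time. Each
   stride's grid starts exactly at its start event and excludes the end
   event (which begins the next stride), so strides tile normalized time
   without duplicated boundary samples. Normalizing per stride removes
   stride-duration variance from the state space; duration variability
   re-enters the analysis only through the %CV measures, which is the
   intended division of labor between the two outcome families.
4. **Embedding** — state m = [v(m), v(m+τ), v(m+2τ), ap(m), …, ml(m+2τ)]
   with τ = 25 samples (¼ gait cycle) and 3 copies per axis: a 9-D space,
   750 states per bout.
5. **Divergence** — for each state, the nearest Euclidean neighbor outside a
   Theiler window of 100 samples (one mean period — the standard mean-period
   exclusion rule; the convention in this literature varies and the window
   is configurable). The curve value at offset k is the mean of
   ln ‖x(i+k) − x(j+k)‖ over all pairs still inside the record. Distances
   are taken in the raw 9-D space without per-channel normalization
   (a flag enables it); natural logarithms throughout.
6. **Fit** — ordinary least squares on the mean curve over 0–50 normalized
   samples (half a stride), rescaled ×100 to nats/stride. The half-stride
   window is the dominant short-term convention for trunk acceleration; a
   full-stride window is available. Divergence curves are averaged pointwise
   across bouts before a single fit (per-bout-fit-then-average is an
   option); curve averaging is the established multi-bout convention and is
   less noisy. Per-bout slopes are always retained.

Numerical details: exactly coincident states are floored at 1e-12 before the
log; an all-identical state space raises a degenerate-input error rather
than propagating −inf; nearest-neighbor ties break to the smallest index.
The neighbor search uses exhaustive O(M²) distances for bout-sized spaces
(M ≤ 2000, faster in practice) and a k-d tree for long reference
trajectories; the two are asserted equal index-for-index in the tests.

λs is reported in nats/stride because normalized time makes seconds
inappropriate for gait. For physically sampled signals (the Lorenz
reference), the same machinery reports nats/s by rescaling with the sample
rate.

### Estimator validation

Two independent routes must agree. `gaitdyn.lyapunov.benettin_lle`
integrates a known ODE together with its exact tangent dynamics (fixed-step
RK4, dt = 0.005 s, 10 s transient, 500 s averaging window), renormalizing
the tangent vector each step — a from-scratch largest-Lyapunov computation
that never touches reconstructed state spaces. The divergence-curve route
is then run on a 300 s, 100 Hz Lorenz trajectory (σ = 10, ρ = 28, β = 8/3;
internal RK4 step half the sample interval) embedded with τ = 15 samples.
For this reference the fit skips the first 75 samples (one mean orbital
period, ~0.75 s) — the initial segment of a divergence curve reflects
neighbor alignment onto the unstable direction, not the exponent — and ends
at 2.5 s, well before the curve saturates at the attractor diameter. The
acceptance checks require agreement within ±20%; the harmonic-oscillator
tangent computation and phase-shifted sinusoids pin the zero-exponent limit,
and a noise-free periodic gait signal must yield |λs| ≤ 0.05 nats/stride.

## Inference layer

Balanced two-factor mixed (split-plot) ANOVA: one between-subjects factor
(age group, 2 levels) and one within-subjects factor (walking condition,
3 levels). Subjects nested in groups form the between-subjects error
stratum; the subject × condition residual forms the within error stratum.
Unbalanced input is an explicit error — the target design is balanced
(25/25), where the classical SS decomposition is unambiguous.

Sphericity: Mauchly's test on the pooled within-group covariance of the
condition vectors (group-centered before pooling — the split-plot
convention; some packages pool without centering, which inflates apparent
nonsphericity when group profiles differ). Greenhouse-Geisser ε comes from
the same matrix via orthonormal (Helmert) contrasts and lies in
[1/(k−1), 1]. The correction is applied to within effects only when Mauchly
rejects at 0.05 (`gg_policy="auto"`), with force-on/off flags; conditional
application mirrors common reporting practice in this literature.

Partial η² is computed both as SS_effect/(SS_effect + SS_error) and as
F·df₁/(F·df₁ + df₂); the two are asserted equal to 12 decimals on every
fitted table, and the second form is invariant to Greenhouse-Geisser df
rescaling. Size classes: < 0.01 negligible, ≥ 0.01 small, ≥ 0.06 medium,
≥ 0.14 large (half-open from above).

Post hocs: the three condition pairs are paired t-tests pooled across
groups, Holm-adjusted as a family of 3; group-specific condition families
are available behind a flag since study figures often annotate per-group
differences. Simple main effects are per-condition two-sample t-tests
(pooled-variance, balanced), Holm family of 3. All tests two-sided,
α = 0.05.

Post-hoc power uses the noncentral F distribution with Cohen's
f = √(η²/(1−η²)) and the repeated-measures noncentrality
λ = f²·N·m/(1−ρ), the G*Power convention for within/interaction effects.
The repeated-measures correlation ρ is an assumption (default 0.5), not an
estimate; power statements are therefore assumption-dependent, which is why
the package treats them as descriptive rather than as exact targets.

## Synthetic data

### Cohort level

`CohortSpec` fixes the study design: 25 participants per group, three
conditions, fully repeated measures. Because the emulated study reports
inferential statistics but not per-cell means, the default cell targets are
anchored to its *ordering pattern*, not to printed magnitudes:

| measure | young (OG, TM, VC) | older (OG, TM, VC) |
|---|---|---|
| stride-time %CV | 2.30, 2.40, 3.80 | 2.30, 3.40, 5.00 |
| stride-length %CV | 2.20, 2.10, 3.20 | 2.20, 3.00, 4.20 |
| λs (nats/stride) | 0.48, 0.42, 0.55 | 0.54, 0.52, 0.65 |

i.e. CV equal between groups overground and elevated in older adults on the
treadmill; both groups highest under visual cues; λs higher in older adults
everywhere, lowest for young adults on the plain treadmill. Magnitudes are
realistic for healthy adults (stride-time CV of 2–5%, short-term trunk λs
of 0.4–0.7 per stride with a half-stride fit).

Participant heterogeneity uses random intercepts shared across conditions
(SD 0.45 %CV-points; 0.035 nats/stride) plus condition-specific residuals
(0.30; 0.020), giving the positive within-subject correlation a repeated-
measures design needs, and compound-symmetric (spherical) covariance under
the null. Participant stride-time/length means are drawn once per
participant (between-SD 0.07 s, 0.10 m around group means of 1.05/1.10 s
and 1.35/1.22 m); within a trial, strides are i.i.d. normal with the SD
implied by the cell's %CV target (an AR(1) option exists but is off by
default — only CV-level statistics are being emulated, and no
autocorrelation structure is claimed).

The %CV measures of a simulated cohort are *measured* — 80 strides per leg
are generated and passed through the same bilateral %CV estimator real data
would use — while λs is drawn at measurement level from its cell
distribution. Driving per-participant λs through full signal synthesis
would require inverting the noise→exponent map per participant; the
measurement-level draw keeps the cohort's covariance structure explicit,
and the signal-level estimator is exercised separately (validation,
monotonicity, and bout-robustness analyses).

### Signal level

A stride is a fixed tri-axial harmonic waveform (documented coefficients in
`gaitdyn.synthetic._WAVEFORM`, amplitudes of ~0.1–1.2 m/s² over three
harmonics of the stride cycle) warped to the stride's duration, scaled by a
per-stride amplitude factor with a specified CV, plus white sensor noise.
The vertical axis is a pure cosine series, so its maximum falls exactly on
the stride-start event — ground truth and the peak detector's target
coincide by construction. Named noise levels scale amplitude CV, sensor
noise, and stride-time CV together: low (0.02, 0.02 m/s², 1%), medium
(0.06, 0.06, 3%), high (0.12, 0.12, 5%), bracketing healthy stride-to-stride
variation.

What this emulates — stride periodicity, stride-to-stride amplitude and
timing variability, sensor noise, exact event ground truth. What it does
not — turning strides (the overground walkway's turns are out of scope;
synthetic walking is straight), drift and nonstationarity, asymmetric or
pathological waveforms, soft-tissue artifact, and any true neuromotor
dynamics: the "instability" injected is stochastic, not deterministic
chaos. Passing tests therefore show the estimator pipeline is correct and
monotone in injected noise, not that it measures fall risk.

## Problem sizes

Simulation-based checks are sized to run comfortably on one core: null
calibration uses 500 replicates at 10 participants/group; noise
monotonicity 20 paired replicates of 92-stride trials; bout robustness 20
replicates of 16 participants at 135 strides (enough for 15 bouts); power
recovery 200 replicates at the full 25/group. The full-size cohort (25 per
group, 80 strides per leg) is used wherever a single run suffices.

## Known limitations

- The default synthetic cohort is cleaner than real data — condition
  residuals are small relative to the planted effects — so its F statistics
  run larger than published ones. Comparisons against the emulated study
  are significance-pattern-level by design; exact F values would require
  the original per-participant table, which the ingest path accepts when
  available.
- The 11-vs-15-bout comparison on an unbiased estimator is a null paired
  t-test: its Cohen's d scatters as t(15)/4 across 16-participant
  replicates, so individual replicates show |d| ≥ 0.3 about a quarter of
  the time even though the pooled difference is zero. The analysis script
  reports the pooled and per-replicate views.
- Greenhouse-Geisser ε conventions differ across packages (group-centered
  vs uncentered pooling); this package's choice matches the split-plot
  textbook treatment and is pinned by an exact spherical-covariance
  construction in the tests.
- Shoe-size → foot-dimension mapping for cue targets is a nominal default
  (0.26 × 0.10 m with a 20% margin), not a sizing table.
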