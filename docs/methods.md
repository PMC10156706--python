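# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Behavioral model and saccade processing

Eye position is sampled at 1 kHz in degrees.  Velocity is obtained by
central differencing followed by a 5-ms boxcar; saccades are maximal
intervals with |velocity| ≥ 30 deg/s (sub-threshold gaps shorter than
20 ms merged, intervals under 10 ms discarded), and primary saccades are
those with 13–17 deg amplitude.  Peak velocity (PV) is the maximum
absolute velocity on the interval, duration the interval length, and
amplitude the position change across it.  Endpoint errors are the
target-minus-eye residual on the horizontal axis: undershoots produce
outward errors (pointing along the movement), overshoots inward errors;
residuals below 0.25 deg are labeled "none".  The early/late fatigue
comparison applies two-sided Wilcoxon signed-rank tests to the first and
last 30 trials, paired by rank order within each block (the pairing is a
package choice; the blocks have no natural correspondence).  Zero
differences are dropped (Wilcoxon convention) and an all-zero sample
reports p = 1.

## Unit classification

MF classification uses unsmoothed trial-averaged rates on a
[−450, +500] ms grid (1-ms bins, saccade-onset aligned; the grid is wider
than the analysis window so the [−400, −200] ms baseline and the
post-saccadic [+200, +400] ms-from-offset baseline fit).  Burst-tonic:
post-saccadic ([150, 250] ms) minus pre-saccadic ([−250, −150] ms) mean
rate exceeding 1.5× the pre-saccadic SD, with statistically
indistinguishable pre/post regression slopes (implemented as overlapping
95% CIs — the underlying test is not otherwise specified).  Otherwise the
modulation onset is the first crossing of baseline mean + 3 SD; a lead
over 15 ms gives long-lead burst, 0–15 ms short-lead burst, and
post-onset or absent bursts are unclassified.  Threshold crossings must
persist for 3 consecutive 1-ms bins: with Poisson spiking at
desk-scale trial counts, single-bin crossings of 3 SD occur by chance in a
200-ms search window often enough to corrupt onset estimates.

PC simple-spike responses are Gaussian-smoothed (SD 5 ms) spike-density
functions.  Threshold labels come from local extrema in the peri-saccadic
window (−50 to +150 ms from saccade end) with minimum peak distance 10 ms
and minimum topographic prominence 2 spikes/s, significant beyond ±5 SD
of the [−250, −100] ms baseline; monophasic/biphasic polarity sequences
map to burst / pause / burst-pause / pause-burst.  Peak finding is
implemented directly (topographic prominence; ties broken toward higher
extrema) so its semantics are exactly those stated.  A PCA(2) + LDA
classifier trained on the threshold labels assigns every response
(including threshold-unlabeled ones) a category; PCA component signs are
fixed by making the largest-|loading| coordinate positive.

## Rate models and pseudo-populations

For each unit, per-trial rates (baseline-subtracted by the trial's
[−250, −100] ms pre-saccadic mean) are regressed, independently per 1-ms
time bin, on kinematic deviations δz = z − z̄ (PV and/or duration, raw
physical units, so the derivatives have interpretable units of
spikes/s per deg/s or per ms).  The intercept is the
kinematics-independent component R0(t) and the coefficients the
kinematic derivatives ∂R/∂z(t).  No temporal smoothing couples the
per-bin fits; per-trial rates are smoothed (SD 5 ms) before fitting.
With z = [PV, duration] the velocity–duration tradeoff makes the design
nearly collinear; the fit warns on condition numbers above 1e4 and
refuses above 1e10.  Pseudo-populations evaluate all fitted units at a
common kinematic grid (each unit's deviation taken from its own session
mean), either with duration co-varying along the empirical
duration-on-PV regression (correlated variation) or with one parameter
clamped (isolated variation).

## Manifolds and perturbation theory

The manifold is the rank-K factorization R0 ≈ W P_K from an uncentered
PCA (SVD) across units — uncentered so the factorization holds exactly
as written and the second-moment matrix C = R0 R0ᵀ/T is the object the
perturbation theory differentiates.  K is the smallest dimensionality
with cumulative explained variance above 0.85, cross-checked by a
held-out-unit reconstruction curve (units split into ~N/10 folds;
held-out rates regressed onto the retained units' latents).

A kinematic perturbation R0 → R0 + δz D changes C to first order by
dC = (D R0ᵀ + R0 Dᵀ)/T.  The loading derivatives follow standard
eigenvector perturbation, mixing only non-retained components into the
retained ones (the within-subspace rotation is unidentifiable after
alignment): dW_k = Σ_{j>K} v_j (v_jᵀ dC w_k)/(λ_k − λ_j), with
denominators regularized when gaps fall below 1e−6 λ₁.  The latent
derivative is ∂z P_K = Wᵀ D + dWᵀ (R0 − W P_K).  A finite-difference
alternative (symmetric PCA re-fits at ±h, Procrustes-aligned to the base)
is selectable and agrees with the analytic route to first order; tests
verify both the agreement and the O(δz²) convergence against a
brute-force PCA re-fit oracle.

Geometry statistics operate on the first two latent dimensions over the
[−250, +400) ms analysis window.  Size is the shoelace area of the closed
trajectory (triangles against the origin).  The rotation phase is the
quadrant-aware unwrapped angle about the reference point (max(x)/2, 0),
shifted to start near −180°; the trajectory is first oriented so its
dominant excursion points along +x (latent signs are arbitrary, and the
reference construction assumes the loop sweeps positive x), and clockwise
loops are mirrored.  T_3/4 is the interpolated first crossing of +90° and
the speed 270°/T_3/4; trajectories that never complete three quarter
turns return NaN.  Phase-based statistics are computed on a trajectory
smoothed with a 15-ms Gaussian: the phase is hypersensitive to
high-frequency noise when the loop passes near the reference point.
Slope angles divide sizes and speeds by the control condition's SDs
before a least-squares line; degenerate cases map to 0° (constant
speeds) and 90° (constant sizes).  Canonical correlations between latent
trajectory sets are computed classically (QR + SVD), making the
comparison invariant to invertible linear maps of either set.

## Complex-spike conditioned analysis

CS-ON directions are the error direction with the larger mean CS count
in the [50, 140) ms post-saccadic window (≥10 error trials per direction
required; ties unresolved).  CS windows are half-open, so a CS at exactly
140 ms belongs to the late [140, 250) window.  Simulated error pooling
takes, per unit, its CS trials when its CS-ON direction matches the
simulated error vector and its no-CS trials otherwise; the trials
*following* the pooled trials (next same-type trial) feed per-unit
rate-model re-fits (PV as the kinematic parameter, ≥30 trials per pool),
a per-condition manifold, size/speed curves over a common PV grid
(10th–90th percentile, 5 points), and slope angles normalized by the
no-CS condition's SDs.  Conditions are compared by one-sided Student's t
tests on leave-one-unit-out jackknife angle distributions.  Velocity
changes from CS to post-CS trials are time-resolved paired differences of
onset-aligned velocity profiles with pointwise t tests plus summary PV
and duration changes.

## Feed-forward network

The MF→PC weight matrix minimizes
E(T) = ‖Y − TX‖² + Σ_zz' Cov[z,z'] (∂zY − T∂zX)·(∂z'Y − T∂z'X), where
Cov is the empirical trial-kinematics covariance (the kinematic deviation
is treated as Gaussian).  Factoring Cov by its symmetric square root
turns this into ordinary least squares on the column-augmented design
[X | Σ_z M_kz ∂zX]; the L1-penalized variant is solved per output unit
(the objective separates) with the penalty chosen by AIC, either along
the LARS path or over an explicit grid (degrees of freedom = nonzero
coefficients).  Manifold-limited prediction reconstructs the inputs from
the top-d_MF MF principal components, pushes them through the fitted
weights, fits a PC manifold to the prediction and scores its first two
latent trajectories against the data-derived PC manifold after
orthogonal Procrustes alignment with scaling (PCA sign/rotation/scale
indeterminacy).  The communication subspace truncates the unconstrained
solution to rank r by projecting the fitted outputs onto their top-r
principal subspace (standard reduced-rank regression in the output
metric).  Population variance spectra report PCA variance fractions and
the power-law exponent from a log-log fit over a stated dimension range.

## Statistics

Across-unit means and SEMs use the leave-one-unit-out jackknife (standard
bias-corrected formulas; for a linear statistic the SEM equals s/√N
exactly).  Goodness-of-fit scores over time points use a 500-repetition
bootstrap.  Wilcoxon signed-rank tests use the exact null for ≤25 untied
pairs and the tie-corrected normal approximation above.

## Synthetic sessions: what they emulate

The generator draws, per trial, a latent PV following a monotone
second-order polynomial drift (defaults 500 → 450 deg/s, matching the
~10% fatigue decline) with i.i.d. log-normal noise (CV 0.05); duration
follows the velocity–duration tradeoff duration =
amplitude/(0.62·PV)·(PV₀/PV)^0.25, slightly over-compensating so slow
saccades lengthen ~12–15% and skew, as observed.  Endpoint noise
(SD 0.75 deg, ≥95% of amplitudes within ±2 deg of the 15-deg target) is
realized as a gain error on the velocity command — undershoots are
slower — which keeps every (PV, duration, amplitude) triple realizable by
the velocity-profile family.  Profiles are unimodal pulses
pv·h(x)^s with h(x) = (x/x*)^{x*}((1−x)/(1−x*))^{1−x*}: the peak is
exactly PV, the sharpness s is solved so the integral equals the
amplitude, the support is solved so the 30 deg/s crossing width equals
the duration, and the peak position x* shifts earlier (longer
deceleration, positive skew) as the required mean-to-peak ratio drops.
Triples outside the family's reachable ratio range raise an explicit
infeasibility error.

MF units have class-shaped envelopes (burst-tonic with a sustained
post-saccadic tonic level; long-lead ramps starting ~150 ms before
onset; short-lead onsets under 15 ms) whose peak intensity is exactly
linear in PV and whose burst offset tracks the saccade offset linearly.
PC simple-spike templates are pure time-warps of a per-unit waveform
(extremum time, lobe width and biphasic gap all proportional to saccade
duration), so a duration change rescales the population trajectory's
time axis without changing its geometry — PV scales the loop radius,
duration scales time, the decoupled structure reported for PC manifolds.
Biphasic lobes straddle the extremum time, giving the quadrature
temporal structure that makes population trajectories rotate.  Spikes
are drawn from an inhomogeneous Poisson process by thinning (the
downstream analyses are rate-based, so refractory structure is omitted).

An endpoint error evokes a shared climbing-fiber volley with probability
0.5; a PC whose CS-ON direction matches the volley fires a CS with
probability 0.7, otherwise 0.1, which preserves the per-trial
conditional marginals P(CS | error matches CS-ON) = 0.4 and
P(CS | otherwise) = 0.1 while giving CSs the across-cell synchrony of a
shared olivary source.  Each CS suppresses the simple-spike intensity
for 10–20 ms.  When the error-contingency is enabled, the next same-type
trial after a volley carries both the behavioral change (+5% PV after an
outward-error volley; −10% duration after an inward-error volley) and
the matching modulation of the PC population's encoding: a transient
+50% gain on the PV slope after outward events, and a transient doubling
of the sensitivity of the response time scale to duration after inward
events.  The encoding modulation is the generator's model of the
climbing-fiber-driven tuning of the population "more towards" PV or
duration coding; pooled-kinematics effects alone move the slope angle by
only ~2° with a sign that depends on population micro-structure, so the
error-type-dependent angle ordering is a genuinely neural phenomenon in
this model, not a by-product of the behavioral change.

What passing tests show: that the estimators recover planted structure
of the kinds the analysis assumes (linear encodings, low-rank
population structure, Poisson variability, CS tuning with a shared
source).  What they do not show: robustness to non-Poisson variability,
non-linear or history-dependent encoding, eye-plant dynamics, recording
artifacts, or session-to-session heterogeneity of real recordings;
printed population values (variance fractions, unit counts, network R²)
from primate data are not reproduced at desk scale.

## Problem sizes and numerical choices

Default synthetic sessions have 300 trials (alternating centrifugal/
centripetal) and 24 MF + 16 PC units in the empirical class proportions.
The conditioned-plasticity experiment uses 48 PCs and 400
centrifugal-only trials per session and 50 seeds; the perturbation
oracle uses N = 50 units and T = 651 bins; parameter-recovery benchmarks
use 48 units × 300 trials with PV spanning 300–700 deg/s (the range the
50-deg/s binning covers across sessions); calibration uses 2000 null
simulations and 100 drift seeds.  These sizes were chosen so the full
validation runs in minutes on one CPU.  Time grids are 1-ms bins;
eigenvalue-gap regularization kicks in below 1e−6 λ₁; the profile
solver brackets its root in the support fraction and reports
infeasibility rather than extrapolating.  All randomized procedures take
explicit integer seeds and are pure functions of (config, seed).

## Known limitations

Rotation-speed estimates are undefined (NaN) for trajectories that never
complete three quarter turns; slope angles near ±90° saturate and their
jackknife distributions become heavy-tailed.  The per-bin rate
regressions are unregularized (an option exists for noisy regimes) and
assume additive noise, which is only approximate for Poisson counts at
low rates.  The LASSO/AIC path treats time bins as independent samples;
autocorrelation from smoothing makes the AIC degrees of freedom
optimistic, which is acceptable here because the penalty is a guard
against overfitting rather than an inferential tool.  The
cross-validation curve for K is reported, not tested against recorded
data.
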