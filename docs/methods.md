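# Methods

This note documents the model implemented by `synemg`, the defaults it
ships with, the numerical choices made where the standard formulation
leaves room, and what the synthetic-data experiments can and cannot show.

## Activation dynamics

The EMG envelope e(t) ∈ [0, 1] of each muscle, delayed by the
electromechanical delay d, drives a second-order recursive filter

    u(t) = α e(t − d) − (C1 + C2) u(t−1) − C1 C2 u(t−2),

whose poles are −C1 and −C2 (stable iff |C1|, |C2| < 1), followed by the
nonlinear shaping

    a(t) = (e^{A u(t)} − 1) / (e^{A} − 1),   A < 0,

which maps [0, 1] onto [0, 1] with adjustable concavity.  Choices:

* **Gain constraint.** α = 1 + (C1 + C2) + C1·C2, pinning the filter's
  steady-state gain to one.  Without it, the filter gain and the maximum
  isometric forces are jointly unidentifiable during calibration.
* **Delay in real time.** d is rounded to whole samples of the original
  (pre-normalization) grid, never applied on the 100-point cycle grid,
  whose physical time step varies with cycle duration.
* **Clipping before the nonlinearity.** u is clipped to [0, 1]; the
  recursion can transiently overshoot and the exponential map is only a
  [0,1] → [0,1] bijection on that domain.
* **Warm-up.** A copy of the first cycle is prepended and discarded so the
  zero initial conditions never contaminate reported activations; the
  transient decays geometrically as max(|C1|, |C2|)^t.
* **Sharing.** A, C1, C2, d are shared across muscles per subject (a
  per-muscle configuration costs 40 parameters and is not identifiable
  from 4 moment channels); per-muscle values can be passed explicitly by
  constructing models per muscle group.

Defaults (also the calibration initials): A = −0.1, C1 = 0.5, C2 = −0.5,
d = 0.05 s; boxes A ∈ [−3, 0), C1, C2 ∈ (−1, 1), d ∈ [0.01, 0.3] s.

## Musculotendon mechanics

Each of the ten muscles is a Hill-type unit: contractile element (CE) and
parallel passive element (PE) in a fiber at pennation angle α to an
elastic tendon in series.  Normalized curves (tilde = normalized by F0m,
fiber length by l0m, tendon length by slack length lst):

* active force–length: fl = exp(−(L̄M − 1)²/γ), γ = 0.6;
* passive: F̄PE = (e^{KPE(L̄M−1)/ε0M} − 1)/(e^{KPE} − 1), KPE = 5,
  ε0M = 0.6, clamped at 0 (no compressive passive force);
* force–velocity with effective maximum shortening velocity
  (0.25 + 0.75a)·Vmax, Vmax = 10 l0m/s, shortening denominator
  b = a·fl + F̄CE/Af (Af = 0.3) and lengthening branch with coefficient
  (2 + 2/Af) saturating at F̄lenM = 1.8;
* tendon: zero below slack, exponential toe up to F̄toe = 0.33 at strain
  ε_toe = 0.609·ε0T, then linear with slope k_lin = 1.712/ε0T, ε0T = 0.04
  (so the strain at F0m is 0.04).

The published rendering of the force–velocity and tendon-toe formulas in
this model family is frequently garbled typographically; the
implementation uses the standard formulation that the printed constants
belong to, and the test suite pins the identities those constants force
(strain 0.02436 at the toe transition, 0.0400 at F̄T = 1, fl(1) = 1,
F̄PE(1.6) = 1, the −1.875 l0m/s shortening example).

**Equilibrium.**  Per frame the normalized fiber length solves
g(L̄M) = F̄T(l̄t(L̄M)) − (F̄CE + F̄PE)·cos α = 0 by bisection on
L̄M ∈ [0.05, 1.8] to a force tolerance of 1e−6, warm-started from a
narrow bracket around the previous frame's solution.  The fiber velocity
entering F̄CE is the backward difference of the solved fiber length
(zero at each cycle's first frame), which makes the per-frame problem
closed-form solvable in the force direction — the force–velocity relation
is inverted analytically per branch, so no activation floor is needed
(a = 0 yields exactly zero contractile force; the floor parameter exists
but defaults to 0).  Frames without a bracketing sign change (fully slack
configurations) fall back to a rigid-tendon estimate and are flagged.
Pennation follows the constant-thickness model sin(pen)·LM = sin(α0)·l0m,
clamped below 84.3°; α0 defaults to 0 for all ten muscles.

These inner loops are compiled with numba; the identical curve formulas
are exposed as plain numpy functions and the suite checks the two paths
against each other and against a rigid-tendon brute-force oracle.

## Moments and the sign structure

M_i = Σ_j F0m_j (F̄CE + F̄PE)_j r_ij cos α_j over the 4 DOFs
(arm adduction–abduction, arm flexion–extension, arm internal–external
rotation, elbow flexion–extension; flexion/adduction/internal
rotation/elbow flexion positive).  Which muscle crosses which DOF, and
with which moment-arm sign, is fixed anatomy encoded in
`moments.SIGN_TABLE`; `check_sign_structure` audits any moment-arm set
against it.  The model drives 10 lumped musculotendon units — one per EMG
channel; no attempt is made to distribute channels over a larger actuator
set.

## Calibration

Objective: J = Σ_cycles Σ_DOFs (1/n) Σ_points (M^mod − M^exp)², a sum of
per-series MSEs (no square root — the root is not monotone across summed
terms, so the sum-of-MSE form is the one actually minimized).  Five
calibration cycles, five held-out validation cycles.

Optimizer: simulated annealing, seeded.  Schedule: exponential cooling
T_k = T0·0.95^k with 200 proposals per temperature; T0 estimated from
warm-up probes so initial uphill acceptance ≈ 0.8; proposals perturb one
uniformly chosen coordinate by a Gaussian step of 10% of its box width,
projected onto the box (simultaneous full-dimensional moves at this step
size have vanishing acceptance in 34 dimensions).  The best-so-far point
is tracked and returned, making the reported objective non-increasing
regardless of the acceptance path.  Budget: 5000 evaluations by default
(~30–40 s on one core with the compiled forward model); all schedule
constants are configurable.

## Synergy decomposition and extrapolation

The measured activation matrix V (9 × n, n = 100 × cycles) is factorized
V ≈ W·H, best of 10 random restarts by reconstruction R² with grand-mean
centering, R² = 1 − ‖V − VR‖²F / ‖V − mean(V)‖²F.  Methods:

* **NMF** (primary): multiplicative updates on the squared Frobenius
  loss, uniform-random nonnegative initialization per restart, max 1000
  iterations, tolerance 1e−6 (scikit-learn's `mu` solver).
* **PCA / ICA / FA** (comparison): time points as samples, muscles as
  features; H is the component-score time course, W the loadings, and the
  reconstruction restores the removed per-muscle means.  ICA is fastICA
  on the whitened matrix; FA is the maximum-likelihood factor model.
  These conventions (sign handling, mean restoration) are this package's
  own reconstruction of methods usually left underspecified; they are
  exactly what the tests pin down.

Synergy number l ranges over 2–7; the cap is 75% of the muscle count
(extracting one synergy per muscle performs no dimensionality reduction).

**Missing-muscle extrapolation.**  With Hm fixed from the measured
muscles, the withheld muscle's activation is a_x = clip(Wx·Hm, 0, 1),
Wx ≥ 0 (1 × l).  Wx minimizes the same sum-of-MSE moment-tracking
objective over all 4 DOFs (configurable subset), by the same annealer
(2000 evaluations default, independent seed stream per withheld muscle).
Implementation choices:

* the fixed 9-muscle moment contribution is computed once; each
  evaluation re-solves only the missing muscle's contraction dynamics;
* values of Wx·Hm above 1 are clipped *and* quadratically penalized
  (weight 1e4 on the mean squared excess) — a pure clip leaves the
  objective flat in the clipped region; sub-zero values are clipped
  without penalty, because for the signed PCA/ICA/FA primitives negative
  excursions are structural, not pathological;
* the upper box for each weight lets a single synergy reach activation
  1.2; the start point is the mean absolute module weight of the measured
  muscles; the all-zero vector is always evaluated as a candidate, so the
  optimizer never does worse than dropping the muscle;
* Hm is computed once over the whole evaluated cycle set (not per cycle);
* a muscle with zero moment arm on every DOF is rejected as
  unidentifiable (its weights cannot influence the objective).

## Statistics

%RMSE and %MAE normalize by the range max(exp) − min(exp) of the
reference series (errors on constant references).  RMSE ≥ MAE always
holds; %RMSE ≥ %MAE does not in general, and is not asserted.  Paired
t-tests compare calibration and validation metrics.  Method and
synergy-number effects use Kruskal–Wallis (tie-corrected) with Dunn's
post-hoc z-tests on mean ranks, tie-corrected, unadjusted p-values by
default (Bonferroni and Holm available).  Aggregate ("overall") metrics
are computed per cycle and then pooled as mean ± SD.

## Synthetic subject

The generator draws, deterministically from a seed: nominal musculotendon
parameters (fixed literature-plausible table: F0m 260–1200 N, l0m
0.076–0.172 m, lst 0.105–0.215 m), joint-angle trajectories (two
harmonics of the cycle per DOF, amplitudes 0.20–0.35 rad), moment-arm
polynomials r_ij(q_i) with the anatomical signs and magnitudes 1.5–4 cm
kept single-signed over the motion range, and a synergy structure of
l_true = 5 wrapped-Gaussian primitives centered at cycle fractions
{0.10, 0.25, 0.40, 0.60, 0.85} with width 0.08 of the cycle — unimodal
bursts of the kind poling produces.  Each muscle loads one dominant
primitive plus weaker uniform contributions, scaled to peak activations
of 0.6–0.9.

Study conditions: 14 cycles of 1.2 s with equal poling/recovery halves,
so the 100-point normalized grid is uniform in time (dt = 12 ms);
envelope noise is multiplicative with sd 0.03 (clipped to [0, 1.05]);
reference-moment noise is additive with sd 2% of each DOF's moment
range.  The subject's true activation parameters are A = −0.15,
C1 = 0.45, C2 = −0.40, d = 0.06 s — mild offsets from the calibration
initials, with the delay an exact number of grid samples.

Internal consistency, by construction rather than by tolerance:

* musculotendon lengths are the closed-form path integrals of the
  moment-arm polynomials, so dLMT_j/dt = −Σ_i r_ij(q_i) q̇_i holds
  exactly;
* envelopes are the exact periodic inverse of the activation dynamics
  applied to the rank-5 activation matrix, so the forward pipeline under
  true parameters returns exactly W_true·H_true;
* reference moments are the package's own forward model evaluated under
  the true parameters (before noise), so the calibration objective at the
  truth is zero on noise-free data up to solver tolerance.

**What this does and does not show.**  Passing recovery tests on this
subject demonstrates that the pipeline is internally consistent, that the
optimization recovers identifiable parameters and in-span missing
activations, and that NMF's nonnegative structure is the right prior when
activations truly are nonnegative mixtures of nonnegative primitives.  It
does not demonstrate robustness to the ways real recordings violate the
model: cycle-to-cycle variability of the primitives themselves,
non-stationary noise, electrode crosstalk, fatigue drift, moment arms
from real geometry, or activations outside the synergy span.  Reported
accuracies on the synthetic subject are therefore upper bounds on what
the same pipeline achieves on experimental data.

## Problem sizes and budgets

Default experiment sizes, chosen as the package's standard study
conditions: calibration on 5 cycles with 5000 annealing evaluations;
extrapolation on 10 cycles with 2000 evaluations per withheld muscle;
NMF with 10 restarts.  One full leave-one-out sweep over 10 muscles runs
in about a minute on a single core; the acceptance script (reconstruction,
full leave-one-out, perturbed-start calibration) completes in a few
minutes.

## Known limitations

* One missing channel at a time; simultaneous multi-channel
  reconstruction is out of scope.
* The pennation model is the constant-thickness approximation with α0 = 0
  defaults; no fiber-type differentiation, tendon damping, or
  activation-dependent optimal-length shift.
* Dunn's test reports raw p-values by default; multiple-comparison
  adjustment is opt-in.
* The equilibrium solver's rigid-tendon fallback flags frames rather than
  failing; long fully-slack stretches should be inspected via the flags.
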