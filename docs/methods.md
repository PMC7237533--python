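# Methods

This note documents the models, numerical choices, and design decisions in
`crittorque`, and what the synthetic fixtures do and do not show about real
data.

## Fatigue model and simulation

The model tracks two capacity states whose product is the current MVIC
torque capacity `h_MVIC ∈ [0, 1]` (all torques normalized to the
unfatigued baseline):

```
dx_slow/dt = p1 (1 − x_slow) − p2 u_abs
dx_fast/dt = p3 (1 − u_abs)^p4 (1 − x_fast) − p5 u_abs
```

`p1, p3` are recovery rates (1/s), `p2, p5` fatigue rates (1/s), and `p4` a
dimensionless exponent that throttles fast recovery under load; all are
nonnegative. An unfatigued muscle starts at `x0 = (1, 1)`. Relative-load
stages substitute `u_abs = u_rel · h_MVIC`, which makes maximal efforts
(`u_rel = 1`) well-posed.

Loading schemes are ordered stages with piecewise-constant controls.
Integration is stage-wise and restarts at every boundary, so control
discontinuities are never smeared. Conventions at the singular load
`u_abs = 1`: `0^0 = 1` and `0^p = 0` for `p > 0`; the derivative of
`(1−u)^p4` is clamped at base `1e-12` for `p4 < 1` (the fixtures use
`p4 ≥ 1`, where no clamp is active).

Two integration paths are used:

- **Relative-load stages** (nonlinear dynamics): `scipy` LSODA with
  relative tolerance `1e-8` and absolute tolerance `1e-10` by default.
- **Constant-absolute-load stages, including rests** (the dynamics become
  linear with constant coefficients): the exact affine-exponential
  solution, evaluated in closed form. This is both faster and more
  accurate than numerical integration; task-failure times are then located
  by `brentq` root finding on the closed-form `h_MVIC(t)`, well below the
  0.01 s refinement target.

Time under tension (TUT) is the integral of the indicator of nonzero load;
for on/off loading it equals the integral of `u_rel`. It accumulates
analytically per stage.

### Termination rules

- *Sustained all-out test*: terminate when both state derivatives fall
  below `1e-6` in magnitude (integrator event on the continuous function
  `max(|f1|, |f2|) − 1e-6`), checked along the whole trajectory.
- *Intermittent all-out test*: compare `h_MVIC` at the onsets of adjacent
  contractions; terminate when they differ by at most `1e-6`.
- *Constant-target loading*: task failure is the first instant `h_MVIC`
  drops below the demanded torque during a contraction.

The default horizon is 3600 s (60 min); thresholds and horizon are
configurable arguments.

## Critical torque

For a duty cycle `d = t_c/(t_c + t_r)` the cycle-averaged steady-state
conditions weight the loaded and resting dynamics by `d` and `1 − d`; the
`(t_c, t_r)` weighting used for a 3 s / 2 s scheme is the same root set up
to the positive factor `t_c + t_r`. Both conditions are linear in their
state, giving closed forms

```
x_slow = 1 − d p2 u / p1
x_fast = 1 − d p5 u / (p3 (d (1−u)^p4 + 1 − d))
```

`x_slow x_fast − u` is strictly decreasing in `u`, so the feasible set is
an interval `[0, u*]` and CT is found by a scan over 10,000 uniform loads
plus bisection of the bracketing interval to width `1e-10` (the default
and the oracle). The multistart mode solves the 3-variable program over
`(u, x_slow, x_fast)` with SLSQP from a uniform grid over the unit cube
(default 20 points per dimension; 5 suffices in practice and is what the
oracle-agreement tests use), keeping the feasible solution with the
highest load, ties broken by grid order. `d = 0` returns `u* = 1` by
convention. At the optimum the capacity constraint `u = x_slow x_fast` is
active unless `u* = 1`.

Consistency between the program and simulated all-out tests is inherently
approximate for intermittent loading: the end-test torque is read at
contraction *onsets* (the within-cycle maximum of the steady cycle), while
the program solves cycle-averaged conditions. The residual offset grows
roughly linearly with the overall rate scale of the parameters and is
positive throughout the explored parameter space. The bundled fixture
region (below) keeps it under 0.2 percentage points of baseline.

## Measurement model and estimation

A torque measurement during a contraction is
`η_j = u_rel(t_j) h_MVIC(t_j) + ε_j` with independent zero-mean normal
errors. The standard deviation is

```
σ_j = σ_2s (2 − u_rel(t_j)) √(2 / Δt_j),    σ_2s = 0.0378
```

`σ_2s` is the empirical coefficient of variation (3.78%) of unfatigued
2 s maximal elbow-flexor measurements, applied as an *absolute* standard
deviation on the normalized torque scale; the `(2 − u_rel)` factor doubles
the uncertainty as contractions become nominally effortless (estimating a
submaximal relative load is hard), and the square-root factor weights a
measurement by duration relative to the 2 s reference, so a 2 s maximal
measurement has `σ = σ_2s` exactly and doubling the duration doubles the
information. Measurements exist only on contraction stages; rest torque is
zero and uninformative.

Parameters are estimated by maximum likelihood (weighted nonlinear least
squares) with `scipy`'s trust-region-reflective solver: bounds `p ≥ 0`
enforced by the solver (never by clipping), analytic Jacobians from
forward sensitivity equations integrated alongside the states (the
relative-load substitution is differentiated through), characteristic
scales `x_scale = |p_init|` (the rates are ~1e-3 next to an O(1)
exponent), and stopping tolerances `gtol 1e-8`, `xtol 1e-10`,
`ftol 1e-10`, at most 300 function evaluations by default.

The covariance approximation is `C = (JᵀJ)⁻¹` with rows
`(1/σ_j) dh/dp(t_j)`. Because the parameters span three orders of
magnitude, the raw Gram matrix is artificially ill conditioned; columns
are equilibrated by their norms before inversion, which is exact and
stable.

### Calibration regime

The covariance approximation is an asymptotic (weak-noise) statement.
For the slow-dynamics fixture parameters a single session leaves the
parameters weakly identified (the to-1-scaled SD of `p4` after even an
optimized 400 s-TUT session is well above 1), and at the physiological
noise level `σ_2s = 0.0378` the likelihood surface is strongly
non-Gaussian: empirical 3σ coverage drops to ~90% and fits can crawl
along a near-degenerate valley (`corr(p1, p3) ≈ −0.99`). The calibration
tests therefore run at `σ_2s × 0.001`, where the fitted estimates agree
with the linearized estimator to ~1% of a standard deviation and coverage
and covariance agreement are clean. This verifies the estimator and
covariance implementation; it deliberately does not claim that a single
real session at full noise identifies all five parameters for these
fixtures.

## Optimum experimental design

A testing session with `n_c` contractions is `n_s = 2 n_c − 1` alternating
contraction/rest stages. Decision variables: all stage durations and one
constant relative load per contraction stage. Objective: the A-criterion
`⅕ tr((JᵀJ)⁻¹)` with parameters scaled to 1, built from 100 (configurable)
uniform *midpoint* measurements per contraction stage with
`Δt = T/n_meas`, which makes the total information invariant under grid
refinement (verified against a dense-quadrature reimplementation of the
continuous-measurement limit). Constraints: stage durations ≥ 0.01 s,
total time ≤ `C_T`, TUT ≤ `C_TUT` with TUT accruing at rate `u_rel` on
contraction stages (identical to the indicator measure for maximal
contractions, smooth in the loads for the optimizer). Measurements on rest
stages are excluded.

The optimizer is SLSQP over normalized variables (durations divided by
`C_T`) with forward finite differences (step `1e-4`) over exact
sensitivity solves, the objective transformed by `log` for conditioning,
and a ridge of `1e-12` on the scaled information matrix so
information-singular iterates stay finite. Every feasible iterate is
recorded and the best one returned, so the result is never worse than a
feasible initial design; the 400 s-TUT problem additionally receives the
200 s solution as a candidate, which makes budget nesting (a larger budget
never hurts) hold by construction even at small iteration caps. The
default initial design is the intuitive testing session (a 3 min maximal
effort plus ten 2 s probes over half an hour; 1982 s total, 200 s TUT).

## Uncertainty propagation

Perturbed parameter vectors are drawn from independent normals
`N(p_i, σ_p_i²)` (optionally the full multivariate normal `N(p, C)`);
vectors with any negative component are rejected and redrawn whole, which
preserves the distribution conditional on nonnegativity — with nonnegative
means the acceptance probability is at least `2⁻⁵`, so rejection sampling
always terminates. The scenario (60 min of intermittent maximal efforts,
or the resistance training session read at the end of its 25th
contraction) is re-simulated per draw and the differences of end-MVIC
torque to the nominal run are summarized by their standard deviation and a
1-D Gaussian KDE with Scott's bandwidth `h = n^{−1/5} σ̂`
(`scipy.stats.gaussian_kde`, verified against the direct kernel sum). All
sampling is seeded through `numpy.random.default_rng` and seeds are
embedded in outputs.

## Synthetic fixtures

The bundled parameter sets (`baseline`, `fatigable`, `enduring`) and the
random battery region

```
p1 ~ U[0.0024, 0.0028]   p2 = p1 · U[2.2, 3.2]
p3 ~ U[0.0026, 0.0030]   p4 ~ U[1.0, 2.0]   p5 = p3 · U[0.7, 1.4]
```

are synthetic stand-ins, not estimates for any muscle group. The region
was chosen (and frozen) so that every vector in it satisfies the package's
cross-module consistency properties: sustained and intermittent CT in
(0, 1) with intermittent above sustained, all-out plateaus reached within
the 60-min horizon at the 1e-6 thresholds, and program-vs-plateau
agreement within 0.2 percentage points (validated on 232 corner and random
draws; worst observed gaps 0.012 / 0.169 pp). These dynamics are slower
than typical published human estimates, a deliberate trade-off: faster
dynamics would improve single-session identifiability but break the
onset-read intermittent-plateau agreement, whose error grows with the rate
scale. Consequently, passing tests demonstrate internal consistency of the
machinery, not that five parameters are recoverable from one real session
at physiological noise.

The frozen `reference_testing_session` (21 stages, 1954 s, 399.6 s TUT at
rate accounting) is the product of a development-time design optimization
for the `baseline` fixture, rounded and bundled so estimation tests are
deterministic and cheap; it is synthetic, not a published protocol.

## Known limitations

- Isometric contractions only; no ramps, no isokinetic/isotonic
  extensions, no EMG or metabolic outputs.
- The curvature constant `W′` of the power-duration relationship is not
  estimable by this approach.
- The duty-weighted steady-state conditions are an approximation for
  intermittent loading; exact periodic-orbit analysis is not implemented.
- Single-experiment estimation; measurement sets can be concatenated, but
  there is no specialized multi-experiment structure exploitation.
- A-criterion only; no D/E-criteria and no optimization over the number
  of stages.
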