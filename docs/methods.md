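# Methods

## Model

The liver subsystem treats endogenous glucose production as affine in three
inputs on each meal segment's own time grid (minutes since that meal):

    EGP(t) = kp1 − kp2·Gp(t) − kp3·Id(t) − kp4*·Ipo(t)

- `Gp = G·Vg` (mg/kg): plasma glucose mass; `Vg` (dl/kg) is the glucose
  distribution volume.
- `Id` (pmol/l): delayed insulin action, plasma insulin filtered through two
  first-order compartments, `dI1/dt = −ki(I1 − I)`, `dId/dt = −ki(Id − I1)`,
  both initialised at the segment's basal insulin.
- `Ipo = ISR/γ` (pmol/kg): portal-vein insulin, with `γ` a fixed transfer
  rate.
- `kp4* = A·kp4` during breakfast, `kp4` otherwise: `A` (dimensionless)
  expresses the documented morning/evening difference in insulin
  sensitivity. `A` multiplies `kp4` in the `kp1` anchoring as well, so the
  anchoring identity below holds on every segment.

`kp1` (mg/kg/min), the extrapolated EGP at zero glucose and insulin, is not
free: per segment it is fixed by the basal (t = 0) anchor values so that
the predicted curve starts exactly at the supplied basal EGP,
`kp1 = EGP_b + kp2·Gp_b + kp3·Id_b + kp4*·Ipo_b`. Segments are modelled as
independent records (the insulin chain restarts at each meal) because
three-meal protocols leave gaps between segments that make continuous
integration over the day impossible.

Negative predicted EGP is returned unclamped with a warning: the equation
is affine and clamping would bias every fit that touches the boundary.

### Fixed constants

| constant | healthy | type 2 diabetic | unit  |
|----------|---------|-----------------|-------|
| Vg       | 1.88    | 1.49            | dl/kg |
| ki       | 0.0079  | 0.0066          | 1/min |
| γ        | 0.5     | 0.5             | 1/min |

Selection is by fasting glucose: healthy values below 99 mg/dl, diabetic
values above 126 mg/dl, linear interpolation of the endpoint pairs in
between (continuous and monotone across the band).

## Tracer-free estimation

Differentiating the EGP equation (with anchored `kp1`) with respect to each
rate parameter and forming weighted pairwise differences yields, per meal,
three coefficients built solely from basal anchors:

    C23 = kp2·Gp_b − kp3·Id_b
    C24 = kp2·Gp_b − kp4*·Ipo_b
    C34 = kp3·Id_b − kp4*·Ipo_b = C24 − C23

The estimator assumes these are invariant across the three meals of a day
and minimises the root sum of squared pairwise differences,
`obj = sqrt(Σ_pairs (ΔC23 + ΔC24 + ΔC34)²)` over unordered meal pairs
(ordered enumeration would scale the objective by √2 without moving the
minimiser). In code `C34` is literally computed as `C24 − C23`, which makes
the identity exact in floating point; consequently the objective reduces to
`2·sqrt(Σ ΔC24²)` — both forms are implemented and cross-checked in tests.

Three structural facts follow and are surfaced rather than repaired:

1. the objective is independent of kp3;
2. it is homogeneous of degree 1 in (kp2, kp3, kp4) at fixed A, so the
   minimiser set is scale-degenerate;
3. a zero objective pins exactly `r = kp2/kp4` and `A`, which are available
   in closed form from the anchors
   (`r = ΔIpo_b/ΔGp_b` over lunch/dinner;
   `A = (r·(Gp_b^b − Gp_b^l) + Ipo_b^l)/Ipo_b^b`) — the independent oracle
   used throughout the tests.

No regularisation is added; reported kp2/kp3/kp4 are one point of the
optimal set under a deterministic policy (minimum objective, ties within
1e-10 broken by start index). How unique per-parameter values could be
read off this objective at all is left open deliberately; the
profile-likelihood module is the package's answer to "how much is actually
determined".

### Optimisation

Bounded trust-region-reflective least squares (`scipy.optimize.least_squares`)
on the residual vector whose 2-norm is the objective, with
ftol = xtol = gtol = 1e-12, from 150 Latin-hypercube start points
(`scipy.stats.qmc`, fixed seed, recorded in the result) inside the box
lower = (0.0009, 0.001, 0.01, 0.8), upper = (0.02, 0.05, 0.09, 1.4) for
(kp2, kp3, kp4, A). When no start trips the formal tolerances — which
happens on exactly flat directions such as kp3 under constant insulin,
where the optimiser exhausts its evaluation budget with the informative
directions long converged — the best terminated solution is reported with
a warning instead of failing the run.

## Direct (reference) fit

With measured EGP curves the same multistart machinery minimises
`V = sqrt(Σ_segments Σ_times (EGP_calc − EGP_exp)²)` (the total sum over
all meals and time points under a single root; minimising it is ordinary
least squares on the stacked residual vector). `A` is a fitted parameter
here too. The result records per-segment `kp1` and flags non-uniqueness
when two converged starts tie in cost (within 1e-10) but differ in
parameters by more than 1e-3 relative — the behaviour produced by designs
in which `Id` and `Ipo` deviations are proportional.

## Profile-likelihood identifiability

The agreement objective is `χ²(θ) = ΣΣ ((y_exp − y_calc)/σ)²` with the
measurement-error model `σ = 0.10·y + 0.05·max(y)`, the maximum taken
within each segment's own EGP curve (per-curve reading of the max term).
After a global multistart χ² fit, each parameter is walked away from its
optimum in multiplicative 2% steps (parameters span decades, so steps are
log-domain), the other three re-optimised at every step warm-started from
the neighbouring grid point, until the χ² increase exceeds
`Δα = Q_χ²(α, df)` (α = 0.68; df = 1 point-wise, df = 4 simultaneous) or
the range — the estimation box extended by a factor 10 on each side — is
exhausted, up to 200 steps per direction. The finite range makes "infinite
confidence region" operationally decidable. Confidence-interval endpoints
are interpolated linearly in log-parameter between the bracketing grid
points. Classification: flat profile (variation below 1e-6 of the χ²
scale, `max(1, χ²_min)`) → structurally non-identifiable; both sides
crossed → identifiable; otherwise practically non-identifiable. A
per-parameter flag reports whether the tracer-free estimate lies inside
the df = 1 interval of the direct fit. Inner re-optimisations keep the
other parameters inside the original box; a failed inner fit marks that
grid point and profiling continues.

## Synthetic data generator

The generator emulates a three-meal study protocol — breakfast/lunch/dinner
segments of 240 min sampled at 0, 15, 30, 45, 60, 90, 120, 150, 180, 210,
240 min, meals of 45/70/70 g at 8 a.m./12 p.m./8 p.m. carried as metadata
only. Observed curves are per-segment basal levels plus gamma-shaped bumps
`amp·(t/t_peak)^shape·e^(shape(1−t/t_peak))`; EGP is produced *exactly* by
the liver equation at the configured truth with per-segment anchoring, so
noise-free datasets satisfy the model to machine precision by
construction.

Defaults (chosen once as plausible study conditions; the curve shapes are
generator plumbing, not physiological claims): truth
θ = (0.0025, 0.0109, 0.045, 0.90) — a healthy-subject parameter set;
basal EGP (2.0, 1.9, 1.8) mg/kg/min over the day; glucose 90 mg/dl basal,
bump 50 @ 45 min; insulin 40 pmol/l, 250 @ 60 min; ISR 1.5 pmol/kg/min,
6 @ 30 min; shape 2; lunch/dinner basal drifts ×1.10 / ×1.05 so the basal
anchor triples differ across meals (near-identical anchors are rejected as
a degenerate design). The ISR bump peaks at 30 min rather than together
with the glucose bump: insulin secretion responds ahead of the plasma
glucose-mass peak, and coincident peaks would make the Gp and Ipo
deviations exactly proportional — a structurally collinear design in which
the direct fit cannot separate kp2 from kp4 (that collinear case is kept
as an explicit test construction instead).

Optional noise is additive Gaussian with
`σ = noise_scale·(0.10·y + 0.05·max(y))` per curve, seeded; glucose,
insulin and ISR are clipped to stay physical (≥1 mg/dl, ≥0, ≥0), EGP is
not clipped. The observed basal EGP of a noisy dataset is the noisy t = 0
sample, as it would be in an experiment; the clean truth is carried
alongside.

**Consistency mode** constructs lunch/dinner basal levels so the
meal-invariance assumption holds exactly at the truth:
`Gp_b^i = drift_i·Gp_b^b`, `Id_b^i = Id_b^b + (kp2/kp3)ΔGp`,
`Ipo_b^i = (kp2/kp4)ΔGp + A·Ipo_b^b` (infeasible negative levels raise an
error). The closed-form oracle inverts this construction exactly, enabling
round-trip tests of the whole tracer-free pipeline.

A soft realism check warns when the default-preset breakfast EGP nadir
falls outside 30–70% of basal within 60–120 min. With the fixed bump
shapes and the slow insulin-action chain (ki = 0.0079 → ~127 min per
compartment) the delayed-insulin deviation keeps rising past 240 min, so
the nadir arrives either early (~45 min, portal/glucose-dominated θ) or at
the segment end (insulin-action-dominated θ); the default preset's nadir
depth is physiological but late, and the check warns by design. What
passing tests on these synthetic data show is internal consistency of the
estimators, not fidelity to whole-body meal physiology: real curves have
secondary excursions, correlated noise and inter-meal carry-over that the
generator does not model.

## Numerical choices

- Insulin-chain integration: piecewise-linear input interpolation, LSODA
  with rtol 1e-8, atol 1e-10, max step one sample interval; verified
  against the closed-form step response `1 − (1 + ki·t)e^(−ki·t)` to
  <1e-4 relative on a 1-min grid.
- EGP prediction is computed in deviation form
  `EGP_b + kp2(Gp_b−Gp) + kp3(Id_b−Id) + kp4*(Ipo_b−Ipo)`, making
  `EGP(0) = EGP_b` bitwise rather than to rounding error.
- CSV I/O writes shortest round-trip decimal and reads with pandas
  `float_precision="round_trip"`, so write→read preserves every double
  bit-for-bit and row order never changes results.
- All stochastic components (start points, noise) draw from
  `numpy.random.default_rng` with recorded seeds; identical configuration
  reproduces results exactly, and ties among multistart optima break by
  start index.

## Scope and limitations

- Problem sizes used in the shipped tests and the acceptance script —
  150 multistarts, 20 noise-free recovery replicates, 200 noise-calibration
  replicates, profile grids of ≤200 steps per side — complete in a couple
  of minutes total; they are the package's chosen study scale.
- ISR is consumed directly; C-peptide deconvolution is out of scope.
- The generator substitutes for whole-body meal simulation; it cannot
  reproduce any specific published dataset.
- The tracer-free route's scale/kp3 degeneracy is documented, surfaced in
  diagnostics and the profile module, and intentionally not repaired by
  regularisation; EGP time courses predicted from tracer-free parameters
  alone are correspondingly unreliable (only kp2/kp4 and A carry
  information).
- The evaluation R² is `1 − SS_res/SS_tot` on the 11-point sampling grid
  per meal; it can be negative and is reported as-is.
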