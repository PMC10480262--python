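# Methods

## Problem and approach

An HDR prostate brachytherapy plan is evaluated clinically on a single
nominal dose distribution, but contouring variation, needle
reconstruction error, organ motion, source positioning and dwell-time
delivery uncertainty all perturb the delivered dose.  `brachyrobust`
quantifies a plan's robustness by simulating many perturbed versions of
the nominal plan ("treatment scenarios"), recomputing dose and
dose-volume histogram (DVH) metrics for each, and summarizing the
resulting metric distributions.

Two scenario families are used:

* **probabilistic** — each of six variable parameters is drawn from a
  zero-mean normal distribution with a literature-derived standard
  deviation, hard-truncated at ±1.65 SD (the 90% confidence interval);
* **worst-case** — the Cartesian product of each parameter's 90% CI
  limits {−1.65 SD, 0, +1.65 SD}, with needle transverse movements
  taken as coordinated direction modes (all needles radially out from /
  in toward the prostate transverse centre line; all needles
  posterior), since independent extreme draws per needle would explode
  combinatorially without representing a physically coherent extreme.

## The six variable parameters

| # | Operation | Default SD | Source of uncertainty |
|---|-----------|-----------|------------------------|
| 1 | dwells slide along the needle (superior +) | 1.5 mm (= 1.1 ⊕ 0.34 ⊕ 1.0) | needle-tip reconstruction, rigid SI needle motion, source positioning |
| 2 | prostate boundary expands/contracts radially from its 3D geometric centre, then is resampled to the original slice width | 2.0 mm | prostate contouring |
| 3 | urethra / rectum contours expand/contract per 2D slice | 0.25 mm / 1.0 mm | OAR contouring (urethra value published as a diameter; halved to a radial SD — a config flag restores the radial reading) |
| 4 | whole needles translate in the transverse plane (per needle, per axis) | 1.5 mm (= 1.2 ⊕ 0.86) | transverse needle reconstruction and rigid motion |
| 5 | dwell times t ← t·(1 + pct/100) + offset | 4.4% (= 1 ⊕ 3 ⊕ 3), 0.06 s | dose calculation, treatment planning, source strength; dwell-time precision |
| 6 | prostate + urethra + dwells translate rigidly; rectum fixed | LR 0.1 mm, AP 0.5 mm | prostate rigid motion relative to the rectum |

(⊕ denotes quadrature combination.)  Operators apply in order 1→6 and
are pure functions; every operator at zero magnitude is the identity to
within stated resampling tolerances.  Negative dwell times after the
offset are clipped to zero (physical non-negativity) with a logged
count.  Source orientation is not updated by transverse needle moves.

Parameter 1's sign convention is positive = superior (toward the
needle tip): a shift x relocates each dwell to the path point whose
arc-length coordinate is the original minus x.  Shifts past a path end
clamp to the end point with a warning.

Parameter 2's resampling follows the slice↔vertex dimension swap: each
superior–inferior curve of index-aligned vertices is refit with an
interpolating cubic B-spline, evaluated densely at 10× the slice
count, and the crossing parameter for each target z-level is then
refined by inverse interpolation so the identity perturbation
reproduces the input slices to ≲1e-9 mm (pure nearest-of-dense-samples
selection would leave ~0.1 mm identity error).  New slices stay on the
original slice lattice, growing or shrinking at the ends.

Worst-case levels for parameter 5 move the percentage and the offset
jointly with the same sign (they share one variable parameter).  The
rigid-motion parameter takes one-axis-at-a-time levels (±LR, ±AP,
zero), reading its "4-way movement" as the four cardinal transverse
directions.  The default enumeration is therefore 3⁵ scalar
combinations × 5 rigid levels × 3 transverse modes = 3645 scenarios;
the composition is fully configurable and the run count is always
reported rather than assumed.

## Dose model

Dose is computed with the TG-43 formalism in homogeneous water (its
standard limitation — no heterogeneity, applicator shielding or
patient-scatter corrections):

D̊(r, θ) = S_K · Λ · [G_L(r, θ)/G_L(r₀, θ₀)] · g(r) · F(r, θ),
r₀ = 1 cm, θ₀ = 90°.

The line-source geometry function uses the subtended-angle form
β/(L·r·sinθ) with the on-axis limit 1/(r² − L²/4); g(r) is
interpolated log-linearly in r (log-linear extrapolation beyond the
table, nearest value below it); F(r, θ) bilinearly with nearest-value
clamping outside the grid.  Point–dwell distances below the minimum
table radius are capped at that radius (the sample then reports the
minimum-radius dose).  Each dwell's source axis is the needle-path
tangent at the nearest path point.  Total dose is the time-weighted
sum over all dwells, evaluated either as a vectorized rate matrix or
through an equivalent compiled (numba) point×dwell loop; the two agree
to ~1e-14 relative.

The bundled default source is a **synthetic** generic HDR Ir-192 line
source (Λ = 1.109 cGy·h⁻¹·U⁻¹, L = 3.5 mm, S_K ≈ 40 820 U ≈ 10 Ci):
g(r) from a cubic attenuation/build-up polynomial normalised at 1 cm,
F(r, θ) from a smooth axial-depression model.  It is physically
representative but is not a measured consensus dataset; clinical use
should load measured tables through the plain-text table interface.
All robustness machinery is source-model-agnostic.

## DVH metrics

Dose points are a deterministic regular grid (default 1 mm) strictly
inside the stacked-polygon volume of each structure, each point
weighted by spacing³; the grid lattice is anchored at half-spacing
offsets from the origin, so sampling is reproducible and independent
of the contour bounding box.  A grid (rather than Monte Carlo
sampling) makes every metric exactly reproducible and
oracle-checkable.  D_x is the minimum dose of the hottest x (% or cc)
of the structure, computed from weighted descending order statistics
without interpolation; V_y is a weighted count.  V100/V150/V200/V75
levels are percentages of the prescription (16 Gy single fraction by
default).  DVH curves use 0.01 Gy bins on a common grid reaching 4×
the prescription.  The eight default objectives are prostate D90 ≥ 16
Gy, V100 ≥ 90%, V150 ≤ 40%, V200 ≤ 10%; urethra D10 ≤ 18.4 Gy,
D0.01cc ≤ 18.4 Gy; rectum V75 ≤ 1.0 cc, D0.1cc ≤ 13 Gy.  Boundary
equality passes; a per-case V200 waiver flag (default off) represents
a clinically accepted exceedance.  Structures are evaluated over
their contoured volume only.

## Statistics

Per metric: mean ± SD, quartiles, and a 95% CI from the standard error
of the mean using the normal quantile z = 1.96 (indistinguishable from
a t-quantile at ensemble sizes of hundreds and matching the way
published intervals are reconstructed from printed moments).
Fisher–Pearson skewness (unadjusted g₁ by default, adjusted G₁
available) flags metrics pressed against physical bounds (V100 near
100%, V75 near 0), for which the bootstrap percentile CI of the median
(1000 resamples, seeded) replaces the mean CI.  One-sample one-tailed
t-tests compare a metric's ensemble mean against its constraint.
Whole-curve robustness is the SD-per-dose area: the across-scenario SD
of relative volume summed over dose bins × bin width (Gy); smaller
area = more robust structure.

## Scenario engine

Scenarios are independent and aggregation is commutative.  A run is
driven by one seed; probabilistic scenario i uses the substream
`default_rng([seed, i])`, making runs bit-for-bit reproducible and
order-independent.  Scenarios that raise are recorded and excluded
with a count.  Because dose is exactly linear in dwell time, scenarios
differing only in the time parameter reuse the dose field
(d → s·d + offset·Σrates); the enumeration orders the time parameter
innermost and caches per-structure dose fields keyed by exactly the
parameters that affect them (the rectum, for instance, is untouched by
prostate-contour and rigid-motion anatomy changes).  The fold is
skipped when time clipping would break linearity.  These are pure
evaluation-order optimisations, equivalent to per-scenario
recomputation up to float associativity.

## Synthetic phantom

The phantom emulates an average single-fraction TRUS-planned case: an
ellipsoidal prostate (axis ratios 1.25 : 0.95 : 1.0 LR:AP:SI) contoured
in 2.5 mm slices and calibrated so the stacked-polygon volume equals
the target 38.1 cc exactly; a central 3 mm-radius urethra extending
9 mm more inferiorly and 6 mm more superiorly than the prostate; a
10 mm-radius posterior rectum tube extending 15 mm more inferiorly and
6 mm more superiorly.  Sixteen needles sit on a 5 mm template grid,
preferring the most peripheral holes within 80% of the elliptical
cross-section and at least 8 mm from the urethra axis; dwells step at
5 mm within 95% of the gland.  Initial dwell times use a fixed
peripheral-loading heuristic (longer toward the capsule and at the
base/apex ends), then a single global factor scales all times so
nominal prostate D90 equals the prescription — D90 is exactly linear
in that factor, so the guarded iteration converges in one step.

What the phantom does *not* emulate: inverse-optimized dwell times.  A
clinical optimizer shapes per-dwell times in 3D to cool the urethra
and limit V150/V200; the heuristic plan meets D90, V100 and both
rectum objectives but runs hot on V150/V200 and the urethra, and its
metric SDs under uncertainty are correspondingly larger than a
polished clinical plan's.  Tests that pass on the phantom therefore
demonstrate the correctness of the evaluation machinery (operators,
dose, metrics, statistics, envelope behaviour), not the clinical
quality of heuristic plans.  Non-convex anatomy (a curved rectum, a
lobed gland) is also not represented; slice-wise star-shaped polygons
are assumed by the contour resampling.

## Numerical choices and problem sizes

* Needle paths: interpolating B-spline (cubic where possible) through
  tip + dwells, 6000 points/needle (< 0.1 mm spacing); single-dwell
  needles extend 20 mm inferiorly (free length) so shifts have room.
  Nearest-point ties break to the lowest index.
* Slice-spacing tolerance 0.01 mm (float round-trip noise); DICOM
  decimal strings written at 8 significant digits (≤ 16 bytes), so
  DICOM round-trips are exact to ≤ 1e-6 mm.
* Default run sizes: 1000 probabilistic scenarios; the test suite and
  the acceptance script use 200 probabilistic scenarios plus the full
  3645-scenario worst-case set at 1 mm grid spacing, which a single
  core evaluates in a few minutes — chosen as the smallest ensemble
  that exercises every enumeration branch while leaving the envelope
  property clearly visible.
* Truncated-normal draws use `scipy.stats.truncnorm` (distributionally
  identical to rejection sampling of the untruncated normal).

## Known limitations

Transit dose, oedema, anatomy-aware collision constraints, robust
optimization and CTV–PTV margin derivation are out of scope.  The
worst-case set assumes extremes occur at the CI limits; interior
combinations could in principle be worse for a non-monotone metric,
though no probabilistic scenario has been observed outside the
worst-case envelope.  Clinical interpretation of robustness summaries
requires benchmarking against a historical cohort, which this package
does not provide.
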