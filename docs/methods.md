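# Methods

## Study design being modelled

The analysis chain emulates a protocol in which healthy adults walk
overground at 1.25 m/s for 30 min, pausing every 5 min for a thermal photo
of the sole of the foot. Each photo is manually segmented into five
plantar regions (hallux, MTP joint, midfoot, arch, heel); segmentation is
therefore an *input* to this package (integer label masks), never a
computation. The package covers everything downstream of segmentation.

## Regional statistics and the whole-foot series

Per frame, each region contributes its arithmetic pixel mean `T_r(t)` and
pixel count `A_r(t)`. The whole-foot temperature is the area-weighted
average `T_foot(t) = Σ A_r(t)·T_r(t) / Σ A_r(t)`. Areas are kept in pixel
units: any physical pixel size cancels in the ratio, so no camera
metadata is needed. Areas may change between frames (the foot is
re-photographed and re-segmented each pause); the weighted mean is
recomputed per frame and never cached.

Degenerate inputs: a region named in the label map but absent from a mask
is dropped with a warning; if the region *set* differs across time points,
the default policy renormalizes the weights over the regions present
(warning), and a strict mode raises instead. Pixel temperatures outside
10–50 °C warn (likely unit errors) but do not fail. Frames and masks must
share orientation; no flips are ever applied implicitly.

## Temporal models

Two models compete for each regional (or whole-foot) series:

* linear, `T = m·t + b` — the expected response if a fixed quantum of
  mechanically generated heat is added every stride;
* generalized logistic (Richards),
  `T(t) = A + (K−A)/(C + Q·e^{−B·t})^{1/ν}` — the S-shaped response
  expected when time-varying physiological heat exchange also operates.

The linear model is solved by least squares (`numpy.linalg.lstsq` on the
`[t, 1]` design); a property test pins it to the closed-form normal
equations. The logistic model is fitted with Levenberg–Marquardt
(`scipy.optimize.least_squares(method="lm")`) on the residuals
`T_model − T_obs`, with C, Q, B, ν optimized on a log scale so the power
base `C + Q·e^{−B·t}` stays positive without box constraints.

Numerical choices:

* default start `A = min(T)`, `K = max(T)`, `C = Q = ν = 1`,
  `B = 0.1 /min`; optional multi-start over
  `B ∈ {0.05, 0.1, 0.2, 0.5} × ν ∈ {0.1, 1, 5}` keeping the lowest
  residual sum of squares (never worse than the single start);
* tolerances `ftol = xtol = gtol = 1e-10`, at most 500 iterations per
  start; the fit is deterministic given identical inputs and starts, and
  non-convergence is returned flagged, never silently;
* the curve is evaluated as `exp(−log(base)/ν)` with the exponent clipped
  to ±700, so near-zero ν (exponents of order 1000, which occur in flat
  regions) cannot overflow;
* series shorter than the parameter count fall back to a trust-region
  reflective solver (same objective; LM requires at least as many
  residuals as parameters), and a warning flags the under-determined fit.

**Identifiability.** The six-parameter family is structurally
non-identifiable — rescaling C and Q jointly can be absorbed into K−A —
so the package asserts *curve* recovery (max absolute prediction error
≤ 1e−3 °C on a dense grid for noiseless inputs), never raw coefficient
equality.

**Fit criteria.** `ss_res = Σ(obs−pred)²`, `mse = ss_res/(n−p)`,
`s_res = √mse`, with p = 2 (linear) or 6 (logistic), so `mse = s_res²`
exactly. This denominator convention reproduces the published
linear-model criteria pairs exactly; the published *nonlinear* pairs are
not internally consistent with any single denominator convention, so the
linear-consistent definition is used globally and the discrepancy is
simply documented. When `n ≤ p` the criteria are NaN with a warning, and
any comparison involving them is flagged inconclusive. The model with the
strictly lower MSE wins; exact equality is a tie, never an arbitrary
winner. With 7 samples the logistic is charged a heavy penalty
(`n−p = 1` versus 5 for the line), so its winning is informative.

## Thermodynamic partition

Assuming the foot returns to the same mechanical energy state after each
stride, the net work of foot structures over a stride is dissipated as
heat, raising the foot temperature by

    ΔT_stride = −W_stride / (m_foot · c_foot)        [°C per stride]

Negative net work (dissipation) heats the foot. Parameters, with the
defaults used throughout the examples and acceptance script:

| parameter | meaning | default | unit |
|---|---|---|---|
| `W_stride_kJ` | net foot work per stride | −0.0034 (bounds −0.0071, +0.00023) | kJ |
| `m_foot_kg` | foot mass, 0.0145 × body mass | 1.17 (for 80.42 kg) | kg |
| `c_foot_kJ_per_kgK` | composite tissue specific heat | 1.96 (bounds 1.31 bone, 3.62 blood) | kJ·kg⁻¹·K⁻¹ |
| `total_strides` | strides in the walk | 1674 | — |
| `duration_min` | walk length | 30 | min |

**Units of c.** The literature table prints the specific-heat constant in
kJ/K, but the per-stride equation divides by `m·c`. Treating c as
kJ·kg⁻¹·K⁻¹ reproduces the quoted ~2.5 °C mechanical rise
(0.0034·1674/(1.17·1.96) = 2.48 °C), whereas kJ/K would give 2.90 °C;
this package uses kJ·kg⁻¹·K⁻¹.

The cumulative mechanical curve is
`ΔT_mech(t) = ΔT_stride · strides(t)`; the default stride schedule is a
constant cadence, `strides(t) = round(total · t/duration)`, and a
`StrideSchedule` object admits non-constant cadence. The curve equals an
explicit stride-by-stride accumulation loop to 1e−12 relative (tested).
The physiological contribution is the pointwise residual
`ΔT_phys = ΔT_exp − ΔT_mech`, so the conservation identity
`ΔT_mech + ΔT_phys = ΔT_exp` holds to machine precision by construction.
Envelopes re-run the mechanical curve at (W_low, W_high) with mean c and
at (c_low, c_high) with mean W; note the *more negative* work bound is
the *hotter* curve, and subtracting a hotter mechanical bound yields a
colder physiological bound.

The composite specific heat is a mass-fraction-weighted average of tissue
components (`Σ f_i·c_i`, fractions summing to 1 within 1e−9); by
convexity the result always lies between the bone and blood endpoints.
Mass weighting is the standard mixture rule; the exact tissue inventory
behind the 1.96 default is not published, so only the endpoints are
checkable.

**Burn extrapolation.** The default mode extrapolates purely mechanical
heating from a user-supplied whole-foot baseline:
`t* = (43.3 − baseline)/rate`, with `t* = 0` if the baseline already
exceeds the threshold and "never" if the rate is non-positive. The
source protocol's description is ambiguous between adding the mechanical
curve to the baseline value and to the time-varying experimental curve;
both are implemented (`mechanical_only`, `experimental_then_mechanical`)
and neither is asserted as canonical. The whole-foot *baseline* itself is
not published; examples and the acceptance script use 30.0 °C, a typical
resting plantar value, and the ~160 min / ~77.5 min crossing times are
conditional on it. Because the mechanical curve ignores energy lost to
sound, proximal transfer and cooling during the walk, it is an
upper-bound heating estimate, and the burn times are correspondingly
lower bounds for a mechanical-only world.

## Synthetic cohorts

The generator stands in for the study's raw thermal images. Defaults *are*
the emulated design: 8 participants, samples every 5 min over 30 min,
five regions with generalized-logistic ground-truth curves matching the
regional responses reported in healthy adults (hallux strongly S-shaped,
rising ~6 °C; arch/midfoot/heel flatter), additive i.i.d. Gaussian
measurement noise of 0.2 °C SD, and a per-participant vertical offset
(SD 0.5 °C) applied to both A and K, i.e. parallel shifts of the cohort
curve. The 0.2 °C within-series noise is a documented assumption — the
emulated study reports only between-participant SDs — chosen well below
the reported regional changes (2–6 °C). Region pixel areas default to
plausible plantar proportions (heel and MTP largest, hallux smallest);
geometry is abstract stacked rectangular blocks on a 22 °C ambient
background, since the weighted-average pipeline depends only on areas and
means, not on foot-shaped outlines.

Random streams are split hierarchically
(cohort → participant → region/frame) with `numpy` `SeedSequence`
spawning, so a fixed seed reproduces the cohort bit-for-bit and adding a
participant never perturbs earlier participants' draws. Frames are
rendered from the participant's noisy series values, so with zero spatial
noise the frame-derived regional means equal the series exactly.

What the generator does **not** emulate: sweating, perfusion dynamics,
shoe microclimate, camera noise structure (vignetting, drift), manual
segmentation error, or any between-region correlation of noise. Passing
tests therefore demonstrate correctness of the *pipeline* under the
stated noise model, not validity of the physiological conclusions for
real thermograms.

## Problem sizes

Tests and the acceptance script run at desk scale: 7 time points × 5
regions × 8 participants per cohort, 200 replicates for the
model-comparison win-rate experiment, 1,000 replicates for the generator
calibration check, and dense 601-point grids for curve-recovery checks.
The thermodynamic quantities are closed-form and instantaneous.

## Known limitations

* The decomposition attributes *everything* non-mechanical to
  "physiology"; environmental exchange is folded into that residual.
* The 77.5-min fast-crossing bound traces to a net-work distribution with
  one outlying participant in the source work data; it should be read as
  a sensitivity bound, not a likely scenario.
* Areas are pixel counts; comparing absolute areas across cameras or
  zoom levels is out of scope.
* No inferential statistics across participants are computed (none are
  defined for this design); cohort curves are simple means.
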