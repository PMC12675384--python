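# podotherm

Analysis of plantar (sole-of-foot) skin temperature during walking, for
researchers in thermal physiology and biomechanics. During a long walk the
sole warms by several °C; the open question is how much of that rise is
*mechanical* (net work dissipated by foot structures each stride, turned
into heat) and how much is *physiological* (skin blood flow through
capillaries and arteriovenous anastomoses, sweating, conduction,
convection). `podotherm` implements the full analysis chain:

1. **Regional extraction** (`podotherm.regions`) — per-region mean
   temperature and pixel area from thermal frames plus manual label masks
   (hallux, MTP, midfoot, arch, heel), and the area-weighted whole-foot
   temperature
   `T_foot(t) = Σ_r A_r(t)·T_r(t) / Σ_r A_r(t)`.
2. **Temporal models** (`podotherm.models`) — competing fits of each
   regional series: a line `T = m·t + b` versus the six-parameter
   generalized logistic (Richards) curve
   `T(t) = A + (K−A)/(C + Q·e^{−B·t})^{1/ν}`,
   fitted by Levenberg–Marquardt least squares and compared on
   `MSE = SS_res/(n−p)` and the residual SD `S_res = √MSE`.
   Both are scikit-learn estimators (`LinearTrendRegressor`,
   `GeneralizedLogisticRegressor`) and compose with sklearn pipelines.
3. **Thermodynamic partition** (`podotherm.thermo`) — per-stride heating
   `ΔT_stride = −W_stride/(m_foot·c_foot)` accumulated over the stride
   schedule gives the mechanical contribution `ΔT_mech(t)`; the
   physiological contribution is the residual
   `ΔT_phys(t) = ΔT_exp(t) − ΔT_mech(t)`. Bound envelopes repeat the
   calculation at the net-work bounds (mean ± 1 SD) and specific-heat
   bounds (bone … blood), and a linear extrapolation estimates the time to
   pass the first-degree-burn threshold (43.3 °C).
4. **Synthetic cohorts** (`podotherm.synthetic`) — seeded generators for
   regional series with known logistic ground truth, plus matching thermal
   frames and masks, so every stage is testable without study data.
5. **CLI** (`podotherm.cli`) — `podotherm simulate|extract|fit|partition|
   burn-time|run-all --config cfg.yaml --seed N --out DIR`.

## Worked example

```python
import numpy as np
import podotherm as pt

params = pt.ThermoParams(
    W_stride_kJ=-0.0034,      # net foot work per stride (negative = dissipation)
    m_foot_kg=1.17,           # 0.0145 x 80.42 kg body mass
    c_foot_kJ_per_kgK=1.96,   # composite tissue specific heat
    total_strides=1674,       # strides in a 30-min walk at 1.25 m/s
    duration_min=30.0,
    W_bounds=(-0.0071, 0.00023),
    c_bounds=(1.31, 3.62),
)
mech = pt.mechanical_curve(params)
print("per-stride heating:", pt.stride_delta_T(params), "degC")
print("mechanical rise over the walk:", mech.final_dT, "degC")

times = np.arange(0.0, 31.0, 5.0)
observed = pt.WholeFootSeries(times, 30.0 + np.linspace(0.0, 3.50, times.size))
part = pt.decompose(observed, pt.mechanical_curve(
    params, pt.StrideSchedule.constant_cadence(1674, 30.0, times=times)))
print("physiological residual at 30 min:", part.dT_phys[-1], "degC")

est = pt.burn_time(baseline_C=30.0, mech_rate_per_min=mech.rate_per_min)
print("time to 43.3 degC:", est.time_to_threshold_min, "min",
      "=", pt.walking_distance_km(est.time_to_threshold_min, 1.25), "km")
```

Output:

```
per-stride heating: 0.001482644339787197 degC
mechanical rise over the walk: 2.481946624803768 degC
physiological residual at 30 min: 1.018053375196232 degC
time to 43.3 degC: 160.7609108159392 min = 12.057068311195442 km
```

Reading: of a 3.50 °C whole-foot rise over a 30-min walk, mechanical
dissipation alone accounts for about 2.5 °C and the remaining ~1.0 °C is
attributed to physiological factors. If only mechanical heating operated,
the sole would not pass the first-degree-burn threshold until roughly
160 min (~12 km at 1.25 m/s) — or as early as ~77 min (~5.8 km) at the
strongest-dissipation net-work bound — which is why physiological
thermoregulation matters on long walks.

A full synthetic end-to-end run:

```
podotherm run-all --config examples/config.yaml --seed 42 --out out/
```

writes the cohort, regional stats, fit tables, the decomposition CSV
(with the conservation identity `dT_mech + dT_phys = dT_exp` holding row
by row) and a burn report with provenance.

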