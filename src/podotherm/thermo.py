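"""Thermodynamic partition of the walking foot-temperature rise.

The foot is assumed to return to the same mechanical energy state after
each stride, so the net work |W_stride| done by foot structures during a
stride is dissipated as heat. The per-stride temperature change is

    dT_stride = -W_stride / (m_foot * c_foot),

with W_stride in kJ (negative = net dissipation, which heats the foot),
m_foot in kg and c_foot in kJ·kg⁻¹·K⁻¹. Accumulated over the stride count
this yields the mechanical contribution dT_mech(t); the physiological
contribution is the residual

    dT_phys(t) = dT_exp(t) - dT_mech(t),

so mechanical + physiological reconstructs the experimental change exactly
at every time point. Bound envelopes repeat the computation at the
net-work bounds (mean ± 1 SD) and at the specific-heat bounds (bone and
blood). A linear extrapolation of the mechanical heating gives the time
at which the skin would pass the first-degree-burn threshold (43.3 °C).

The mechanical curve neglects energy lost to sound, proximal transfer and
conduction/convection during the walk, so it is an upper-bound estimate
of mechanical heating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .regions import WholeFootSeries

__all__ = [
    "BURN_THRESHOLD_C",
    "FOOT_MASS_FRACTION",
    "ThermoParams",
    "TissueComponent",
    "StrideSchedule",
    "MechanicalCurve",
    "MechanicalEnvelope",
    "DecompositionResult",
    "BurnEstimate",
    "foot_mass_from_body",
    "composite_specific_heat",
    "stride_delta_T",
    "mechanical_curve",
    "mechanical_envelope",
    "decompose",
    "burn_time",
    "walking_distance_km",
]

#: Skin temperature above which prolonged exposure may cause first-degree burns.
BURN_THRESHOLD_C = 43.3

#: Standardized segment anthropometry: foot mass as a fraction of body mass.
FOOT_MASS_FRACTION = 0.0145


@dataclass(frozen=True)
class ThermoParams:
    """Inputs to the mechanical-heating estimate.

    Parameters
    ----------
    W_stride_kJ : float
        Net foot work per stride, kJ, signed; negative = net dissipation.
    m_foot_kg : float
        Foot mass, kg.
    c_foot_kJ_per_kgK : float
        Composite specific heat of foot tissue, kJ·kg⁻¹·K⁻¹.
    total_strides : int
        Stride count over the walk.
    duration_min : float
        Walk length, minutes.
    W_bounds : (low, high) in kJ, optional
        Net-work bounds (e.g. mean ± 1 SD).
    c_bounds : (low, high) in kJ·kg⁻¹·K⁻¹, optional
        Specific-heat bounds (e.g. bone .. blood).
    """

    W_stride_kJ: float
    m_foot_kg: float
    c_foot_kJ_per_kgK: float
    total_strides: int
    duration_min: float
    W_bounds: tuple[float, float] | None = None
    c_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.m_foot_kg <= 0:
            raise ValueError("m_foot_kg must be positive")
        if self.c_foot_kJ_per_kgK <= 0:
            raise ValueError("c_foot_kJ_per_kgK must be positive")
        if self.total_strides < 0:
            raise ValueError("total_strides must be >= 0")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        for name in ("W_bounds", "c_bounds"):
            b = getattr(self, name)
            if b is not None:
                lo, hi = b
                if lo > hi:
                    raise ValueError(f"{name} must be ordered (low <= high)")
                object.__setattr__(self, name, (float(lo), float(hi)))

    def replace(self, **kw) -> "ThermoParams":
        from dataclasses import replace

        return replace(self, **kw)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ThermoParams":
        """Build from a config mapping (YAML/JSON keys match field names)."""
        def _pair(key):
            v = cfg.get(key)
            return None if v is None else (float(v[0]), float(v[1]))

        return cls(
            W_stride_kJ=float(cfg["W_stride_kJ"]),
            m_foot_kg=float(cfg["m_foot_kg"]),
            c_foot_kJ_per_kgK=float(cfg["c_foot_kJ_per_kgK"]),
            total_strides=int(cfg["total_strides"]),
            duration_min=float(cfg["duration_min"]),
            W_bounds=_pair("W_bounds"),
            c_bounds=_pair("c_bounds"),
        )


@dataclass(frozen=True)
class TissueComponent:
    """One tissue in the composite specific-heat mixture (mass fraction)."""

    name: str
    fraction: float
    c: float  # kJ·kg⁻¹·K⁻¹

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"{self.name}: fraction must be in [0, 1]")
        if self.c <= 0:
            raise ValueError(f"{self.name}: specific heat must be positive")


@dataclass(frozen=True)
class StrideSchedule:
    """Cumulative stride count over the walk.

    Starts at 0 strides at time 0 and is non-decreasing. The default is a
    constant cadence; a non-constant cadence can be supplied directly.
    """

    times: np.ndarray
    cumulative_strides: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.cumulative_strides, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ValueError("times and cumulative_strides must be equal-length 1-D")
        if t[0] != 0 or s[0] != 0:
            raise ValueError("schedule must start at 0 strides at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(s) < 0):
            raise ValueError("cumulative strides must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_strides", s)

    @property
    def total_strides(self) -> int:
        return int(round(self.cumulative_strides[-1]))

    @classmethod
    def constant_cadence(
        cls,
        total_strides: int,
        duration_min: float,
        times: Sequence[float] | None = None,
    ) -> "StrideSchedule":
        """Uniform cadence: cumulative_strides(t) = round(total * t/duration)."""
        if times is None:
            times = np.arange(0.0, duration_min + 1e-9, 5.0)
        t = np.asarray(times, dtype=float)
        cum = np.round(total_strides * t / duration_min)
        return cls(t, cum)


@dataclass(frozen=True)
class MechanicalCurve:
    """Cumulative mechanical temperature change dT_mech(t), °C."""

    times: np.ndarray
    dT: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.dT, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and dT must be equal-length 1-D arrays")
        if d[0] != 0:
            raise ValueError("mechanical curve must start at dT = 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dT", d)

    @property
    def final_dT(self) -> float:
        return float(self.dT[-1])

    @property
    def rate_per_min(self) -> float:
        """Mean heating rate over the walk, °C/min."""
        return float(self.dT[-1] / self.times[-1])


@dataclass(frozen=True)
class MechanicalEnvelope:
    """Mechanical curves at the input bounds.

    ``work_low``/``work_high`` use (W_low, W_high) with the mean specific
    heat; ``c_low``/``c_high`` use (c_low, c_high) with the mean work.
    Because dT = -W·strides/(m·c), the *low* work bound (more negative,
    more dissipation) gives the hottest curve.
    """

    work_low: MechanicalCurve
    work_high: MechanicalCurve
    c_low: MechanicalCurve
    c_high: MechanicalCurve


@dataclass(frozen=True)
class DecompositionResult:
    """Pointwise split dT_exp = dT_mech + dT_phys, with optional envelopes."""

    times: np.ndarray
    dT_exp: np.ndarray
    dT_mech: np.ndarray
    dT_phys: np.ndarray
    phys_envelopes: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        data = {
            "time_min": self.times,
            "dT_exp": self.dT_exp,
            "dT_mech": self.dT_mech,
            "dT_phys": self.dT_phys,
        }
        for k, v in self.phys_envelopes.items():
            data[k] = v
        return pd.DataFrame(data)


@dataclass(frozen=True)
class BurnEstimate:
    """Time for the foot surface to pass the first-degree-burn threshold."""

    threshold_C: float
    baseline_C: float
    mode: str
    time_to_threshold_min: float  # math.inf encodes "never"
    envelope_times_min: tuple[float, float] | None = None

    @property
    def reaches_threshold(self) -> bool:
        return math.isfinite(self.time_to_threshold_min)

    def to_dict(self) -> dict:
        def _t(x):
            return "never" if not math.isfinite(x) else x

        d = {
            "threshold_C": self.threshold_C,
            "baseline_C": self.baseline_C,
            "mode": self.mode,
            "time_to_threshold_min": _t(self.time_to_threshold_min),
        }
        if self.envelope_times_min is not None:
            d["envelope_times_min"] = [_t(x) for x in self.envelope_times_min]
        return d


def foot_mass_from_body(body_mass_kg: float, fraction: float = FOOT_MASS_FRACTION) -> float:
    """Foot mass from body mass via standardized segment anthropometry."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    return fraction * body_mass_kg


def composite_specific_heat(components: Sequence[TissueComponent]) -> float:
    """Mass-fraction-weighted specific heat of a tissue mixture.

    The result is convex: it always lies within [min c_i, max c_i].
    """
    if not components:
        raise ValueError("no tissue components supplied")
    total = sum(c.fraction for c in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"mass fractions sum to {total:.12g}, not 1 (deficit {1.0 - total:+.12g})"
        )
    return float(sum(c.fraction * c.c for c in components))


def stride_delta_T(params: ThermoParams) -> float:
    """Temperature change per stride: -W/(m·c), °C.

    Negative net work (dissipation) yields positive heating; the small
    positive upper work bound yields a (slightly) negative change.
    """
    return -params.W_stride_kJ / (params.m_foot_kg * params.c_foot_kJ_per_kgK)


def mechanical_curve(
    params: ThermoParams, schedule: StrideSchedule | None = None
) -> MechanicalCurve:
    """Accumulate the per-stride change over the stride schedule.

    dT(t) = stride_delta_T × cumulative_strides(t); identical to adding
    the per-stride change once per stride.
    """
    if schedule is None:
        schedule = StrideSchedule.constant_cadence(
            params.total_strides, params.duration_min
        )
    if schedule.total_strides != params.total_strides:
        raise ValueError(
            f"schedule total ({schedule.total_strides}) != params.total_strides "
            f"({params.total_strides})"
        )
    dT = stride_delta_T(params) * schedule.cumulative_strides
    return MechanicalCurve(schedule.times, dT)


def mechanical_envelope(
    params: ThermoParams, schedule: StrideSchedule | None = None
) -> MechanicalEnvelope:
    """Mechanical curves at the net-work and specific-heat bounds.

    Requires both ``W_bounds`` and ``c_bounds`` on ``params``; each pair of
    curves brackets the mean curve whenever the bounds bracket the mean
    inputs.
    """
    if params.W_bounds is None:
        raise ValueError("params.W_bounds is required for the envelope")
    if params.c_bounds is None:
        raise ValueError("params.c_bounds is required for the envelope")
    W_lo, W_hi = params.W_bounds
    c_lo, c_hi = params.c_bounds
    return MechanicalEnvelope(
        work_low=mechanical_curve(params.replace(W_stride_kJ=W_lo), schedule),
        work_high=mechanical_curve(params.replace(W_stride_kJ=W_hi), schedule),
        c_low=mechanical_curve(params.replace(c_foot_kJ_per_kgK=c_lo), schedule),
        c_high=mechanical_curve(params.replace(c_foot_kJ_per_kgK=c_hi), schedule),
    )


def decompose(
    exp_series: WholeFootSeries,
    mech: MechanicalCurve,
    envelope: MechanicalEnvelope | None = None,
    interpolate: bool = False,
) -> DecompositionResult:
    """Physiological residual: dT_phys(t) = dT_exp(t) - dT_mech(t).

    The mechanical curve must share the experimental time grid, or
    ``interpolate=True`` to linearly interpolate it (and any envelope)
    onto the experimental times. Envelope curves propagate by subtraction
    from the experimental change; note that the *hotter* mechanical bound
    yields the *colder* physiological bound.
    """
    t = exp_series.times
    d_exp = exp_series.delta

    def _on_grid(curve: MechanicalCurve) -> np.ndarray:
        if curve.times.shape == t.shape and np.allclose(curve.times, t):
            return curve.dT
        if not interpolate:
            raise ValueError(
                "mechanical curve time grid differs from the experimental grid "
                "(pass interpolate=True to interpolate)"
            )
        return np.interp(t, curve.times, curve.dT)

    d_mech = _on_grid(mech)
    envelopes: dict[str, np.ndarray] = {}
    if envelope is not None:
        envelopes = {
            "phys_low_work": d_exp - _on_grid(envelope.work_low),
            "phys_high_work": d_exp - _on_grid(envelope.work_high),
            "phys_low_c": d_exp - _on_grid(envelope.c_low),
            "phys_high_c": d_exp - _on_grid(envelope.c_high),
        }
    return DecompositionResult(
        times=t,
        dT_exp=d_exp,
        dT_mech=d_mech,
        dT_phys=d_exp - d_mech,
        phys_envelopes=envelopes,
    )


def burn_time(
    baseline_C: float,
    mech_rate_per_min: float,
    threshold_C: float = BURN_THRESHOLD_C,
    mode: str = "mechanical_only",
    exp_series: WholeFootSeries | None = None,
) -> BurnEstimate:
    """Extrapolated walking time to pass the burn threshold.

    ``mechanical_only`` (default): the smallest t >= 0 with
    baseline + rate·t >= threshold — 0 if already at or above the
    threshold, never (inf) if the rate is non-positive below it.

    ``experimental_then_mechanical``: follow the measured whole-foot
    temperature over the walk (absolute °C, from ``exp_series``), then
    continue at the mechanical rate from its final value. Crossings inside
    the measured window are located by linear interpolation.
    """
    if not math.isfinite(threshold_C):
        raise ValueError("threshold must be finite")
    if mode == "mechanical_only":
        if baseline_C >= threshold_C:
            t_hit = 0.0
        elif mech_rate_per_min <= 0:
            t_hit = math.inf
        else:
            t_hit = (threshold_C - baseline_C) / mech_rate_per_min
    elif mode == "experimental_then_mechanical":
        if exp_series is None:
            raise ValueError("exp_series is required for experimental_then_mechanical")
        temps = exp_series.temps
        times = exp_series.times
        if temps[0] >= threshold_C:
            t_hit = 0.0
        elif np.any(temps >= threshold_C):
            i = int(np.argmax(temps >= threshold_C))
            t0, t1 = times[i - 1], times[i]
            y0, y1 = temps[i - 1], temps[i]
            t_hit = float(t0 + (threshold_C - y0) * (t1 - t0) / (y1 - y0))
        elif mech_rate_per_min <= 0:
            t_hit = math.inf
        else:
            t_hit = float(times[-1] + (threshold_C - temps[-1]) / mech_rate_per_min)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BurnEstimate(
        threshold_C=threshold_C,
        baseline_C=baseline_C,
        mode=mode,
        time_to_threshold_min=t_hit,
    )


def walking_distance_km(time_min: float, speed_m_per_s: float) -> float:
    """Distance covered walking ``time_min`` minutes at ``speed_m_per_s``."""
    if not math.isfinite(time_min):
        return math.inf
    if time_min < 0 or speed_m_per_s < 0:
        raise ValueError("time and speed must be non-negative")
    return speed_m_per_s * time_min * 60.0 / 1000.0


def load_thermo_config(path: str | Path) -> dict:
    """Load a YAML or JSON thermo/tissue config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
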