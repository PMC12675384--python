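"""Temporal models for regional foot-temperature series.

Two competing models for temperature T versus walking time t (minutes):

* a straight line, ``T = m*t + b`` — the response expected if a constant
  amount of mechanical heat is deposited every stride;
* a six-parameter generalized logistic (Richards) curve,

      T(t) = A + (K - A) / (C + Q * exp(-B*t))**(1/nu),

  the S-shaped response expected when time-varying physiological factors
  (skin blood flow, sweating, conduction, convection) also contribute.

Both are exposed as scikit-learn regressors (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with pipelines and model selection, plus thin functional
wrappers operating on :class:`TemperatureSeries`.

Fit quality uses the residual sum of squares with p fitted parameters:
``mse = ss_res / (n - p)`` and ``s_res = sqrt(mse)``, so ``mse == s_res**2``
holds by construction. The model with the lower MSE wins the comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TemperatureSeries",
    "LinearFit",
    "LogisticFit",
    "FitCriteria",
    "FitComparison",
    "LinearTrendRegressor",
    "GeneralizedLogisticRegressor",
    "generalized_logistic",
    "evaluate_logistic",
    "fit_linear",
    "fit_logistic",
    "fit_criteria",
    "compare_models",
    "read_series_csv",
]

# Multi-start grid for the rate and shape parameters; spans the magnitudes
# seen in plantar data (B ~ 0.1-0.2 /min, nu from ~1e-3 to ~1).
_MULTISTART_B = (0.05, 0.1, 0.2, 0.5)
_MULTISTART_NU = (0.1, 1.0, 5.0)


@dataclass(frozen=True)
class TemperatureSeries:
    """A (time, temperature) series for one region or the whole foot."""

    times: np.ndarray
    temps: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.temps, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and temps must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and temps must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temps", y)

    def __len__(self) -> int:
        return self.times.size


class FitCriteria(NamedTuple):
    """Residual fit criteria: ``mse = ss_res/(n-p)``, ``s_res = sqrt(mse)``."""

    ss_res: float
    mse: float
    s_res: float


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line ``T = m*t + b`` with fit criteria."""

    m: float
    b: float
    ss_res: float
    mse: float
    s_res: float
    n: int

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.m * np.asarray(t, dtype=float) + self.b

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted generalized-logistic coefficients with fit criteria.

    A and K set the vertical placement (°C); C and Q are dimensionless
    shape factors; B is the rate (1/min); nu the asymmetry exponent.
    """

    A: float
    K: float
    C: float
    Q: float
    B: float
    nu: float
    ss_res: float
    mse: float
    s_res: float
    n: int
    converged: bool
    n_iter: int

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return generalized_logistic(t, self.A, self.K, self.C, self.Q, self.B, self.nu)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FitComparison:
    """MSE-based verdict between the linear and logistic fits of one series."""

    winner: str  # "linear" | "logistic" | "tie" | "inconclusive"
    linear_mse: float
    linear_s_res: float
    logistic_mse: float
    logistic_s_res: float

    def to_dict(self) -> dict:
        return asdict(self)


def generalized_logistic(
    t: np.ndarray | float,
    A: float,
    K: float,
    C: float,
    Q: float,
    B: float,
    nu: float,
) -> np.ndarray | float:
    """Evaluate the Richards curve ``A + (K-A)/(C + Q*exp(-B*t))**(1/nu)``.

    The power is computed as ``exp(-log(base)/nu)`` with the exponent
    clipped to ±700 so tiny nu (exponents of order 1000) cannot overflow.
    A non-positive base is a domain error.
    """
    t = np.asarray(t, dtype=float)
    base = C + Q * np.exp(-B * t)
    if np.any(base <= 0):
        raise ValueError("C + Q*exp(-B*t) must be positive")
    expo = np.clip(-np.log(base) / nu, -700.0, 700.0)
    out = A + (K - A) * np.exp(expo)
    return out if out.ndim else float(out)


# Name used in reports and the CLI; identical to generalized_logistic.
evaluate_logistic = generalized_logistic


def fit_criteria(
    observed: Sequence[float], predicted: Sequence[float], p: int
) -> FitCriteria:
    """Residual criteria for a fit with ``p`` free parameters.

    ``ss_res`` is always defined; ``mse`` and ``s_res`` use the residual
    degrees of freedom ``n - p`` and are NaN (with a warning) when
    ``n <= p``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    ss = float(np.sum((obs - pred) ** 2))
    if n <= p:
        warnings.warn(
            f"n={n} <= p={p}: residual degrees of freedom exhausted; "
            "mse and s_res undefined",
            stacklevel=2,
        )
        return FitCriteria(ss, math.nan, math.nan)
    mse = ss / (n - p)
    return FitCriteria(ss, mse, math.sqrt(mse))


class LinearTrendRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least-squares line through a temperature series.

    Follows the scikit-learn estimator protocol: ``X`` is the (n, 1) array
    of times in minutes, ``y`` the temperatures in °C.

    Attributes
    ----------
    slope_ : float
        m, °C/min.
    intercept_ : float
        b, °C.
    ss_res_, mse_, s_res_ : float
        Residual criteria with p = 2.
    n_ : int
        Number of points fitted.
    """

    def fit(self, X, y):
        t, y = _validate_xy(X, y)
        if t.size < 2:
            raise ValueError("need at least 2 points for a linear fit")
        if np.ptp(t) == 0:
            raise ValueError("singular fit: all time points identical")
        design = np.column_stack([t, np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.slope_ = float(coef[0])
        self.intercept_ = float(coef[1])
        self.n_ = int(t.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            crit = fit_criteria(y, design @ coef, p=2)
        self.ss_res_, self.mse_, self.s_res_ = crit
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * t + self.intercept_


class GeneralizedLogisticRegressor(RegressorMixin, BaseEstimator):
    """Richards-curve regressor fitted by Levenberg–Marquardt least squares.

    Positivity of C, Q, B and nu is enforced by optimizing their
    logarithms, which keeps the power base positive without explicit box
    constraints. The default start places A and K at the data extremes
    with C = Q = nu = 1 and B = 0.1 /min; ``multi_start=True`` adds a grid
    over B and nu and keeps the solution with the lowest residual sum of
    squares. The fit is deterministic given identical inputs and starts.

    Parameters
    ----------
    init : mapping, optional
        Starting values for any of A, K, C, Q, B, nu.
    multi_start : bool, default False
        Try the B × nu grid in addition to the (possibly user-supplied)
        default start.
    max_iter : int, default 500
        Iteration cap for each start.
    tol : float, default 1e-10
        Relative tolerance on the cost and step for convergence.

    Attributes
    ----------
    A_, K_, C_, Q_, B_, nu_ : float
        Fitted coefficients.
    ss_res_, mse_, s_res_ : float
        Residual criteria with p = 6 (NaN when n <= 6).
    converged_ : bool
        Whether the winning start satisfied the tolerances.
    n_iter_ : int
        Function evaluations used by the winning start.
    """

    _PARAM_NAMES = ("A", "K", "C", "Q", "B", "nu")

    def __init__(self, init=None, multi_start=False, max_iter=500, tol=1e-10):
        self.init = init
        self.multi_start = multi_start
        self.max_iter = max_iter
        self.tol = tol

    def _starts(self, y: np.ndarray) -> list[dict]:
        base = {
            "A": float(y.min()),
            "K": float(y.max()),
            "C": 1.0,
            "Q": 1.0,
            "B": 0.1,
            "nu": 1.0,
        }
        if self.init is not None:
            bad = set(self.init) - set(self._PARAM_NAMES)
            if bad:
                raise ValueError(f"unknown init parameters: {sorted(bad)}")
            for k in ("C", "Q", "B", "nu"):
                if k in self.init and self.init[k] <= 0:
                    raise ValueError(f"init {k} must be positive")
            base.update({k: float(v) for k, v in self.init.items()})
        starts = [base]
        if self.multi_start:
            for B in _MULTISTART_B:
                for nu in _MULTISTART_NU:
                    s = dict(base)
                    s["B"], s["nu"] = B, nu
                    starts.append(s)
        return starts

    def fit(self, X, y):
        t, y = _validate_xy(X, y)
        if t.size < 2:
            raise ValueError("need at least 2 points")
        if t.size <= 6:
            warnings.warn(
                f"fitting 6 parameters to {t.size} points: residual degrees "
                "of freedom are scarce or exhausted",
                stacklevel=2,
            )

        def residuals(theta: np.ndarray) -> np.ndarray:
            A, K = theta[0], theta[1]
            C, Q, B, nu = np.exp(theta[2:])
            return generalized_logistic(t, A, K, C, Q, B, nu) - y

        best = None
        for start in self._starts(y):
            theta0 = np.array(
                [
                    start["A"],
                    start["K"],
                    math.log(start["C"]),
                    math.log(start["Q"]),
                    math.log(start["B"]),
                    math.log(start["nu"]),
                ]
            )
            # Levenberg-Marquardt needs at least as many residuals as
            # parameters; under-determined series fall back to a trust-region
            # reflective solver (identical objective, no bounds).
            method = "lm" if t.size >= theta0.size else "trf"
            try:
                res = least_squares(
                    residuals,
                    theta0,
                    method=method,
                    ftol=self.tol,
                    xtol=self.tol,
                    gtol=self.tol,
                    max_nfev=self.max_iter * (theta0.size + 1),
                )
            except ValueError:
                continue
            ss = float(2.0 * res.cost)
            if best is None or ss < best[0]:
                best = (ss, res)
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        ss, res = best
        A, K = res.x[0], res.x[1]
        C, Q, B, nu = np.exp(res.x[2:])
        self.A_, self.K_, self.C_, self.Q_, self.B_, self.nu_ = (
            float(A),
            float(K),
            float(C),
            float(Q),
            float(B),
            float(nu),
        )
        self.converged_ = bool(res.status > 0)
        self.n_iter_ = int(res.nfev)
        self.n_ = int(t.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            crit = fit_criteria(y, generalized_logistic(t, A, K, C, Q, B, nu), p=6)
        self.ss_res_, self.mse_, self.s_res_ = crit
        if not self.converged_:
            warnings.warn(
                "logistic fit did not converge within the iteration budget",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return generalized_logistic(t, self.A_, self.K_, self.C_, self.Q_, self.B_, self.nu_)


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2:
        if t.shape[1] != 1:
            raise ValueError("X must be (n,) or (n, 1) times in minutes")
        t = t[:, 0]
    y = np.asarray(y, dtype=float).reshape(-1)
    if t.shape != y.shape:
        raise ValueError("X and y must have equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return t, y


def fit_linear(series: TemperatureSeries) -> LinearFit:
    """Ordinary least-squares line fit of a temperature series."""
    est = LinearTrendRegressor().fit(series.times, series.temps)
    return LinearFit(
        m=est.slope_,
        b=est.intercept_,
        ss_res=est.ss_res_,
        mse=est.mse_,
        s_res=est.s_res_,
        n=est.n_,
    )


def fit_logistic(
    series: TemperatureSeries,
    init: dict | None = None,
    multi_start: bool = False,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> LogisticFit:
    """Generalized-logistic fit of a temperature series (Levenberg–Marquardt)."""
    est = GeneralizedLogisticRegressor(
        init=init, multi_start=multi_start, max_iter=max_iter, tol=tol
    ).fit(series.times, series.temps)
    return LogisticFit(
        A=est.A_,
        K=est.K_,
        C=est.C_,
        Q=est.Q_,
        B=est.B_,
        nu=est.nu_,
        ss_res=est.ss_res_,
        mse=est.mse_,
        s_res=est.s_res_,
        n=est.n_,
        converged=est.converged_,
        n_iter=est.n_iter_,
    )


def compare_models(linear: LinearFit, logistic: LogisticFit) -> FitComparison:
    """Pick the model with the lower MSE; exact equality is a tie.

    Undefined criteria in either fit (NaN, from exhausted degrees of
    freedom) make the comparison inconclusive.
    """
    if math.isnan(linear.mse) or math.isnan(logistic.mse):
        winner = "inconclusive"
    elif logistic.mse < linear.mse:
        winner = "logistic"
    elif linear.mse < logistic.mse:
        winner = "linear"
    else:
        winner = "tie"
    return FitComparison(
        winner=winner,
        linear_mse=linear.mse,
        linear_s_res=linear.s_res,
        logistic_mse=logistic.mse,
        logistic_s_res=logistic.s_res,
    )


def read_series_csv(path) -> list[TemperatureSeries]:
    """Read series from CSV with columns time_min, temp_C and optional label.

    Returns one series per distinct label (a single unlabeled series reads
    as one series with an empty label).
    """
    import pandas as pd

    df = pd.read_csv(path)
    if not {"time_min", "temp_C"} <= set(df.columns):
        raise ValueError(f"{path}: need columns time_min and temp_C")
    if "label" not in df.columns:
        return [TemperatureSeries(df["time_min"].to_numpy(), df["temp_C"].to_numpy())]
    out = []
    for lab, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            TemperatureSeries(
                grp["time_min"].to_numpy(), grp["temp_C"].to_numpy(), label=str(lab)
            )
        )
    return out
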