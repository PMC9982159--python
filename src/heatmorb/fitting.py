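"""Two-stage iterative least-squares fitting with year-wise LOOCV.

For one location class the model for day t is

    y(t) = a * (exp(k(t) * u(t)) + l) * S,   k(t) = f * A(t) + g

with u the class's lag input, A the J-day adaptation average and S the
age-risk population sum. The stages alternate:

    1. (a, l) by linear least squares with k fixed,
    2. (f, g) by nonlinear least squares with (a, l) fixed,

warm-started from a log-linear regression, iterated to convergence, and
optionally polished by a joint nonlinear solve over all free parameters
(``a`` log-parameterized to stay positive). Each stage can only decrease
the shared sum-of-squares objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientHistoryError, SingularDesignError
from .exposure import AdaptationConfig, adaptation_series, indoor_lag_series
from .io import SeasonDataset
from .risk_model import (
    INPUT_COLUMNS,
    LocationParams,
    THERMO_INPUT_KINDS,
    population_risk_sum,
)
from .evaluation import r_squared

__all__ = [
    "FitConfig",
    "FoldFit",
    "FitResult",
    "build_design",
    "fit_scale_offset",
    "fit_adaptation",
    "fit_iterative",
    "loocv_by_year",
    "scan_adaptation_window",
]

logger = logging.getLogger(__name__)

Location = Literal["indoor", "outdoor"]

#: Regularizer added to per-capita counts inside the warm-start logarithm.
WARM_START_EPS = 0.1


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the two-stage fit for one location class."""

    input_kind: str = "average_temperature"
    J: int = 40
    l_policy: Literal["fixed", "free"] = "free"
    f_policy: Literal["free", "absent"] = "free"
    weight_shape: str = "linear_decreasing"
    max_iterations: int = 50
    convergence_tol: float = 1e-8
    objective: Literal["ols", "poisson"] = "ols"
    joint_polish: bool = True
    min_days: int = 10

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.input_kind in THERMO_INPUT_KINDS and self.l_policy != "fixed":
            raise ValueError(
                "l must be fixed at -1 for sweating / core-temperature inputs"
            )

    @classmethod
    def for_input(cls, input_kind: str, location: Location, J: int, **kw) -> "FitConfig":
        """Parameter-policy conventions per input kind and location class:
        temperature inputs fit all four parameters; thermophysiological
        inputs pin l = -1, and outdoor classes additionally drop f.
        """
        if input_kind in THERMO_INPUT_KINDS:
            l_policy = "fixed"
            f_policy = "absent" if location == "outdoor" else "free"
        else:
            l_policy, f_policy = "free", "free"
        if f_policy == "absent":
            J = 0
        return cls(
            input_kind=input_kind, J=J, l_policy=l_policy, f_policy=f_policy, **kw
        )


@dataclass
class IterativeFit:
    params: LocationParams
    iterations: int
    converged: bool
    objective_trace: list[float]


@dataclass
class FoldFit:
    year: int
    params: LocationParams
    prediction: pd.DataFrame  # date, y_pred
    r2: float
    fit: IterativeFit


@dataclass
class FitResult:
    location: Location
    folds: list[FoldFit]
    averaged: LocationParams

    @property
    def mean_r2(self) -> float:
        return float(np.mean([f.r2 for f in self.folds]))


def build_design(
    seasons: list[SeasonDataset],
    cfg: FitConfig,
    location: Location,
    drop_days: Optional[int] = None,
) -> pd.DataFrame:
    """Per-day design rows (u, A, y, S, year, date) pooled over seasons.

    Within each season the first ``max(J, 2)`` days are dropped (no
    zero-filling of missing lag history); ``drop_days`` overrides the
    default drop, e.g. to hold the evaluated day set fixed while J varies.
    """
    column = INPUT_COLUMNS[cfg.input_kind]
    use_adaptation = cfg.f_policy == "free"
    drop = max(cfg.J if use_adaptation else 0, 2)
    if drop_days is not None:
        drop = max(drop, int(drop_days))
    rows = []
    for season in seasons:
        expo = season.exposure
        if len(expo) <= drop:
            continue
        x = expo[column].to_numpy(dtype=float)
        if location == "indoor":
            u = indoor_lag_series(x)
        else:
            u = x.astype(float)
        if use_adaptation:
            adapt = adaptation_series(
                x, AdaptationConfig(J=cfg.J, weight_shape=cfg.weight_shape)
            )
        else:
            adapt = np.zeros_like(x)
        S = population_risk_sum(season.age)
        frame = pd.DataFrame(
            {
                "date": pd.to_datetime(expo["date"]),
                "u": u,
                "A": adapt,
                "S": S,
                "year": season.year,
            }
        ).iloc[drop:]
        counts = season.counts[["date", location]].rename(columns={location: "y"})
        counts = counts.assign(date=pd.to_datetime(counts["date"]))
        rows.append(frame.merge(counts, on="date", how="inner"))
    if not rows:
        raise InsufficientHistoryError("no season supplies enough lag history")
    design = pd.concat(rows, ignore_index=True)
    return design.dropna(subset=["u", "A", "y"]).reset_index(drop=True)


def _model(a, l, f, g, u, A, S):
    k = g if f is None else f * A + g
    return a * (np.exp(k * u) + l) * S


def _objective(y, pred) -> float:
    return float(np.sum((y - pred) ** 2))


def fit_scale_offset(design: pd.DataFrame, k, cfg: FitConfig) -> tuple[float, float]:
    """Stage 1: least-squares (a, l) with the exponent coefficient fixed.

    Closed form: with l free, regress y on [S*exp(k*u), S]; with l fixed
    at -1, project y on the single basis vector S*(exp(k*u) - 1).
    """
    y = design["y"].to_numpy(dtype=float)
    S = design["S"].to_numpy(dtype=float)
    z = np.exp(np.asarray(k, dtype=float) * design["u"].to_numpy(dtype=float))
    if cfg.l_policy == "fixed":
        basis = S * (z - 1.0)
        denom = float(basis @ basis)
        if denom <= 0 or not np.isfinite(denom):
            if np.allclose(y, 0.0):
                logger.warning("all-zero counts with zero exposure: a unidentifiable, set to 0")
                return 0.0, -1.0
            raise SingularDesignError("degenerate design: exp(k*u) constant at 1")
        a = float(basis @ y) / denom
        return max(a, 0.0), -1.0
    X = np.column_stack([S * z, S])
    if np.ptp(z) < 1e-12:
        raise SingularDesignError("degenerate design: constant exposure input")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha, beta = coef
    if alpha <= 0:
        # transient pathology during iteration; keep a positive and refit l
        alpha = max(alpha, 1e-12)
    return float(alpha), float(beta / alpha)


def fit_adaptation(
    design: pd.DataFrame,
    a: float,
    l: float,
    cfg: FitConfig,
    start: tuple[Optional[float], float],
) -> tuple[Optional[float], float]:
    """Stage 2: least-squares (f, g) with (a, l) fixed.

    With ``f_policy="absent"`` only g is fitted and f is returned as None.
    """
    y = design["y"].to_numpy(dtype=float)
    u = design["u"].to_numpy(dtype=float)
    A = design["A"].to_numpy(dtype=float)
    S = design["S"].to_numpy(dtype=float)
    f0, g0 = start

    if cfg.f_policy == "absent":
        def resid(theta):
            return a * (np.exp(theta[0] * u) + l) * S - y

        sol = least_squares(resid, x0=[g0], method="lm")
        return None, float(sol.x[0])

    if np.ptp(A) < 1e-12:
        raise SingularDesignError(
            "adaptation average is constant: slope f unidentifiable"
        )

    def resid(theta):
        return a * (np.exp((theta[0] * A + theta[1]) * u) + l) * S - y

    sol = least_squares(resid, x0=[0.0 if f0 is None else f0, g0], method="lm")
    return float(sol.x[0]), float(sol.x[1])


def _warm_start(design: pd.DataFrame, cfg: FitConfig) -> tuple[float, float, Optional[float], float]:
    """Log-linear initialization: regress log(y/S + eps) on u for (g, a)."""
    y = design["y"].to_numpy(dtype=float)
    u = design["u"].to_numpy(dtype=float)
    S = design["S"].to_numpy(dtype=float)
    w = np.log(y / S + WARM_START_EPS)
    if np.ptp(u) < 1e-12:
        raise SingularDesignError("constant exposure input: model unidentifiable")
    g, log_a = np.polyfit(u, w, 1)
    a = float(np.exp(log_a))
    l = -1.0
    f = None if cfg.f_policy == "absent" else 0.0
    return a, l, f, float(g)


def _joint_polish(
    design: pd.DataFrame, a, l, f, g, cfg: FitConfig
) -> tuple[float, float, Optional[float], float]:
    y = design["y"].to_numpy(dtype=float)
    u = design["u"].to_numpy(dtype=float)
    A = design["A"].to_numpy(dtype=float)
    S = design["S"].to_numpy(dtype=float)
    free_l = cfg.l_policy == "free"
    free_f = cfg.f_policy == "free"

    def unpack(theta):
        i = 1
        aa = np.exp(theta[0])
        ll = theta[i] if free_l else l
        i += free_l
        ff = theta[i] if free_f else None
        i += free_f
        return aa, ll, ff, theta[i]

    def resid(theta):
        aa, ll, ff, gg = unpack(theta)
        k = gg if ff is None else ff * A + gg
        return aa * (np.exp(k * u) + ll) * S - y

    theta0 = [np.log(max(a, 1e-300))]
    if free_l:
        theta0.append(l)
    if free_f:
        theta0.append(0.0 if f is None else f)
    theta0.append(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = least_squares(resid, x0=theta0, method="lm", max_nfev=2000)
    aa, ll, ff, gg = unpack(sol.x)
    return float(aa), float(ll), None if ff is None else float(ff), float(gg)


def fit_iterative(design: pd.DataFrame, cfg: FitConfig) -> IterativeFit:
    """Alternate the two stages to convergence; return the best iterate.

    Convergence is declared when the maximum relative parameter change
    over one full (a, l) -> (f, g) sweep falls below ``convergence_tol``.
    """
    if len(design) < cfg.min_days:
        raise InsufficientHistoryError(
            f"need at least {cfg.min_days} usable days, got {len(design)}"
        )
    y = design["y"].to_numpy(dtype=float)
    u = design["u"].to_numpy(dtype=float)
    A = design["A"].to_numpy(dtype=float)
    S = design["S"].to_numpy(dtype=float)

    a, l, f, g = _warm_start(design, cfg)
    if cfg.l_policy == "free":
        l = -1.0
    trace: list[float] = []
    converged = False
    iterations = 0
    best = (np.inf, (a, l, f, g))
    for iterations in range(1, cfg.max_iterations + 1):
        prev = np.array([a, l if cfg.l_policy == "free" else 0.0,
                         0.0 if f is None else f, g])
        k = g if f is None else f * A + g
        with np.errstate(over="ignore"):
            a, l = fit_scale_offset(design, k, cfg)
            trace.append(_objective(y, _model(a, l, f, g, u, A, S)))
            f, g = fit_adaptation(design, a, l, cfg, start=(f, g))
        obj = _objective(y, _model(a, l, f, g, u, A, S))
        trace.append(obj)
        if cfg.joint_polish:
            # joint refinement of the sweep's iterate; least_squares never
            # returns a worse point than its start, so the trace stays
            # monotone and the stage coupling cannot stall the iteration
            cand = _joint_polish(design, a, l, f, g, cfg)
            cand_obj = _objective(y, _model(*cand, u, A, S))
            if cand_obj <= obj:
                a, l, f, g = cand
                obj = cand_obj
                trace.append(obj)
        if obj < best[0]:
            best = (obj, (a, l, f, g))
        cur = np.array([a, l if cfg.l_policy == "free" else 0.0,
                        0.0 if f is None else f, g])
        rel = np.max(np.abs(cur - prev) / (np.abs(prev) + 1e-12))
        if rel < cfg.convergence_tol:
            converged = True
            break
    a, l, f, g = best[1]
    params = LocationParams(
        a=max(a, 0.0),
        l=l,
        g=g,
        f=f,
        input_kind=cfg.input_kind,
        J=cfg.J if cfg.f_policy == "free" else 0,
    )
    return IterativeFit(
        params=params, iterations=iterations, converged=converged, objective_trace=trace
    )


def _predict(design: pd.DataFrame, p: LocationParams) -> np.ndarray:
    pred = _model(
        p.a,
        p.l,
        p.f,
        p.g,
        design["u"].to_numpy(dtype=float),
        design["A"].to_numpy(dtype=float),
        design["S"].to_numpy(dtype=float),
    )
    return np.maximum(pred, 0.0)


def _mean_params(sets: list[LocationParams], cfg: FitConfig) -> LocationParams:
    fs = [p.f for p in sets]
    f = None if fs[0] is None else float(np.mean(fs))
    return LocationParams(
        a=float(np.mean([p.a for p in sets])),
        l=float(np.mean([p.l for p in sets])),
        g=float(np.mean([p.g for p in sets])),
        f=f,
        input_kind=cfg.input_kind,
        J=sets[0].J,
    )


def loocv_by_year(
    seasons: list[SeasonDataset],
    cfg: FitConfig,
    location: Location = "indoor",
    drop_days: Optional[int] = None,
) -> FitResult:
    """Leave-one-year-out fit: train on the pooled other years, predict the
    held-out year; the reported parameter set is the across-fold mean."""
    if len(seasons) < 3:
        raise InsufficientHistoryError("LOOCV by year needs at least 3 seasons")
    design = build_design(seasons, cfg, location, drop_days=drop_days)
    folds = []
    for season in seasons:
        train = design[design["year"] != season.year]
        test = design[design["year"] == season.year]
        if len(test) == 0:
            logger.warning("year %s has no usable days; excluded", season.year)
            continue
        fit = fit_iterative(train.reset_index(drop=True), cfg)
        pred = _predict(test, fit.params)
        r2 = r_squared(test["y"].to_numpy(dtype=float), pred)
        folds.append(
            FoldFit(
                year=season.year,
                params=fit.params,
                prediction=pd.DataFrame({"date": test["date"], "y_pred": pred}),
                r2=r2,
                fit=fit,
            )
        )
    if not folds:
        raise InsufficientHistoryError("no usable folds")
    averaged = _mean_params([f.params for f in folds], cfg)
    return FitResult(location=location, folds=folds, averaged=averaged)


def scan_adaptation_window(
    seasons: list[SeasonDataset],
    cfg: FitConfig,
    J_range,
    location: Location = "indoor",
) -> pd.DataFrame:
    """Mean held-out R² as a function of the adaptation window length J.

    All window lengths are scored on a common day subset (the days with
    enough history for the largest J considered) so the R² values are
    comparable across J.
    """
    min_len = min(len(s.exposure) for s in seasons)
    usable = [int(J) for J in J_range if J < min_len]
    for J in J_range:
        if J >= min_len:
            logger.warning("J=%d exceeds available history; skipped", J)
    if not usable:
        return pd.DataFrame(columns=["J", "mean_r2"])
    common_drop = max(max(usable), 2)
    rows = []
    for J in usable:
        result = loocv_by_year(
            seasons, replace(cfg, J=J), location, drop_days=common_drop
        )
        rows.append({"J": J, "mean_r2": result.mean_r2})
    return pd.DataFrame(rows)
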