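"""Scoring of daily estimates against observed counts.

Metrics: coefficient of determination (1 - SS_res/SS_tot, computed on
held-out predictions, not squared correlation), MAE normalized to a
million population, an overall-regression F-test, a binned seasonal MAE
profile, and the hot-day (WBGT >= 31 °C) error summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvariantError
from .exposure import hot_day_mask

__all__ = [
    "r_squared",
    "mae_per_million",
    "f_test",
    "seasonal_mae_profile",
    "hot_day_errors",
    "HotDayErrors",
    "EvaluationReport",
    "evaluate",
]


def _aligned(observed, estimated):
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.shape != est.shape:
        raise InvariantError(
            f"observed and estimated lengths differ: {obs.shape} vs {est.shape}"
        )
    return obs, est


def r_squared(observed, estimated) -> float:
    """1 - SS_res/SS_tot. Undefined (error) for constant observations."""
    obs, est = _aligned(observed, estimated)
    if obs.size < 2:
        raise InvariantError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise InvariantError("R^2 undefined: observed series is constant")
    ss_res = float(np.sum((obs - est) ** 2))
    return 1.0 - ss_res / ss_tot


def mae_per_million(observed, estimated, population: float) -> float:
    """Mean absolute daily error scaled to one million population."""
    if population <= 0:
        raise InvariantError("population must be positive")
    obs, est = _aligned(observed, estimated)
    return float(np.mean(np.abs(obs - est)) * 1e6 / population)


def f_test(observed, estimated, n_params: int) -> float:
    """p-value of the overall-regression F statistic.

    Tests the fitted model (``n_params`` fitted parameters beyond the
    intercept-equivalent) against the intercept-only model:

        F = ((SS_tot - SS_res)/p) / (SS_res/(n - p - 1))

    with (p, n - p - 1) degrees of freedom.
    """
    obs, est = _aligned(observed, estimated)
    n = obs.size
    if n <= n_params + 1:
        raise InvariantError("too few observations for the requested F-test")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - est) ** 2))
    if ss_tot == 0.0:
        raise InvariantError("degenerate residuals: observed series is constant")
    if ss_res == 0.0:
        return 0.0
    fstat = ((ss_tot - ss_res) / n_params) / (ss_res / (n - n_params - 1))
    return float(stats.f.sf(fstat, n_params, n - n_params - 1))


def seasonal_mae_profile(
    observed: pd.DataFrame,
    estimated: pd.DataFrame,
    population: float,
    bin_days: int = 10,
) -> pd.DataFrame:
    """Within-season MAE-per-million profile in consecutive calendar bins.

    Days are indexed by day-of-season (days since each season's first
    calendar day, pooled over years by month/day) and grouped into
    ``bin_days``-wide bins. Returns per-bin pooled MAE and the standard
    deviation of per-year bin MAEs.
    """
    if bin_days < 1:
        raise InvariantError("bin_days must be >= 1")
    merged = observed.merge(estimated, on="date")
    dates = pd.to_datetime(merged["date"])
    err = (merged["total"] - merged["y"]).abs() * 1e6 / population
    doy = dates.dt.dayofyear
    season_day = doy - doy.groupby(dates.dt.year).transform("min")
    frame = pd.DataFrame(
        {
            "bin": (season_day // bin_days).astype(int),
            "year": dates.dt.year,
            "err": err,
        }
    )
    pooled = frame.groupby("bin")["err"].mean().rename("mae_per_million")
    per_year = frame.groupby(["bin", "year"])["err"].mean()
    sd = per_year.groupby("bin").std(ddof=0).rename("sd_across_years")
    out = pd.concat([pooled, sd], axis=1).reset_index()
    out["start_day"] = out["bin"] * bin_days
    return out


@dataclass
class HotDayErrors:
    differences: pd.DataFrame  # date, diff_per_million (observed - estimated)
    mae_per_million: Optional[float]
    n_days: int


def hot_day_errors(
    observed: pd.DataFrame,
    estimated: pd.DataFrame,
    population: float,
    exposure: pd.DataFrame,
    threshold: float = 31.0,
) -> HotDayErrors:
    """Signed per-day errors restricted to WBGT >= threshold dates.

    Differences are observed minus estimated, per million population.
    With an empty mask the MAE is reported as None and n_days = 0.
    """
    mask = hot_day_mask(exposure, threshold)
    merged = observed.merge(estimated, on="date")
    merged = merged[pd.to_datetime(merged["date"]).isin(mask)]
    diffs = (merged["total"] - merged["y"]) * 1e6 / population
    frame = pd.DataFrame({"date": merged["date"], "diff_per_million": diffs})
    if len(frame) == 0:
        return HotDayErrors(differences=frame, mae_per_million=None, n_days=0)
    return HotDayErrors(
        differences=frame.reset_index(drop=True),
        mae_per_million=float(diffs.abs().mean()),
        n_days=int(len(frame)),
    )


@dataclass
class EvaluationReport:
    r2_all: float
    r2_indoor: float
    r2_outdoor: float
    mae_all: float
    mae_indoor: float
    mae_outdoor: float
    f_p_indoor: float
    f_p_outdoor: float
    profile: pd.DataFrame
    hot_days: HotDayErrors

    def to_dict(self) -> dict:
        return {
            "r2": {"all": self.r2_all, "indoor": self.r2_indoor, "outdoor": self.r2_outdoor},
            "mae_per_million": {
                "all": self.mae_all,
                "indoor": self.mae_indoor,
                "outdoor": self.mae_outdoor,
            },
            "f_test_p": {"indoor": self.f_p_indoor, "outdoor": self.f_p_outdoor},
            "hot_days": {
                "n_days": self.hot_days.n_days,
                "mae_per_million": self.hot_days.mae_per_million,
            },
        }


def evaluate(
    observed: pd.DataFrame,
    estimated: pd.DataFrame,
    population: float,
    exposure: pd.DataFrame,
    n_params_indoor: int = 4,
    n_params_outdoor: int = 4,
    bin_days: int = 10,
    threshold: float = 31.0,
) -> EvaluationReport:
    """Full metric suite for aligned observed counts and estimates."""
    merged = observed.merge(estimated, on="date")
    return EvaluationReport(
        r2_all=r_squared(merged["total"], merged["y"]),
        r2_indoor=r_squared(merged["indoor"], merged["y_in"]),
        r2_outdoor=r_squared(merged["outdoor"], merged["y_out"]),
        mae_all=mae_per_million(merged["total"], merged["y"], population),
        mae_indoor=mae_per_million(merged["indoor"], merged["y_in"], population),
        mae_outdoor=mae_per_million(merged["outdoor"], merged["y_out"], population),
        f_p_indoor=f_test(merged["indoor"], merged["y_in"], n_params_indoor),
        f_p_outdoor=f_test(merged["outdoor"], merged["y_out"], n_params_outdoor),
        profile=seasonal_mae_profile(observed, estimated, population, bin_days),
        hot_days=hot_day_errors(observed, estimated, population, exposure, threshold),
    )
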