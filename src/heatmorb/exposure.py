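"""Per-day model inputs: daily aggregates, lag operators, WBGT, hot-day mask.

An exposure frame has one row per day with columns

    date, mean_temp_c, max_temp_c, peak_core_increase_c, total_sweat_g, wbgt_c

Lagged operators treat contiguous date runs ("seasons") independently and
never borrow history across a season boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .errors import InsufficientHistoryError, InvariantError, SchemaError

__all__ = [
    "EXPOSURE_COLUMNS",
    "AdaptationConfig",
    "adaptation_weights",
    "daily_aggregate",
    "indoor_lag_input",
    "indoor_lag_series",
    "adaptation_average",
    "adaptation_series",
    "compute_wbgt",
    "hot_day_mask",
    "build_exposure",
    "iter_seasons",
]

EXPOSURE_COLUMNS = [
    "date",
    "mean_temp_c",
    "max_temp_c",
    "peak_core_increase_c",
    "total_sweat_g",
    "wbgt_c",
]

#: 3-day weights applied to (today, yesterday, two days ago) for indoor cases.
INDOOR_LAG_WEIGHTS = (0.6, 0.2, 0.2)

#: Outdoor-WBGT regression coefficients (temperature/humidity terms of the
#: Ono & Tonouchi approximation used operationally in Japan; solar and wind
#: terms dropped because the pipeline carries neither):
#:     WBGT = 0.735*T + 0.0374*RH + 0.00292*T*RH - 4.064
WBGT_COEFFS = {"t": 0.735, "rh": 0.0374, "t_rh": 0.00292, "const": -4.064}


@dataclass(frozen=True)
class AdaptationConfig:
    """Trailing-window configuration for the heat-adaptation average."""

    J: int
    weight_shape: Literal["linear_decreasing", "uniform"] = "linear_decreasing"

    def __post_init__(self):
        if self.J < 1:
            raise InvariantError(f"window length J must be >= 1, got {self.J}")
        if self.weight_shape not in ("linear_decreasing", "uniform"):
            raise InvariantError(f"unknown weight shape {self.weight_shape!r}")


def adaptation_weights(cfg: AdaptationConfig) -> np.ndarray:
    """Weights w_1..w_J over lags 1..J (most recent first), summing to 1.

    linear_decreasing: w_i = 2*(J - i + 1) / (J*(J + 1)).
    """
    J = cfg.J
    if cfg.weight_shape == "uniform":
        return np.full(J, 1.0 / J)
    i = np.arange(1, J + 1)
    return 2.0 * (J - i + 1) / (J * (J + 1))


def iter_seasons(frame: pd.DataFrame) -> Iterator[tuple[int, pd.DataFrame]]:
    """Yield (season_id, sub-frame) for each contiguous run of daily dates."""
    if len(frame) == 0:
        return
    dates = pd.to_datetime(frame["date"])
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise InvariantError("dates must be strictly increasing")
    breaks = dates.diff().dt.days.fillna(1).ne(1).cumsum()
    for sid, sub in frame.groupby(breaks.to_numpy()):
        yield int(sid), sub.reset_index(drop=True)


def daily_aggregate(weather: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-day mean and max temperature from a sub-daily series."""
    if len(weather) == 0:
        raise SchemaError("empty weather series")
    ts = pd.to_datetime(weather["timestamp"])
    grouped = weather.groupby(ts.dt.normalize())["temp_c"]
    out = grouped.agg(mean_temp_c="mean", max_temp_c="max").reset_index(
        names="date"
    )
    return out


def indoor_lag_series(x: np.ndarray) -> np.ndarray:
    """3-day weighted input 0.6*x_t + 0.2*x_{t-1} + 0.2*x_{t-2}.

    The first two entries, which lack history, are NaN.
    """
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    if len(x) >= 3:
        w0, w1, w2 = INDOOR_LAG_WEIGHTS
        out[2:] = w0 * x[2:] + w1 * x[1:-1] + w2 * x[:-2]
    return out


def indoor_lag_input(x, t: int) -> float:
    """3-day weighted input at integer position ``t`` of series ``x``."""
    x = np.asarray(x, dtype=float)
    if t < 2 or t >= len(x):
        raise InsufficientHistoryError(
            f"day {t} lacks the 2 preceding days required by the 3-day input"
        )
    w0, w1, w2 = INDOOR_LAG_WEIGHTS
    return float(w0 * x[t] + w1 * x[t - 1] + w2 * x[t - 2])


def adaptation_series(x: np.ndarray, cfg: AdaptationConfig) -> np.ndarray:
    """Trailing J-day weighted average over lags 1..J for every position.

    Excludes the current day; positions with fewer than J preceding days
    are NaN.
    """
    x = np.asarray(x, dtype=float)
    w = adaptation_weights(cfg)
    out = np.full_like(x, np.nan)
    J = cfg.J
    if len(x) > J:
        # row t uses x[t-1] ... x[t-J] weighted w_1 ... w_J
        windows = np.lib.stride_tricks.sliding_window_view(x, J)[:-1]
        out[J:] = windows @ w[::-1]
    return out


def adaptation_average(x, t: int, cfg: AdaptationConfig) -> float:
    """Adaptation average at integer position ``t`` of series ``x``."""
    x = np.asarray(x, dtype=float)
    if t < cfg.J or t >= len(x):
        raise InsufficientHistoryError(
            f"day {t} lacks the {cfg.J} preceding days required by the window"
        )
    w = adaptation_weights(cfg)
    return float(np.dot(w, x[t - 1 :: -1][: cfg.J]))


def compute_wbgt(temp_c, rh_pct):
    """Outdoor WBGT (°C) from temperature and relative humidity.

    Direct evaluation of the documented regression (see ``WBGT_COEFFS``);
    monotone nondecreasing in both arguments on the domain of interest.
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise InvariantError("relative humidity must lie in [0, 100] %")
    c = WBGT_COEFFS
    out = c["t"] * t + c["rh"] * rh + c["t_rh"] * t * rh + c["const"]
    return float(out) if out.ndim == 0 else out


def hot_day_mask(exposure: pd.DataFrame, threshold: float = 31.0) -> set:
    """Dates whose WBGT is at or above ``threshold`` (default 31 °C)."""
    if "wbgt_c" not in exposure.columns or exposure["wbgt_c"].isna().all():
        raise SchemaError("exposure frame has no populated wbgt_c column")
    hot = exposure.loc[exposure["wbgt_c"] >= threshold, "date"]
    return set(pd.to_datetime(hot))


def build_exposure(
    weather: pd.DataFrame, thermo_daily: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the exposure frame from weather and (optional) thermo output.

    Daily WBGT is the max of hourly WBGT, since the index is used to flag
    hot days. When ``thermo_daily`` is None the thermophysiological columns
    are zero-filled (valid only for temperature-input analyses).
    """
    daily = daily_aggregate(weather)
    wbgt_hourly = compute_wbgt(weather["temp_c"], weather["rh_pct"])
    days = pd.to_datetime(weather["timestamp"]).dt.normalize()
    wbgt = (
        pd.DataFrame({"date": days, "wbgt_c": wbgt_hourly})
        .groupby("date")["wbgt_c"]
        .max()
        .reset_index()
    )
    out = daily.merge(wbgt, on="date", how="left")
    if thermo_daily is not None:
        thermo = thermo_daily.copy()
        thermo["date"] = pd.to_datetime(thermo["date"])
        out = out.merge(
            thermo[["date", "peak_core_increase_c", "total_sweat_g"]],
            on="date",
            how="left",
        )
        if out[["peak_core_increase_c", "total_sweat_g"]].isna().any().any():
            raise SchemaError("thermo daily summaries do not cover all weather days")
    else:
        out["peak_core_increase_c"] = 0.0
        out["total_sweat_g"] = 0.0
    return out[EXPOSURE_COLUMNS]
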