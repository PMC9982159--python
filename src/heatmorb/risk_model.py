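"""Nonlinear indoor/outdoor daily morbidity model.

Expected daily counts are

    y(t)     = y_in(t) + y_out(t)
    y_in(t)  = a_in  * (exp(k_in(t)  * u_in(t))  + l_in)  * S
    y_out(t) = a_out * (exp(k_out(t) * u_out(t)) + l_out) * S
    k(t)     = f * A(t) + g          (k = g when f is absent)

where ``u_in`` is the 3-day weighted input (weights 0.6/0.2/0.2),
``u_out`` is the same-day input, ``A(t)`` is the trailing J-day weighted
average of the input (heat-adaptation term) and ``S`` is the
age-composition risk sum ``sum_n P(n) * (b*exp(c*n) + d)``.

Negative model values are floored at zero: expected counts cannot be
negative, and with ``l = -1`` the model vanishes exactly at zero heat
load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .errors import InsufficientHistoryError, InvariantError
from . import exposure as _exposure

__all__ = [
    "N_AGE_CATEGORIES",
    "INPUT_COLUMNS",
    "AgeComposition",
    "AgeRiskConstants",
    "LocationParams",
    "RiskParameters",
    "age_risk_weight",
    "population_risk_sum",
    "adaptation_coefficient",
    "estimate_indoor",
    "estimate_outdoor",
    "estimate_series",
    "estimate_with_band",
]

#: Number of 5-year adult age categories: n=1 (20-24) ... n=14 (85+).
N_AGE_CATEGORIES = 14

#: Exposure-frame column backing each input-variable kind.
INPUT_COLUMNS = {
    "average_temperature": "mean_temp_c",
    "sweating": "total_sweat_g",
    "core_temperature_increase": "peak_core_increase_c",
}

InputKind = Literal["average_temperature", "sweating", "core_temperature_increase"]

#: Input kinds that may be exactly zero on cool days; for these the model
#: offset is pinned to -1 so estimates vanish at zero heat load.
THERMO_INPUT_KINDS = frozenset({"sweating", "core_temperature_increase"})


@dataclass(frozen=True)
class AgeRiskConstants:
    """Constants of the age-risk regression curve ``b*exp(c*n) + d``."""

    b: float = 0.171
    c: float = 0.494
    d: float = 190.7

    def __post_init__(self):
        if self.b < 0 or self.c <= 0:
            raise InvariantError("age-risk constants require b >= 0 and c > 0")


@dataclass(frozen=True)
class AgeComposition:
    """Population fractions over the 14 adult 5-year age categories."""

    fractions: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.fractions, dtype=float)
        if arr.shape != (N_AGE_CATEGORIES,):
            raise InvariantError(
                f"age composition must have {N_AGE_CATEGORIES} categories, got {arr.shape}"
            )
        if np.any(arr < 0):
            raise InvariantError("age composition fractions must be nonnegative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise InvariantError(
                f"age composition must sum to 1 (got {arr.sum():.12f})"
            )
        object.__setattr__(self, "fractions", arr)

    @classmethod
    def uniform(cls) -> "AgeComposition":
        return cls(np.full(N_AGE_CATEGORIES, 1.0 / N_AGE_CATEGORIES))

    @classmethod
    def from_counts(cls, counts) -> "AgeComposition":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum())

    def mean_category(self) -> float:
        return float(np.dot(np.arange(1, N_AGE_CATEGORIES + 1), self.fractions))


@dataclass
class LocationParams:
    """Full parameter set for one location class (indoor or outdoor).

    ``f`` may be ``None`` (no adaptation slope), in which case ``k = g``
    for every day and ``J`` is ignored (conventionally 0).
    """

    a: float
    l: float
    g: float
    f: Optional[float] = None
    input_kind: InputKind = "average_temperature"
    J: int = 0

    def __post_init__(self):
        if self.a < 0:
            raise InvariantError(f"scale parameter a must be >= 0, got {self.a}")
        if self.input_kind not in INPUT_COLUMNS:
            raise InvariantError(f"unknown input kind {self.input_kind!r}")
        if self.f is not None and self.J < 1:
            raise InvariantError("J >= 1 required when the adaptation slope f is present")
        if self.input_kind in THERMO_INPUT_KINDS and self.l != -1.0:
            raise InvariantError(
                "l must be exactly -1 for sweating / core-temperature inputs"
            )

    @property
    def history_days(self) -> int:
        """Days of history a day needs before it can be estimated."""
        j = self.J if self.f is not None else 0
        return max(j, 2)


@dataclass
class RiskParameters:
    indoor: LocationParams
    outdoor: LocationParams
    constants: AgeRiskConstants = field(default_factory=AgeRiskConstants)

    @property
    def history_days(self) -> int:
        return max(self.indoor.history_days, self.outdoor.history_days)


def age_risk_weight(n, consts: AgeRiskConstants = AgeRiskConstants()):
    """Relative heat-illness risk of age category ``n`` in 1..14."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 1) or np.any(n_arr > N_AGE_CATEGORIES):
        raise InvariantError(f"age category out of range 1..{N_AGE_CATEGORIES}: {n}")
    out = consts.b * np.exp(consts.c * n_arr) + consts.d
    return float(out) if np.isscalar(n) else out


def population_risk_sum(
    pop: AgeComposition, consts: AgeRiskConstants = AgeRiskConstants()
) -> float:
    """``sum_n P(n) * (b*exp(c*n) + d)`` over the 14 categories."""
    n = np.arange(1, N_AGE_CATEGORIES + 1)
    return float(np.dot(pop.fractions, age_risk_weight(n, consts)))


def adaptation_coefficient(f: Optional[float], g: float, adaptation_avg):
    """Daily exponent coefficient ``k = f * A + g`` (``k = g`` if f is None)."""
    if f is None:
        if np.isscalar(adaptation_avg) or adaptation_avg is None:
            return g
        return np.full(np.shape(adaptation_avg), g, dtype=float)
    return f * np.asarray(adaptation_avg, dtype=float) + g


def _floored(values):
    return np.maximum(values, 0.0)


def estimate_indoor(params: LocationParams, k, lag_input, pop_sum: float):
    """Expected indoor count: ``a * (exp(k*u) + l) * S`` floored at 0.

    ``lag_input`` must already be the 3-day weighted input for the day.
    """
    expo = np.asarray(k, dtype=float) * np.asarray(lag_input, dtype=float)
    if not np.all(np.isfinite(expo)):
        raise InvariantError("non-finite exponent in indoor estimate")
    out = _floored(params.a * (np.exp(expo) + params.l) * pop_sum)
    return float(out) if out.ndim == 0 else out


def estimate_outdoor(params: LocationParams, k, x0, pop_sum: float):
    """Expected outdoor count from the same-day input ``x0``."""
    expo = np.asarray(k, dtype=float) * np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(expo)):
        raise InvariantError("non-finite exponent in outdoor estimate")
    out = _floored(params.a * (np.exp(expo) + params.l) * pop_sum)
    return float(out) if out.ndim == 0 else out


def _season_inputs(
    season: pd.DataFrame, params: LocationParams, weight_shape: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (lag-or-same-day input u, adaptation average A) for one season."""
    x = season[INPUT_COLUMNS[params.input_kind]].to_numpy(dtype=float)
    if params.f is not None:
        cfg = _exposure.AdaptationConfig(J=params.J, weight_shape=weight_shape)
        adapt = _exposure.adaptation_series(x, cfg)
    else:
        adapt = np.zeros_like(x)
    return x, adapt


def estimate_series(
    exposure: pd.DataFrame,
    pop: AgeComposition,
    params: RiskParameters,
    weight_shape: str = "linear_decreasing",
) -> pd.DataFrame:
    """Evaluate the model for every day with sufficient history.

    Seasons (contiguous date runs) are processed independently; within
    each season the first ``max(J_in, J_out, 2)`` days are dropped, never
    zero-filled. Returns columns ``date, y_in, y_out, y``.
    """
    if len(exposure) == 0:
        raise InsufficientHistoryError("empty exposure series")
    S = population_risk_sum(pop, params.constants)
    drop = params.history_days
    frames = []
    for _, season in _exposure.iter_seasons(exposure):
        if len(season) <= drop:
            continue
        x_in, adapt_in = _season_inputs(season, params.indoor, weight_shape)
        x_out, adapt_out = _season_inputs(season, params.outdoor, weight_shape)
        lag_in = _exposure.indoor_lag_series(x_in)

        sl = slice(drop, None)
        k_in = adaptation_coefficient(params.indoor.f, params.indoor.g, adapt_in[sl])
        k_out = adaptation_coefficient(params.outdoor.f, params.outdoor.g, adapt_out[sl])
        y_in = estimate_indoor(params.indoor, k_in, lag_in[sl], S)
        y_out = estimate_outdoor(params.outdoor, k_out, x_out[sl], S)
        frames.append(
            pd.DataFrame(
                {
                    "date": season["date"].to_numpy()[sl],
                    "y_in": np.atleast_1d(y_in),
                    "y_out": np.atleast_1d(y_out),
                }
            )
        )
    if not frames:
        raise InsufficientHistoryError(
            f"no season long enough to supply {drop} days of history"
        )
    est = pd.concat(frames, ignore_index=True)
    est["y"] = est["y_in"] + est["y_out"]
    return est


def estimate_with_band(
    exposure: pd.DataFrame,
    pop: AgeComposition,
    parameter_sets: list[RiskParameters],
    n_boot: int = 500,
    seed: int = 0,
    weight_shape: str = "linear_decreasing",
) -> pd.DataFrame:
    """Point estimate plus a 95 % band from per-held-out-year parameter sets.

    The band is a bootstrap over years: parameter sets are resampled with
    replacement, per-day predictions averaged within each draw, and the
    2.5/97.5 percentiles taken across draws. The point estimate uses the
    arithmetic mean of the parameter sets' predictions.
    """
    if not parameter_sets:
        raise InvariantError("need at least one parameter set")
    preds = [
        estimate_series(exposure, pop, p, weight_shape)["y"].to_numpy()
        for p in parameter_sets
    ]
    base = estimate_series(exposure, pop, parameter_sets[0], weight_shape)
    preds = np.vstack(preds)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, preds.shape[0], size=(n_boot, preds.shape[0]))
    boot_means = preds[idx].mean(axis=1)  # (n_boot, n_days)
    out = base[["date"]].copy()
    out["y"] = preds.mean(axis=0)
    out["lo95"] = np.minimum(np.percentile(boot_means, 2.5, axis=0), out["y"])
    out["hi95"] = np.maximum(np.percentile(boot_means, 97.5, axis=0), out["y"])
    return out
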