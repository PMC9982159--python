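"""Synthetic multi-year weather, population and patient-count generators.

These emulate the statistical structure the downstream analysis assumes —
summer-only seasons with a rainy-season break, prefecture-like age
pyramids, and Poisson daily counts whose mean follows the morbidity model
— so every stage of the pipeline can be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InsufficientHistoryError, InvariantError
from .io import SeasonDataset
from .risk_model import (
    AgeComposition,
    LocationParams,
    N_AGE_CATEGORIES,
    RiskParameters,
    THERMO_INPUT_KINDS,
    estimate_series,
)

__all__ = [
    "WeatherScenario",
    "TrueModelSpec",
    "generate_weather",
    "generate_age_composition",
    "generate_patient_counts",
    "default_true_model",
    "make_dataset",
]

#: Hour of day at which the diurnal temperature cycle peaks.
DIURNAL_PEAK_HOUR = 14.0


@dataclass(frozen=True)
class WeatherScenario:
    """Parameters of the seasonal weather generator.

    Daily mean temperature over each season of length L days is

        base + amplitude*sin(pi*d/L) + AR(1) noise
             - rainy_season_cooling   (for d < rainy_season_end)

    with an hourly diurnal cosine (peak 14:00) superimposed; relative
    humidity is anticorrelated with temperature and clipped to [5, 100].
    """

    n_years: int = 7
    start_year: int = 2013
    season_start: str = "06-01"
    season_end: str = "09-30"
    base_temp: float = 24.0
    seasonal_amplitude: float = 6.0
    diurnal_amplitude: float = 4.0
    rainy_season_end: int = 50
    rainy_season_cooling: float = 2.0
    ar1_coef: float = 0.6
    noise_sd: float = 1.2
    rh_base: float = 70.0
    rh_temp_slope: float = 2.0
    rh_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise InvariantError("n_years must be positive")
        if not 0 <= self.ar1_coef < 1:
            raise InvariantError("ar1_coef must lie in [0, 1)")
        if self.noise_sd < 0 or self.rh_noise_sd < 0:
            raise InvariantError("noise standard deviations must be >= 0")
        # validates the date fragments and the ordering
        s = pd.Timestamp(f"{self.start_year}-{self.season_start}")
        e = pd.Timestamp(f"{self.start_year}-{self.season_end}")
        if e <= s:
            raise InvariantError("season_end must fall after season_start")

    @classmethod
    def hot_summer(cls, **kw) -> "WeatherScenario":
        """A hotter variant (subtropical-metropolis-like) under which the
        thermophysiological outputs are nonzero on most days and a useful
        number of days cross the WBGT 31 °C hot-day threshold."""
        kw.setdefault("base_temp", 26.0)
        kw.setdefault("seasonal_amplitude", 8.0)
        return cls(**kw)

    def season_days(self, year: int) -> pd.DatetimeIndex:
        return pd.date_range(
            f"{year}-{self.season_start}", f"{year}-{self.season_end}", freq="D"
        )

    def daily_mean_curve(self, n_days: int) -> np.ndarray:
        """Closed-form (noise-free) daily mean trajectory for one season."""
        d = np.arange(n_days, dtype=float)
        curve = self.base_temp + self.seasonal_amplitude * np.sin(np.pi * d / n_days)
        curve[d < self.rainy_season_end] -= self.rainy_season_cooling
        return curve


def generate_weather(scenario: WeatherScenario) -> pd.DataFrame:
    """Hourly weather over all seasons; bit-identical for a given seed."""
    rng = np.random.default_rng(scenario.seed)
    frames = []
    for year in range(scenario.start_year, scenario.start_year + scenario.n_years):
        days = scenario.season_days(year)
        n_days = len(days)
        noise = np.zeros(n_days)
        eps = rng.normal(0.0, scenario.noise_sd, size=n_days)
        for d in range(1, n_days):
            noise[d] = scenario.ar1_coef * noise[d - 1] + eps[d]
        noise[0] = eps[0]
        daily = scenario.daily_mean_curve(n_days) + noise

        hours = np.arange(24.0)
        diurnal = scenario.diurnal_amplitude * np.cos(
            2 * np.pi * (hours - DIURNAL_PEAK_HOUR) / 24.0
        )
        temp = (daily[:, None] + diurnal[None, :]).ravel()
        timestamps = pd.date_range(days[0], periods=n_days * 24, freq="h")

        rh = (
            scenario.rh_base
            - scenario.rh_temp_slope * (temp - scenario.base_temp)
            + rng.normal(0.0, scenario.rh_noise_sd, size=temp.size)
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": timestamps,
                    "temp_c": temp,
                    "rh_pct": np.clip(rh, 5.0, 100.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_age_composition(aging_index: float) -> AgeComposition:
    """Age pyramid over the 14 adult categories; 0 = flat, larger = older.

    ``P(n) proportional to exp(aging_index * (n - 1) / (N - 1))`` so the
    mean category index increases strictly with ``aging_index``.
    """
    if aging_index < 0:
        raise InvariantError("aging_index must be >= 0")
    n = np.arange(N_AGE_CATEGORIES, dtype=float)
    logits = aging_index * n / (N_AGE_CATEGORIES - 1)
    weights = np.exp(logits - logits.max())
    return AgeComposition(weights / weights.sum())


@dataclass(frozen=True)
class TrueModelSpec:
    """Generating model for synthetic counts: parameters plus noise law."""

    params: RiskParameters
    noise: Literal["poisson", "none"] = "poisson"
    population: float = 8.0e6

    def __post_init__(self):
        for loc in (self.params.indoor, self.params.outdoor):
            if loc.a < 0:
                raise InvariantError("generating a must be nonnegative")
            if loc.f is not None and loc.f > 0:
                raise InvariantError("adaptation slope f must be <= 0")
            if loc.input_kind in THERMO_INPUT_KINDS and loc.l != -1.0:
                raise InvariantError("l must be -1 for thermophysiological inputs")
        if self.noise not in ("poisson", "none"):
            raise InvariantError(f"unknown noise model {self.noise!r}")


def generate_patient_counts(
    exposure: pd.DataFrame,
    pop: AgeComposition,
    spec: TrueModelSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily indoor/outdoor/total counts whose mean follows the model.

    Under ``noise="none"`` the real-valued model means are emitted; under
    ``"poisson"`` indoor and outdoor are independent Poisson draws and
    total is their sum, so total = indoor + outdoor always holds.
    """
    need = spec.params.history_days + 1
    if len(exposure) < need:
        raise InsufficientHistoryError(
            f"exposure must cover at least {need} days, got {len(exposure)}"
        )
    mean = estimate_series(exposure, pop, spec.params)
    if spec.noise == "none":
        indoor = mean["y_in"].to_numpy()
        outdoor = mean["y_out"].to_numpy()
    else:
        rng = np.random.default_rng(seed)
        indoor = rng.poisson(mean["y_in"].to_numpy()).astype(float)
        outdoor = rng.poisson(mean["y_out"].to_numpy()).astype(float)
    return pd.DataFrame(
        {
            "date": mean["date"],
            "indoor": indoor,
            "outdoor": outdoor,
            "total": indoor + outdoor,
            "population": spec.population,
        }
    )


def default_true_model(
    input_kind: str = "average_temperature",
    noise: str = "poisson",
    J_indoor: int = 40,
    J_outdoor: int = 30,
    f_indoor: float | None = "default",
    population: float = 8.0e6,
) -> TrueModelSpec:
    """A generating model with magnitudes typical of a large prefecture.

    Calibrated so that on the default weather scenario daily totals range
    from a handful early in the season to several tens at the peak.
    """
    if input_kind == "average_temperature":
        indoor = LocationParams(
            a=6.0e-6, l=-1.0e3, g=0.55, f=-7.0e-3, input_kind=input_kind, J=J_indoor
        )
        outdoor = LocationParams(
            a=3.0e-5, l=-5.0e2, g=0.46, f=-6.0e-3, input_kind=input_kind, J=J_outdoor
        )
    elif input_kind == "core_temperature_increase":
        indoor = LocationParams(
            a=3.0e-2, l=-1.0, g=5.5, f=-3.0, input_kind=input_kind, J=J_indoor
        )
        outdoor = LocationParams(
            a=1.9e-2, l=-1.0, g=3.6, f=None, input_kind=input_kind, J=0
        )
    elif input_kind == "sweating":
        indoor = LocationParams(
            a=3.0e-3, l=-1.0, g=1.4e-3, f=-1.0e-7, input_kind=input_kind, J=J_indoor
        )
        outdoor = LocationParams(
            a=2.5e-3, l=-1.0, g=1.5e-3, f=None, input_kind=input_kind, J=0
        )
    else:
        raise InvariantError(f"unknown input kind {input_kind!r}")
    if f_indoor != "default":
        if f_indoor is None:
            indoor = replace(indoor, f=None, J=0)
        else:
            indoor = replace(indoor, f=f_indoor)
    return TrueModelSpec(
        params=RiskParameters(indoor=indoor, outdoor=outdoor),
        noise=noise,
        population=population,
    )


def make_dataset(
    scenario: WeatherScenario,
    spec: TrueModelSpec,
    aging_index: float = 3.0,
    seed: int = 0,
    subject=None,
    thermo_dt: float = 60.0,
) -> list[SeasonDataset]:
    """Full synthetic pipeline: weather -> exposure -> counts, by season.

    The thermophysiological simulation only runs when the generating model
    actually consumes one of its outputs.
    """
    from .exposure import build_exposure

    weather = generate_weather(scenario)
    kinds = {spec.params.indoor.input_kind, spec.params.outdoor.input_kind}
    if kinds & THERMO_INPUT_KINDS:
        from .thermophysiology import simulate_season

        thermo = simulate_season(weather, subject, dt=thermo_dt)
    else:
        thermo = None
    exposure = build_exposure(weather, thermo)
    pop = generate_age_composition(aging_index)
    counts = generate_patient_counts(exposure, pop, spec, seed=seed)
    return [
        SeasonDataset(
            year=int(year),
            exposure=expo.reset_index(drop=True),
            counts=counts[counts["date"].dt.year == year].reset_index(drop=True),
            population=spec.population,
            age=pop,
        )
        for year, expo in exposure.groupby(exposure["date"].dt.year)
    ]
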