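"""Two-node (core/skin) thermoregulation surrogate.

Computes the two daily strain inputs used by the morbidity model — daily
peak core-temperature increase and daily total sweating — for a standard
resting subject driven by an ambient temperature / relative-humidity
series.

Model sketch (all fluxes in W, positive = heat leaving the named node):

    C_core dT_core/dt = M - q_res - q_core->skin
    C_skin dT_skin/dt = q_core->skin - q_dry - q_evap

    q_core->skin = (K_min + rho_b * SkBF) * (T_core - T_skin) * A
    SkBF         = basal + vasodilation_gain * max(0, T_core - T_core,set)
    sweat rate   = sweating_gain * [0.9 (T_core-set)+ + 0.1 (T_skin-set)+] * A,
                   capped at max_sweat_rate
    q_dry        = (T_skin - T_amb) * A / (0.155*I_clo + 1/(f_cl*(h_c+h_r)))
    q_evap       = min(E_max, 0.06*E_max + 0.94*E_sweat)   (Gagge wettedness)
    E_max        = h_e * (P_sat(T_skin) - P_air) * A
    q_res        = 0.0014*M*(34 - T_amb) + 0.0173*M*(5.87 - P_air)

Saturated vapor pressure uses the Tetens form
``P_sat(T) = 0.61078 * exp(17.27*T / (T + 237.3))`` kPa.

Integration is explicit Euler (default dt = 60 s), continuous across each
contiguous weather block with no daily reset; daily summaries are
aggregated afterwards. This is a deliberately desk-scale stand-in for a
full anatomical simulation: every physiological constant lives in
``SubjectModel`` so a richer model can be swapped in behind the same
daily-summary interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvariantError, SimulationInstabilityError, WeatherGapError

__all__ = [
    "SubjectModel",
    "ThermoState",
    "saturation_vapor_pressure_kpa",
    "step_heat_balance",
    "simulate_season",
    "heat_balance_residual",
    "thermoneutral_calibration",
]

# Fixed physical constants (documented in the module docstring).
TISSUE_HEAT_CAPACITY = 3490.0  # J/(kg K)
CORE_MASS_FRACTION = 0.9
MIN_CONDUCTANCE = 5.28  # W/(m2 K) core-skin conduction floor
BLOOD_HEAT_EQUIV = 1.163  # W h/(L K)
H_CONV = 4.0  # W/(m2 K)
H_RAD = 4.7  # W/(m2 K)
LEWIS_RATIO = 16.5  # K/kPa
CLO_RESISTANCE = 0.155  # m2 K/W per clo
CLOTHING_VAPOR_PERMEATION = 0.34  # i_cl
LATENT_HEAT_SWEAT = 2430.0  # J/g
INSENSIBLE_WETTEDNESS = 0.06
WARM_CORE_WEIGHT = 0.9
WARM_SKIN_WEIGHT = 0.1
TEMP_BOUNDS = (30.0, 45.0)  # °C; outside -> instability error


def saturation_vapor_pressure_kpa(temp_c):
    """Tetens saturated vapor pressure over water, kPa."""
    t = np.asarray(temp_c, dtype=float)
    out = 0.61078 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SubjectModel:
    """Lumped-parameter standard subject (resting, lightly clothed)."""

    body_mass: float = 70.0  # kg
    body_surface_area: float = 1.8  # m2
    metabolic_rate: float = 90.0  # W
    core_heat_capacity: float = CORE_MASS_FRACTION * 70.0 * TISSUE_HEAT_CAPACITY
    skin_heat_capacity: float = (1 - CORE_MASS_FRACTION) * 70.0 * TISSUE_HEAT_CAPACITY
    basal_skin_blood_flow: float = 8.7  # L/(m2 h)
    vasodilation_gain: float = 40.0  # L/(m2 h K)
    sweating_gain: float = 100.0  # g/(m2 h K)
    core_setpoint: float = 36.8  # °C
    skin_setpoint: float = 33.7  # °C
    clothing_insulation: float = 0.3  # clo
    max_sweat_rate: float = 1500.0  # g/h

    def __post_init__(self):
        positive = (
            "body_mass",
            "body_surface_area",
            "core_heat_capacity",
            "skin_heat_capacity",
            "basal_skin_blood_flow",
            "vasodilation_gain",
            "sweating_gain",
            "max_sweat_rate",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvariantError(f"{name} must be positive")
        if self.metabolic_rate < 0 or self.clothing_insulation < 0:
            raise InvariantError("metabolic_rate and clothing_insulation must be >= 0")
        if self.core_setpoint <= self.skin_setpoint:
            raise InvariantError("core_setpoint must exceed skin_setpoint")

    @property
    def dry_heat_coeff(self) -> float:
        """Effective skin->ambient dry coefficient through clothing, W/(m2 K)."""
        f_cl = 1.0 + 0.2 * self.clothing_insulation
        return 1.0 / (
            CLO_RESISTANCE * self.clothing_insulation + 1.0 / (f_cl * (H_CONV + H_RAD))
        )

    @property
    def evap_heat_coeff(self) -> float:
        """Effective evaporative coefficient through clothing, W/(m2 kPa)."""
        f_cl = 1.0 + 0.2 * self.clothing_insulation
        r_cl = CLO_RESISTANCE * self.clothing_insulation / (
            CLOTHING_VAPOR_PERMEATION * LEWIS_RATIO
        )
        r_air = 1.0 / (LEWIS_RATIO * H_CONV * f_cl)
        return 1.0 / (r_cl + r_air)


@dataclass
class ThermoState:
    core_temp: float
    skin_temp: float
    cumulative_sweat: float = 0.0  # g
    time: pd.Timestamp | None = None

    @classmethod
    def at_setpoints(cls, subject: SubjectModel, time=None) -> "ThermoState":
        return cls(subject.core_setpoint, subject.skin_setpoint, 0.0, time)


def _fluxes(core, skin, ambient, rh, subject: SubjectModel):
    """All instantaneous fluxes (W) and the sweat rate (g/h)."""
    area = subject.body_surface_area
    met = subject.metabolic_rate
    p_air = rh / 100.0 * 0.61078 * math.exp(17.27 * ambient / (ambient + 237.3))

    q_res = 0.0014 * met * (34.0 - ambient) + 0.0173 * met * (5.87 - p_air)

    warm_core = max(0.0, core - subject.core_setpoint)
    warm_skin = max(0.0, skin - subject.skin_setpoint)
    skbf = subject.basal_skin_blood_flow + subject.vasodilation_gain * warm_core
    q_core_skin = (MIN_CONDUCTANCE + BLOOD_HEAT_EQUIV * skbf) * (core - skin) * area

    q_dry = subject.dry_heat_coeff * (skin - ambient) * area

    p_skin = 0.61078 * math.exp(17.27 * skin / (skin + 237.3))
    e_max = max(0.0, subject.evap_heat_coeff * (p_skin - p_air) * area)
    warm = WARM_CORE_WEIGHT * warm_core + WARM_SKIN_WEIGHT * warm_skin
    sweat_gh = min(subject.sweating_gain * warm * area, subject.max_sweat_rate)
    e_sweat = sweat_gh * LATENT_HEAT_SWEAT / 3600.0
    q_evap = min(e_max, INSENSIBLE_WETTEDNESS * e_max + (1 - INSENSIBLE_WETTEDNESS) * e_sweat)

    return {
        "metabolic": met,
        "respiratory": q_res,
        "core_to_skin": q_core_skin,
        "dry": q_dry,
        "evaporative": q_evap,
        "sweat_rate_gh": sweat_gh,
    }


def _check_bounds(core, skin, time):
    lo, hi = TEMP_BOUNDS
    if not (lo <= core <= hi and lo <= skin <= hi):
        raise SimulationInstabilityError(
            f"node temperature left [{lo}, {hi}] °C at {time} "
            f"(core={core:.2f}, skin={skin:.2f})",
            timestamp=time,
        )


def step_heat_balance(
    state: ThermoState,
    ambient_temp: float,
    rh: float,
    subject: SubjectModel,
    dt: float,
) -> ThermoState:
    """One explicit-Euler update of the two-node balance."""
    if not 0 < dt <= 300:
        raise InvariantError(f"dt must lie in (0, 300] s, got {dt}")
    if not 0 <= rh <= 100:
        raise InvariantError(f"relative humidity out of [0, 100]: {rh}")
    _check_bounds(state.core_temp, state.skin_temp, state.time)
    fl = _fluxes(state.core_temp, state.skin_temp, ambient_temp, rh, subject)
    d_core = (fl["metabolic"] - fl["respiratory"] - fl["core_to_skin"]) / subject.core_heat_capacity
    d_skin = (fl["core_to_skin"] - fl["dry"] - fl["evaporative"]) / subject.skin_heat_capacity
    new_time = None if state.time is None else state.time + pd.Timedelta(seconds=dt)
    new = ThermoState(
        core_temp=state.core_temp + d_core * dt,
        skin_temp=state.skin_temp + d_skin * dt,
        cumulative_sweat=state.cumulative_sweat + fl["sweat_rate_gh"] / 3600.0 * dt,
        time=new_time,
    )
    _check_bounds(new.core_temp, new.skin_temp, new.time)
    return new


#: Weather gaps up to this many hours are interpolated across; larger gaps
#: up to SEASON_BREAK_DAYS are treated as data defects and rejected; gaps of
#: SEASON_BREAK_DAYS or more separate seasons and restart the integration.
MAX_GAP_HOURS = 3.0
SEASON_BREAK_DAYS = 30


def _weather_blocks(weather: pd.DataFrame):
    ts = pd.to_datetime(weather["timestamp"]).to_numpy()
    if len(ts) < 2:
        raise WeatherGapError("weather series too short to integrate")
    gaps_h = np.diff(ts).astype("timedelta64[s]").astype(float) / 3600.0
    bad = (gaps_h > MAX_GAP_HOURS) & (gaps_h < SEASON_BREAK_DAYS * 24.0)
    if bad.any():
        i = int(np.argmax(bad))
        raise WeatherGapError(
            f"gap of {gaps_h[i]:.1f} h in weather series after {ts[i]}"
        )
    breaks = np.flatnonzero(gaps_h >= SEASON_BREAK_DAYS * 24.0) + 1
    for block in np.split(np.arange(len(ts)), breaks):
        yield weather.iloc[block]


#: Ambient floor (°C) applied by `simulate_season`: below this the subject
#: is assumed sheltered in mild conditions. A two-node model without
#: vasoconstriction/shivering has no cold defense, so unsheltered cool
#: nights would drive the skin node below its physical bound.
MIN_AMBIENT_EXPOSURE_C = 26.0


def _integrate_block(
    block: pd.DataFrame, subject: SubjectModel, dt: float, min_ambient_c: float
):
    """Fast Euler loop over one contiguous weather block.

    Returns (dates, peak_core_increase per day, total_sweat per day).
    """
    ts = pd.to_datetime(block["timestamp"])
    t_sec = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    grid = np.arange(0.0, t_sec[-1] + dt / 2, dt)
    ta = np.interp(grid, t_sec, block["temp_c"].to_numpy(dtype=float))
    ta = np.maximum(ta, min_ambient_c)
    rh = np.interp(grid, t_sec, block["rh_pct"].to_numpy(dtype=float))
    p_air = rh / 100.0 * 0.61078 * np.exp(17.27 * ta / (ta + 237.3))

    day_idx = (
        (ts.iloc[0] + pd.to_timedelta(grid, unit="s")).normalize().to_numpy()
    )
    dates, day_of = np.unique(day_idx, return_inverse=True)
    n_days = len(dates)
    peak = np.zeros(n_days)
    sweat = np.zeros(n_days)

    sub = subject
    area = sub.body_surface_area
    met = sub.metabolic_rate
    c_core = sub.core_heat_capacity
    c_skin = sub.skin_heat_capacity
    h_dry = sub.dry_heat_coeff
    h_evap = sub.evap_heat_coeff
    core_set, skin_set = sub.core_setpoint, sub.skin_setpoint
    basal, dila, sgain = sub.basal_skin_blood_flow, sub.vasodilation_gain, sub.sweating_gain
    max_sweat = sub.max_sweat_rate
    lo, hi = TEMP_BOUNDS

    core = core_set
    skin = skin_set
    exp = math.exp
    for i in range(len(grid)):
        d = day_of[i]
        inc = core - core_set
        if inc > peak[d]:
            peak[d] = inc
        q_res = 0.0014 * met * (34.0 - ta[i]) + 0.0173 * met * (5.87 - p_air[i])
        warm_core = inc if inc > 0.0 else 0.0
        warm_skin = skin - skin_set
        if warm_skin < 0.0:
            warm_skin = 0.0
        skbf = basal + dila * warm_core
        q_cs = (MIN_CONDUCTANCE + BLOOD_HEAT_EQUIV * skbf) * (core - skin) * area
        q_dry = h_dry * (skin - ta[i]) * area
        p_skin = 0.61078 * exp(17.27 * skin / (skin + 237.3))
        e_max = h_evap * (p_skin - p_air[i]) * area
        if e_max < 0.0:
            e_max = 0.0
        sweat_gh = sgain * (WARM_CORE_WEIGHT * warm_core + WARM_SKIN_WEIGHT * warm_skin) * area
        if sweat_gh > max_sweat:
            sweat_gh = max_sweat
        e_sweat = sweat_gh * LATENT_HEAT_SWEAT / 3600.0
        q_evap = INSENSIBLE_WETTEDNESS * e_max + (1 - INSENSIBLE_WETTEDNESS) * e_sweat
        if q_evap > e_max:
            q_evap = e_max
        core += (met - q_res - q_cs) / c_core * dt
        skin += (q_cs - q_dry - q_evap) / c_skin * dt
        sweat[d] += sweat_gh / 3600.0 * dt
        if not (lo <= core <= hi and lo <= skin <= hi):
            when = ts.iloc[0] + pd.Timedelta(seconds=float(grid[i]))
            raise SimulationInstabilityError(
                f"node temperature left [{lo}, {hi}] °C at {when} "
                f"(core={core:.2f}, skin={skin:.2f})",
                timestamp=when,
            )
    peak = np.maximum(peak, 0.0)
    return dates, peak, sweat


def simulate_season(
    weather: pd.DataFrame,
    subject: SubjectModel | None = None,
    dt: float = 60.0,
    min_ambient_c: float = MIN_AMBIENT_EXPOSURE_C,
) -> pd.DataFrame:
    """Daily peak core-temperature increase and total sweat over a series.

    Weather must be hourly or finer within contiguous blocks; blocks
    separated by a month or more (distinct seasons) are integrated
    independently, each starting from setpoint conditions. The effective
    ambient temperature is floored at ``min_ambient_c`` (sheltering; see
    ``MIN_AMBIENT_EXPOSURE_C``). Returns a frame with
    ``date, peak_core_increase_c, total_sweat_g``.
    """
    if subject is None:
        subject = SubjectModel()
    if not 0 < dt <= 300:
        raise InvariantError(f"dt must lie in (0, 300] s, got {dt}")
    frames = []
    for block in _weather_blocks(weather):
        dates, peak, sweat = _integrate_block(block, subject, dt, min_ambient_c)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "peak_core_increase_c": peak,
                    "total_sweat_g": sweat,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def heat_balance_residual(trajectory: pd.DataFrame, subject: SubjectModel) -> float:
    """Conservation check: |stored-heat rate - net flux| (W) at the end
    of a trajectory.

    ``trajectory`` needs columns ``time, core_temp, skin_temp,
    ambient_temp, rh``; the stored-heat rate is a finite difference over
    the last step, net flux is metabolic minus respiratory, dry and
    evaporative losses evaluated at the penultimate state (the Euler
    left endpoint).
    """
    if len(trajectory) < 2:
        raise InvariantError("trajectory must contain at least two states")
    a, b = trajectory.iloc[-2], trajectory.iloc[-1]
    dt = (pd.Timestamp(b["time"]) - pd.Timestamp(a["time"])).total_seconds()
    stored = (
        subject.core_heat_capacity * (b["core_temp"] - a["core_temp"])
        + subject.skin_heat_capacity * (b["skin_temp"] - a["skin_temp"])
    ) / dt
    fl = _fluxes(a["core_temp"], a["skin_temp"], a["ambient_temp"], a["rh"], subject)
    net = fl["metabolic"] - fl["respiratory"] - fl["dry"] - fl["evaporative"]
    return abs(stored - net)


def thermoneutral_calibration(
    subject: SubjectModel, rh: float = 50.0
) -> tuple[float, SubjectModel]:
    """Ambient temperature and adjusted subject for setpoint equilibrium.

    Solves for the ambient temperature at which passive losses from skin
    held at its setpoint balance metabolism net of respiration, then
    adjusts ``basal_skin_blood_flow`` so the core->skin conductance carries
    exactly that flux across the setpoint gradient. At the returned
    (ambient, subject) pair the setpoint state is a fixed point of
    :func:`step_heat_balance`.
    """

    def imbalance(ambient):
        fl = _fluxes(
            subject.core_setpoint, subject.skin_setpoint, ambient, rh, subject
        )
        return fl["metabolic"] - fl["respiratory"] - fl["dry"] - fl["evaporative"]

    ambient = brentq(imbalance, 0.0, subject.skin_setpoint - 1e-6, xtol=1e-12)
    fl = _fluxes(subject.core_setpoint, subject.skin_setpoint, ambient, rh, subject)
    needed = fl["metabolic"] - fl["respiratory"]
    gradient = subject.core_setpoint - subject.skin_setpoint
    conductance = needed / (gradient * subject.body_surface_area)
    basal = (conductance - MIN_CONDUCTANCE) / BLOOD_HEAT_EQUIV
    if basal <= 0:
        raise InvariantError("calibration requires positive basal skin blood flow")
    return ambient, replace(subject, basal_skin_blood_flow=basal)
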