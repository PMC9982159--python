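"""Readers/writers for the pipeline's CSV dialects and parameter files.

All files are plain UTF-8 CSV with a header row; dates are ISO-8601.
Validation failures name the offending line (header = line 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvariantError, SchemaError
from .risk_model import (
    AgeComposition,
    AgeRiskConstants,
    LocationParams,
    N_AGE_CATEGORIES,
    RiskParameters,
)

__all__ = [
    "SeasonDataset",
    "read_weather",
    "write_weather",
    "read_population",
    "write_population",
    "read_counts",
    "write_counts",
    "read_exposure",
    "write_exposure",
    "write_estimates",
    "read_parameters",
    "write_parameters",
    "split_total_by_location",
    "split_seasons",
]

WEATHER_COLUMNS = ["timestamp", "temp_c", "rh_pct"]
COUNT_COLUMNS = ["date", "indoor", "outdoor", "total", "population"]


@dataclass
class SeasonDataset:
    """One season (year) of aligned inputs for fitting/evaluation."""

    year: int
    exposure: pd.DataFrame
    counts: pd.DataFrame
    population: float
    age: AgeComposition = field(default_factory=AgeComposition.uniform)


def _require_columns(df: pd.DataFrame, columns, path):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _line(df_index: int) -> int:
    # +2: header line plus 1-based numbering
    return int(df_index) + 2


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, WEATHER_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        raise SchemaError(
            f"{path}: unparseable timestamp at line {_line(ts.isna().idxmax())}"
        )
    bad_rh = (df["rh_pct"] < 0) | (df["rh_pct"] > 100) | df["rh_pct"].isna()
    if bad_rh.any():
        raise SchemaError(
            f"{path}: relative humidity outside [0, 100] at line {_line(bad_rh.idxmax())}"
        )
    out = df[WEATHER_COLUMNS].copy()
    out["timestamp"] = ts
    return out.sort_values("timestamp", ignore_index=True)


def write_weather(weather: pd.DataFrame, path) -> None:
    _require_columns(weather, WEATHER_COLUMNS, path)
    weather[WEATHER_COLUMNS].to_csv(path, index=False)


def read_population(path) -> AgeComposition:
    df = pd.read_csv(path)
    _require_columns(df, ["category", "fraction"], path)
    if sorted(df["category"]) != list(range(1, N_AGE_CATEGORIES + 1)):
        raise SchemaError(
            f"{path}: expected exactly categories 1..{N_AGE_CATEGORIES}"
        )
    fractions = df.sort_values("category")["fraction"].to_numpy(dtype=float)
    return AgeComposition(fractions)


def write_population(pop: AgeComposition, path) -> None:
    pd.DataFrame(
        {"category": np.arange(1, N_AGE_CATEGORIES + 1), "fraction": pop.fractions}
    ).to_csv(path, index=False)


def read_counts(path, atol: float = 1e-9) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    dates = pd.to_datetime(df["date"], errors="coerce")
    if dates.isna().any():
        raise SchemaError(
            f"{path}: unparseable date at line {_line(dates.isna().idxmax())}"
        )
    for col in ("indoor", "outdoor", "total"):
        bad = df[col] < 0
        if bad.any():
            raise SchemaError(
                f"{path}: negative {col} count at line {_line(bad.idxmax())}"
            )
    mismatch = (df["indoor"] + df["outdoor"] - df["total"]).abs() > atol
    if mismatch.any():
        raise InvariantError(
            f"{path}: total != indoor + outdoor at line {_line(mismatch.idxmax())}"
        )
    out = df[COUNT_COLUMNS].copy()
    out["date"] = dates
    return out.sort_values("date", ignore_index=True)


def write_counts(counts: pd.DataFrame, path) -> None:
    _require_columns(counts, COUNT_COLUMNS, path)
    counts[COUNT_COLUMNS].to_csv(path, index=False)


def read_exposure(path) -> pd.DataFrame:
    from .exposure import EXPOSURE_COLUMNS

    df = pd.read_csv(path)
    _require_columns(df, EXPOSURE_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"])
    return df[EXPOSURE_COLUMNS].sort_values("date", ignore_index=True)


def write_exposure(exposure: pd.DataFrame, path) -> None:
    from .exposure import EXPOSURE_COLUMNS

    _require_columns(exposure, EXPOSURE_COLUMNS, path)
    exposure[EXPOSURE_COLUMNS].to_csv(path, index=False)


def write_estimates(estimates: pd.DataFrame, path) -> None:
    cols = [c for c in ("date", "y_in", "y_out", "y", "lo95", "hi95") if c in estimates]
    estimates[cols].to_csv(path, index=False)


def _location_to_dict(p: LocationParams) -> dict:
    return {
        "a": float(p.a),
        "l": float(p.l),
        "f": None if p.f is None else float(p.f),
        "g": float(p.g),
        "input_kind": p.input_kind,
        "J": int(p.J),
    }


def write_parameters(params: RiskParameters, path) -> None:
    """One block per location class, flat key-value entries (YAML)."""
    doc = {
        "indoor": _location_to_dict(params.indoor),
        "outdoor": _location_to_dict(params.outdoor),
        "constants": {
            "b": params.constants.b,
            "c": params.constants.c,
            "d": params.constants.d,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_parameters(path) -> RiskParameters:
    doc = yaml.safe_load(Path(path).read_text())
    for block in ("indoor", "outdoor"):
        if block not in doc:
            raise SchemaError(f"{path}: missing parameter block {block!r}")
    consts = AgeRiskConstants(**doc.get("constants", {}))
    return RiskParameters(
        indoor=LocationParams(**doc["indoor"]),
        outdoor=LocationParams(**doc["outdoor"]),
        constants=consts,
    )


def split_total_by_location(total: float, indoor_fraction: float):
    """Split a total count by the mean indoor share; conserves the total.

    The split is real-valued (the historical totals are scaled by a
    multi-year average percentage); rounding is left to display.
    """
    if not 0.0 <= indoor_fraction <= 1.0:
        raise InvariantError(
            f"indoor fraction must lie in [0, 1], got {indoor_fraction}"
        )
    indoor = total * indoor_fraction
    return indoor, total - indoor


def split_seasons(
    exposure: pd.DataFrame,
    counts: pd.DataFrame,
    population: float,
    age: AgeComposition | None = None,
) -> list[SeasonDataset]:
    """Group aligned exposure/count frames into per-year season datasets."""
    if age is None:
        age = AgeComposition.uniform()
    exposure = exposure.copy()
    counts = counts.copy()
    exposure["date"] = pd.to_datetime(exposure["date"])
    counts["date"] = pd.to_datetime(counts["date"])
    out = []
    for year, expo in exposure.groupby(exposure["date"].dt.year):
        cnt = counts[counts["date"].dt.year == year]
        out.append(
            SeasonDataset(
                year=int(year),
                exposure=expo.reset_index(drop=True),
                counts=cnt.reset_index(drop=True),
                population=population,
                age=age,
            )
        )
    return out
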