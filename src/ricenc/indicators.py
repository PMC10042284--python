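"""Growth and thermal indicators from raw plot samples and daily weather.

Field measurements come in on a per-sampled-tiller basis (a handful of
tillers are cut, measured and dried per plot); everything is scaled to
ground area through the plot's tiller density.  Thermal time uses the
mean-temperature growing-degree-day convention with the japonica rice
base temperature of 12.5 °C.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidSampleError,
    InvalidWeatherError,
    InvalidWindowError,
)

#: Base temperature (°C) for japonica rice development.
T_BASE_JAPONICA = 12.5

#: Column order of the plot-level samples table.
SAMPLE_COLUMNS = [
    "experiment_id", "cultivar", "region", "year", "management",
    "n_rate", "stage", "date", "replicate",
    "leaf_area_reading", "tiller_density", "sampled_tillers",
    "leaf_dw", "stem_dw", "spike_dw", "plant_n_conc",
]

#: Sampling-stage labels in phenological order (tillering → heading).
STAGE_ORDER = ["TI", "SE", "PI", "BT", "HD"]


@dataclass(frozen=True)
class WeatherDay:
    """One day of station weather: date plus daily extreme temperatures."""

    date: dt.date
    tmax: float
    tmin: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise InvalidWeatherError(
                f"tmax ({self.tmax}) < tmin ({self.tmin}) on {self.date}"
            )


def compute_lai(
    leaf_area_reading: float, tiller_density: float, sampled_tillers: int
) -> float:
    """Leaf area index from a leaf-area-meter reading.

    ``LAI = r * s * 1e-4 / k`` where *r* is the summed one-side leaf area
    (cm²) of the *k* sampled tillers and *s* is the tiller density
    (tillers m⁻²); 1e-4 converts cm² to m².
    """
    if sampled_tillers < 1:
        raise InvalidSampleError("sampled_tillers must be >= 1")
    if leaf_area_reading < 0 or tiller_density < 0:
        raise InvalidSampleError("leaf area and tiller density must be >= 0")
    return leaf_area_reading * tiller_density * 1e-4 / sampled_tillers


def compute_organ_dw(
    weight: float, tiller_density: float, sampled_tillers: int
) -> float:
    """Organ dry matter (t ha⁻¹) from the dried sample weight.

    ``DW = w * s * 1e-2 / k`` with *w* the organ dry weight (g) of the
    *k* sampled tillers and *s* the tiller density (tillers m⁻²).
    Plant DW is the sum over leaf, stem and spike.
    """
    if sampled_tillers < 1:
        raise InvalidSampleError("sampled_tillers must be >= 1")
    if weight < 0 or tiller_density < 0:
        raise InvalidSampleError("weight and tiller density must be >= 0")
    return weight * tiller_density * 1e-2 / sampled_tillers


def compute_slr(stem_dw: float, leaf_dw: float) -> float:
    """Stem-to-leaf dry-weight ratio (dry-matter partitioning index)."""
    if leaf_dw <= 0:
        raise InvalidSampleError("leaf_dw must be > 0 for SLR")
    return stem_dw / leaf_dw


def compute_sla(leaf_area: float, leaf_dw: float) -> float:
    """Specific leaf area (cm² g⁻¹): one-side leaf area per leaf dry weight."""
    if leaf_dw <= 0:
        raise InvalidSampleError("leaf_dw must be > 0 for SLA")
    return leaf_area / leaf_dw


def compute_gdd(
    day: WeatherDay, t_base: float = T_BASE_JAPONICA, clamp: bool = True
) -> float:
    """Growing degree days for one day: ``(tmax + tmin)/2 - t_base``.

    Negative thermal time is clamped to zero by default (standard
    agronomic convention; set ``clamp=False`` to keep negative values).
    """
    gdd = (day.tmax + day.tmin) / 2.0 - t_base
    if clamp:
        return max(0.0, gdd)
    return gdd


def compute_agdd(
    days: Sequence[WeatherDay] | Iterable[WeatherDay],
    t_base: float = T_BASE_JAPONICA,
    clamp: bool = True,
) -> float:
    """Accumulated growing degree days over a window of days."""
    days = list(days)
    if not days:
        raise InvalidWindowError("AGDD window must contain at least one day")
    return float(sum(compute_gdd(d, t_base=t_base, clamp=clamp) for d in days))


def plant_dw(row: pd.Series | dict) -> float:
    """Plant dry matter (t ha⁻¹) of one sample row: leaf + stem + spike."""
    return float(
        sum(
            compute_organ_dw(
                row[c], row["tiller_density"], int(row["sampled_tillers"])
            )
            for c in ("leaf_dw", "stem_dw", "spike_dw")
        )
    )


def add_derived_columns(samples: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the samples table with dw/lai/slr/sla columns added."""
    out = samples.copy()
    s = out["tiller_density"].to_numpy(float)
    k = out["sampled_tillers"].to_numpy(float)
    if (k < 1).any():
        raise InvalidSampleError("sampled_tillers must be >= 1 in every row")
    organ = {c: out[c].to_numpy(float) * s * 1e-2 / k
             for c in ("leaf_dw", "stem_dw", "spike_dw")}
    out["dw"] = organ["leaf_dw"] + organ["stem_dw"] + organ["spike_dw"]
    out["lai"] = out["leaf_area_reading"].to_numpy(float) * s * 1e-4 / k
    out["slr"] = out["stem_dw"].to_numpy(float) / out["leaf_dw"].to_numpy(float)
    out["sla"] = (
        out["leaf_area_reading"].to_numpy(float) / out["leaf_dw"].to_numpy(float)
    )
    return out


def compute_indicator_table(
    samples: pd.DataFrame,
    weather: pd.DataFrame | None = None,
    group_col: str = "experiment_id",
    tillering_stage: str = "TI",
    vegetative_stages: Sequence[str] = ("TI", "SE", "PI", "BT"),
    t_base: float = T_BASE_JAPONICA,
) -> pd.DataFrame:
    """Per-group growth/thermal indicators computed from raw records.

    Stage windows follow the sampling-stage labels of the input table:
    "-T" indicators are taken at the tillering-end stage and "-V"
    indicators as maxima (DW, LAI) or end values (SLR, SLA) over the
    vegetative stages.  Thermal indicators need a weather table; they are
    omitted when none is given (cultivar reference values TGW/AC/PH come
    from an external lookup and are never computed here).
    """
    df = add_derived_columns(samples)
    rows = []
    for gid, g in df.groupby(group_col, sort=True):
        ti = g[g["stage"] == tillering_stage]
        veg = g[g["stage"].isin(vegetative_stages)]
        last_stage = [s for s in STAGE_ORDER if s in set(veg["stage"])][-1]
        end = veg[veg["stage"] == last_stage]
        row = {
            group_col: gid,
            "DW-T": ti["dw"].max(),
            "LAI-T": ti["lai"].max(),
            "SLR-T": ti["slr"].mean(),
            "SLA-T": ti["sla"].mean(),
            "DW-V": veg["dw"].max(),
            "LAI-V": veg["lai"].max(),
            "SLR-V": end["slr"].mean(),
            "SLA-V": end["sla"].mean(),
        }
        if weather is not None:
            wdays = weather_to_days(weather)
            dates = pd.to_datetime(g["date"]).dt.date
            t_end = pd.to_datetime(ti["date"]).dt.date.max()
            v_end = dates.max()
            row["AGDD"] = compute_agdd(wdays, t_base=t_base)
            row["AGDD-T"] = compute_agdd(
                [d for d in wdays if d.date <= t_end], t_base=t_base
            )
            row["AGDD-V"] = compute_agdd(
                [d for d in wdays if d.date <= v_end], t_base=t_base
            )
        rows.append(row)
    return pd.DataFrame(rows)


def weather_to_days(weather: pd.DataFrame) -> list[WeatherDay]:
    """Convert a weather table (date, tmax, tmin) to WeatherDay records."""
    dates = pd.to_datetime(weather["date"]).dt.date.to_list()
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise InvalidWeatherError("weather dates must be strictly increasing")
    return [
        WeatherDay(d, float(tx), float(tn))
        for d, tx, tn in zip(dates, weather["tmax"], weather["tmin"])
    ]


def read_samples_csv(path) -> pd.DataFrame:
    """Read a samples CSV (UTF-8, '.' decimals, '#' metadata lines)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidSampleError(f"samples CSV missing columns: {missing}")
    return df


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("date", "tmax", "tmin") if c not in df.columns]
    if missing:
        raise InvalidWeatherError(f"weather CSV missing columns: {missing}")
    if (np.asarray(df["tmax"]) < np.asarray(df["tmin"])).any():
        raise InvalidWeatherError("weather CSV contains tmax < tmin")
    return df
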