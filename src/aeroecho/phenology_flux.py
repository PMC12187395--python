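"""Season assignment, seasonal aggregation and corridor-wide flux.

Season windows follow the migration phenology of the eastern
Mediterranean corridor: spring 1 Mar–10 Jun, summer 11 Jun–31 Jul,
autumn 1 Aug–30 Nov, winter 1 Dec–29 Feb (all bounds inclusive; the
windows partition the calendar year, 29 Feb falling in winter).

Corridor-wide flux per season multiplies the mean daily and nightly
traffic rates (insects km⁻¹ period⁻¹, pooled over sites) by the corridor
width (default 70 km) and the number of days in the season window;
biomass assumes a mean individual mass (default 50 mg, a literature
value for radar-detectable insects of >10 mg body mass that has not been
validated locally — treat biomass as indicative).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular_stats import DirectionalSummary, circular_summary

__all__ = [
    "SeasonConfig",
    "FluxEstimate",
    "assign_season",
    "season_length_days",
    "seasonal_mtr_means",
    "percent_day_night_difference",
    "extrapolate_flux",
    "detect_mass_migration_events",
    "diel_detection_count",
    "seasonal_direction",
    "DEFAULT_CORRIDOR_WIDTH_KM",
    "DEFAULT_MEAN_MASS_MG",
]

DEFAULT_CORRIDOR_WIDTH_KM = 70.0
DEFAULT_MEAN_MASS_MG = 50.0

SEASONS = ("spring", "summer", "autumn", "winter")


@dataclass(frozen=True)
class SeasonConfig:
    """Inclusive (month, day) windows per season; must partition the year."""

    spring: tuple[tuple[int, int], tuple[int, int]] = ((3, 1), (6, 10))
    summer: tuple[tuple[int, int], tuple[int, int]] = ((6, 11), (7, 31))
    autumn: tuple[tuple[int, int], tuple[int, int]] = ((8, 1), (11, 30))
    winter: tuple[tuple[int, int], tuple[int, int]] = ((12, 1), (2, 29))

    def window(self, season: str) -> tuple[tuple[int, int], tuple[int, int]]:
        try:
            return getattr(self, season)
        except AttributeError:
            raise ValueError(f"unknown season {season!r}") from None


def _md(date: dt.date) -> tuple[int, int]:
    return (date.month, date.day)


def assign_season(date: dt.date, config: SeasonConfig | None = None) -> str:
    """Season label of a calendar date (inclusive window bounds)."""
    config = config or SeasonConfig()
    md = _md(date)
    for season in SEASONS:
        lo, hi = config.window(season)
        if lo <= hi:
            if lo <= md <= hi:
                return season
        else:  # wraps the new year (winter)
            if md >= lo or md <= hi:
                return season
    raise ValueError(f"date {date} not covered by season windows")


def season_length_days(season: str, config: SeasonConfig | None = None, year: int = 2021) -> int:
    """Inclusive day count of the season window.

    ``year`` fixes the calendar used for month lengths (winter spans the
    new year and is counted into that year's February: 90 days in a
    non-leap year, 91 when the February reached is leap).
    """
    config = config or SeasonConfig()
    (m0, d0), (m1, d1) = config.window(season)
    start = dt.date(year, m0, d0)
    if (m0, d0) <= (m1, d1):
        end = dt.date(year, m1, d1)
    else:  # wraps the new year
        end_year = year + 1
        if m1 == 2:
            d1 = min(d1, 29 if _is_leap(end_year) else 28)
        end = dt.date(end_year, m1, d1)
    return (end - start).days + 1


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def seasonal_mtr_means(
    mtr_records: pd.DataFrame,
    season: str,
    phase: str,
    config: SeasonConfig | None = None,
) -> dict:
    """Mean and empirical 10–90 percentiles of MTR in one season × phase.

    Period records are pooled across sites unweighted; percentiles use
    linear interpolation.  An empty stratum is flagged missing.
    """
    config = config or SeasonConfig()
    df = mtr_records.copy()
    if "season" not in df.columns:
        df["season"] = [assign_season(_as_date(d), config) for d in df["date"]]
    sub = df[(df["season"] == season) & (df["phase"] == phase)]
    if sub.empty:
        return {"season": season, "phase": phase, "n": 0, "missing": True,
                "mean": float("nan"), "p10": float("nan"), "p90": float("nan")}
    x = sub["mtr"].to_numpy(dtype=float)
    return {
        "season": season,
        "phase": phase,
        "n": int(x.size),
        "missing": False,
        "mean": float(np.mean(x)),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


def _as_date(d) -> dt.date:
    if isinstance(d, dt.date) and not isinstance(d, dt.datetime):
        return d
    return pd.Timestamp(d).date()


def percent_day_night_difference(mean_day: float, mean_night: float) -> int:
    """Percent by which the daytime mean falls short of the nightly mean.

    100 · (night − day) / night, rounded to the nearest integer percent.
    Undefined (ValueError) when the nightly mean is zero.
    """
    if mean_night == 0:
        raise ValueError("percent difference undefined for zero nightly mean")
    return int(round(100.0 * (mean_night - mean_day) / mean_night))


@dataclass(frozen=True)
class FluxEstimate:
    """Corridor-wide seasonal passage and biomass."""

    season: str
    total_insects: float
    biomass_kg: float
    mean_day_mtr: float
    mean_night_mtr: float
    width_km: float
    n_days: int
    mean_mass_mg: float

    @property
    def total_millions(self) -> float:
        return self.total_insects / 1e6

    @property
    def biomass_tonnes(self) -> float:
        return self.biomass_kg / 1000.0

    def to_dict(self) -> dict:
        return {
            "season": self.season,
            "total_insects": self.total_insects,
            "total_millions": self.total_millions,
            "biomass_kg": self.biomass_kg,
            "biomass_tonnes": self.biomass_tonnes,
            "inputs": {
                "mean_day_mtr": self.mean_day_mtr,
                "mean_night_mtr": self.mean_night_mtr,
                "width_km": self.width_km,
                "n_days": self.n_days,
                "mean_mass_mg": self.mean_mass_mg,
            },
        }


def extrapolate_flux(
    mean_day_mtr: float,
    mean_night_mtr: float,
    width_km: float = DEFAULT_CORRIDOR_WIDTH_KM,
    n_days: int = 102,
    mean_mass_mg: float = DEFAULT_MEAN_MASS_MG,
    season: str = "spring",
) -> FluxEstimate:
    """Scale mean diel traffic rates to a corridor-and-season total.

    total = (mean_day_mtr + mean_night_mtr) · width_km · n_days insects;
    biomass_kg = total · mean_mass_mg · 10⁻⁶.  Linear in every input.
    """
    if min(mean_day_mtr, mean_night_mtr, width_km, mean_mass_mg) < 0:
        raise ValueError("flux inputs must be >= 0")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    total = (mean_day_mtr + mean_night_mtr) * width_km * n_days
    biomass_kg = total * mean_mass_mg * 1e-6
    return FluxEstimate(
        season=season,
        total_insects=total,
        biomass_kg=biomass_kg,
        mean_day_mtr=mean_day_mtr,
        mean_night_mtr=mean_night_mtr,
        width_km=width_km,
        n_days=n_days,
        mean_mass_mg=mean_mass_mg,
    )


def detect_mass_migration_events(
    mtr_series: pd.DataFrame,
    window: int = 7,
    percentile: float = 90.0,
    ratio: float = 2.0,
) -> list:
    """Dates of mass-migration events in one site-phase MTR series.

    A period is an event iff its MTR exceeds the series' ``percentile``
    level AND exceeds ``ratio`` × the median of the surrounding ``window``
    periods (self excluded) — a sudden peak preceded and followed by
    substantially lower values.  The definition is scale-free
    (percentile + ratio) because no quantitative rule is standard.
    Series shorter than window + 1 yield no events.
    """
    df = mtr_series.sort_values("date").reset_index(drop=True)
    n = len(df)
    if n < window + 1:
        return []
    x = df["mtr"].to_numpy(dtype=float)
    level = np.percentile(x, percentile)
    half = window // 2
    events = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neighbours = np.concatenate([x[lo:i], x[i + 1:hi]])
        if neighbours.size == 0:
            continue
        med = np.median(neighbours)
        if x[i] > level and x[i] > ratio * med:
            events.append(df["date"].iloc[i])
    return events


def diel_detection_count(echoes: pd.DataFrame, site_id: str, date: dt.date) -> int:
    """Raw retained-echo count for one site over one 24 h calendar day.

    No beam normalisation — the cross-network comparability statistic.
    """
    if echoes.empty:
        return 0
    ts = pd.to_datetime(echoes["timestamp"], utc=True)
    mask = (echoes["site_id"] == site_id) & (ts.dt.date == date)
    return int(mask.sum())


def seasonal_direction(
    period_summaries: pd.DataFrame,
    second_order: bool = True,
) -> DirectionalSummary:
    """Seasonal circular summary from per-period directional summaries.

    ``second_order=True`` (default) takes the circular mean of per-period
    mean directions — each day or night weighs equally regardless of its
    echo count.  Expects a ``mean_direction`` column; rows with undefined
    means are dropped.
    """
    col = "mean_direction"
    dirs = period_summaries[col].to_numpy(dtype=float)
    dirs = dirs[np.isfinite(dirs)]
    if dirs.size == 0:
        raise ValueError("no defined per-period mean directions")
    if not second_order:
        raise NotImplementedError("pooled echo-level mean is computed upstream")
    return circular_summary(dirs)
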