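"""Diel period assignment and migration-traffic-rate estimation.

A vertical-looking radar observes a cone above the antenna; an insect at
altitude h crosses an effective transect of width w(h) = 2·h·tan(θ/2)
(θ the half-power beamwidth), so each detection represents 1/w(h)
insects per kilometre of transect.  Summing those weights over a diel
period (sunrise→sunset day, sunset→sunrise night) and dividing by the
duty fraction actually observed gives the migration traffic rate (MTR)
in insects·km⁻¹·period⁻¹.

Sun times come from the NOAA solar-position equations (accurate to well
under two minutes at mid-latitudes); nights are labelled with the date
of their sunset so a night spanning midnight carries one label.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BeamConfig",
    "DielPeriodRecord",
    "MtrRecord",
    "sun_times",
    "assign_period",
    "assign_periods_frame",
    "build_periods",
    "effective_transect_width",
    "compute_mtr",
    "compute_mtr_table",
    "vertical_profile",
    "groundspeed_comparison",
    "DEFAULT_DUTY_FRACTION",
]

DEFAULT_DUTY_FRACTION = 40.0 / 60.0  # radar collects 40 min of every hour
MAX_ABS_LATITUDE = 66.5  # no polar day/night handling


def _default_width_fn(theta_deg: float) -> Callable[[np.ndarray], np.ndarray]:
    half = np.deg2rad(theta_deg / 2.0)

    def width_km(h_m: np.ndarray) -> np.ndarray:
        return 2.0 * np.asarray(h_m, dtype=float) * np.tan(half) / 1000.0

    return width_km


@dataclass(frozen=True)
class BeamConfig:
    """Radar beam geometry used to normalise detections to a 1-km transect.

    half_power_beamwidth is in degrees; the default width function is the
    standard cone geometry w(h) = 2·h·tan(θ/2).  Both are configurable so
    alternative normalisation conventions can be matched — absolute MTR
    values are convention-dependent, ratios are not.
    """

    half_power_beamwidth: float = 25.0
    reference_width_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def width_km(self, altitude_agl_m: np.ndarray) -> np.ndarray:
        fn = self.reference_width_fn or _default_width_fn(self.half_power_beamwidth)
        return fn(altitude_agl_m)


@dataclass
class DielPeriodRecord:
    """One site-date day or night observation window."""

    site_id: str
    date: dt.date
    phase: str  # "day" | "night"
    start: pd.Timestamp
    end: pd.Timestamp
    sunrise: pd.Timestamp
    sunset: pd.Timestamp
    observed_fraction: float = DEFAULT_DUTY_FRACTION
    n_echoes: int = 0
    n_directional_echoes: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.observed_fraction <= 1.0:
            raise ValueError("observed_fraction must lie in (0, 1]")
        if self.phase not in ("day", "night"):
            raise ValueError("phase must be 'day' or 'night'")


@dataclass(frozen=True)
class MtrRecord:
    """Migration traffic rate for one diel period (insects km⁻¹ period⁻¹)."""

    site_id: str
    date: dt.date
    phase: str
    mtr: float
    n_echoes: int
    mean_altitude: float

    def __post_init__(self) -> None:
        if self.mtr < 0:
            raise ValueError("mtr must be >= 0")
        if (self.mtr == 0) != (self.n_echoes == 0):
            raise ValueError("mtr is zero iff the period has no echoes")


# --------------------------------------------------------------------------
# NOAA solar position
# --------------------------------------------------------------------------

def _solar_coefficients(jc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equation of time (minutes) and solar declination (radians)."""
    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m_rad = np.deg2rad(m)
    eq_center = (
        np.sin(m_rad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m_rad) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m_rad) * 0.000289
    )
    true_long = l0 + eq_center
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    obliq_rad = np.deg2rad(obliq)
    decl = np.arcsin(np.sin(obliq_rad) * np.sin(np.deg2rad(app_long)))
    var_y = np.tan(obliq_rad / 2.0) ** 2
    l0_rad = np.deg2rad(l0)
    eqtime = 4.0 * np.rad2deg(
        var_y * np.sin(2 * l0_rad)
        - 2.0 * ecc * np.sin(m_rad)
        + 4.0 * ecc * var_y * np.sin(m_rad) * np.cos(2 * l0_rad)
        - 0.5 * var_y**2 * np.sin(4 * l0_rad)
        - 1.25 * ecc**2 * np.sin(2 * m_rad)
    )
    return eqtime, decl


def _julian_century(date: dt.date, minutes_utc: np.ndarray) -> np.ndarray:
    ordinal = np.float64(date.toordinal())
    jd = ordinal + 1721424.5 + minutes_utc / 1440.0
    return (jd - 2451545.0) / 36525.0


def sun_times(latitude: float, longitude: float, date: dt.date) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunrise and sunset (UTC) for one calendar date at a site.

    Zenith 90.833° (refraction plus solar radius).  Two refinement passes
    re-evaluate the equation of time and declination at the event itself.
    Raises for polar latitudes where the day/night dichotomy breaks down.
    """
    if abs(latitude) >= MAX_ABS_LATITUDE:
        raise ValueError(
            f"latitude {latitude} is polewards of ±{MAX_ABS_LATITUDE}°: "
            "polar day/night is not supported"
        )
    lat_rad = np.deg2rad(latitude)
    zenith = np.deg2rad(90.833)

    # first pass at approximate local solar noon, then refine at the events
    rise_min = np.float64(720.0 - 4.0 * longitude)
    set_min = np.float64(720.0 - 4.0 * longitude)
    for _ in range(3):
        events = np.array([rise_min, set_min])
        jc = _julian_century(date, events)
        eqtime, decl = _solar_coefficients(jc)
        cos_ha = (np.cos(zenith) - np.sin(lat_rad) * np.sin(decl)) / (
            np.cos(lat_rad) * np.cos(decl)
        )
        if np.any(np.abs(cos_ha) > 1.0):
            raise ValueError("sun does not rise/set on this date at this latitude")
        ha_deg = np.rad2deg(np.arccos(cos_ha))
        noon = 720.0 - 4.0 * longitude - eqtime
        rise_min = noon[0] - 4.0 * ha_deg[0]
        set_min = noon[1] + 4.0 * ha_deg[1]

    base = pd.Timestamp(date, tz="UTC")
    return (
        base + pd.to_timedelta(float(rise_min), unit="m"),
        base + pd.to_timedelta(float(set_min), unit="m"),
    )


# --------------------------------------------------------------------------
# Period assignment
# --------------------------------------------------------------------------

def assign_period(
    timestamp: pd.Timestamp,
    sunrise: pd.Timestamp,
    sunset: pd.Timestamp,
    next_sunrise: pd.Timestamp | None = None,
) -> tuple[dt.date, str]:
    """Label a single echo timestamp with its diel period.

    Day is the half-open window [sunrise, sunset); a night is labelled by
    the date of its sunset.  A timestamp exactly at sunrise belongs to the
    day; exactly at sunset, to that evening's night.
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    date = sunrise.date()
    if sunrise <= ts < sunset:
        return date, "day"
    if ts >= sunset:
        if next_sunrise is not None and ts >= next_sunrise:
            raise ValueError("timestamp beyond the night following this date")
        return date, "night"
    # before sunrise: tail of the previous night
    return date - dt.timedelta(days=1), "night"


def _site_sun_table(latitude: float, longitude: float, dates: Iterable[dt.date]) -> pd.DataFrame:
    rows = []
    for d in dates:
        sr, ss = sun_times(latitude, longitude, d)
        rows.append({"date": d, "sunrise": sr, "sunset": ss})
    return pd.DataFrame(rows)


def assign_periods_frame(
    echoes: pd.DataFrame,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Vectorised diel assignment for an echo table.

    ``sites`` needs columns site_id, latitude, longitude.  Adds columns
    ``period_date`` and ``phase``; every echo receives exactly one label.
    """
    if echoes.empty:
        out = echoes.copy()
        out["period_date"] = pd.Series(dtype=object)
        out["phase"] = pd.Series(dtype=object)
        return out
    site_meta = sites.set_index("site_id")
    parts = []
    for site_id, grp in echoes.groupby("site_id", sort=False):
        lat = float(site_meta.loc[site_id, "latitude"])
        lon = float(site_meta.loc[site_id, "longitude"])
        ts = pd.to_datetime(grp["timestamp"], utc=True)
        d0 = ts.min().date() - dt.timedelta(days=1)
        d1 = ts.max().date() + dt.timedelta(days=1)
        dates = [d0 + dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]
        suntab = _site_sun_table(lat, lon, dates)
        # event boundaries: sunrise_d opens day d, sunset_d opens night d
        bounds = np.concatenate(
            [suntab["sunrise"].values.astype("datetime64[ns]"),
             suntab["sunset"].values.astype("datetime64[ns]")]
        )
        labels = [(d, "day") for d in suntab["date"]] + [(d, "night") for d in suntab["date"]]
        order = np.argsort(bounds)
        bounds = bounds[order]
        labels = [labels[i] for i in order]
        idx = np.searchsorted(bounds, ts.values.astype("datetime64[ns]"), side="right") - 1
        if np.any(idx < 0):
            raise ValueError("echo precedes the computed sun-time table")
        g = grp.copy()
        g["period_date"] = [labels[i][0] for i in idx]
        g["phase"] = [labels[i][1] for i in idx]
        parts.append(g)
    return pd.concat(parts).sort_index()


def build_periods(
    sites: pd.DataFrame,
    start: dt.date,
    end: dt.date,
    observed_fraction: float = DEFAULT_DUTY_FRACTION,
) -> list[DielPeriodRecord]:
    """Enumerate day and night observation windows for each site-date."""
    if end < start:
        raise ValueError("end date precedes start date")
    records: list[DielPeriodRecord] = []
    for row in sites.itertuples(index=False):
        dates = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
        sun = {d: sun_times(row.latitude, row.longitude, d) for d in dates}
        last = end + dt.timedelta(days=1)
        sun[last] = sun_times(row.latitude, row.longitude, last)
        for d in dates:
            sr, ss = sun[d]
            next_sr = sun[d + dt.timedelta(days=1)][0]
            records.append(
                DielPeriodRecord(
                    site_id=row.site_id, date=d, phase="day",
                    start=sr, end=ss, sunrise=sr, sunset=ss,
                    observed_fraction=observed_fraction,
                )
            )
            records.append(
                DielPeriodRecord(
                    site_id=row.site_id, date=d, phase="night",
                    start=ss, end=next_sr, sunrise=sr, sunset=ss,
                    observed_fraction=observed_fraction,
                )
            )
    return records


# --------------------------------------------------------------------------
# MTR
# --------------------------------------------------------------------------

def effective_transect_width(altitude_agl_m: float | np.ndarray, beam: BeamConfig) -> float | np.ndarray:
    """Effective transect width w(h) in km at altitude h."""
    h = np.asarray(altitude_agl_m, dtype=float)
    if np.any(h <= 0):
        raise ValueError("altitude must be positive")
    w = beam.width_km(h)
    return float(w) if np.isscalar(altitude_agl_m) else w


def compute_mtr(
    echoes_in_period: pd.DataFrame,
    period: DielPeriodRecord,
    beam: BeamConfig | None = None,
) -> MtrRecord:
    """MTR of one diel period.

    mtr = (1 / observed_fraction) · Σᵢ 1 / w(hᵢ), insects km⁻¹ period⁻¹.
    All retained echoes contribute, including those without a measured
    displacement direction.
    """
    beam = beam or BeamConfig()
    if period.observed_fraction <= 0:
        raise ValueError("observed_fraction must be positive")
    n = len(echoes_in_period)
    if n == 0:
        return MtrRecord(period.site_id, period.date, period.phase, 0.0, 0, float("nan"))
    h = echoes_in_period["altitude_agl_m"].to_numpy(dtype=float)
    w = effective_transect_width(h, beam)
    mtr = float(np.sum(1.0 / w) / period.observed_fraction)
    return MtrRecord(period.site_id, period.date, period.phase, mtr, n, float(h.mean()))


def compute_mtr_table(
    echoes: pd.DataFrame,
    periods: list[DielPeriodRecord],
    beam: BeamConfig | None = None,
) -> pd.DataFrame:
    """MTR per period for an assigned echo table (period_date/phase columns).

    Every enumerated period appears in the output, zero-MTR when no echo
    fell inside it.
    """
    beam = beam or BeamConfig()
    grouped = (
        echoes.groupby(["site_id", "period_date", "phase"], sort=False)
        if not echoes.empty
        else None
    )
    groups = {k: v for k, v in grouped} if grouped is not None else {}
    rows = []
    for per in periods:
        key = (per.site_id, per.date, per.phase)
        sub = groups.get(key)
        if sub is None:
            rec = MtrRecord(per.site_id, per.date, per.phase, 0.0, 0, float("nan"))
        else:
            rec = compute_mtr(sub, per, beam)
        rows.append(
            {
                "site_id": rec.site_id,
                "date": rec.date,
                "phase": rec.phase,
                "mtr": rec.mtr,
                "n_echoes": rec.n_echoes,
                "mean_altitude": rec.mean_altitude,
            }
        )
    return pd.DataFrame(rows)


def vertical_profile(
    echoes: pd.DataFrame,
    bin_width_m: float = 50.0,
    alt_range: tuple[float, float] = (50.0, 500.0),
) -> pd.DataFrame:
    """Normalised altitude histogram per diel phase.

    Bins are half-open [lo, hi) of ``bin_width_m`` starting at the
    analysis floor; per-phase proportions sum to 1.  An empty phase is
    flagged (all-zero row, ``empty=True``).
    """
    lo, hi = alt_range
    edges = np.arange(lo, hi + bin_width_m / 2, bin_width_m)
    rows = []
    for phase in ("day", "night"):
        sub = echoes[echoes["phase"] == phase] if "phase" in echoes else echoes.iloc[0:0]
        counts, _ = np.histogram(sub["altitude_agl_m"], bins=edges)
        total = counts.sum()
        props = counts / total if total else np.zeros_like(counts, dtype=float)
        for b_lo, b_hi, p in zip(edges[:-1], edges[1:], props):
            rows.append(
                {"phase": phase, "bin_lo_m": b_lo, "bin_hi_m": b_hi,
                 "proportion": p, "empty": total == 0}
            )
    return pd.DataFrame(rows)


def groundspeed_comparison(
    group_a: np.ndarray | pd.Series,
    group_b: np.ndarray | pd.Series,
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
) -> dict:
    """Compare ground speeds of two groups of echoes.

    Shapiro–Wilk normality check on each group at ``alpha``; a two-tailed
    t-test (Welch) when both pass, otherwise a two-sided Mann–Whitney U.
    Groups with fewer than three values skip the comparison with a reason.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    out: dict = {
        "groups": {
            labels[0]: _speed_summary(a),
            labels[1]: _speed_summary(b),
        },
        "alpha": alpha,
    }
    if a.size < 3 or b.size < 3:
        out.update(test=None, skipped=True, reason="group with n < 3")
        return out
    # Shapiro–Wilk is defined for n <= 5000; subsample deterministically above
    def _normal(x: np.ndarray) -> bool:
        xs = x if x.size <= 5000 else x[:: max(1, x.size // 5000)][:5000]
        if np.ptp(xs) == 0:
            return False
        return stats.shapiro(xs).pvalue > alpha

    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    out.update(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        skipped=False,
    )
    return out


def _speed_summary(x: np.ndarray) -> dict:
    if x.size == 0:
        return {"n": 0, "mean": float("nan"), "median": float("nan")}
    return {"n": int(x.size), "mean": float(np.mean(x)), "median": float(np.median(x))}
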