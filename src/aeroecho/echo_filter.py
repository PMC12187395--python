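"""Reading and quality-filtering of echo-level radar detection tables.

A vertical-looking biological radar exports one row per detected target
with kinematic fields (altitude, displacement direction, ground speed),
a wingbeat frequency, and per-class classification probabilities.  The
analysis set keeps echoes that

* carry a cumulative bird-class probability of at most 50% (echoes whose
  summed bird-class probabilities exceed the threshold are likely
  misclassified vertebrates),
* have wingbeat frequency of at least 10 Hz (lower frequencies are rare
  in insects and overlap with vertebrate signatures), and
* fly strictly between 50 m (ground clutter / non-migratory movements)
  and 500 m (detection ceiling for insect-sized targets) above ground.

Both altitude bounds are exclusive.  Missing direction or ground speed
never excludes an echo: only half the collection time has the rotating
antenna mode that measures displacement direction, and direction-less
echoes still count toward traffic rates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RadarEcho",
    "FilterConfig",
    "EchoTable",
    "FilterReport",
    "read_echo_table",
    "apply_filters",
    "echoes_to_frame",
    "MANDATORY_COLUMNS",
    "BIRD_PROB_PATTERN",
]

MANDATORY_COLUMNS = (
    "timestamp",
    "site_id",
    "altitude_agl_m",
    "wbf_hz",
    "direction_deg",
    "ground_speed_ms",
    "insect_prob",
)
BIRD_PROB_PATTERN = re.compile(r"^bird_prob_\d+$")

RULE_BIRD = "bird_probability"
RULE_WBF = "low_wbf"
RULE_ALTITUDE = "altitude_band"
FILTER_RULES = (RULE_BIRD, RULE_WBF, RULE_ALTITUDE)


@dataclass(frozen=True)
class RadarEcho:
    """A single radar-detected target."""

    timestamp: pd.Timestamp
    site_id: str
    altitude_agl: float
    wbf: float
    direction: float | None
    ground_speed: float | None
    insect_prob: float
    bird_prob_components: tuple[float, ...]
    rcs_proxy: float | None = None
    polarity_shape: float | None = None

    def __post_init__(self) -> None:
        if self.altitude_agl < 0:
            raise ValueError("altitude_agl must be >= 0")
        if self.wbf < 0:
            raise ValueError("wbf must be >= 0")
        if not 0 <= self.insect_prob <= 100:
            raise ValueError("insect_prob must be a percent in [0, 100]")
        for p in self.bird_prob_components:
            if not 0 <= p <= 100:
                raise ValueError("bird probabilities must be percents in [0, 100]")
        if self.direction is not None and not np.isnan(self.direction):
            if not 0 <= self.direction < 360:
                raise ValueError("direction must lie in [0, 360)")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the echo quality filters.

    ``bird_prob_threshold`` excludes echoes whose *cumulative* bird-class
    probability is strictly greater than the threshold (exactly 50 is
    retained).  ``min_wbf`` excludes wingbeat frequencies strictly below
    it.  Altitude bounds are exclusive at both ends.
    """

    bird_prob_threshold: float = 50.0
    min_wbf: float = 10.0
    min_altitude: float = 50.0
    max_altitude: float = 500.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_altitude < self.max_altitude:
            raise ValueError("require 0 <= min_altitude < max_altitude")
        if self.bird_prob_threshold < 0 or self.min_wbf < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class EchoTable:
    """Parsed echo table plus row-level parse bookkeeping."""

    frame: pd.DataFrame
    n_skipped: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def to_echoes(self) -> list[RadarEcho]:
        """Materialise the table as RadarEcho records."""
        bird_cols = [c for c in self.frame.columns if BIRD_PROB_PATTERN.match(c)]
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            out.append(
                RadarEcho(
                    timestamp=d["timestamp"],
                    site_id=d["site_id"],
                    altitude_agl=d["altitude_agl_m"],
                    wbf=d["wbf_hz"],
                    direction=d["direction_deg"],
                    ground_speed=d["ground_speed_ms"],
                    insect_prob=d["insect_prob"],
                    bird_prob_components=tuple(d[c] for c in bird_cols),
                )
            )
        return out


@dataclass
class FilterReport:
    """Removal bookkeeping with first-failing-rule attribution."""

    n_input: int
    n_retained: int
    removed_by_rule: dict[str, int]
    config: FilterConfig

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    @property
    def fraction_removed_by_rule(self) -> dict[str, float]:
        if self.n_input == 0:
            return {r: 0.0 for r in self.removed_by_rule}
        return {r: c / self.n_input for r, c in self.removed_by_rule.items()}

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "removed_by_rule": dict(self.removed_by_rule),
            "fraction_removed_by_rule": self.fraction_removed_by_rule,
            "config": {
                "bird_prob_threshold": self.config.bird_prob_threshold,
                "min_wbf": self.config.min_wbf,
                "min_altitude": self.config.min_altitude,
                "max_altitude": self.config.max_altitude,
            },
        }


def read_echo_table(path: str | Path) -> EchoTable:
    """Read an echo CSV with strict typing and row-level error tolerance.

    Mandatory columns: timestamp, site_id, altitude_agl_m, wbf_hz,
    direction_deg, ground_speed_ms, insect_prob, plus one or more
    bird_prob_<k> columns.  A missing mandatory column raises a schema
    error naming it.  Rows with unparseable timestamps or numerics are
    skipped and counted, never silently coerced into the analysis set.
    Timestamps are normalised to UTC.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"echo table is missing mandatory column {col!r}")
    bird_cols = [c for c in df.columns if BIRD_PROB_PATTERN.match(c)]
    if not bird_cols:
        raise ValueError("echo table is missing bird_prob_<k> columns")

    skip_reasons: dict[str, int] = {}
    bad = pd.Series(False, index=df.index)

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="mixed")
    _flag(bad, skip_reasons, ts.isna(), "unparseable_timestamp")

    numeric: dict[str, pd.Series] = {}
    required_numeric = ["altitude_agl_m", "wbf_hz", "insect_prob", *bird_cols]
    for col in required_numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        _flag(bad, skip_reasons, vals.isna(), f"unparseable_{col}")
        numeric[col] = vals
    # direction and speed may legitimately be blank (non-rotating antenna)
    for col in ("direction_deg", "ground_speed_ms"):
        raw = df[col].where(df[col] != "", other=np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        _flag(bad, skip_reasons, vals.isna() & raw.notna(), f"unparseable_{col}")
        numeric[col] = vals

    _flag(bad, skip_reasons, numeric["altitude_agl_m"] < 0, "negative_altitude")
    _flag(bad, skip_reasons, numeric["wbf_hz"] < 0, "negative_wbf")
    dir_vals = numeric["direction_deg"]
    _flag(
        bad,
        skip_reasons,
        dir_vals.notna() & ((dir_vals < 0) | (dir_vals >= 360)),
        "direction_out_of_range",
    )

    keep = ~bad
    out = pd.DataFrame(
        {
            "timestamp": ts[keep],
            "site_id": df.loc[keep, "site_id"].astype(str),
            **{c: numeric[c][keep].astype(float) for c in numeric},
        }
    ).reset_index(drop=True)
    return EchoTable(frame=out, n_skipped=int(bad.sum()), skip_reasons=skip_reasons)


def _flag(bad: pd.Series, reasons: dict[str, int], mask: pd.Series, reason: str) -> None:
    new = mask & ~bad
    n = int(new.sum())
    if n:
        reasons[reason] = reasons.get(reason, 0) + n
        bad |= new


def cumulative_bird_probability(frame: pd.DataFrame) -> pd.Series:
    """Sum of all bird-class probability columns, per echo."""
    bird_cols = [c for c in frame.columns if BIRD_PROB_PATTERN.match(c)]
    if not bird_cols:
        raise ValueError("no bird_prob_<k> columns present")
    return frame[bird_cols].sum(axis=1)


def apply_filters(
    echoes: pd.DataFrame | EchoTable,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the analysis filters; attribute removals to the first failing rule.

    Rules, in order: cumulative bird probability > threshold; wingbeat
    frequency < min_wbf; altitude outside the open interval
    (min_altitude, max_altitude).  Idempotent: re-filtering the retained
    set removes nothing.
    """
    config = config or FilterConfig()
    frame = echoes.frame if isinstance(echoes, EchoTable) else echoes
    if frame.empty:
        report = FilterReport(0, 0, {r: 0 for r in FILTER_RULES}, config)
        return frame.copy(), report

    bird_fail = cumulative_bird_probability(frame) > config.bird_prob_threshold
    wbf_fail = frame["wbf_hz"] < config.min_wbf
    alt = frame["altitude_agl_m"]
    alt_fail = ~((alt > config.min_altitude) & (alt < config.max_altitude))

    first_rule = pd.Series("", index=frame.index)
    first_rule[alt_fail] = RULE_ALTITUDE
    first_rule[wbf_fail] = RULE_WBF
    first_rule[bird_fail] = RULE_BIRD  # listed order wins: bird, wbf, altitude

    removed_by_rule = {r: int((first_rule == r).sum()) for r in FILTER_RULES}
    retained = frame[first_rule == ""].reset_index(drop=True)
    report = FilterReport(
        n_input=len(frame),
        n_retained=len(retained),
        removed_by_rule=removed_by_rule,
        config=config,
    )
    return retained, report


def echoes_to_frame(echoes: list[RadarEcho]) -> pd.DataFrame:
    """Convert RadarEcho records to the tabular schema."""
    if not echoes:
        return pd.DataFrame(columns=list(MANDATORY_COLUMNS) + ["bird_prob_1"])
    k = max(len(e.bird_prob_components) for e in echoes)
    rows = []
    for e in echoes:
        row = {
            "timestamp": e.timestamp,
            "site_id": e.site_id,
            "altitude_agl_m": e.altitude_agl,
            "wbf_hz": e.wbf,
            "direction_deg": np.nan if e.direction is None else e.direction,
            "ground_speed_ms": np.nan if e.ground_speed is None else e.ground_speed,
            "insect_prob": e.insect_prob,
        }
        for i in range(k):
            comp = e.bird_prob_components
            row[f"bird_prob_{i + 1}"] = comp[i] if i < len(comp) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
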