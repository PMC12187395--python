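"""End-to-end orchestration: simulate/ingest → filter → MTR → directions →
seasonal flux → weather models, with a reproducibility manifest.

Every stage reads only prior-stage outputs; rerunning with the same
config and seed reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular_stats import period_directionality, downwind_direction, watson_u2
from .diel_mtr import (
    BeamConfig,
    DEFAULT_DUTY_FRACTION,
    assign_periods_frame,
    build_periods,
    compute_mtr_table,
)
from .echo_filter import FilterConfig, apply_filters, read_echo_table
from .phenology_flux import (
    DEFAULT_CORRIDOR_WIDTH_KM,
    DEFAULT_MEAN_MASS_MG,
    SeasonConfig,
    assign_season,
    detect_mass_migration_events,
    extrapolate_flux,
    percent_day_night_difference,
    season_length_days,
    seasonal_direction,
    seasonal_mtr_means,
)
from .synthetic_radar import SimulationConfig, SiteMetadata, generate_campaign
from .weather_brt import (
    BrtConfig,
    average_weather_by_period,
    build_design_strata,
    predictor_correlations,
    relative_influence,
    step_select,
)

__all__ = ["RunConfig", "run_pipeline", "read_weather_table"]

logger = logging.getLogger("aeroecho")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    output_dir: Path
    seed: int = 0
    simulate: bool = True
    sim_config: SimulationConfig | None = None
    echoes_path: Path | None = None
    weather_path: Path | None = None
    sites_path: Path | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    beam: BeamConfig = field(default_factory=BeamConfig)
    observed_fraction: float = DEFAULT_DUTY_FRACTION
    season_config: SeasonConfig = field(default_factory=SeasonConfig)
    brt_config: BrtConfig | None = None
    run_brt: bool = False
    corridor_width_km: float = DEFAULT_CORRIDOR_WIDTH_KM
    mean_mass_mg: float = DEFAULT_MEAN_MASS_MG
    min_directional_echoes: int = 10

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not self.simulate:
            for p in (self.echoes_path, self.weather_path, self.sites_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"ingest mode requires existing input path, got {p}")


def read_weather_table(path: str | Path) -> pd.DataFrame:
    """Hourly weather from CSV or NetCDF (.nc via xarray, scipy engine)."""
    path = Path(path)
    if path.suffix == ".nc":
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        df = ds.to_dataframe().reset_index()
    else:
        df = pd.read_csv(path)
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return df


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (dt.date, dt.datetime, Path)):
            return str(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return repr(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (dt.date, dt.datetime)):
            return o.isoformat()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "aeroecho": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    try:
        # ---- stage 1: simulate or ingest -------------------------------
        if config.simulate:
            sim = config.sim_config or SimulationConfig(seed=config.seed)
            echoes, weather, truth = generate_campaign(sim)
            sites = pd.DataFrame(
                [
                    {
                        "site_id": s.site_id, "latitude": s.latitude,
                        "longitude": s.longitude, "elevation": s.elevation,
                        "deployment_start": s.deployment_start,
                        "deployment_end": s.deployment_end,
                    }
                    for s in sim.sites
                ]
            )
            echoes.to_csv(out / "echoes.csv", index=False)
            weather.to_csv(out / "weather.csv", index=False)
            sites.to_csv(out / "sites.csv", index=False)
            _write_json(out / "truth.json", truth)
        else:
            table = read_echo_table(config.echoes_path)
            echoes = table.frame
            weather = read_weather_table(config.weather_path)
            sites = pd.read_csv(config.sites_path)
            manifest["stages"]["ingest_skipped_rows"] = table.n_skipped
        manifest["stages"]["input"] = {"n_echoes": len(echoes), "n_weather_hours": len(weather)}
        logger.info("input: %d echoes, %d weather hours", len(echoes), len(weather))

        # ---- stage 2: filter -------------------------------------------
        filtered, report = apply_filters(echoes, config.filter_config)
        filtered.to_csv(out / "filtered.csv", index=False)
        _write_json(out / "filter_report.json", report.to_dict())
        manifest["stages"]["filter"] = {"rows_in": report.n_input, "rows_out": report.n_retained}
        logger.info("filter: %d -> %d rows", report.n_input, report.n_retained)

        # ---- stage 3: periods and MTR ----------------------------------
        assigned = assign_periods_frame(filtered, sites)
        ts = pd.to_datetime(assigned["timestamp"], utc=True) if len(assigned) else None
        if len(assigned):
            start, end = ts.min().date(), ts.max().date()
        else:
            raise RuntimeError("no echoes survive filtering; nothing to analyse")
        periods = build_periods(sites, start, end, config.observed_fraction)
        mtr = compute_mtr_table(assigned, periods, config.beam)
        mtr["season"] = [assign_season(d, config.season_config) for d in mtr["date"]]
        mtr.to_csv(out / "mtr.csv", index=False)
        manifest["stages"]["mtr"] = {"n_periods": len(mtr)}
        logger.info("mtr: %d diel periods", len(mtr))

        # ---- stage 4: directions ---------------------------------------
        dir_rows = []
        for (site_id, date, phase), grp in assigned.groupby(
            ["site_id", "period_date", "phase"], sort=True
        ):
            summ = period_directionality(
                grp["direction_deg"], n_min=config.min_directional_echoes
            )
            dir_rows.append(
                {
                    "site_id": site_id, "date": date, "phase": phase,
                    "season": assign_season(date, config.season_config),
                    "n_directional": summ.n, "mean_direction": summ.mean_direction,
                    "r": summ.r, "rayleigh_z": summ.rayleigh_z,
                    "rayleigh_p": summ.rayleigh_p, "ns_component": summ.ns_component,
                    "significant": summ.significant, "insufficient": summ.insufficient,
                }
            )
        directions = pd.DataFrame(dir_rows)
        period_weather = average_weather_by_period(weather, periods)
        period_weather["downwind_deg"] = downwind_direction(
            period_weather["u_wind_ms"].to_numpy(), period_weather["v_wind_ms"].to_numpy()
        )
        directions = directions.merge(
            period_weather[["site_id", "date", "phase", "downwind_deg"]],
            on=["site_id", "date", "phase"], how="left",
        )
        directions.to_csv(out / "directions.csv", index=False)
        seasonal_dirs = {}
        usable = directions[directions["significant"] & ~directions["insufficient"]]
        for (season, phase), grp in usable.groupby(["season", "phase"]):
            if len(grp) < 2:
                continue
            s = seasonal_direction(grp)
            seasonal_dirs[f"{season}:{phase}"] = {
                "n_periods": s.n, "mean_direction": s.mean_direction, "r": s.r,
                "rayleigh_p": s.rayleigh_p, "ns_component": s.ns_component,
                "angular_deviation": s.angular_deviation, "circular_std": s.circular_std,
            }
        # insect displacement vs downwind direction, per migration season/phase
        for (season, phase), grp in usable.groupby(["season", "phase"]):
            if season not in ("spring", "autumn"):
                continue
            insect = grp["mean_direction"].to_numpy(dtype=float)
            wind = grp["downwind_deg"].to_numpy(dtype=float)
            ok = np.isfinite(insect) & np.isfinite(wind)
            if ok.sum() < 8:
                continue
            res = watson_u2(insect[ok], wind[ok], n_permutations=999, seed=config.seed)
            key = f"{season}:{phase}"
            seasonal_dirs.setdefault(key, {})["watson_u2_vs_downwind"] = {
                "u2": res.u2, "p": res.p, "n": res.n1,
            }
        _write_json(out / "seasonal_directions.json", seasonal_dirs)
        manifest["stages"]["directions"] = {"n_period_summaries": len(directions)}

        # ---- stage 5: seasonal flux ------------------------------------
        flux: dict = {"seasonal_means": {}, "extrapolations": {}, "events": {}}
        for season in ("spring", "autumn"):
            means = {
                phase: seasonal_mtr_means(mtr, season, phase, config.season_config)
                for phase in ("day", "night")
            }
            flux["seasonal_means"][season] = means
            if means["day"]["missing"] or means["night"]["missing"]:
                continue
            n_days = season_length_days(season, config.season_config)
            est = extrapolate_flux(
                means["day"]["mean"], means["night"]["mean"],
                width_km=config.corridor_width_km, n_days=n_days,
                mean_mass_mg=config.mean_mass_mg, season=season,
            )
            flux["extrapolations"][season] = est.to_dict()
            try:
                flux[f"percent_day_night_difference_{season}"] = percent_day_night_difference(
                    means["day"]["mean"], means["night"]["mean"]
                )
            except ValueError:
                flux[f"percent_day_night_difference_{season}"] = None
        for (site_id, phase), grp in mtr.groupby(["site_id", "phase"]):
            for season in ("spring", "autumn"):
                sub = grp[grp["season"] == season]
                events = detect_mass_migration_events(sub)
                if events:
                    flux["events"][f"{site_id}:{phase}:{season}"] = [str(d) for d in events]
        _write_json(out / "flux.json", flux)
        manifest["stages"]["flux"] = {
            "seasons_extrapolated": sorted(flux["extrapolations"].keys())
        }

        # ---- stage 6: weather models (optional, slow) -------------------
        if config.run_brt:
            brt_cfg = config.brt_config or BrtConfig(seed=config.seed)
            mtr_joined = mtr.copy()
            strata = build_design_strata(mtr_joined, period_weather)
            brt_out = {}
            for (season, phase), design in strata.items():
                if len(design.y) < 30:
                    continue
                corr = predictor_correlations(design)
                model = step_select(design, brt_cfg)
                brt_out[f"{season}:{phase}"] = {
                    "n_rows": int(len(design.y)),
                    "n_trees_selected": model.n_trees_selected,
                    "cv_correlation": model.cv_correlation,
                    "relative_influence": relative_influence(model),
                    "high_predictor_correlations": corr[corr["high"]].to_dict("records"),
                }
            _write_json(out / "brt.json", brt_out)
            manifest["stages"]["brt"] = {"strata": sorted(brt_out.keys())}

        _write_json(out / "manifest.json", manifest)
        return manifest
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        partial = out / "manifest.partial.json"
        manifest["error"] = str(exc)
        _write_json(partial, manifest)
        raise
    finally:
        logger.removeHandler(handler)
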