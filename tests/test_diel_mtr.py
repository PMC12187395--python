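"""Sun times, diel assignment, beam geometry, MTR and ground speeds."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from aeroecho.diel_mtr import (
    BeamConfig,
    DielPeriodRecord,
    assign_period,
    assign_periods_frame,
    build_periods,
    compute_mtr,
    compute_mtr_table,
    effective_transect_width,
    groundspeed_comparison,
    sun_times,
    vertical_profile,
)


def _noaa_series_sun_times(lat, lon, date):
    """Independent oracle: NOAA's low-order Fourier-series formulation.

    Uses the fractional-year expansion of the equation of time and solar
    declination — a different derivation from the spreadsheet ephemeris
    used by the implementation.
    """
    lat_r = np.deg2rad(lat)
    doy = date.timetuple().tm_yday
    out = {}
    for which, guess in (("rise", 6.0), ("set", 18.0)):
        hour = guess - lon / 15.0
        for _ in range(3):
            gamma = 2 * np.pi / 365.0 * (doy - 1 + (hour - 12) / 24.0)
            eqtime = 229.18 * (
                0.000075 + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
                - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma)
            )
            decl = (
                0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
                - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
                - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma)
            )
            cos_ha = np.cos(np.deg2rad(90.833)) / (np.cos(lat_r) * np.cos(decl)) - np.tan(
                lat_r
            ) * np.tan(decl)
            ha = np.rad2deg(np.arccos(np.clip(cos_ha, -1, 1)))
            if which == "rise":
                minutes = 720 - 4 * (lon + ha) - eqtime
            else:
                minutes = 720 - 4 * (lon - ha) - eqtime
            hour = minutes / 60.0
        out[which] = minutes
    return out["rise"], out["set"]


class TestSunTimes:
    def test_equatorial_equinox_symmetry(self):
        # at the equator on an equinox the day is 12 h (plus ~7 min of
        # refraction) centred on solar noon, itself within the equation
        # of time (±~8 min) of 12:00 UTC at longitude 0
        sr, ss = sun_times(0.0, 0.0, dt.date(2020, 3, 20))
        assert abs((sr - pd.Timestamp("2020-03-20 06:00", tz="UTC")).total_seconds()) < 600
        day_length_s = (ss - sr).total_seconds()
        assert abs(day_length_s - 12 * 3600) < 600
        noon = sr + (ss - sr) / 2
        assert abs((noon - pd.Timestamp("2020-03-20 12:00", tz="UTC")).total_seconds()) < 600

    def test_consecutive_days_shift_slowly(self):
        sr1, ss1 = sun_times(33.1, 35.6, dt.date(2021, 4, 10))
        sr2, ss2 = sun_times(33.1, 35.6, dt.date(2021, 4, 11))
        day = dt.timedelta(days=1)
        assert abs((sr2 - sr1 - day).total_seconds()) < 180
        assert abs((ss2 - ss1 - day).total_seconds()) < 180

    @pytest.mark.parametrize(
        "lat,lon,date",
        [
            (33.1, 35.6, dt.date(2020, 6, 21)),
            (33.1, 35.6, dt.date(2020, 12, 21)),
            (45.0, -120.0, dt.date(2021, 9, 1)),
            (-20.0, 30.0, dt.date(2021, 1, 15)),
        ],
    )
    def test_matches_independent_noaa_series(self, lat, lon, date):
        # the 3-term Fourier oracle itself truncates at ~±2 min in the
        # worst season/latitude, so the agreement bound is 3 min
        sr, ss = sun_times(lat, lon, date)
        rise_min, set_min = _noaa_series_sun_times(lat, lon, date)
        base = pd.Timestamp(date, tz="UTC")
        assert abs((sr - base).total_seconds() / 60.0 - rise_min) < 3.0
        assert abs((ss - base).total_seconds() / 60.0 - set_min) < 3.0

    def test_solstice_reference_value(self):
        # cross-checked by explicit hour-angle arithmetic (declination
        # 23.44°, equation of time −1.7 min): sunrise 02:29 UTC
        sr, _ = sun_times(33.1, 35.6, dt.date(2020, 6, 21))
        assert abs((sr - pd.Timestamp("2020-06-21 02:29", tz="UTC")).total_seconds()) < 120

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            sun_times(70.0, 0.0, dt.date(2020, 6, 21))


class TestAssignPeriod:
    def setup_method(self):
        self.sr = pd.Timestamp("2021-04-01 03:00", tz="UTC")
        self.ss = pd.Timestamp("2021-04-01 15:30", tz="UTC")
        self.next_sr = pd.Timestamp("2021-04-02 02:59", tz="UTC")

    def test_exact_sunrise_is_day(self):
        date, phase = assign_period(self.sr, self.sr, self.ss)
        assert phase == "day" and date == dt.date(2021, 4, 1)

    def test_exact_sunset_opens_night_of_same_date(self):
        date, phase = assign_period(self.ss, self.sr, self.ss)
        assert phase == "night" and date == dt.date(2021, 4, 1)

    def test_just_before_next_sunrise_is_previous_night(self):
        ts = self.next_sr - pd.Timedelta(seconds=1)
        date, phase = assign_period(ts, self.next_sr, self.ss + pd.Timedelta(days=1))
        assert phase == "night" and date == dt.date(2021, 4, 1)

    def test_stream_partition_covers_every_echo_once(self, spring_sites_frame):
        """A uniform 48 h echo stream is partitioned without loss or overlap."""
        times = pd.date_range("2021-04-05", periods=288, freq="10min", tz="UTC")
        echoes = pd.DataFrame(
            {"timestamp": times, "site_id": "hula", "altitude_agl_m": 200.0}
        )
        assigned = assign_periods_frame(echoes, spring_sites_frame)
        assert len(assigned) == len(echoes)
        assert assigned["phase"].isin(["day", "night"]).all()
        # every (date, phase) group is a contiguous block in time
        codes = assigned.sort_values("timestamp")[["period_date", "phase"]].astype(str).agg(
            ":".join, axis=1
        )
        changes = (codes != codes.shift()).sum()
        assert changes == codes.nunique()


class TestBeamGeometry:
    def test_right_angle_beam(self):
        assert effective_transect_width(100.0, BeamConfig(90.0)) == pytest.approx(0.2)

    def test_sixty_degree_closed_form(self):
        assert effective_transect_width(250.0, BeamConfig(60.0)) == pytest.approx(
            0.288675, abs=1e-5
        )

    def test_width_shrinks_with_beamwidth(self):
        widths = [effective_transect_width(200.0, BeamConfig(th)) for th in (40, 20, 10, 5, 1)]
        assert all(a > b for a, b in zip(widths, widths[1:]))
        assert widths[-1] < 0.01

    def test_nonpositive_altitude_rejected(self):
        with pytest.raises(ValueError):
            effective_transect_width(0.0, BeamConfig())


def _period(observed_fraction=1.0):
    return DielPeriodRecord(
        site_id="hula", date=dt.date(2021, 4, 1), phase="day",
        start=pd.Timestamp("2021-04-01 03:00", tz="UTC"),
        end=pd.Timestamp("2021-04-01 15:30", tz="UTC"),
        sunrise=pd.Timestamp("2021-04-01 03:00", tz="UTC"),
        sunset=pd.Timestamp("2021-04-01 15:30", tz="UTC"),
        observed_fraction=observed_fraction,
    )


class TestComputeMtr:
    def test_no_echoes_zero_mtr(self):
        rec = compute_mtr(pd.DataFrame({"altitude_agl_m": []}), _period())
        assert rec.mtr == 0.0 and rec.n_echoes == 0

    def test_single_echo_reciprocal_width(self):
        # w(h) = 0.1 km at h = 100 m with θ = 53.13° (2·tan(θ/2) = 1)
        theta = 2 * np.degrees(np.arctan(0.5))
        rec = compute_mtr(
            pd.DataFrame({"altitude_agl_m": [100.0]}), _period(1.0), BeamConfig(theta)
        )
        assert rec.mtr == pytest.approx(10.0)

    def test_linearity_in_echo_count(self):
        df = pd.DataFrame({"altitude_agl_m": [120.0, 250.0, 400.0]})
        single = compute_mtr(df, _period())
        doubled = compute_mtr(pd.concat([df, df]), _period())
        assert doubled.mtr == pytest.approx(2 * single.mtr)

    def test_duty_fraction_scaling(self):
        df = pd.DataFrame({"altitude_agl_m": [120.0, 250.0]})
        full = compute_mtr(df, _period(1.0))
        half = compute_mtr(df, _period(0.5))
        assert half.mtr == pytest.approx(2 * full.mtr)

    def test_estimator_recovers_planted_flux(self, dense_campaign, spring_sites_frame):
        """Paired mean MTR within 5% of the generator's true per-period flux."""
        from aeroecho.echo_filter import apply_filters

        echoes, _, truth = dense_campaign
        filtered, _ = apply_filters(echoes)
        assigned = assign_periods_frame(filtered, spring_sites_frame)
        tdf = pd.DataFrame(truth["periods"])
        tdf["date"] = pd.to_datetime(tdf["date"]).dt.date
        periods = build_periods(
            spring_sites_frame, tdf["date"].min(), tdf["date"].max(),
            truth["planted"]["observed_fraction"],
        )
        mtr = compute_mtr_table(
            assigned, periods, BeamConfig(truth["planted"]["half_power_beamwidth"])
        )
        joined = mtr.merge(
            tdf[["site_id", "date", "phase", "flux_per_km"]],
            on=["site_id", "date", "phase"],
        )
        big = joined[joined["n_echoes"] >= 200]
        assert len(big) >= 40
        rel_bias = (big["mtr"].mean() - big["flux_per_km"].mean()) / big["flux_per_km"].mean()
        assert abs(rel_bias) < 0.05


class TestVerticalProfile:
    def test_single_altitude_single_bin(self):
        df = pd.DataFrame({"altitude_agl_m": [260.0] * 20, "phase": "day"})
        prof = vertical_profile(df)
        day = prof[prof["phase"] == "day"]
        assert day.loc[day["bin_lo_m"] == 250.0, "proportion"].iloc[0] == pytest.approx(1.0)
        assert day["proportion"].sum() == pytest.approx(1.0)

    def test_uniform_altitudes_near_uniform_bins(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"altitude_agl_m": rng.uniform(50, 500, 9000), "phase": "night"}
        )
        prof = vertical_profile(df)
        night = prof[prof["phase"] == "night"]["proportion"].to_numpy()
        assert np.all(np.abs(night - 1 / 9) < 4 * np.sqrt((1 / 9) * (8 / 9) / 9000))

    def test_generator_truth_profiles(self, spring_campaign, spring_sites_frame):
        """Day mode near 300 m; night proportions decay above 150 m."""
        from scipy.stats import spearmanr

        from aeroecho.echo_filter import apply_filters

        echoes, _, _ = spring_campaign
        filtered, _ = apply_filters(echoes)
        filtered = assign_periods_frame(filtered, spring_sites_frame)
        prof = vertical_profile(filtered)
        day = prof[prof["phase"] == "day"].reset_index(drop=True)
        modal = day.loc[day["proportion"].idxmax()]
        assert 250.0 <= modal["bin_lo_m"] <= 300.0  # modal bin overlaps 280–320 m
        night = prof[(prof["phase"] == "night") & (prof["bin_lo_m"] >= 150.0)]
        rho = spearmanr(night["bin_lo_m"], night["proportion"]).statistic
        assert rho < 0

    def test_empty_phase_flagged(self):
        prof = vertical_profile(pd.DataFrame({"altitude_agl_m": [], "phase": []}))
        assert prof["empty"].all()


class TestGroundspeed:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.6, 0.9, 300)
        rep = groundspeed_comparison(x, x)
        assert rep["p_value"] > 0.5

    def test_power_for_day_night_contrast(self):
        """Means 5.5 vs 5.9 (sd 0.9, n=600) detected in ≥95% of runs."""
        hits = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            day = rng.normal(5.5, 0.9, 600)
            night = rng.normal(5.9, 0.9, 600)
            rep = groundspeed_comparison(day, night)
            hits += rep["significant"]
        assert hits / runs >= 0.95

    def test_skewed_group_takes_rank_based_path(self):
        rng = np.random.default_rng(2)
        normal = rng.normal(5.6, 0.9, 200)
        skewed = np.exp(rng.normal(1.5, 0.8, 200))
        rep = groundspeed_comparison(normal, skewed)
        assert rep["test"] == "mann-whitney"

    def test_tiny_group_skipped_with_reason(self):
        rep = groundspeed_comparison([5.0, 5.5], [5.0, 5.1, 5.2, 5.3])
        assert rep["skipped"] and "n < 3" in rep["reason"]
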