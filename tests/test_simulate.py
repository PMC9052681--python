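import numpy as np
import pandas as pd
import pytest

from mantatel.config import load_config
from mantatel.geo import haversine_m
from mantatel.qc import daily_presence, retained, run_qc
from mantatel.residency import residency_summary
from mantatel.simulate import (
    ABSENT_CENTER,
    SEASONAL_CENTERS,
    default_receivers,
    detection_probability,
    land_mask,
    simulate_dataset,
    simulate_detections,
    simulate_environment,
    simulate_geosensor,
    synthetic_sst,
)


def _cfg(**sim_overrides):
    return load_config(overrides={"simulate": sim_overrides})


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = _cfg(n_animals=3, start="2013-03-01", end="2013-04-15")
        a = simulate_dataset(cfg, seed=9)
        b = simulate_dataset(cfg, seed=9)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_different_seed_differs(self):
        cfg = _cfg(n_animals=3, start="2013-03-01", end="2013-04-15")
        a = simulate_dataset(cfg, seed=9)
        b = simulate_dataset(cfg, seed=10)
        assert len(a["detections"]) != len(b["detections"]) or not a["detections"].equals(b["detections"])


class TestDetectionCurve:
    def test_half_detection_at_540m(self):
        """An animal parked at the 50% range is heard on ~half its pings."""
        cfg = _cfg(start="2013-01-01", end="2013-01-31")
        sim = cfg["simulate"]
        start = pd.Timestamp("2013-01-01", tz="UTC")
        end = pd.Timestamp("2013-01-31", tz="UTC")
        receivers = pd.DataFrame(
            [("R1", 20.80, 37.20, "C", start, end + pd.Timedelta(days=1))],
            columns=["receiver_id", "lat", "lon", "region", "active_start", "active_end"],
        )
        lat = 20.80 + 540.0 / 111_195  # 540 m due north
        steps = pd.date_range(start, end, freq="10min")
        positions = pd.DataFrame({"animal_id": "A1", "timestep": steps, "lat": lat, "lon": 37.20})
        deployments = pd.DataFrame(
            {"animal_id": ["A1"], "tag_id": ["T1"], "release_time": start, "sex": ["F"],
             "wingspan_cm": [300], "maturity": ["mature"], "satellite_tag": ["none"]}
        )
        cfg["simulate"]["noise"] = {"echo_rate": 0.0, "false_per_tag_day": 0.0}
        det, labels = simulate_detections(positions, receivers, deployments, cfg, np.random.default_rng(0))
        horizon = len(steps) * 600.0
        n_pings = horizon / 360.0
        frac = len(det) / n_pings
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_mean_transmission_gap_360s(self):
        """With near-certain detection at the receiver, gaps recover uniform(310,410)."""
        cfg = _cfg(start="2013-01-01", end="2013-01-31", detect_pmax=0.999999)
        sim = cfg["simulate"]
        start = pd.Timestamp("2013-01-01", tz="UTC")
        end = pd.Timestamp("2013-01-31", tz="UTC")
        receivers = pd.DataFrame(
            [("R1", 20.80, 37.20, "C", start, end + pd.Timedelta(days=1))],
            columns=["receiver_id", "lat", "lon", "region", "active_start", "active_end"],
        )
        steps = pd.date_range(start, end, freq="10min")
        positions = pd.DataFrame({"animal_id": "A1", "timestep": steps, "lat": 20.80, "lon": 37.20})
        deployments = pd.DataFrame(
            {"animal_id": ["A1"], "tag_id": ["T1"], "release_time": start, "sex": ["F"],
             "wingspan_cm": [300], "maturity": ["mature"], "satellite_tag": ["none"]}
        )
        cfg["simulate"]["noise"] = {"echo_rate": 0.0, "false_per_tag_day": 0.0}
        det, _ = simulate_detections(positions, receivers, deployments, cfg, np.random.default_rng(1))
        gaps = det["timestamp"].diff().dt.total_seconds().dropna()
        gaps = gaps[gaps < 1000]  # exclude rare missed-ping doubles
        assert gaps.mean() == pytest.approx(360.0, abs=5.0)
        assert gaps.min() >= 309.0

    def test_probability_at_zero_is_pmax(self):
        assert detection_probability(0.0) == pytest.approx(0.95, abs=1e-6)

    def test_probability_at_twice_r50_is_low(self):
        assert detection_probability(1080.0) == pytest.approx(0.05, abs=1e-6)

    def test_no_detection_beyond_noise_floor(self):
        assert detection_probability(2000.0) == 0.0


class TestEnvironment:
    def test_moon_cycle_extremes_and_period(self):
        cfg = _cfg(start="2013-01-01", end="2013-12-31")
        env = simulate_environment(cfg, np.random.default_rng(0))
        moon = env["moon_frac"].to_numpy()
        assert moon.min() <= 0.01 and moon.max() >= 0.99
        # successive full moons ~29.5 days apart (peak finding)
        peaks = np.flatnonzero((moon[1:-1] > moon[:-2]) & (moon[1:-1] >= moon[2:])) + 1
        full = peaks[moon[peaks] > 0.9]
        assert np.abs(np.diff(full).mean() - 29.53) < 0.6

    def test_chla_positive_with_summer_peak(self):
        cfg = _cfg(start="2013-01-01", end="2013-12-31")
        env = simulate_environment(cfg, np.random.default_rng(0))
        assert (env["chla"] > 0).all()
        month = pd.to_datetime(env["date"]).dt.month
        assert env.loc[month.isin([6, 7, 8]), "chla"].mean() > env.loc[month.isin([12, 1, 2]), "chla"].mean()

    def test_one_row_per_day_no_gaps(self):
        cfg = _cfg(start="2013-01-01", end="2013-03-31")
        env = simulate_environment(cfg, np.random.default_rng(0))
        assert len(env) == 90
        assert pd.to_datetime(env["date"]).diff().dt.days.iloc[1:].eq(1).all()


class TestMovement:
    def test_hard_speed_cap(self, year_sim):
        cfg, data = year_sim
        cap = cfg["simulate"]["speed_cap_mps"] * cfg["simulate"]["step_minutes"] * 60.0
        for _, grp in data["truth_positions"].groupby("animal_id"):
            d = haversine_m(
                grp["lat"].iloc[:-1].to_numpy(), grp["lon"].iloc[:-1].to_numpy(),
                grp["lat"].iloc[1:].to_numpy(), grp["lon"].iloc[1:].to_numpy(),
            )
            assert d.max() <= cap * 1.001

    def test_zero_noise_sits_at_seasonal_center(self):
        cfg = _cfg(n_animals=1, start="2013-09-05", end="2013-09-25")
        cfg["simulate"]["movement"].update(
            station_visit_prob=0.0, roam_sd_m=0.0, dwell_sd_m=0.0, step_sd_m=0.0, roam_clearance_m=0.0
        )
        cfg["simulate"]["presence"]["intercept"] = 30.0  # always in the bay
        data = simulate_dataset(cfg, seed=2)
        pos = data["truth_positions"]
        tail = pos.tail(144)  # last simulated day
        clat, clon = SEASONAL_CENTERS[9]
        assert haversine_m(tail["lat"], tail["lon"], clat, clon).max() < 1.0

    def test_center_switches_at_season_boundary(self):
        cfg = _cfg(n_animals=1, start="2013-03-20", end="2013-04-10")
        cfg["simulate"]["movement"].update(
            station_visit_prob=0.0, roam_sd_m=0.0, dwell_sd_m=0.0, step_sd_m=0.0, roam_clearance_m=0.0
        )
        cfg["simulate"]["presence"]["intercept"] = 30.0
        data = simulate_dataset(cfg, seed=2)
        pos = data["truth_positions"].set_index("timestep")
        march = pos.loc["2013-03-28":"2013-03-31"]
        april = pos.loc["2013-04-07":"2013-04-10"]
        assert haversine_m(march["lat"], march["lon"], *SEASONAL_CENTERS[3]).max() < 1.0
        assert haversine_m(april["lat"], april["lon"], *SEASONAL_CENTERS[4]).max() < 1.0

    def test_presence_draws_match_configured_logit(self, year_sim):
        """Realized daily in-bay states are calibrated to the configured curve."""
        cfg, data = year_sim
        truth = data["truth_presence"]
        rho = cfg["simulate"]["presence"]["persistence"]
        infl = (1 + rho) / (1 - rho)  # autocorrelation-inflated variance
        for _, grp in truth.groupby(pd.qcut(truth["p_present"], 4, duplicates="drop"), observed=True):
            n = len(grp)
            p = grp["p_present"].mean()
            tol = 3.5 * np.sqrt(infl * p * (1 - p) / n)
            assert abs(grp["present"].mean() - p) < tol


class TestTruthTables:
    def test_every_detection_traces_to_one_label(self, small_sim):
        cfg, data = small_sim
        det, lab = data["detections"], data["truth_labels"]
        assert len(det) == len(lab)
        pd.testing.assert_frame_equal(det, lab[["timestamp", "receiver_id", "tag_id"]])
        assert set(lab["kind"]) <= {"genuine", "echo", "false"}

    def test_false_singles_only_in_bay(self, small_sim):
        cfg, data = small_sim
        lab = data["truth_labels"]
        offshore = {"OFF1", "OFF2"}
        assert not lab.loc[lab["kind"] == "false", "receiver_id"].isin(offshore).any()


class TestGeosensor:
    def test_longitude_error_coverage(self, year_sim):
        cfg, data = year_sim
        geo = data["geosensor"]
        err = (geo["lon_est"] - geo["true_lon"]).abs()
        frac = (err < 1.0).mean()
        assert 0.58 < frac < 0.78  # ~68% within one sigma

    def test_zero_noise_peaks_at_truth(self):
        cfg = _cfg(n_animals=2, start="2013-01-01", end="2013-01-20")
        cfg["simulate"]["geosensor"] = {"sigma_lon_deg": 0.0, "sigma_sst_c": 0.0}
        data = simulate_dataset(cfg, seed=4)
        geo = data["geosensor"]
        assert np.allclose(geo["lon_est"], geo["true_lon"])
        assert np.allclose(geo["sst_tag"], synthetic_sst(geo["true_lat"].to_numpy()))

    def test_land_mask_is_west_of_coast(self):
        assert land_mask(20.8, 36.9)
        assert not land_mask(20.8, 37.3)


class TestRecovery:
    def test_ri_recovers_occupancy_as_detection_improves(self):
        """With detection probability pushed toward 1 over a wide range, the
        estimated residence index approaches the true in-bay occupancy."""
        base = dict(n_animals=4, start="2013-01-01", end="2013-06-30")

        def ri_error(**det_kw):
            cfg = _cfg(**base, **det_kw)
            data = simulate_dataset(cfg, seed=13)
            labelled, _ = run_qc(data["detections"], data["receivers"], data["deployments"], cfg)
            presence = daily_presence(labelled, cfg["tz_offset_hours"])
            summary = residency_summary(labelled, data["receivers"], presence, cfg["tz_offset_hours"])
            dep = data["deployments"].set_index("tag_id")["animal_id"]
            truth = data["truth_presence"]
            errs = []
            for tag, row in summary.iterrows():
                t = truth[truth["animal_id"] == dep[tag]]
                # occupancy over the same first-to-last-detection span RI uses
                span = t[(t["date"] >= row["first_day"]) & (t["date"] <= row["last_day"])]
                errs.append(abs(row["ri"] - span["present"].mean()))
            return float(np.mean(errs))

        err_default = ri_error()
        err_boosted = ri_error(detect_pmax=0.999, detect_r50_m=2500.0, detect_max_range_m=3500.0)
        assert err_boosted < err_default
        assert err_boosted < 0.06


def test_receiver_battery_failures_reduce_effort():
    rec = default_receivers("2012-11-02", "2014-10-24")
    spans = rec.groupby("receiver_id").apply(lambda g: (g["active_end"] - g["active_start"]).sum(), include_groups=False)
    assert (spans < spans.max()).sum() == 4
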