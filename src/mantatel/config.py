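"""Pipeline configuration: one nested mapping holding every threshold.

Defaults encode the study conditions: a 15-receiver in-bay array plus two
offshore stations, ~2 m/s speed cap, 1-h event timeout, 48-h post-release
exclusion, 310-410 s tag transmission delays and a 540 m 50% detection range.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "tz_offset_hours": 3.0,
    "qc": {
        "isolation_window_min": 60.0,
        "exempt_regions": ["OFFSHORE"],
        "post_release_hours": 48.0,
        "vmax_mps": 2.0,
        "speed_drop": "later",  # or "both"
    },
    "residency": {
        "event_timeout_min": 60.0,
        "track_days_inclusive": True,
    },
    "model": {
        "smooths": ["Day", "Hour", "Moon", "CHLA"],
        "k": {"Day": 7, "Hour": 7, "Moon": 6, "CHLA": 7},
        "lambda_grid": [0.01, 1.0, 100.0, 10000.0, 1000000.0],
        "max_pirls_iter": 100,
    },
    "space_use": {
        "coa_bin_minutes": 360,
        "grid_cells": 100,
        "levels": [50, 95],
        "min_coas_per_month": 5,
    },
    "geolocation": {
        "cell_deg": 0.25,
        "speed_mps": 2.0,
        "sigma_lon_deg": 1.0,
        "sigma_sst_c": 0.5,
        "coa_bin_minutes": 720,
    },
    "simulate": {
        "n_animals": 19,
        "start": "2012-11-02",
        "end": "2014-10-24",
        "step_minutes": 10,
        "ping_delay_s": [310.0, 410.0],
        "detect_r50_m": 540.0,
        "detect_pmax": 0.95,
        "detect_max_range_m": 1100.0,
        "speed_cap_mps": 2.0,
        "movement": {
            "station_visit_prob": 0.4,
            "region_prob": 0.65,
            "station_dwell_floor_min": 30.0,
            "station_dwell_extra_min": 20.0,
            "roam_dwell_floor_min": 60.0,
            "roam_dwell_extra_min": 180.0,
            "roam_sd_m": 1400.0,
            "roam_clearance_m": 2000.0,
            "dwell_sd_m": 150.0,
            "dwell_reversion": 0.15,
            "transit_mps": 0.2,
            "excursion_mps": 1.2,
            "step_sd_m": 60.0,
        },
        "presence": {
            "persistence": 0.85,
            "intercept": -0.3,
            "day_amplitude": 1.6,
            "day_peak": 285,  # day of year of peak presence (mid-October)
            "chla_coef": 1.2,
            "moon_coef": 0.4,
        },
        "noise": {"echo_rate": 0.01, "false_per_tag_day": 0.05},
        "env": {
            "chla_mean_log": -0.7,
            "chla_amplitude_log": 0.8,
            "chla_peak_day": 200,  # summer chlorophyll peak
            "chla_noise_sd_log": 0.15,
            "synodic_days": 29.53,
        },
        "geosensor": {"sigma_lon_deg": 1.0, "sigma_sst_c": 0.5},
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _merge(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and a dict of overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    return cfg
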