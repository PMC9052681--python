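"""Shared fixtures: a miniature receiver array and deployment table, a helper
for building detection frames from compact tuples, and a module-scoped small
synthetic dataset for the slower audits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mantatel.config import load_config
from mantatel.simulate import simulate_dataset

T0 = pd.Timestamp("2013-01-10T00:00:00Z")


@pytest.fixture(scope="session")
def receivers():
    """Three in-bay receivers on a line 5 km apart plus one offshore."""
    start = pd.Timestamp("2013-01-01T00:00:00Z")
    end = pd.Timestamp("2014-01-01T00:00:00Z")
    rows = [
        ("R1", 20.80, 37.20, "C", start, end),
        ("R2", 20.80 + 5 / 111.195, 37.20, "C", start, end),  # 5 km north of R1
        ("R3", 20.80 + 10 / 111.195, 37.20, "N", start, end),
        ("OFF", 20.20, 37.40, "OFFSHORE", start, end),
    ]
    return pd.DataFrame(
        rows, columns=["receiver_id", "lat", "lon", "region", "active_start", "active_end"]
    )


@pytest.fixture(scope="session")
def deployments():
    return pd.DataFrame(
        {
            "animal_id": ["A1", "A2"],
            "tag_id": ["T1", "T2"],
            "release_time": pd.Timestamp("2013-01-01T00:00:00Z"),
            "sex": ["F", "M"],
            "wingspan_cm": [330, 280],
            "maturity": ["mature", "immature"],
            "satellite_tag": ["none", "none"],
        }
    )


def make_detections(rows):
    """rows: (minutes offset from T0, receiver_id, tag_id) tuples."""
    return pd.DataFrame(
        {
            "timestamp": [T0 + pd.Timedelta(minutes=m) for m, _, _ in rows],
            "receiver_id": [r for _, r, _ in rows],
            "tag_id": [t for _, _, t in rows],
        }
    )


@pytest.fixture()
def det_builder():
    return make_detections


@pytest.fixture(scope="session")
def small_sim():
    """Six animals over six months, full generator output plus its config."""
    cfg = load_config(
        overrides={"simulate": {"n_animals": 6, "start": "2013-01-01", "end": "2013-06-30"}}
    )
    data = simulate_dataset(cfg, seed=20)
    return cfg, data


@pytest.fixture(scope="session")
def year_sim():
    """Six animals over a full year (covers all 12 months for the KUD tests)."""
    cfg = load_config(
        overrides={"simulate": {"n_animals": 6, "start": "2013-01-01", "end": "2013-12-31"}}
    )
    data = simulate_dataset(cfg, seed=7)
    return cfg, data
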