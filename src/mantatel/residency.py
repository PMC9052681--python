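"""Residency statistics, event segmentation, movement networks, group tests.

The residence index (RI) of an animal is the number of calendar days it was
detected in the array divided by the number of days spanned from its first to
its last detection day (endpoints inclusive).  A residency event is a
contiguous visit to one receiver: it opens on the second consecutive detection
at that receiver and closes when the animal is detected elsewhere or one hour
passes with no further detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import haversine_m
from .io import DETECTION_SORT, station_positions, to_calendar_day
from .qc import _tag_slices, retained


def residence_index(detection_days: int, track_days: int) -> float:
    """detection_days / track_days, the fraction of spanned days with presence."""
    if track_days <= 0:
        raise ValueError("track_days must be >= 1")
    if detection_days < 0 or detection_days > track_days:
        raise ValueError("detection_days must be in [0, track_days]")
    return round(detection_days / track_days, 4)


def track_and_detection_days(
    detections: pd.DataFrame, tz_offset_hours: float = 3.0, inclusive: bool = True
) -> pd.DataFrame:
    """Per-tag first/last detection day span and count of distinct detection days."""
    det = retained(detections)
    days = to_calendar_day(det["timestamp"], tz_offset_hours)
    grouped = det.assign(day=days).groupby("tag_id")["day"]
    first = grouped.min()
    last = grouped.max()
    span = (pd.to_datetime(last.astype(str)) - pd.to_datetime(first.astype(str))).dt.days
    track = span + (1 if inclusive else 0)
    out = pd.DataFrame(
        {
            "first_day": first,
            "last_day": last,
            "track_days": track,
            "detection_days": grouped.nunique(),
        }
    )
    return out


def segment_residency_events(detections: pd.DataFrame, timeout_min: float = 60.0) -> pd.DataFrame:
    """Segment per-tag detection sequences into single-receiver residency events.

    An event opens on the SECOND consecutive detection at the same receiver
    with gap < timeout; it extends while detections continue at that receiver
    within the timeout and ends at the last member detection.  A detection at
    a different receiver closes the current event and becomes the new
    candidate; a lone detection at a receiver never forms an event.
    """
    det = retained(detections).sort_values(DETECTION_SORT, kind="mergesort").reset_index(drop=True)
    timeout = pd.Timedelta(minutes=timeout_min)
    rid = det["receiver_id"].to_numpy()
    tag = det["tag_id"].to_numpy()
    ts = det["timestamp"].to_numpy()

    events = []
    for start, stop in _tag_slices(tag):
        open_start = None  # index of first detection of the open event
        n_members = 0
        anchor = start  # candidate/current-event last detection index
        for i in range(start + 1, stop):
            same = rid[i] == rid[anchor]
            within = (ts[i] - ts[anchor]) < timeout
            if same and within:
                if open_start is None:
                    open_start = anchor
                    n_members = 1
                n_members += 1
                anchor = i
            else:
                if open_start is not None:
                    events.append((tag[anchor], rid[anchor], ts[open_start], ts[anchor], n_members))
                    open_start, n_members = None, 0
                anchor = i
        if open_start is not None:
            events.append((tag[anchor], rid[anchor], ts[open_start], ts[anchor], n_members))
    return pd.DataFrame(events, columns=["tag_id", "receiver_id", "start", "end", "n_detections"])


def max_nonresidence(presence: pd.DataFrame) -> pd.Series:
    """Longest run of absent days strictly between two present days, per tag."""
    out = {}
    for tag, row in presence.iterrows():
        vals = row.to_numpy(dtype=bool)
        present_idx = np.flatnonzero(vals)
        if len(present_idx) < 2:
            out[tag] = 0
            continue
        gaps = np.diff(present_idx) - 1
        out[tag] = int(gaps.max())
    return pd.Series(out, name="max_absence_days")


def min_distance_travelled(
    detections: pd.DataFrame, receivers: pd.DataFrame, tz_offset_hours: float = 3.0
):
    """Summed straight-line receiver-to-receiver distance per tag.

    Returns (daily, total): daily km per (tag, local date of the arrival
    detection) and total km per tag.  Consecutive detections at the same
    receiver contribute zero.
    """
    det = retained(detections).sort_values(DETECTION_SORT, kind="mergesort").reset_index(drop=True)
    pos = station_positions(receivers)
    lat = det["receiver_id"].map(pos["lat"]).to_numpy()
    lon = det["receiver_id"].map(pos["lon"]).to_numpy()
    tag = det["tag_id"].to_numpy()

    dist_km = np.zeros(len(det))
    if len(det) > 1:
        step = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]) / 1000.0
        same_tag = tag[1:] == tag[:-1]
        dist_km[1:] = np.where(same_tag, step, 0.0)
    df = det.assign(step_km=dist_km, day=to_calendar_day(det["timestamp"], tz_offset_hours))
    daily = df.groupby(["tag_id", "day"])["step_km"].sum()
    total = df.groupby("tag_id")["step_km"].sum().rename("min_distance_km")
    return daily, total


def build_network(detections: pd.DataFrame, receivers: pd.DataFrame):
    """Movement network: node weights and directed transition counts.

    Nodes are all receivers in the station table (zero-detection receivers are
    carried as isolated nodes); a directed edge (a, b) counts consecutive
    detections of one animal at distinct receivers a then b.
    """
    det = retained(detections).sort_values(DETECTION_SORT, kind="mergesort").reset_index(drop=True)
    all_ids = station_positions(receivers).index
    nodes = det["receiver_id"].value_counts().reindex(all_ids, fill_value=0).rename("n_detections")

    rid = det["receiver_id"].to_numpy()
    tag = det["tag_id"].to_numpy()
    if len(det) > 1:
        move = (tag[1:] == tag[:-1]) & (rid[1:] != rid[:-1])
        edges = pd.DataFrame({"from": rid[:-1][move], "to": rid[1:][move]})
        edge_counts = edges.groupby(["from", "to"]).size().rename("n_movements").reset_index()
    else:
        edge_counts = pd.DataFrame(columns=["from", "to", "n_movements"])
    return nodes, edge_counts.sort_values(["from", "to"]).reset_index(drop=True)


def undirected_edges(edge_counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse directed transition counts to undirected pair weights."""
    if edge_counts.empty:
        return pd.DataFrame(columns=["a", "b", "n_movements"])
    pairs = edge_counts.apply(lambda r: tuple(sorted((r["from"], r["to"]))), axis=1)
    out = (
        edge_counts.assign(a=[p[0] for p in pairs], b=[p[1] for p in pairs])
        .groupby(["a", "b"])["n_movements"]
        .sum()
        .reset_index()
    )
    return out


def residency_summary(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    presence: pd.DataFrame,
    tz_offset_hours: float = 3.0,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-tag summary in the shape of the cohort reference table."""
    det = retained(detections)
    spans = track_and_detection_days(det, tz_offset_hours, inclusive)
    _, total_km = min_distance_travelled(det, receivers, tz_offset_hours)
    absence = max_nonresidence(presence)
    counts = det.groupby("tag_id").size().rename("total_detections")
    out = spans.join([counts, total_km, absence])
    out["ri"] = [
        residence_index(d, t) for d, t in zip(out["detection_days"], out["track_days"])
    ]
    return out


@dataclass
class GroupStats:
    """Group-comparison results on residence indices and detection counts."""

    welch_sex: dict
    pearson_size_detections: dict
    pearson_size_ri: dict
    diagnostics: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in (
            ("welch_ri_by_sex", self.welch_sex),
            ("pearson_wingspan_vs_detections", self.pearson_size_detections),
            ("pearson_wingspan_vs_ri", self.pearson_size_ri),
        ):
            rows.append({"test": name, **res})
        return pd.DataFrame(rows)


def group_stats(summary: pd.DataFrame, deployments: pd.DataFrame) -> GroupStats:
    """Welch's t-test of RI by sex plus size correlations and diagnostics.

    ``summary`` is indexed by tag_id with columns ri and total_detections;
    sex and wingspan come from the deployment table.
    """
    meta = deployments.set_index("tag_id")
    df = summary.join(meta[["sex", "wingspan_cm", "maturity"]], how="inner")

    groups = {s: df.loc[df["sex"] == s, "ri"].to_numpy() for s in ("F", "M")}
    degenerate = any(len(g) < 2 or np.var(g) == 0 for g in groups.values())
    if degenerate:
        welch = {"statistic": np.nan, "pvalue": np.nan, "skipped": True}
    else:
        t = stats.ttest_ind(groups["F"], groups["M"], equal_var=False)
        welch = {"statistic": float(t.statistic), "pvalue": float(t.pvalue), "skipped": False}

    def _pearson(x, y):
        if len(df) < 3 or np.var(x) == 0 or np.var(y) == 0:
            return {"statistic": np.nan, "pvalue": np.nan, "skipped": True}
        r = stats.pearsonr(x, y)
        return {"statistic": float(r.statistic), "pvalue": float(r.pvalue), "skipped": False}

    diag = {}
    if len(df) >= 3 and df["ri"].var() > 0:
        sw = stats.shapiro(df["ri"])
        diag["shapiro"] = {"statistic": float(sw.statistic), "pvalue": float(sw.pvalue)}
    if not degenerate:
        lv = stats.levene(groups["F"], groups["M"])
        diag["levene"] = {"statistic": float(lv.statistic), "pvalue": float(lv.pvalue)}
    diag["mean_ri_by_sex"] = {s: float(np.mean(g)) if len(g) else np.nan for s, g in groups.items()}

    return GroupStats(
        welch_sex=welch,
        pearson_size_detections=_pearson(df["wingspan_cm"].to_numpy(), df["total_detections"].to_numpy()),
        pearson_size_ri=_pearson(df["wingspan_cm"].to_numpy(), df["ri"].to_numpy()),
        diagnostics=diag,
    )
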