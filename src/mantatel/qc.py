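"""Detection quality control.

Three filters are applied in a fixed order, each record being removed by at
most one stage:

1. isolated singles — a detection with no companion detection of the same tag
   anywhere in the array within +/- a time window (default 60 min) is treated
   as a decoding artefact and dropped, except at offshore stations where tag
   density is too low for collisions and lone detections are kept;
2. post-release — detections within 48 h of the animal's release reflect
   capture stress, not natural behaviour;
3. speed — consecutive detections at different receivers implying a sustained
   straight-line swim speed above 2 m/s are physically implausible; the later
   record is dropped and the scan re-evaluates against the surviving
   predecessor.

The daily-presence rule (an animal counts as present on a calendar day only
with >=2 retained detections that day) is also implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_m
from .io import DETECTION_SORT, station_positions, to_calendar_day

RETAINED = "retained"
STAGE_SINGLES = "isolated_single"
STAGE_RELEASE = "post_release"
STAGE_SPEED = "speed"


def _sorted(detections: pd.DataFrame) -> pd.DataFrame:
    return detections.sort_values(DETECTION_SORT, kind="mergesort").reset_index(drop=True)


def remove_isolated_singles(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    window_min: float = 60.0,
    exempt_regions=("OFFSHORE",),
):
    """Drop detections with no same-tag companion within +/- window_min.

    Companions may be at any receiver.  Detections at receivers whose region is
    in ``exempt_regions`` are always kept.  Returns (retained, removed).
    """
    det = _sorted(detections)
    if det.empty:
        return det, det
    pos = station_positions(receivers)
    region = det["receiver_id"].map(pos["region"])
    window = pd.Timedelta(minutes=window_min)

    t = det["timestamp"]
    same_prev = det["tag_id"].eq(det["tag_id"].shift(1))
    same_next = det["tag_id"].eq(det["tag_id"].shift(-1))
    near_prev = same_prev & (t - t.shift(1) <= window)
    near_next = same_next & (t.shift(-1) - t <= window)
    isolated = ~(near_prev.fillna(False) | near_next.fillna(False))
    isolated &= ~region.isin(exempt_regions)
    return det[~isolated].reset_index(drop=True), det[isolated].reset_index(drop=True)


def remove_post_release(detections: pd.DataFrame, deployments: pd.DataFrame, hours: float = 48.0):
    """Drop detections earlier than release_time + hours for each tag."""
    det = _sorted(detections)
    release = deployments.set_index("tag_id")["release_time"]
    unknown = sorted(set(det["tag_id"]) - set(release.index))
    if unknown:
        raise ValueError(f"tags with no deployment row: {unknown}")
    if det.empty:
        return det, det
    cutoff = det["tag_id"].map(release) + pd.Timedelta(hours=hours)
    early = det["timestamp"] < cutoff
    return det[~early].reset_index(drop=True), det[early].reset_index(drop=True)


def speed_filter(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    vmax_mps: float = 2.0,
    drop: str = "later",
):
    """Remove detections implying > vmax_mps between distinct receivers.

    Scans each tag's chronological sequence keeping a pointer to the last
    surviving detection; a violating later record is removed and the next
    record is re-evaluated against the survivor.  ``drop="both"`` removes the
    earlier member of the violating pair as well.  Same-receiver pairs are
    never removed (zero implied distance).
    """
    if drop not in ("later", "both"):
        raise ValueError("drop must be 'later' or 'both'")
    det = _sorted(detections)
    if det.empty:
        return det, det
    pos = station_positions(receivers)
    lat = det["receiver_id"].map(pos["lat"]).to_numpy()
    lon = det["receiver_id"].map(pos["lon"]).to_numpy()
    rid = det["receiver_id"].to_numpy()
    tag = det["tag_id"].to_numpy()
    tsec = det["timestamp"].astype("int64").to_numpy() / 1e9

    keep = np.ones(len(det), dtype=bool)
    for start, stop in _tag_slices(tag):
        kept: list[int] = []
        for i in range(start, stop):
            if not kept:
                kept.append(i)
                continue
            j = kept[-1]
            if rid[i] == rid[j]:
                kept.append(i)
                continue
            dt = tsec[i] - tsec[j]
            dist = haversine_m(lat[j], lon[j], lat[i], lon[i])
            if dt <= 0 or dist / dt > vmax_mps:
                keep[i] = False
                if drop == "both":
                    keep[j] = False
                    kept.pop()
            else:
                kept.append(i)
    return det[keep].reset_index(drop=True), det[~keep].reset_index(drop=True)


def _tag_slices(tags: np.ndarray):
    """Yield (start, stop) index ranges of each tag in a tag-sorted array."""
    if len(tags) == 0:
        return
    changes = np.flatnonzero(tags[1:] != tags[:-1]) + 1
    bounds = np.concatenate(([0], changes, [len(tags)]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield int(a), int(b)


@dataclass
class FilterReport:
    """Bookkeeping of the three-stage QC with exact conservation."""

    n_raw: int
    n_isolated_singles: int
    n_post_release: int
    n_speed: int
    n_retained: int
    stage_order: tuple = (STAGE_SINGLES, STAGE_RELEASE, STAGE_SPEED)
    per_animal: pd.DataFrame = field(default=None, repr=False)

    def check_conservation(self) -> bool:
        return self.n_retained == (
            self.n_raw - self.n_isolated_singles - self.n_post_release - self.n_speed
        )

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {
                "stage": ["raw", *self.stage_order, RETAINED],
                "count": [
                    self.n_raw,
                    self.n_isolated_singles,
                    self.n_post_release,
                    self.n_speed,
                    self.n_retained,
                ],
            }
        )
        return head


def run_qc(detections, receivers, deployments, config: dict, max_passes: int = 10):
    """Full three-stage QC.  Returns (labelled detections, FilterReport).

    The returned frame carries a ``qc_stage`` column naming the removing stage
    or ``"retained"``; filtering order is singles -> post-release -> speed.
    The stage sequence is iterated to a fixed point (a removal by a later
    stage can leave an earlier survivor newly isolated), so the QC is
    idempotent; each record is attributed to the stage that removed it.
    """
    qc = config["qc"]
    kept = _sorted(detections)
    removed = {STAGE_SINGLES: [], STAGE_RELEASE: [], STAGE_SPEED: []}
    for _ in range(max_passes):
        n_before = len(kept)
        kept, rm1 = remove_isolated_singles(
            kept, receivers, qc["isolation_window_min"], tuple(qc["exempt_regions"])
        )
        kept, rm2 = remove_post_release(kept, deployments, qc["post_release_hours"])
        kept, rm3 = speed_filter(kept, receivers, qc["vmax_mps"], qc["speed_drop"])
        for stage, rm in ((STAGE_SINGLES, rm1), (STAGE_RELEASE, rm2), (STAGE_SPEED, rm3)):
            if len(rm):
                removed[stage].append(rm)
        if len(kept) == n_before:
            break

    parts = [kept.assign(qc_stage=RETAINED)]
    for stage, frames in removed.items():
        if frames:
            parts.append(pd.concat(frames, ignore_index=True).assign(qc_stage=stage))
    labelled = _sorted(pd.concat(parts, ignore_index=True))

    breakdown = (
        labelled.groupby(["tag_id", "qc_stage"]).size().unstack(fill_value=0)
        if len(labelled)
        else pd.DataFrame()
    )
    n_removed = {stage: sum(len(f) for f in frames) for stage, frames in removed.items()}
    report = FilterReport(
        n_raw=len(labelled),
        n_isolated_singles=n_removed[STAGE_SINGLES],
        n_post_release=n_removed[STAGE_RELEASE],
        n_speed=n_removed[STAGE_SPEED],
        n_retained=len(kept),
        per_animal=breakdown,
    )
    assert report.check_conservation()
    return labelled, report


def retained(labelled: pd.DataFrame) -> pd.DataFrame:
    """Retained rows of a QC-labelled detection table (qc_stage dropped)."""
    if "qc_stage" not in labelled.columns:
        return labelled
    out = labelled[labelled["qc_stage"] == RETAINED].drop(columns=["qc_stage"])
    return out.reset_index(drop=True)


def daily_presence(detections: pd.DataFrame, tz_offset_hours: float = 3.0) -> pd.DataFrame:
    """Boolean tag x calendar-day presence matrix (>=2 detections per day).

    Spans the first to last detection date of the whole cohort; a day counts
    as present only with at least two retained detections of that tag.
    """
    det = retained(detections)
    if det.empty:
        return pd.DataFrame()
    days = to_calendar_day(det["timestamp"], tz_offset_hours)
    counts = det.groupby(["tag_id", days]).size()
    counts.index.names = ["tag_id", "date"]
    present = (counts >= 2).unstack(fill_value=False)
    full_range = pd.date_range(min(present.columns), max(present.columns), freq="D").date
    present = present.reindex(columns=full_range, fill_value=False)
    return present


def cohort_presence_days(presence: pd.DataFrame) -> tuple[int, int]:
    """(days with >=1 animal present, total days spanned by the matrix)."""
    if presence.empty:
        return 0, 0
    return int(presence.any(axis=0).sum()), presence.shape[1]
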