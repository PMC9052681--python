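"""Centers of activity and monthly kernel utilization distributions.

A center of activity (COA) is the detection-count-weighted mean position of an
animal's detecting receivers within a fixed time bin (6 h for the space-use
analysis, 12 h when feeding acoustically fixed positions to the geolocation
model).  Pooled COAs are kernel-smoothed per calendar month on a local planar
projection; the q% utilization contour is the smallest region holding q% of
the gridded probability mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import azimuthal_equidistant, inverse_azimuthal_equidistant
from .io import station_positions
from .qc import retained


def compute_coas(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    bin_minutes: int = 360,
    tz_offset_hours: float = 3.0,
) -> pd.DataFrame:
    """Per-animal detection-weighted mean positions in fixed time bins.

    Bins tile the study window aligned to local midnight; bins with no
    detections yield no COA.
    """
    det = retained(detections)
    if det.empty:
        return pd.DataFrame(columns=["tag_id", "bin_start", "lat", "lon", "n_detections"])
    pos = station_positions(receivers)
    offset = pd.Timedelta(hours=tz_offset_hours)
    local = det["timestamp"] + offset
    bin_start = local.dt.floor(f"{bin_minutes}min") - offset  # bins aligned to local midnight

    df = pd.DataFrame(
        {
            "tag_id": det["tag_id"],
            "bin_start": bin_start,
            "lat": det["receiver_id"].map(pos["lat"]),
            "lon": det["receiver_id"].map(pos["lon"]),
        }
    )
    grouped = df.groupby(["tag_id", "bin_start"])
    out = grouped.agg(lat=("lat", "mean"), lon=("lon", "mean"), n_detections=("lat", "size"))
    return out.reset_index().sort_values(["tag_id", "bin_start"]).reset_index(drop=True)


@dataclass
class UtilizationDistribution:
    """Gridded monthly kernel utilization distribution."""

    month: str
    x: np.ndarray  # cell-centre eastings (m)
    y: np.ndarray  # cell-centre northings (m)
    mass: np.ndarray  # cell probability mass, sums to 1
    bandwidth_m: float
    n_coas: int
    origin: tuple  # (lat0, lon0) of the projection
    levels: dict  # q -> {"threshold": mass-density level, "area_km2": float}

    def contour_mask(self, q: int) -> np.ndarray:
        return self.mass >= self.levels[q]["threshold"]


def _href(x: np.ndarray, y: np.ndarray) -> float:
    """Reference bandwidth: mean of coordinate SDs times n^(-1/6)."""
    n = len(x)
    sigma = 0.5 * (np.std(x, ddof=1) + np.std(y, ddof=1))
    return float(sigma * n ** (-1.0 / 6.0))


def kud_monthly(
    coas: pd.DataFrame,
    grid_cells: int = 100,
    levels=(50, 95),
    min_coas: int = 5,
) -> dict[str, UtilizationDistribution]:
    """Monthly KUDs from pooled COAs (months pool across years).

    Bivariate Gaussian product kernel with the reference bandwidth on an
    azimuthal-equidistant plane about the COA centroid; the evaluation grid is
    the COA bounding box padded by 3 bandwidths, and the gridded mass is
    normalized to one.  Months with fewer than ``min_coas`` COAs are skipped.
    """
    if coas.empty:
        return {}
    lat0 = float(coas["lat"].mean())
    lon0 = float(coas["lon"].mean())
    month = pd.to_datetime(coas["bin_start"]).dt.month
    out: dict[str, UtilizationDistribution] = {}
    for m in sorted(month.unique()):
        sub = coas[month == m]
        if len(sub) < min_coas:
            continue
        x, y = azimuthal_equidistant(sub["lat"].to_numpy(), sub["lon"].to_numpy(), lat0, lon0)
        h = _href(x, y)
        if h <= 0:
            raise ValueError(
                f"month {m}: all COAs identical, zero bandwidth; jitter positions or pool more data"
            )
        pad = 3.0 * h
        gx = np.linspace(x.min() - pad, x.max() + pad, grid_cells)
        gy = np.linspace(y.min() - pad, y.max() + pad, grid_cells)
        dens = _gaussian_kde_grid(x, y, gx, gy, h)
        cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
        mass = dens * cell_area
        mass /= mass.sum()
        lv = {q: _contour_level(mass, q / 100.0, cell_area) for q in levels}
        out[f"{m:02d}"] = UtilizationDistribution(
            month=f"{m:02d}",
            x=gx,
            y=gy,
            mass=mass,
            bandwidth_m=h,
            n_coas=len(sub),
            origin=(lat0, lon0),
            levels=lv,
        )
    return out


def _gaussian_kde_grid(x, y, gx, gy, h) -> np.ndarray:
    """Product-kernel Gaussian KDE evaluated on a grid; shape (len(gy), len(gx))."""
    kx = np.exp(-0.5 * ((gx[None, :] - x[:, None]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[None, :] - y[:, None]) / h) ** 2)
    dens = ky.T @ kx / (len(x) * 2.0 * np.pi * h * h)
    return dens


def _contour_level(mass: np.ndarray, q: float, cell_area: float) -> dict:
    """Largest threshold whose superlevel set holds at least q of the mass."""
    flat = np.sort(mass.ravel())[::-1]
    cum = np.cumsum(flat)
    idx = int(np.searchsorted(cum, q))
    idx = min(idx, len(flat) - 1)
    threshold = flat[idx]
    n_cells = int((mass >= threshold).sum())
    return {"threshold": float(threshold), "area_km2": n_cells * cell_area / 1e6}


def seasonal_area_series(uds: dict[str, UtilizationDistribution], levels=(50, 95)) -> pd.DataFrame:
    """Contour areas (km^2) by month; missing months flagged."""
    rows = []
    for m in range(1, 13):
        key = f"{m:02d}"
        if key in uds:
            ud = uds[key]
            row = {"month": key, "n_coas": ud.n_coas, "missing": False}
            for q in levels:
                row[f"area{q}_km2"] = ud.levels[q]["area_km2"]
        else:
            row = {"month": key, "n_coas": 0, "missing": True}
            for q in levels:
                row[f"area{q}_km2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def contours_geojson(ud: UtilizationDistribution, levels=(50, 95)) -> str:
    """Contour polylines of the q% regions as a GeoJSON FeatureCollection."""
    from skimage import measure

    lat0, lon0 = ud.origin
    features = []
    for q in levels:
        thr = ud.levels[q]["threshold"]
        for contour in measure.find_contours(ud.mass, thr):
            # contour rows are (row=y index, col=x index) in grid coordinates
            xs = np.interp(contour[:, 1], np.arange(len(ud.x)), ud.x)
            ys = np.interp(contour[:, 0], np.arange(len(ud.y)), ud.y)
            lat, lon = inverse_azimuthal_equidistant(xs, ys, lat0, lon0)
            coords = [[round(float(lo), 6), round(float(la), 6)] for lo, la in zip(lon, lat)]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"month": ud.month, "level_pct": q},
                    "geometry": {"type": "LineString", "coordinates": coords},
                }
            )
    return json.dumps({"type": "FeatureCollection", "features": features})
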