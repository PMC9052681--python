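"""Gridded hidden Markov model geolocation for satellite-tag tracks.

States are cells of a regular lat/lon grid (default 0.25 degrees).  Each day
the state diffuses through a Gaussian movement kernel hard-truncated at the
distance an animal can cover at the a-priori speed cap (2 m/s -> 172.8 km per
day), then is weighted by the day's observation likelihood: a Gaussian match
of the light-based longitude estimate, a Gaussian match of tag SST against
the day's SST field (the only latitude information), and a land mask.  Days
with an acoustically derived position are clamped to that cell ("fixed"
locations).  Forward filtering / backward smoothing yields per-day posterior
fields; a Viterbi pass gives the single most probable track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_m


@dataclass
class GeoGrid:
    """Regular lat/lon grid of candidate positions with a water mask."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_deg: float = 0.25
    water: np.ndarray = field(default=None, repr=False)  # (nlat, nlon) bool

    def __post_init__(self):
        self.lats = np.arange(self.lat_min + self.cell_deg / 2, self.lat_max, self.cell_deg)
        self.lons = np.arange(self.lon_min + self.cell_deg / 2, self.lon_max, self.cell_deg)
        if self.water is None:
            self.water = np.ones((len(self.lats), len(self.lons)), dtype=bool)
        self.water = np.asarray(self.water, dtype=bool)
        if self.water.shape != (len(self.lats), len(self.lons)):
            raise ValueError("water mask shape does not match grid")
        if self.water.sum() < 2:
            raise ValueError("grid needs at least 2 water cells")
        self.cell_lat, self.cell_lon = np.meshgrid(self.lats, self.lons, indexing="ij")

    @property
    def n_cells(self) -> int:
        return self.water.size

    @property
    def water_flat(self) -> np.ndarray:
        return self.water.ravel()

    def cell_index(self, lat: float, lon: float) -> int:
        """Flat index of the cell containing (lat, lon)."""
        i = int(np.clip((lat - self.lat_min) // self.cell_deg, 0, len(self.lats) - 1))
        j = int(np.clip((lon - self.lon_min) // self.cell_deg, 0, len(self.lons) - 1))
        return i * len(self.lons) + j

    def cell_area_km2(self) -> np.ndarray:
        """Per-cell area in km^2 (shrinks with cos latitude)."""
        dlat_km = self.cell_deg * 111.195
        dlon_km = self.cell_deg * 111.195 * np.cos(np.radians(self.cell_lat))
        return (dlat_km * dlon_km).ravel()


def build_movement_kernel(grid: GeoGrid, speed_mps: float = 2.0, dt_days: float = 1.0) -> np.ndarray:
    """Row-stochastic daily transition matrix (truncated Gaussian diffusion).

    Hard truncation at speed * 86400 * dt metres; the Gaussian sigma places
    99% of untruncated mass inside that bound.  Rows are renormalized over
    water cells; land is absorbing-with-zero-mass (never entered nor left).
    """
    if speed_mps <= 0:
        raise ValueError("speed must be positive")
    max_m = speed_mps * 86400.0 * dt_days
    sigma = max_m / np.sqrt(2.0 * np.log(100.0))  # 99% of 2-D Gaussian mass within bound
    lat = grid.cell_lat.ravel()
    lon = grid.cell_lon.ravel()
    d = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    K = np.exp(-0.5 * (d / sigma) ** 2)
    K[d > max_m] = 0.0
    K[:, ~grid.water_flat] = 0.0
    K[~grid.water_flat, :] = 0.0
    rowsum = K.sum(axis=1, keepdims=True)
    np.divide(K, rowsum, out=K, where=rowsum > 0)
    return K


def daily_likelihood(
    obs: dict,
    grid: GeoGrid,
    sst_field: np.ndarray | None = None,
    sigma_lon_deg: float = 1.0,
    sigma_sst_c: float = 0.5,
) -> np.ndarray:
    """Per-cell observation likelihood for one day.

    ``obs`` may contain lon_est, sst_tag (either may be missing/NaN) and
    fixed_cell (flat index).  No information -> uniform over water.  A fixed
    acoustic position yields a delta at that cell.
    """
    fixed = obs.get("fixed_cell")
    if fixed is not None and not (isinstance(fixed, float) and np.isnan(fixed)):
        fixed = int(fixed)
        if not grid.water_flat[fixed]:
            raise ValueError(f"fixed cell {fixed} is on land ({obs.get('date')})")
        L = np.zeros(grid.n_cells)
        L[fixed] = 1.0
        return L

    L = np.ones(grid.n_cells)
    lon_est = obs.get("lon_est")
    if lon_est is not None and np.isfinite(lon_est):
        L *= np.exp(-0.5 * ((grid.cell_lon.ravel() - lon_est) / sigma_lon_deg) ** 2)
    sst_tag = obs.get("sst_tag")
    if sst_tag is not None and np.isfinite(sst_tag):
        if sst_field is None:
            raise ValueError("sst_tag given but no SST field")
        L *= np.exp(-0.5 * ((np.asarray(sst_field).ravel() - sst_tag) / sigma_sst_c) ** 2)
    L *= grid.water_flat
    if L.max() <= 0:
        raise ValueError(f"likelihood identically zero over water on {obs.get('date')}")
    return L


def forward_backward(likelihoods: np.ndarray, kernel: np.ndarray, prior: np.ndarray):
    """HMM filtering and smoothing with per-step renormalization.

    likelihoods: (T, n_cells); kernel: row-stochastic (n, n); prior: day-0
    state distribution (before the day-0 likelihood).  Returns (smoothed,
    filtered, log_evidence) with each day's field summing to one.
    """
    T, n = likelihoods.shape
    alpha = np.empty((T, n))
    logev = 0.0
    a = prior * likelihoods[0]
    c = a.sum()
    if c <= 0:
        raise ValueError("zero forward mass on day 0")
    alpha[0] = a / c
    logev += np.log(c)
    for t in range(1, T):
        a = (alpha[t - 1] @ kernel) * likelihoods[t]
        c = a.sum()
        if c <= 0 or not np.isfinite(c):
            raise ValueError(f"zero forward mass on day {t}: observations inconsistent with movement")
        alpha[t] = a / c
        logev += np.log(c)

    beta = np.ones(n)
    smoothed = np.empty((T, n))
    smoothed[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        beta = kernel @ (likelihoods[t + 1] * beta)
        s = beta.sum()
        if s <= 0:
            raise ValueError(f"zero backward mass on day {t}")
        beta = beta / s
        post = alpha[t] * beta
        smoothed[t] = post / post.sum()
    return smoothed, alpha, float(logev)


def viterbi(likelihoods: np.ndarray, kernel: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Most probable joint state path (indices), steps confined to kernel support."""
    T, n = likelihoods.shape
    with np.errstate(divide="ignore"):
        logK = np.log(kernel)
        logL = np.log(likelihoods)
        logp = np.log(prior)
    delta = logp + logL[0]
    back = np.zeros((T, n), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + logK  # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(n)] + logL[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def most_probable_track(
    posteriors: np.ndarray,
    likelihoods: np.ndarray,
    kernel: np.ndarray,
    prior: np.ndarray,
    grid: GeoGrid,
    dates=None,
    hpd: float = 0.95,
) -> pd.DataFrame:
    """Viterbi track with per-day posterior mode and 95% HPD cell-set area."""
    path = viterbi(likelihoods, kernel, prior)
    areas = grid.cell_area_km2()
    lat_flat = grid.cell_lat.ravel()
    lon_flat = grid.cell_lon.ravel()
    rows = []
    for t in range(len(path)):
        post = posteriors[t]
        order = np.argsort(post)[::-1]
        cum = np.cumsum(post[order])
        k = int(np.searchsorted(cum, hpd)) + 1
        hpd_cells = order[:k]
        mode = int(order[0])
        rows.append(
            {
                "day": t if dates is None else dates[t],
                "lat": lat_flat[path[t]],
                "lon": lon_flat[path[t]],
                "mode_lat": lat_flat[mode],
                "mode_lon": lon_flat[mode],
                "hpd_area_km2": float(areas[hpd_cells].sum()),
            }
        )
    return pd.DataFrame(rows)


def observations_from_tables(
    geosensor: pd.DataFrame,
    grid: GeoGrid,
    coas: pd.DataFrame | None = None,
    tag_id: str | None = None,
) -> list[dict]:
    """Daily observation dicts, attaching 12-h COA days as fixed cells.

    For a day with acoustic COAs, the COA with the most detections becomes
    the day's fixed (clamped) position.
    """
    fixed_by_date = {}
    if coas is not None and not coas.empty:
        sub = coas if tag_id is None else coas[coas["tag_id"] == tag_id]
        sub = sub.assign(date=pd.to_datetime(sub["bin_start"]).dt.date)
        for date, grp in sub.groupby("date"):
            best = grp.loc[grp["n_detections"].idxmax()]
            fixed_by_date[date] = grid.cell_index(float(best["lat"]), float(best["lon"]))
    obs = []
    for _, row in geosensor.iterrows():
        date = row["date"]
        obs.append(
            {
                "date": date,
                "lon_est": row.get("lon_est", np.nan),
                "sst_tag": row.get("sst_tag", np.nan),
                "fixed_cell": fixed_by_date.get(date),
            }
        )
    return obs


def run_geolocation(
    geosensor: pd.DataFrame,
    grid: GeoGrid,
    sst_field: np.ndarray,
    release_cell: int,
    coas: pd.DataFrame | None = None,
    tag_id: str | None = None,
    speed_mps: float = 2.0,
    sigma_lon_deg: float = 1.0,
    sigma_sst_c: float = 0.5,
):
    """End-to-end geolocation: likelihoods, smoothing, most probable track."""
    kernel = build_movement_kernel(grid, speed_mps)
    obs = observations_from_tables(geosensor, grid, coas, tag_id)
    L = np.stack(
        [daily_likelihood(o, grid, sst_field, sigma_lon_deg, sigma_sst_c) for o in obs]
    )
    prior = np.zeros(grid.n_cells)
    prior[release_cell] = 1.0
    smoothed, filtered, logev = forward_backward(L, kernel, prior)
    track = most_probable_track(
        smoothed, L, kernel, prior, grid, dates=[o["date"] for o in obs]
    )
    return {
        "posteriors": smoothed,
        "filtered": filtered,
        "log_evidence": logev,
        "track": track,
        "kernel": kernel,
        "likelihoods": L,
    }
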