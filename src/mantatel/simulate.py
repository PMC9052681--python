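"""Synthetic telemetry generator emulating the study's structure.

The generator produces every input table the pipeline consumes — detections,
stations, deployments, daily environment, geosensor series — plus ground-truth
tables (true positions, presence states, per-detection labels) so that every
downstream stage can be audited against known truth without any external data.

Emulated structure:

* a 15-receiver in-bay array in five regions (channel CH, central C, west W,
  south S, north N; the two farthest stations ~29 km apart) plus two offshore
  stations ~70 and ~125 km south;
* tags with i.i.d. uniform(310, 410) s transmission delays and a logistic
  distance-detection curve with 50% range 540 m (0.95 at the receiver,
  falling to 0.05 by twice the 50% range);
* daily in-bay presence driven by a logistic model on cyclic day-of-year,
  chlorophyll-a and lunar illuminated fraction; movement is a mean-reverting
  walk around a season-dependent activity centre with every 10-min step hard
  capped at 2 m/s;
* noise: cross-receiver echo duplicates within seconds of a genuine detection
  and isolated false single detections;
* a daily light-based longitude estimate and tag SST for the satellite-tag
  geolocation stage, over a synthetic meridional SST gradient and a land mask.

All randomness flows from one seed via spawned child generators in a fixed
order, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import default_config
from .geo import azimuthal_equidistant, haversine_m, inverse_azimuthal_equidistant

# (receiver_id, lat, lon, region) — in-bay stations ~2 km apart within their
# region, N1 to S3 ~29 km
ARRAY_LAYOUT = [
    ("CH1", 20.842, 37.296, "CH"),
    ("CH2", 20.828, 37.310, "CH"),
    ("CH3", 20.856, 37.312, "CH"),
    ("C1", 20.872, 37.262, "C"),
    ("C2", 20.856, 37.248, "C"),
    ("C3", 20.884, 37.238, "C"),
    ("W1", 20.806, 37.212, "W"),
    ("W2", 20.822, 37.228, "W"),
    ("W3", 20.790, 37.196, "W"),
    ("S1", 20.774, 37.248, "S"),
    ("S2", 20.760, 37.222, "S"),
    ("S3", 20.746, 37.231, "S"),
    ("S4", 20.768, 37.270, "S"),
    ("S5", 20.784, 37.284, "S"),
    ("N1", 21.005, 37.195, "N"),
    ("OFF1", 20.190, 37.350, "OFFSHORE"),  # ~70 km south of the bay
    ("OFF2", 19.700, 37.420, "OFFSHORE"),  # ~125 km south of the bay
]

#: month -> preferred region and seasonal activity centre (lat, lon): north in
#: winter, the southern basin in spring, the channel mouth in summer, central
#: in fall.
SEASONAL_REGION = {
    **{m: "N" for m in (12, 1, 2, 3)},
    **{m: "S" for m in (4, 5)},
    **{m: "CH" for m in (6, 7, 8)},
    **{m: "C" for m in (9, 10, 11)},
}
SEASONAL_CENTERS = {
    **{m: (20.985, 37.215) for m in (12, 1, 2, 3)},
    **{m: (20.762, 37.250) for m in (4, 5)},
    **{m: (20.836, 37.302) for m in (6, 7, 8)},
    **{m: (20.868, 37.250) for m in (9, 10, 11)},
}

#: resting point of an animal that has left the array region
ABSENT_CENTER = (20.700, 37.450)

ARRAY_CENTROID = (20.82, 37.24)


def default_receivers(start, end, battery_failures: bool = True) -> pd.DataFrame:
    """Station table with full-window active intervals.

    With ``battery_failures`` four in-bay receivers drop out one to four
    months before the study end, providing the varying-effort (nStations)
    signal the presence model controls for.
    """
    start = pd.Timestamp(start, tz="UTC")
    end = pd.Timestamp(end, tz="UTC")
    early_end = {"S4": 4, "W3": 3, "C1": 2, "CH3": 1} if battery_failures else {}
    rows = []
    for rid, lat, lon, region in ARRAY_LAYOUT:
        stop = max(start, end - pd.Timedelta(days=30 * early_end.get(rid, 0)))
        rows.append((rid, lat, lon, region, start, stop))
    return pd.DataFrame(
        rows, columns=["receiver_id", "lat", "lon", "region", "active_start", "active_end"]
    )


def default_deployments(n_animals: int, release_time, rng: np.random.Generator) -> pd.DataFrame:
    """Tag deployment table; maturity from the 3.2 m wingspan rule."""
    release_time = pd.Timestamp(release_time, tz="UTC")
    wingspan = np.round(rng.uniform(240, 370, n_animals)).astype(int)
    sex = np.where(np.arange(n_animals) % 2 == 0, "M", "F")
    return pd.DataFrame(
        {
            "animal_id": [f"A{i + 1}" for i in range(n_animals)],
            "tag_id": [f"T{i + 1}" for i in range(n_animals)],
            "release_time": release_time,
            "sex": sex,
            "wingspan_cm": wingspan,
            "maturity": np.where(wingspan >= 320, "mature", "immature"),
            "satellite_tag": ["PSAT" if i < 2 else ("SPOT" if i == 2 else "none") for i in range(n_animals)],
        }
    )


def simulate_environment(config: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Daily chlorophyll-a (seasonal lognormal) and lunar illuminated fraction."""
    sim = config["simulate"]
    env = sim["env"]
    dates = pd.date_range(sim["start"], sim["end"], freq="D")
    t = np.arange(len(dates), dtype=float)
    moon = 0.5 * (1.0 - np.cos(2 * np.pi * t / env["synodic_days"]))
    doy = dates.dayofyear.to_numpy().astype(float)
    log_chla = (
        env["chla_mean_log"]
        + env["chla_amplitude_log"] * np.cos(2 * np.pi * (doy - env["chla_peak_day"]) / 365.0)
        + rng.normal(0.0, env["chla_noise_sd_log"], len(dates))
    )
    return pd.DataFrame({"date": dates.date, "chla": np.exp(log_chla), "moon_frac": moon})


def presence_probability(doy, chla, moon, coefs: dict) -> np.ndarray:
    """Configured daily logit model for being inside the array region."""
    eta = (
        coefs["intercept"]
        + coefs["day_amplitude"] * np.cos(2 * np.pi * (np.asarray(doy, float) - coefs["day_peak"]) / 365.0)
        + coefs["chla_coef"] * np.asarray(chla, float)
        + coefs["moon_coef"] * np.asarray(moon, float)
    )
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_movement(
    config: dict,
    environment: pd.DataFrame,
    deployments: pd.DataFrame,
    rng: np.random.Generator,
):
    """Site-visit movement: dwell bouts at stations or roam spots, slow transits.

    Receivers in this kind of study are deliberately placed at aggregation
    sites, so animals are modelled as alternating short dwell bouts at a
    station (tight mean-reverting jitter, producing the multi-detection visit
    bouts receiver data show) with longer bouts at open-water roam spots drawn
    around the month's seasonal activity centre, connected by directed
    transits well below the 2 m/s cap.  The month's preferred region biases
    which stations get visited (north in winter, central in fall, ...).
    Animals whose daily in-bay state is absent commute to an offshore resting
    point.  Every step displacement is hard-capped at speed_cap * dt.

    Returns (positions, presence_truth): positions has one row per animal per
    timestep (lat, lon); presence_truth one row per animal per day with the
    drawn in-bay state and its probability.
    """
    sim = config["simulate"]
    mov = sim["movement"]
    dt_s = sim["step_minutes"] * 60.0
    cap_m = sim["speed_cap_mps"] * dt_s
    transit_step = mov["transit_mps"] * dt_s
    excursion_step = mov["excursion_mps"] * dt_s
    step_sd = mov["step_sd_m"]
    dwell_sd = mov["dwell_sd_m"]
    dwell_rev = mov["dwell_reversion"]
    def draw_dwell(floor_min, extra_min):
        return (floor_min + rng.exponential(extra_min)) / sim["step_minutes"]

    station_dwell = (mov["station_dwell_floor_min"], mov["station_dwell_extra_min"])
    roam_dwell = (mov["roam_dwell_floor_min"], mov["roam_dwell_extra_min"])
    arrive_m = max(2.0 * dwell_sd, 100.0)
    lat0, lon0 = ARRAY_CENTROID

    env = environment.set_index("date")
    dates = environment["date"].to_numpy()
    doy = pd.DatetimeIndex(pd.to_datetime(environment["date"])).dayofyear.to_numpy().astype(float)
    months = pd.DatetimeIndex(pd.to_datetime(environment["date"])).month.to_numpy()
    p_daily = presence_probability(doy, env["chla"].to_numpy(), env["moon_frac"].to_numpy(), sim["presence"])

    n_animals = len(deployments)
    n_days = len(dates)
    # persistent daily states: latent Gaussian AR(1) thresholded at the
    # configured probability, so marginals are exactly Bernoulli(p_t) while
    # absences run for days to weeks as they do in real arrays
    rho = sim["presence"]["persistence"]
    eps = rng.normal(size=(n_days, n_animals))
    z = np.empty_like(eps)
    z[0] = eps[0]
    for d in range(1, n_days):
        z[d] = rho * z[d - 1] + np.sqrt(1.0 - rho**2) * eps[d]
    present = z < stats.norm.ppf(np.clip(p_daily, 1e-12, 1 - 1e-12))[:, None]

    stations = [s for s in ARRAY_LAYOUT if s[3] != "OFFSHORE"]
    st_xy = np.array([azimuthal_equidistant(s[1], s[2], lat0, lon0) for s in stations])
    st_region = np.array([s[3] for s in stations])
    centers_xy = {m: np.array(azimuthal_equidistant(c[0], c[1], lat0, lon0)) for m, c in SEASONAL_CENTERS.items()}
    absent_xy = np.array(azimuthal_equidistant(*ABSENT_CENTER, lat0, lon0))

    steps_per_day = int(round(86400.0 / dt_s))
    start = pd.Timestamp(sim["start"], tz="UTC")
    times = start + pd.to_timedelta(np.arange(n_days * steps_per_day) * dt_s, unit="s")

    def new_target(month, here):
        """Next visit target: a station of the preferred region, any station, or a roam spot."""
        if rng.uniform() < mov["station_visit_prob"]:
            if rng.uniform() < mov["region_prob"]:
                idx = np.flatnonzero(st_region == SEASONAL_REGION[month])
            else:
                idx = np.arange(len(stations))
            j = int(idx[rng.integers(len(idx))])
            return st_xy[j], draw_dwell(*station_dwell)
        # roam spots are open water, clear of every station's detection range,
        # drawn between here and the seasonal centre so hops stay short
        anchor = 0.5 * (centers_xy[month] + here)
        for _ in range(100):
            spot = anchor + rng.normal(0.0, mov["roam_sd_m"], 2)
            if np.linalg.norm(st_xy - spot, axis=1).min() >= mov["roam_clearance_m"]:
                break
        return spot, draw_dwell(*roam_dwell)

    pos = np.empty((n_days * steps_per_day, n_animals, 2))
    xy = np.tile(centers_xy[months[0]], (n_animals, 1))
    target = xy.copy()
    dwelling = np.ones(n_animals, dtype=bool)
    dwell_left = np.array([draw_dwell(*roam_dwell) for _ in range(n_animals)])
    was_present = np.ones(n_animals, dtype=bool)
    commuting = np.zeros(n_animals, dtype=bool)  # fast bay <-> offshore legs

    t_idx = 0
    for d in range(n_days):
        month = months[d]
        pres_d = present[d]
        switched = pres_d != was_present
        for a in np.flatnonzero(switched):
            if pres_d[a]:
                target[a], dwell_left[a] = new_target(month, xy[a])
            else:
                target[a], dwell_left[a] = absent_xy, np.inf
            dwelling[a] = False
            commuting[a] = True
        was_present = pres_d.copy()

        noise = rng.normal(0.0, 1.0, (steps_per_day, n_animals, 2))
        for s in range(steps_per_day):
            to_target = target - xy
            dist = np.linalg.norm(to_target, axis=1, keepdims=True)
            # bay <-> offshore commutes move faster than local transits
            speed = np.where(commuting, excursion_step, transit_step)[:, None]
            drift = np.where(
                dwelling[:, None],
                dwell_rev * to_target,
                to_target / np.maximum(dist, 1e-12) * np.minimum(speed, dist),
            )
            sd = np.where(dwelling, dwell_sd, step_sd)[:, None]
            delta = drift + noise[s] * sd
            norm = np.linalg.norm(delta, axis=1, keepdims=True)
            delta *= np.minimum(1.0, cap_m / np.maximum(norm, 1e-12))
            xy = xy + delta
            pos[t_idx] = xy
            t_idx += 1

            arrived = ~dwelling & (np.linalg.norm(target - xy, axis=1) < arrive_m)
            for a in np.flatnonzero(arrived):
                dwelling[a] = True
                commuting[a] = False
                dwell_left[a] = draw_dwell(
                    *(station_dwell if _is_station(target[a], st_xy) else roam_dwell)
                )
            dwell_left[dwelling] -= 1.0
            done = dwelling & (dwell_left <= 0) & pres_d
            for a in np.flatnonzero(done):
                target[a], dwell_left[a] = new_target(month, xy[a])
                dwelling[a] = False

    lat, lon = inverse_azimuthal_equidistant(pos[:, :, 0], pos[:, :, 1], lat0, lon0)
    animals = deployments["animal_id"].to_numpy()
    positions = pd.DataFrame(
        {
            "animal_id": np.tile(animals, len(times)),
            "timestep": np.repeat(times, n_animals),
            "lat": lat.ravel(),
            "lon": lon.ravel(),
        }
    )
    presence_truth = pd.DataFrame(
        {
            "animal_id": np.tile(animals, n_days),
            "date": np.repeat(dates, n_animals),
            "present": present.ravel(),
            "p_present": np.repeat(p_daily, n_animals),
        }
    )
    return positions, presence_truth


def _is_station(xy: np.ndarray, st_xy: np.ndarray) -> bool:
    return bool((np.linalg.norm(st_xy - xy, axis=1) < 1.0).any())


def detection_probability(
    distance_m, r50_m: float = 540.0, p_max: float = 0.95, max_range_m: float = 1100.0
) -> np.ndarray:
    """Logistic distance-detection curve with p(r50) = 0.5 and p(0) = p_max.

    With the defaults p falls to 0.05 by twice the 50% range; beyond
    ``max_range_m`` the signal is below the reef noise floor and p is zero.
    """
    s = r50_m / np.log(p_max / (1.0 - p_max))
    d = np.asarray(distance_m, float)
    pr = 1.0 / (1.0 + np.exp(-(r50_m - d) / s))
    return np.where(d > max_range_m, 0.0, pr)


def simulate_detections(
    positions: pd.DataFrame,
    receivers: pd.DataFrame,
    deployments: pd.DataFrame,
    config: dict,
    rng: np.random.Generator,
):
    """Transmissions, probabilistic reception, and labelled noise.

    Returns (detections, labels) where labels carries one row per emitted
    detection with kind in {genuine, echo, false}.  Echoes are cross-receiver
    ghost decodes 1-5 s after a genuine detection; false singles are placed
    at in-bay receivers isolated (>= 2 h) from any other detection of the tag.
    """
    sim = config["simulate"]
    active = receivers[receivers["region"] != "OFFSHORE"]
    if receivers.empty:
        raise ValueError("no receivers")
    rec_lat = receivers["lat"].to_numpy()
    rec_lon = receivers["lon"].to_numpy()
    rec_id = receivers["receiver_id"].to_numpy()
    rec_start = receivers["active_start"].astype("int64").to_numpy() / 1e9
    rec_end = receivers["active_end"].astype("int64").to_numpy() / 1e9
    inbay_ids = active["receiver_id"].unique()

    dt_s = sim["step_minutes"] * 60.0
    start = pd.Timestamp(sim["start"], tz="UTC")
    t0 = start.value / 1e9
    lo, hi = sim["ping_delay_s"]
    r50 = sim["detect_r50_m"]
    pmax = sim["detect_pmax"]
    max_range = sim["detect_max_range_m"]

    pos_by_animal = dict(tuple(positions.groupby("animal_id", sort=True)))
    n_steps = max(len(v) for v in pos_by_animal.values())
    horizon = n_steps * dt_s

    rows = []  # (t_sec, receiver, tag, kind)
    for _, dep in deployments.iterrows():
        p = pos_by_animal[dep["animal_id"]]
        plat = p["lat"].to_numpy()
        plon = p["lon"].to_numpy()
        n_ping = int(horizon / lo) + 2
        gaps = rng.uniform(lo, hi, n_ping)
        t_ping = np.cumsum(gaps)
        t_ping = t_ping[t_ping < horizon]
        idx = np.minimum((t_ping / dt_s).astype(int), len(plat) - 1)
        lat_p, lon_p = plat[idx], plon[idx]
        tabs = t0 + t_ping
        for r in range(len(rec_id)):
            d = haversine_m(lat_p, lon_p, rec_lat[r], rec_lon[r])
            near = d < 3000.0
            if not near.any():
                continue
            pr = detection_probability(d[near], r50, pmax, max_range)
            live = (tabs[near] >= rec_start[r]) & (tabs[near] < rec_end[r])
            heard = (rng.uniform(size=near.sum()) < pr) & live
            for t in tabs[near][heard]:
                rows.append((t, rec_id[r], dep["tag_id"], "genuine"))

    rows.sort()
    # cross-receiver echoes
    echo_rows = []
    echo_rate = sim["noise"]["echo_rate"]
    for t, rid, tag, _ in rows:
        if rng.uniform() < echo_rate:
            others = inbay_ids[inbay_ids != rid]
            ghost = others[rng.integers(len(others))]
            echo_rows.append((t + rng.uniform(1.0, 5.0), ghost, tag, "echo"))

    # isolated false singles
    false_rows = []
    rate = sim["noise"]["false_per_tag_day"]
    n_days = horizon / 86400.0
    iso_gap = 2.0 * config["qc"]["isolation_window_min"] * 60.0
    for _, dep in deployments.iterrows():
        tag = dep["tag_id"]
        t_existing = np.sort(
            np.array([t for t, _, g, _ in rows if g == tag] + [t for t, _, g, _ in echo_rows if g == tag])
        )
        n_false = rng.poisson(rate * n_days)
        placed = []
        attempts = 0
        while len(placed) < n_false and attempts < 50 * max(n_false, 1):
            attempts += 1
            t = t0 + rng.uniform(0.0, horizon)
            j = np.searchsorted(t_existing, t)
            near_genuine = (j > 0 and t - t_existing[j - 1] < iso_gap) or (
                j < len(t_existing) and t_existing[j] - t < iso_gap
            )
            near_placed = any(abs(t - q) < iso_gap for q in placed)
            if near_genuine or near_placed:
                continue
            placed.append(t)
            ghost = inbay_ids[rng.integers(len(inbay_ids))]
            false_rows.append((t, ghost, tag, "false"))

    all_rows = sorted(rows + echo_rows + false_rows)
    det = pd.DataFrame(all_rows, columns=["t", "receiver_id", "tag_id", "kind"])
    if det.empty:
        det["t"] = det["t"].astype(float)
    # acoustic receivers log at second resolution
    det["timestamp"] = pd.to_datetime(det.pop("t").round().astype("int64"), unit="s", utc=True)
    det = det.sort_values(["tag_id", "timestamp", "receiver_id"], kind="mergesort").reset_index(drop=True)
    labels = det[["timestamp", "receiver_id", "tag_id", "kind"]].copy()
    detections = det[["timestamp", "receiver_id", "tag_id"]].copy()
    return detections, labels


def synthetic_sst(lat) -> np.ndarray:
    """Smooth meridional SST gradient (degC), the latitude signal for geolocation."""
    return 32.0 - 0.55 * (np.asarray(lat, dtype=float) - 18.0)


def land_mask(lat, lon) -> np.ndarray:
    """True where a cell is land: the coastline runs along 37.0 E here."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return lon < 37.0


def simulate_geosensor(
    positions: pd.DataFrame,
    animal_id: str,
    config: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Daily light-based longitude estimate and tag SST for one animal.

    Longitude carries direct (noisy) information; latitude is only observable
    through the SST match against the meridional field.
    """
    g = config["simulate"]["geosensor"]
    p = positions[positions["animal_id"] == animal_id]
    if p.empty:
        raise ValueError(f"no positions for animal {animal_id}")
    daily = p.set_index("timestep").resample("1D")[["lat", "lon"]].mean().dropna()
    n = len(daily)
    return pd.DataFrame(
        {
            "date": daily.index.date,
            "lon_est": daily["lon"].to_numpy() + rng.normal(0.0, g["sigma_lon_deg"], n),
            "sst_tag": synthetic_sst(daily["lat"].to_numpy()) + rng.normal(0.0, g["sigma_sst_c"], n),
            "true_lat": daily["lat"].to_numpy(),
            "true_lon": daily["lon"].to_numpy(),
        }
    )


def simulate_hourly_presence(
    n_animals: int = 15,
    n_days: int = 140,
    seed: int = 0,
    coefs: dict | None = None,
    animal_sd: float = 0.4,
    start: str = "2013-01-01",
) -> tuple[pd.DataFrame, dict]:
    """Hourly binomial observations drawn directly from a known logit model.

    Used to audit the presence GAMM against known truth without the detection
    process in between.  ``coefs`` may contain intercept, day_amplitude,
    day_peak, hour_amplitude, hour_peak, chla_coef, moon_coef (absent terms
    default to zero effect except the seasonal defaults below).

    Returns (table, truth) where truth holds the generating functions on the
    logit scale: truth["day_effect"](doy), truth["hour_effect"](hour).
    """
    defaults = {
        "intercept": -0.3,
        "day_amplitude": 1.6,
        "day_peak": 285,
        "hour_amplitude": 0.0,
        "hour_peak": 8,
        "chla_coef": 1.2,
        "moon_coef": 0.0,
        "stations_coef": 0.0,
    }
    c = dict(defaults, **(coefs or {}))
    ss = np.random.SeedSequence(seed)
    rng_env, rng_y, rng_u = (np.random.default_rng(s) for s in ss.spawn(3))

    dates = pd.date_range(start, periods=n_days, freq="D")
    t = np.arange(n_days, dtype=float)
    moon = 0.5 * (1.0 - np.cos(2 * np.pi * t / 29.53))
    doy_d = dates.dayofyear.to_numpy().astype(float)
    chla = np.exp(-0.7 + 0.8 * np.cos(2 * np.pi * (doy_d - 200) / 365.0) + rng_env.normal(0, 0.15, n_days))

    hours = np.arange(24, dtype=float)
    doy = np.repeat(doy_d, 24)
    hr = np.tile(hours, n_days)
    moon_h = np.repeat(moon, 24)
    chla_h = np.repeat(chla, 24)
    hour_start = pd.date_range(dates[0], periods=n_days * 24, freq="h", tz="UTC")
    # receiver effort declines stepwise over the window (battery failures)
    n_stations = np.repeat(15.0 - np.floor(4.0 * np.arange(n_days) / n_days), 24)

    u = rng_u.normal(0.0, animal_sd, n_animals)

    def day_effect(d):
        return c["day_amplitude"] * np.cos(2 * np.pi * (np.asarray(d, float) - c["day_peak"]) / 365.0)

    def hour_effect(h):
        return c["hour_amplitude"] * np.cos(2 * np.pi * (np.asarray(h, float) - c["hour_peak"]) / 24.0)

    frames = []
    for a in range(n_animals):
        eta = (
            c["intercept"]
            + day_effect(doy)
            + hour_effect(hr)
            + c["chla_coef"] * chla_h
            + c["moon_coef"] * moon_h
            + c["stations_coef"] * (n_stations - 15.0)
            + u[a]
        )
        y = (rng_y.uniform(size=len(eta)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": f"A{a + 1}",
                    "hour_start": hour_start,
                    "y": y,
                    "day_of_year": doy,
                    "hour": hr,
                    "moon_frac": moon_h,
                    "chla": chla_h,
                    "n_stations": n_stations,
                    "sex": "F" if a % 2 else "M",
                    "maturity": "mature" if a % 3 else "immature",
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    truth = {"day_effect": day_effect, "hour_effect": hour_effect, "coefs": c, "animal_effects": u}
    return table, truth


def simulate_dataset(config: dict | None = None, seed: int = 0) -> dict:
    """Run the full generator; returns a dict of tables keyed by name.

    Keys: receivers, deployments, environment, detections, truth_labels,
    truth_positions, truth_presence, geosensor (for the first PSAT animal).
    """
    config = config or default_config()
    sim = config["simulate"]
    ss = np.random.SeedSequence(seed)
    rng_env, rng_dep, rng_move, rng_det, rng_geo = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    receivers = default_receivers(sim["start"], sim["end"])
    deployments = default_deployments(sim["n_animals"], sim["start"], rng_dep)
    environment = simulate_environment(config, rng_env)
    positions, presence_truth = simulate_movement(config, environment, deployments, rng_move)
    detections, labels = simulate_detections(positions, receivers, deployments, config, rng_det)
    psat = deployments.loc[deployments["satellite_tag"] == "PSAT", "animal_id"]
    geosensor = (
        simulate_geosensor(positions, psat.iloc[0], config, rng_geo) if len(psat) else pd.DataFrame()
    )
    return {
        "receivers": receivers,
        "deployments": deployments,
        "environment": environment,
        "detections": detections,
        "truth_labels": labels,
        "truth_positions": positions,
        "truth_presence": presence_truth,
        "geosensor": geosensor,
    }
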