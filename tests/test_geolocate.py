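import numpy as np
import pandas as pd
import pytest

from mantatel.geo import haversine_m
from mantatel.geolocate import (
    GeoGrid,
    build_movement_kernel,
    daily_likelihood,
    forward_backward,
    most_probable_track,
    observations_from_tables,
    run_geolocation,
    viterbi,
)
from mantatel.simulate import land_mask, synthetic_sst

MAX_DAY_M = 2.0 * 86400.0  # speed bound: 172.8 km/day


@pytest.fixture()
def grid15():
    """15 x 15 grid with a land strip along the west edge."""
    g = GeoGrid(18.5, 22.25, 36.0, 39.75, 0.25)
    g.water = ~land_mask(g.cell_lat, g.cell_lon)
    return g


def _oracle_forward_backward(L, K, prior):
    """Explicit per-state loop implementation (no vectorisation shortcuts)."""
    T, n = L.shape
    alpha = np.zeros((T, n))
    for j in range(n):
        alpha[0, j] = prior[j] * L[0, j]
    alpha[0] /= alpha[0].sum()
    for t in range(1, T):
        for j in range(n):
            s = 0.0
            for i in range(n):
                s += alpha[t - 1, i] * K[i, j]
            alpha[t, j] = s * L[t, j]
        alpha[t] /= alpha[t].sum()
    beta = np.ones(n)
    gamma = np.zeros((T, n))
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        nb = np.zeros(n)
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += K[i, j] * L[t + 1, j] * beta[j]
            nb[i] = s
        beta = nb / nb.sum()
        gamma[t] = alpha[t] * beta
        gamma[t] /= gamma[t].sum()
    return gamma


class TestKernel:
    def test_rows_stochastic_over_water(self, grid15):
        K = build_movement_kernel(grid15)
        water = grid15.water_flat
        np.testing.assert_allclose(K[water].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(K[:, ~water] == 0.0)
        assert np.all(K[~water] == 0.0)

    def test_slow_speed_limit_is_identity(self, grid15):
        # displacement bound below the cell spacing leaves only the self-cell
        K = build_movement_kernel(grid15, speed_mps=0.1)  # 8.6 km/day < 25 km cells
        water = grid15.water_flat
        np.testing.assert_allclose(K[np.ix_(water, water)], np.eye(water.sum()), atol=1e-12)

    def test_no_mass_beyond_speed_bound(self, grid15):
        K = build_movement_kernel(grid15)
        lat = grid15.cell_lat.ravel()
        lon = grid15.cell_lon.ravel()
        i, j = np.nonzero(K)
        d = haversine_m(lat[i], lon[i], lat[j], lon[j])
        assert d.max() <= MAX_DAY_M

    def test_nonpositive_speed_rejected(self, grid15):
        with pytest.raises(ValueError):
            build_movement_kernel(grid15, speed_mps=0.0)


class TestLikelihood:
    def test_no_information_uniform_over_water(self, grid15):
        L = daily_likelihood({"lon_est": np.nan, "sst_tag": np.nan}, grid15)
        water = grid15.water_flat
        assert np.all(L[water] == 1.0)
        assert np.all(L[~water] == 0.0)

    def test_fixed_cell_is_delta(self, grid15):
        cell = grid15.cell_index(20.0, 38.0)
        L = daily_likelihood({"fixed_cell": cell}, grid15)
        assert L[cell] == 1.0 and L.sum() == 1.0

    def test_fixed_cell_on_land_rejected(self, grid15):
        cell = grid15.cell_index(20.0, 36.1)
        with pytest.raises(ValueError, match="land"):
            daily_likelihood({"fixed_cell": cell}, grid15)

    def test_zero_noise_peak_at_true_cell(self, grid15):
        true_lat, true_lon = 20.125, 38.125
        sst = synthetic_sst(grid15.cell_lat)
        obs = {"lon_est": true_lon, "sst_tag": float(synthetic_sst(true_lat))}
        L = daily_likelihood(obs, grid15, sst, sigma_lon_deg=0.2, sigma_sst_c=0.1)
        assert int(np.argmax(L)) == grid15.cell_index(true_lat, true_lon)

    def test_inconsistent_observation_errors(self, grid15):
        sst = synthetic_sst(grid15.cell_lat)
        with pytest.raises(ValueError, match="zero"):
            # SST far outside the field with near-zero noise
            daily_likelihood({"sst_tag": 500.0}, grid15, sst, sigma_sst_c=1e-6)


class TestForwardBackward:
    def _random_problem(self, grid, T, seed, with_fixed=False):
        rng = np.random.default_rng(seed)
        sst = synthetic_sst(grid.cell_lat)
        L = []
        for t in range(T):
            obs = {
                "lon_est": rng.uniform(36.5, 39.5),
                "sst_tag": rng.uniform(float(sst.min()), float(sst.max())),
            }
            L.append(daily_likelihood(obs, grid, sst, 1.0, 1.0))
        L = np.stack(L)
        if with_fixed:
            cell = grid.cell_index(20.0, 38.0)
            L[T // 2] = daily_likelihood({"fixed_cell": cell}, grid)
        prior = grid.water_flat / grid.water_flat.sum()
        return L, prior

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_loop_oracle(self, grid15, seed):
        K = build_movement_kernel(grid15)
        L, prior = self._random_problem(grid15, 8, seed, with_fixed=(seed == 2))
        smoothed, filtered, _ = forward_backward(L, K, prior)
        oracle = _oracle_forward_backward(L, K, prior)
        assert np.abs(smoothed - oracle).max() < 1e-8

    def test_posteriors_normalized_and_masked(self, grid15):
        K = build_movement_kernel(grid15)
        L, prior = self._random_problem(grid15, 10, 3)
        smoothed, filtered, _ = forward_backward(L, K, prior)
        np.testing.assert_allclose(smoothed.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(filtered.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(smoothed[:, ~grid15.water_flat] == 0.0)

    def test_delta_likelihoods_pass_through(self, grid15):
        K = build_movement_kernel(grid15)
        cells = [grid15.cell_index(20.0, 38.0), grid15.cell_index(20.25, 38.25), grid15.cell_index(20.5, 38.5)]
        L = np.stack([daily_likelihood({"fixed_cell": c}, grid15) for c in cells])
        prior = np.zeros(grid15.n_cells)
        prior[cells[0]] = 1.0
        smoothed, _, _ = forward_backward(L, K, prior)
        for t, c in enumerate(cells):
            assert smoothed[t, c] == pytest.approx(1.0)

    def test_time_reversal_symmetry(self, grid15):
        """With a symmetric doubly-stochastic kernel and uniform prior the
        chain is reversible: smoothing the reversed inputs reverses the
        posteriors."""
        K = build_movement_kernel(grid15)
        water = grid15.water_flat
        # Sinkhorn-balance the water block into a symmetric doubly
        # stochastic kernel (d_i K_ij d_j keeps symmetry)
        G = K[np.ix_(water, water)] + K[np.ix_(water, water)].T
        d = np.ones(G.shape[0])
        for _ in range(200):
            d = 1.0 / np.sqrt((G * d[None, :]).sum(axis=1) / d)
        Ksym = np.zeros_like(K)
        Ksym[np.ix_(water, water)] = d[:, None] * G * d[None, :]
        assert np.abs(Ksym[water].sum(axis=1) - 1.0).max() < 1e-12
        L, prior = self._random_problem(grid15, 6, 4)
        fwd, _, _ = forward_backward(L, Ksym, prior)
        rev, _, _ = forward_backward(L[::-1], Ksym, prior)
        assert np.abs(fwd - rev[::-1]).max() < 1e-10

    def test_uniform_likelihoods_diffuse_from_prior(self, grid15):
        K = build_movement_kernel(grid15)
        T = 6
        L = np.tile(grid15.water_flat.astype(float), (T, 1))
        prior = np.zeros(grid15.n_cells)
        prior[grid15.cell_index(20.0, 38.0)] = 1.0
        smoothed, filtered, _ = forward_backward(L, K, prior)
        # with no information the filtered law is the prior diffused by kernel
        # powers, so spread (entropy) never decreases
        ent = [-np.sum(f[f > 0] * np.log(f[f > 0])) for f in filtered]
        assert all(b >= a - 1e-9 for a, b in zip(ent, ent[1:]))

    def test_fixed_day_does_not_raise_neighbor_entropy(self, grid15):
        """Clamping a day to an acoustic position never makes adjacent days
        less certain."""
        K = build_movement_kernel(grid15)
        L, prior = self._random_problem(grid15, 9, 5)
        base, _, _ = forward_backward(L, K, prior)
        Lf = L.copy()
        mid = 4
        cell = int(np.argmax(base[mid]))
        Lf[mid] = daily_likelihood({"fixed_cell": cell}, grid15)
        fixed, _, _ = forward_backward(Lf, K, prior)

        def entropy(p):
            p = p[p > 0]
            return -np.sum(p * np.log(p))

        for t in (mid - 1, mid + 1):
            assert entropy(fixed[t]) <= entropy(base[t]) + 1e-6


class TestTrack:
    def test_single_cell_posteriors_track_through(self, grid15):
        K = build_movement_kernel(grid15)
        cells = [grid15.cell_index(20.0, 38.0), grid15.cell_index(20.25, 38.0)]
        L = np.stack([daily_likelihood({"fixed_cell": c}, grid15) for c in cells])
        prior = np.zeros(grid15.n_cells)
        prior[cells[0]] = 1.0
        smoothed, _, _ = forward_backward(L, K, prior)
        track = most_probable_track(smoothed, L, K, prior, grid15)
        got = [grid15.cell_index(la, lo) for la, lo in zip(track["lat"], track["lon"])]
        assert got == cells

    def test_viterbi_steps_within_speed_bound(self, grid15):
        K = build_movement_kernel(grid15)
        rng = np.random.default_rng(6)
        sst = synthetic_sst(grid15.cell_lat)
        L = np.stack(
            [
                daily_likelihood(
                    {"lon_est": rng.uniform(37.5, 39.0), "sst_tag": rng.uniform(30.2, 31.0)},
                    grid15, sst,
                )
                for _ in range(12)
            ]
        )
        prior = grid15.water_flat / grid15.water_flat.sum()
        path = viterbi(L, K, prior)
        lat = grid15.cell_lat.ravel()[path]
        lon = grid15.cell_lon.ravel()[path]
        steps = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
        assert steps.max() <= MAX_DAY_M


class TestEndToEnd:
    def test_synthetic_track_reconstruction(self, year_sim):
        """Track error: exact at acoustically fixed days, bounded elsewhere."""
        cfg, data = year_sim
        geo = data["geosensor"].iloc[:120].copy()
        grid = GeoGrid(18.5, 23.0, 36.5, 39.5, 0.25)
        grid.water = ~land_mask(grid.cell_lat, grid.cell_lon)
        sst_field = synthetic_sst(grid.cell_lat)
        # fixed acoustic positions every 7th day at the true cell
        coas = pd.DataFrame(
            {
                "tag_id": "T",
                "bin_start": pd.to_datetime(geo["date"].iloc[::7]).dt.tz_localize("UTC"),
                "lat": geo["true_lat"].iloc[::7].to_numpy(),
                "lon": geo["true_lon"].iloc[::7].to_numpy(),
                "n_detections": 5,
            }
        )
        release = grid.cell_index(float(geo["true_lat"].iloc[0]), float(geo["true_lon"].iloc[0]))
        result = run_geolocation(geo, grid, sst_field, release, coas, "T")
        track = result["track"]
        err = haversine_m(
            track["lat"].to_numpy(), track["lon"].to_numpy(),
            geo["true_lat"].to_numpy(), geo["true_lon"].to_numpy(),
        ) / 1000.0
        fixed_days = np.arange(len(geo)) % 7 == 0
        cell_diag_km = 0.25 * 111.2 * np.sqrt(2)
        assert np.median(err[fixed_days]) < cell_diag_km
        assert np.median(err[~fixed_days]) < 150.0
        np.testing.assert_allclose(result["posteriors"].sum(axis=1), 1.0, atol=1e-10)

    def test_observations_attach_fixed_days(self, grid15):
        geo = pd.DataFrame(
            {
                "date": pd.date_range("2013-02-01", periods=3).date,
                "lon_est": [38.0, 38.1, 38.2],
                "sst_tag": [30.8, 30.8, 30.8],
            }
        )
        coas = pd.DataFrame(
            {
                "tag_id": "T1",
                "bin_start": [pd.Timestamp("2013-02-02T00:00:00Z"), pd.Timestamp("2013-02-02T12:00:00Z")],
                "lat": [20.0, 20.5],
                "lon": [38.0, 38.5],
                "n_detections": [2, 7],
            }
        )
        obs = observations_from_tables(geo, grid15, coas, "T1")
        assert obs[0]["fixed_cell"] is None
        # the COA with more detections wins the day
        assert obs[1]["fixed_cell"] == grid15.cell_index(20.5, 38.5)
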