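"""HMM grid filter: grid construction, predict/update steps, full filter."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from seatrack import (FilterConfig, HMMGeolocator, SimConfig, TagDeployment,
                      best_daily_location, build_grid, depth_mask,
                      light_likelihood, predict_step, run_filter,
                      simulate_observations, simulate_track, sst_likelihood,
                      transition_matrix, update_step)
from seatrack.geolocation import _point_mass
from seatrack.grid import KM_PER_DEG

from conftest import flat_sea_grid


class TestBuildGrid:
    def test_cell_count_and_centroids(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        assert g.n_cells == 100
        assert g.lons[0] == pytest.approx(0.5)
        assert g.lats[0] == pytest.approx(40.5)

    def test_all_land_rejected(self):
        lons = np.linspace(0, 10, 5)
        lats = np.linspace(40, 50, 5)
        with pytest.raises(ValueError, match="sea"):
            build_grid((0, 10, 40, 50), 1.0,
                       (lons, lats, np.zeros((5, 5))))

    def test_resolution_must_divide_extent(self):
        lons = np.linspace(0, 10, 5)
        lats = np.linspace(40, 50, 5)
        with pytest.raises(ValueError, match="divide"):
            build_grid((0, 10, 40, 50), 3.0,
                       (lons, lats, np.full((5, 5), 100.0)))


class TestPredictStep:
    def test_zero_diffusion_is_identity(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        p = _point_mass(g, 5.0, 45.0)
        out = predict_step(p, g, FilterConfig(D=0.0), 1.0)
        assert np.array_equal(out, p)

    def test_mass_conserved_with_reflecting_boundaries(self):
        g = flat_sea_grid((0, 10, 40, 50), 0.5)
        p = _point_mass(g, 0.75, 40.75)  # near a corner
        out = p
        for _ in range(30):
            out = predict_step(out, g, FilterConfig(D=2000.0), 1.0)
        assert abs(out.sum() - 1.0) < 1e-9
        assert (out >= 0).all()

    def test_point_mass_spreads_with_analytic_variance(self):
        """One day of diffusion at D=1,000 km^2/day gives per-axis
        variance 2*D*t = 2,000 km^2 (analytic Gaussian solution)."""
        g = flat_sea_grid((-10, 10, 35, 55), 0.2)
        p = _point_mass(g, 0.0, 45.0)
        i, j = g.cell_of(0.0, 45.0)
        out = predict_step(p, g, FilterConfig(D=1000.0), 1.0)
        glat, glon = g.mesh()
        x = (glon - g.lons[j]) * KM_PER_DEG * np.cos(np.radians(glat))
        y = (glat - g.lats[i]) * KM_PER_DEG
        vx = (out * x**2).sum() - (out * x).sum() ** 2
        vy = (out * y**2).sum() - (out * y).sum() ** 2
        assert vx == pytest.approx(2000.0, rel=0.02)
        assert vy == pytest.approx(2000.0, rel=0.02)
        assert abs(out.sum() - 1.0) < 1e-9

    def test_no_leak_onto_land(self, env):
        g = build_grid(env.extent, 1.0, env)
        p = _point_mass(g, -9.0, 56.0)
        for _ in range(10):
            p = predict_step(p, g, FilterConfig(D=3000.0), 1.0)
        assert p[~g.sea].sum() == 0.0

    def test_unnormalised_input_rejected(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        with pytest.raises(ValueError, match="normalis"):
            predict_step(np.full(g.shape, 0.5), g, FilterConfig(), 1.0)

    def test_advection_shifts_the_mean(self):
        g = flat_sea_grid((-10, 10, 35, 55), 0.5)
        p = _point_mass(g, 0.0, 45.0)
        cfg = FilterConfig(D=200.0, advection=(30.0, 0.0))  # 30 km/day east
        out = predict_step(p, g, cfg, 1.0)
        lon0 = best_daily_location(p, g)[0]
        lon1 = best_daily_location(out, g)[0]
        shift_km = (lon1 - lon0) * KM_PER_DEG * np.cos(np.radians(45))
        assert shift_km == pytest.approx(30.0, rel=0.05)
        assert abs(out.sum() - 1.0) < 1e-9


class TestLikelihoods:
    def test_light_mode_and_symmetry(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        L = light_likelihood((5.5, 45.5), g, FilterConfig())
        i, j = g.cell_of(5.5, 45.5)
        assert L[i, j] == L.max()
        assert L[i - 1, j] == pytest.approx(L[i + 1, j])

    def test_light_latitude_ratio_is_half_gaussian_unit(self):
        """Cells 3.5 deg apart in latitude (= one sigma) have likelihood
        ratio exp(1/2)."""
        g = flat_sea_grid((0, 10, 40, 50), 0.5)
        cfg = FilterConfig()
        L = light_likelihood((5.25, 42.25), g, cfg)
        i, j = g.cell_of(5.25, 42.25)
        ip, _ = g.cell_of(5.25, 42.25 + 3.5)
        assert L[i, j] / L[ip, j] == pytest.approx(np.exp(0.5), rel=1e-9)

    def test_missing_light_fix_is_uniform(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        L = light_likelihood((np.nan, 45.0), g, FilterConfig())
        assert (L == 1.0).all()

    def test_sst_ratio_and_uninformative_field(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        cfg = FilterConfig()
        field = np.full(g.shape, 12.0)
        field[3, 4] = 12.5
        L = sst_likelihood(12.5, field, cfg)
        assert L[3, 4] == L.max()
        # |obs - field| = 0.5 degC (= one sigma) vs exact match
        assert L[0, 0] / L[3, 4] == pytest.approx(np.exp(-0.5), rel=1e-9)
        Lflat = sst_likelihood(12.0, np.full(g.shape, 12.0), cfg)
        assert np.ptp(Lflat) == 0.0

    def test_depth_mask_counts(self):
        lons = np.linspace(0, 10, 11)
        lats = np.linspace(40, 50, 11)
        bathy = np.tile(np.linspace(50, 1050, 11), (11, 1))  # varies by lon
        g = build_grid((0, 10, 40, 50), 1.0, (lons, lats, bathy))
        m = depth_mask(300.0, g)
        expected = (g.bathymetry >= 300.0) & g.sea
        assert np.array_equal(m.astype(bool), expected)
        assert np.array_equal(depth_mask(0.0, g).astype(bool), g.sea)
        assert depth_mask(5000.0, g).sum() == 0  # contradictory observation
        assert np.array_equal(depth_mask(None, g).astype(bool), g.sea)


class TestUpdateStep:
    def test_flat_prior_returns_normalised_likelihood(self):
        prior = np.full((1, 4), 0.25)
        L = np.array([[1.0, 2.0, 3.0, 4.0]])
        post = update_step(prior, {"light": L})
        np.testing.assert_allclose(post, L / L.sum())

    def test_uniform_likelihoods_leave_prior(self):
        prior = np.array([[0.1, 0.2, 0.3, 0.4]])
        post = update_step(prior, {"light": np.ones((1, 4)),
                                   "sst": np.ones((1, 4))})
        np.testing.assert_allclose(post, prior)

    def test_three_cell_hand_computation(self):
        prior = np.array([[0.5, 0.3, 0.2]])
        L = np.array([[0.1, 0.1, 0.8]])
        post = update_step(prior, {"light": L})
        np.testing.assert_allclose(post, [[5 / 24, 3 / 24, 16 / 24]],
                                   atol=1e-12)

    def test_contradictory_depth_dropped_first_then_sst(self):
        prior = np.array([[0.5, 0.5]])
        zero = np.zeros((1, 2))
        good = np.array([[0.2, 0.8]])
        with pytest.warns(RuntimeWarning, match="depth"):
            post = update_step(prior, {"light": good, "depth": zero})
        np.testing.assert_allclose(post, good / good.sum())
        with pytest.warns(RuntimeWarning) as rec:
            post = update_step(prior, {"light": good, "sst": zero,
                                       "depth": zero})
        assert [str(w.message).split()[1] for w in rec] == ["depth", "sst"]

    def test_everything_contradictory_names_the_date(self):
        prior = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError, match="2014-11-02"):
            update_step(prior, {"light": np.zeros((1, 2))},
                        date="2014-11-02")


class TestRunFilter:
    def _oracle_forward(self, grid, cfg, dep, likelihood_seq):
        """Independent dense-matrix HMM forward recursion."""
        T = transition_matrix(grid, cfg, 1.0)
        f = _point_mass(grid, dep.lon, dep.lat).ravel()
        out = [f]
        for L in likelihood_seq:
            pred = T @ out[-1]
            upd = pred * L.ravel()
            out.append(upd / upd.sum())
        return out

    def test_matches_dense_forward_oracle_1d(self):
        lons = np.arange(0.25, 10, 0.5)
        lats = np.array([0.25])
        g = build_grid((0, 10, 0, 0.5), 0.5,
                       (lons, lats, np.full((1, len(lons)), 3000.0)))
        cfg = FilterConfig(D=800.0, sigma_lon=1.0, sigma_lat=3.5)
        dep = TagDeployment("t", "2014-01-01", 5.1, 0.25)
        fixes = [4.2, 6.0, 5.5, 3.9, 7.1]
        obs = pd.DataFrame({
            "date": pd.date_range("2014-01-02", periods=5),
            "light_lon": fixes, "light_lat": [0.25] * 5})
        res = run_filter(obs, g, cfg, dep)
        Ls = [light_likelihood((x, 0.25), g, cfg) for x in fixes]
        oracle = self._oracle_forward(g, cfg, dep, Ls)
        for t in range(6):
            assert np.abs(res.posteriors[t].ravel()
                          - oracle[t]).max() < 1e-10

    def test_matches_dense_forward_oracle_2d(self):
        g = flat_sea_grid((0, 5, 40, 45), 0.5)  # 100 cells
        cfg = FilterConfig(D=500.0)
        dep = TagDeployment("t", "2014-01-01", 2.4, 42.6)
        rng = np.random.default_rng(7)
        obs = pd.DataFrame({
            "date": pd.date_range("2014-01-02", periods=7),
            "light_lon": 2.5 + rng.normal(0, 1, 7),
            "light_lat": 42.5 + rng.normal(0, 1, 7)})
        res = run_filter(obs, g, cfg, dep)
        Ls = [light_likelihood((r.light_lon, r.light_lat), g, cfg)
              for r in obs.itertuples()]
        oracle = self._oracle_forward(g, cfg, dep, Ls)
        for t in range(8):
            assert np.abs(res.posteriors[t].ravel()
                          - oracle[t]).max() < 1e-10

    def test_no_observations_equals_pure_diffusion(self):
        g = flat_sea_grid((0, 10, 40, 50), 0.5)
        cfg = FilterConfig(D=1000.0)
        dep = TagDeployment("t", "2014-01-01", 5.25, 45.25)
        obs = pd.DataFrame({"date": pd.date_range("2014-01-04", periods=1)})
        res = run_filter(obs, g, cfg, dep)
        p = _point_mass(g, dep.lon, dep.lat)
        for t in range(1, 4):
            p = predict_step(p, g, cfg, 1.0)
            np.testing.assert_allclose(res.posteriors[t], p, atol=1e-12)

    def test_posteriors_are_proper_distributions(self, env, deployment):
        tr = simulate_track(deployment, "a", env, seed=3, n_days=40)
        obs = simulate_observations(tr, env, SimConfig(seed=0), seed=4)
        g = build_grid(env.extent, 1.0, env)
        res = run_filter(obs.archival, g, FilterConfig(), deployment,
                         env=env)
        sums = res.posteriors.reshape(len(res.dates), -1).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert (res.posteriors >= 0).all()
        assert res.posteriors[:, ~g.sea].sum() == 0.0

    def test_smoothing_collapses_final_day_at_popoff(self, env, deployment):
        tr = simulate_track(deployment, "a", env, seed=3, n_days=60)
        obs = simulate_observations(tr, env, SimConfig(seed=0), seed=4)
        last = tr.positions.iloc[-1]
        dep = dataclasses.replace(deployment, popoff_date=last["date"],
                                  popoff_lon=float(last["lon"]),
                                  popoff_lat=float(last["lat"]))
        g = build_grid(env.extent, 1.0, env)
        res = run_filter(obs.archival, g, FilterConfig(), dep, env=env)
        assert res.smoothed
        lon, lat = best_daily_location(res.posteriors[-1], g)
        from seatrack import haversine_km
        assert haversine_km((lon, lat),
                            (last["lon"], last["lat"])) < 120  # ~1 cell

    def test_deployment_outside_grid_rejected(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        dep = TagDeployment("t", "2014-01-01", 20.0, 45.0)
        obs = pd.DataFrame({"date": pd.date_range("2014-01-02", periods=1),
                            "light_lon": [5.0], "light_lat": [45.0]})
        with pytest.raises(ValueError, match="outside"):
            run_filter(obs, g, FilterConfig(), dep)

    def test_resolution_stability_on_smooth_case(self):
        """Doubling the grid resolution moves best daily locations by less
        than half a coarse cell."""
        dep = TagDeployment("t", "2014-01-01", 5.1, 45.1)
        obs = pd.DataFrame({
            "date": pd.date_range("2014-01-02", periods=6),
            "light_lon": np.linspace(5.0, 6.5, 6),
            "light_lat": np.linspace(45.0, 46.0, 6)})
        tracks = {}
        for res_deg in (1.0, 0.5):
            g = flat_sea_grid((0, 10, 40, 50), res_deg)
            tracks[res_deg] = run_filter(obs, g, FilterConfig(), dep).track
        d = np.hypot(tracks[1.0]["lon"] - tracks[0.5]["lon"],
                     tracks[1.0]["lat"] - tracks[0.5]["lat"])
        assert (d < 0.5).all()


class TestBestDailyLocation:
    def test_point_mass_gives_centroid(self):
        g = flat_sea_grid((0, 10, 40, 50), 1.0)
        p = _point_mass(g, 3.2, 44.9)
        lon, lat = best_daily_location(p, g)
        assert (lon, lat) == (3.5, 44.5)

    def test_weighted_mean(self):
        g = flat_sea_grid((0, 20, 40, 50), 1.0)
        p = np.zeros(g.shape)
        i, j0 = g.cell_of(0.5, 45.5)
        _, j1 = g.cell_of(10.5, 45.5)
        p[i, j0], p[i, j1] = 0.2, 0.8
        lon, lat = best_daily_location(p, g)
        assert lon == pytest.approx(0.2 * 0.5 + 0.8 * 10.5)
        assert lat == pytest.approx(45.5)


class TestEstimator:
    def test_fit_predict_and_params(self, env, deployment):
        tr = simulate_track(deployment, "a", env, seed=1, n_days=30)
        obs = simulate_observations(tr, env, SimConfig(seed=0), seed=2)
        geo = HMMGeolocator(resolution=1.0)
        assert geo.get_params()["D"] == 1000.0
        geo.set_params(D=500.0)
        geo.fit(obs.archival, env=env, deployment=deployment)
        track = geo.predict()
        assert len(track) == len(geo.dates_)
        ext = geo.grid_.extent
        assert track["lon"].between(ext[0], ext[1]).all()
        assert track["lat"].between(ext[2], ext[3]).all()

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            HMMGeolocator().predict()
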