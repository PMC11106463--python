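"""Synthetic-world generator: connectivity, covariance and Poisson contracts."""

import numpy as np
import pytest

from geosmr.errors import InvalidConfigError
from geosmr.geostat import pairwise_distances
from geosmr.synth import (
    SyntheticConfig,
    build_world,
    grid_coords,
    make_regions,
    simulate_exposure_series,
    simulate_grf,
    simulate_mortality,
)


def flood_fill_connected(cells: set) -> bool:
    """Oracle: is this set of (i, j) cells 4-connected?"""
    start = next(iter(cells))
    seen = {start}
    frontier = [start]
    while frontier:
        i, j = frontier.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (i + di, j + dj)
            if nb in cells and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return seen == cells


class TestMakeRegions:
    def test_single_cell(self):
        assert make_regions(1, 1, seed=0).tolist() == [0]

    def test_all_singletons(self):
        m = make_regions(4, 16, seed=0)
        assert sorted(m.tolist()) == list(range(16))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_partition_is_connected_and_covering(self, seed):
        side, n_regions = 10, 7
        m = make_regions(side, n_regions, seed=seed)
        assert len(m) == side * side
        assert set(m.tolist()) == set(range(n_regions))
        for rid in range(n_regions):
            cells = {(c // side, c % side) for c in np.nonzero(m == rid)[0]}
            assert cells, f"region {rid} empty"
            assert flood_fill_connected(cells), f"region {rid} disconnected"

    def test_too_many_regions_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_regions(3, 10, seed=0)


class TestSimulateGRF:
    def test_vanishing_sill_gives_zero_field(self):
        coords = grid_coords(5)
        z = simulate_grf(coords, range_=2.0, sill=1e-18, nugget=0.0, seed=0)
        assert np.all(np.abs(z) < 1e-6)

    def test_coincident_points_perfectly_correlated(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 1.0]])
        z = simulate_grf(coords, range_=2.0, sill=1.0, nugget=0.0, seed=1)
        # jitter regularization of the singular covariance allows tiny drift
        assert z[0] == pytest.approx(z[1], abs=1e-3)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_grf(grid_coords(3), range_=-1.0, sill=1.0, nugget=0.0, seed=0)

    def test_empirical_semivariance_matches_model_sill(self):
        # pooled over replicates, semivariance at lags >= range should sit
        # near the sill (within 15%): Monte-Carlo check of the stated
        # covariance model C(d) = sill * exp(-3 d / range)
        coords = grid_coords(20)
        dist = pairwise_distances(coords)
        iu, ju = np.triu_indices(len(coords), k=1)
        far = dist[iu, ju] >= 10.0
        acc = []
        for rep in range(50):
            z = simulate_grf(coords, range_=10.0, sill=1.0, nugget=0.0, seed=rep)
            acc.append(0.5 * np.mean((z[iu] - z[ju])[far] ** 2))
        assert np.mean(acc) == pytest.approx(1.0, rel=0.15)


class TestExposureSeries:
    def test_zero_noise_reproduces_base(self):
        base = np.arange(5.0)
        s = simulate_exposure_series(base, 7, temporal_sd=0.0, seed=0)
        assert np.array_equal(s, np.tile(base[:, None], (1, 7)))

    def test_single_timestep_shape(self):
        s = simulate_exposure_series(np.zeros(4), 1, temporal_sd=1.0, seed=0)
        assert s.shape == (4, 1)

    def test_temporal_std_concentrates_with_n(self):
        # chi-square bounds: sample sd of 365 N(0,1) draws in [0.85, 1.15]
        # for at least 95% of cells
        s = simulate_exposure_series(np.zeros(400), 365, temporal_sd=1.0, seed=3)
        sd = s.std(axis=1, ddof=1)
        assert np.mean((sd > 0.85) & (sd < 1.15)) >= 0.95


class TestSimulateMortality:
    def test_zero_population_means_zero_deaths(self):
        deaths = simulate_mortality(np.zeros(3), np.zeros((3, 2)), np.array([]), np.array([]), seed=0)
        assert np.array_equal(deaths, np.zeros(3, dtype=int))

    def test_known_relative_risk_poisson_mean(self):
        # E=100, one active feature at x=1 with beta=ln 2 -> Poisson mean 200
        x = np.ones((1, 1))
        means = [
            simulate_mortality(np.array([100.0]), x, np.array([np.log(2)]), np.array([0]), seed=s)[0]
            for s in range(1000)
        ]
        assert 190 <= np.mean(means) <= 210

    def test_null_betas_mean_smr_is_one(self):
        # with no planted effects the mean SMR is 1 within 3 standard errors
        rng = np.random.default_rng(7)
        expected = rng.uniform(100, 500, size=50)
        smrs = []
        for s in range(20):
            deaths = simulate_mortality(expected, np.zeros((50, 1)), np.array([]), np.array([]), seed=s)
            smrs.append(deaths / expected)
        smrs = np.concatenate(smrs)
        se = np.sqrt(np.mean(1.0 / np.repeat(expected, 20))) / np.sqrt(len(smrs))
        assert abs(np.mean(smrs) - 1.0) < 3 * se


class TestBuildWorld:
    def test_determinism(self):
        cfg = SyntheticConfig(grid_side=8, n_regions=10, n_timesteps=10, seed=5,
                              n_pollutants=2, n_features=6)
        w1, w2 = build_world(cfg), build_world(cfg)
        assert np.array_equal(w1.regions.observed_deaths, w2.regions.observed_deaths)
        assert w1.features.equals(w2.features)
        for k in w1.grid.series:
            assert np.array_equal(w1.grid.series[k], w2.grid.series[k])

    def test_feature_bookkeeping(self):
        cfg = SyntheticConfig(grid_side=8, n_regions=10, n_timesteps=5, seed=1,
                              n_features=15, active_features=(0, 1), betas=(0.2, -0.2))
        w = build_world(cfg)
        assert w.features.shape[1] == 15
        assert np.nonzero(w.true_betas)[0].tolist() == [0, 1]

    def test_world_invariants(self, small_world):
        cfg, w = small_world
        assert len(w.grid.membership) == cfg.grid_side**2
        counts = np.bincount(w.grid.membership, minlength=cfg.n_regions)
        assert counts.min() >= 1
        assert set(w.features.index) == set(w.regions.region_ids.tolist())

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_world(SyntheticConfig(n_regions=10**6))
        with pytest.raises(InvalidConfigError):
            build_world(SyntheticConfig(active_features=(0,), betas=()))
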