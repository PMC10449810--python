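import math

import numpy as np
import pytest

from emphymap.imaging_io import SlicePattern, Window2D
from emphymap.point_process import (
    CHI2_Q90_2DF, ChainSettings, SNCPDraw, SNCPPosterior, SNCPPriors, SNCPState,
    _sample_invwishart, aggregate_subject, fit_sncp_slice, sncp_log_likelihood,
    summarize_slice, SliceClusterSummary,
)
from conftest import four_cluster_pattern
from oracles import riemann_log_likelihood


def homogeneous_state(eps, k=0):
    return SNCPState(np.empty((0, 2)), np.empty(0), np.empty((0, 2, 2)), eps)


class TestLogLikelihood:
    def test_homogeneous_closed_form(self, rng):
        window = Window2D(np.ones((10, 10), bool), (1.0, 1.0))  # |W| = 100
        pts = rng.random((10, 2)) * 10
        pattern = SlicePattern(pts, window)
        ll = sncp_log_likelihood(pattern, homogeneous_state(0.5))
        assert ll == pytest.approx(10 * math.log(0.5) - 50.0, abs=1e-12)

    def test_zero_intensity_gives_minus_inf(self, rng):
        window = Window2D(np.ones((5, 5), bool), (1.0, 1.0))
        pattern = SlicePattern(rng.random((3, 2)) * 5, window)
        assert sncp_log_likelihood(pattern, homogeneous_state(0.0)) == -math.inf

    def test_matches_fine_grid_riemann_oracle(self, rng):
        for _ in range(6):
            nx, ny = rng.integers(20, 40, 2)
            grid = np.ones((nx, ny), bool)
            # non-rectangular window: carve a corner out
            grid[: nx // 3, : ny // 3] = False
            window = Window2D(grid, (1.0, 1.0))
            k = int(rng.integers(1, 4))
            extent = np.array([nx, ny], dtype=float)
            centers = rng.random((k, 2)) * extent
            sigmas = rng.uniform(2.0, 6.0, k)
            kernels = np.array([s**2 * np.eye(2) for s in sigmas])
            state = SNCPState(centers, rng.uniform(20, 80, k), kernels,
                              rng.uniform(0.001, 0.02))
            cells = window.cell_centers()
            pts = cells[rng.integers(len(cells), size=30)] + rng.random((30, 2)) - 0.5
            pts = pts[window.contains(pts)]
            pattern = SlicePattern(pts, window)
            ours = sncp_log_likelihood(pattern, state)
            oracle = riemann_log_likelihood(pattern.points, grid, (1.0, 1.0), state)
            assert ours == pytest.approx(oracle, rel=1e-3)


class TestSampler:
    def test_same_seed_bit_identical_draws(self, square_window):
        pattern = four_cluster_pattern(5, square_window)
        chain = ChainSettings(n_iter=300, burn_in=100, thin=2)
        a = fit_sncp_slice(pattern, chain=chain, seed=11)
        b = fit_sncp_slice(pattern, chain=chain, seed=11)
        assert a.n_draws == b.n_draws
        for da, db in zip(a.draws, b.draws):
            assert da.state.K == db.state.K
            np.testing.assert_array_equal(da.state.centers, db.state.centers)
            np.testing.assert_array_equal(da.state.weights, db.state.weights)
            assert da.state.epsilon == db.state.epsilon

    def test_invalid_chain_settings_error(self):
        with pytest.raises(ValueError, match="burn_in"):
            ChainSettings(n_iter=100, burn_in=100)

    def test_empty_pattern_short_circuits_flagged(self, square_window):
        pattern = SlicePattern(np.empty((0, 2)), square_window)
        post = fit_sncp_slice(pattern, seed=3)
        assert post.flagged_empty
        assert all(d.state.K == 0 for d in post.draws)
        assert all(d.state.epsilon >= 0 for d in post.draws)

    def test_prior_only_chain_recovers_poisson_k_prior(self, square_window):
        """With the likelihood held constant the K-marginal must match its
        truncated-Poisson prior (a correctness check of the birth-death
        balance)."""
        pattern = four_cluster_pattern(1, square_window)
        chain = ChainSettings(n_iter=6000, burn_in=500, thin=1, n_bd_moves=4,
                              prior_only=True)
        post = fit_sncp_slice(pattern, priors=SNCPPriors(k_rate=5.0), chain=chain,
                              seed=99)
        ks = post.k_values()
        assert ks.mean() == pytest.approx(5.0, abs=0.5)
        assert ks.var() == pytest.approx(5.0, rel=0.35)

    def test_recovers_truth_on_simulated_pattern(self, square_window):
        pattern = four_cluster_pattern(7, square_window)
        post = fit_sncp_slice(pattern, chain=ChainSettings(n_iter=1500, burn_in=600,
                                                           thin=3), seed=21)
        summ = summarize_slice(post, pattern)
        assert abs(post.k_values().mean() - 4.0) <= 1.0
        assert summ.acs == pytest.approx(150.0, rel=0.25)
        assert abs(summ.pct_diffuse - 15.0) <= 7.0

    def test_pure_noise_pattern_concentrates_on_small_k(self, square_window):
        rng = np.random.default_rng(4)
        pts = rng.random((120, 2)) * 60
        pattern = SlicePattern(pts, square_window)
        post = fit_sncp_slice(pattern, chain=ChainSettings(n_iter=1500, burn_in=600,
                                                           thin=3), seed=8)
        ks = post.k_values()
        assert np.bincount(ks).argmax() <= 1
        summ = summarize_slice(post, pattern)
        assert summ.pct_diffuse > 80.0

    def test_invwishart_sampler_mean(self, rng):
        df, scale = 7.0, np.array([[4.0, 1.0], [1.0, 3.0]])
        draws = np.mean([_sample_invwishart(rng, df, scale) for _ in range(4000)],
                        axis=0)
        np.testing.assert_allclose(draws, scale / (df - 3.0), rtol=0.1)


class TestSummaries:
    def _posterior_of(self, states_masses, window):
        chain = ChainSettings(n_iter=2, burn_in=1)
        draws = [SNCPDraw(s, m) for s, m in states_masses]
        return SNCPPosterior(draws=draws, seed=0, settings=chain, priors=SNCPPriors())

    def test_single_draw_arithmetic(self, square_window):
        # lung area of the 60x60 window is 3600 mm² = 36 cm²; scale to 150 cm²
        window = Window2D(np.ones((100, 150), bool), (1.0, 1.0))  # 15000 mm²
        pattern = SlicePattern(np.array([[5.0, 5.0]]), window)
        state = SNCPState(np.array([[50.0, 75.0]] * 3), np.array([10.0] * 3),
                          np.array([25.0 * np.eye(2)] * 3), epsilon=0.0)
        post = self._posterior_of([(state, np.ones(3))], window)
        summ = summarize_slice(post, pattern)
        assert summ.nc_rate == pytest.approx(3 / 150.0 * 100.0)  # 2 per 100 cm²
        assert summ.aca == pytest.approx(math.pi * CHI2_Q90_2DF * 25.0, rel=1e-12)
        assert summ.aca == pytest.approx(361.7, abs=0.05)

    def test_pct_diffuse_share(self, square_window):
        pattern = SlicePattern(np.array([[5.0, 5.0]]), square_window)
        # epsilon*|W| = 20 against cluster mass 80 -> 20% diffuse
        eps = 20.0 / square_window.area
        state = SNCPState(np.array([[30.0, 30.0]]), np.array([80.0]),
                          np.array([9.0 * np.eye(2)]), epsilon=eps)
        post = self._posterior_of([(state, np.ones(1))], square_window)
        assert summarize_slice(post, pattern).pct_diffuse == pytest.approx(20.0)

    def test_all_k0_draws(self, square_window):
        pattern = SlicePattern(np.array([[5.0, 5.0]]), square_window)
        state = homogeneous_state(0.01)
        post = self._posterior_of([(state, np.empty(0))] * 3, square_window)
        summ = summarize_slice(post, pattern)
        assert summ.nc_rate == 0.0
        assert np.isnan(summ.acs) and np.isnan(summ.aca)
        assert summ.pct_diffuse == 100.0

    def test_aggregate_idempotent_and_missing_rules(self):
        s1 = SliceClusterSummary(nc_rate=2.0, acs=10.0, pct_diffuse=30.0, aca=50.0,
                                 n_points=100, lung_area=1000.0, slice_index=0)
        s2 = SliceClusterSummary(nc_rate=4.0, acs=30.0, pct_diffuse=40.0, aca=70.0,
                                 n_points=80, lung_area=900.0, slice_index=1)
        s3 = SliceClusterSummary(nc_rate=0.0, acs=np.nan, pct_diffuse=np.nan,
                                 aca=np.nan, n_points=0, lung_area=800.0, slice_index=2)
        same = aggregate_subject([s1, s1])
        assert same.acs == 10.0 and same.nc_rate == 2.0
        prof = aggregate_subject([s1, s2])
        assert prof.acs == pytest.approx(20.0)
        with_missing = aggregate_subject([s1, s3])
        assert with_missing.acs == pytest.approx(10.0)   # missing slice excluded
        assert with_missing.nc_rate == pytest.approx(1.0)  # zero included
        assert with_missing.n_slices == 2

    def test_aggregate_requires_slices(self):
        with pytest.raises(ValueError):
            aggregate_subject([])
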