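"""State-array inference: grid, RBME likelihood, EM occupations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smtkit import (
    StateArray,
    StateGrid,
    classify_fractions,
    infer_occupations,
    likelihood_matrix,
    marginalize_error,
    mean_diffusion_coefficient,
    rbme_log_likelihood,
    simulate_free_tracks,
)


class TestGrid:
    def test_printed_dimensions_and_endpoints(self):
        grid = StateGrid.default()
        assert grid.shape == (100, 31)
        assert grid.diffusion[0] == 0.01 and grid.diffusion[-1] == 100.0
        assert grid.sigma[0] == 0.02 and grid.sigma[-1] == 0.08
        assert (np.diff(grid.diffusion) > 0).all()
        assert (np.diff(grid.sigma) > 0).all()

    def test_diffusion_axis_log_spaced(self):
        grid = StateGrid.default()
        ratios = grid.diffusion[1:] / grid.diffusion[:-1]
        np.testing.assert_allclose(ratios, ratios[0])


class TestRBME:
    def test_single_zero_jump_closed_form(self):
        d, sigma, dt = 1.0, 0.03, 0.01
        v = 2 * d * dt + 2 * sigma**2
        expected = -np.log(2 * np.pi * v)
        got = rbme_log_likelihood(np.array([[0.0, 0.0]]), np.array([1]), d, sigma, dt)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_rotation_invariance(self, rng):
        jumps = rng.normal(0, 0.1, size=(20, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        gaps = np.ones(20)
        a = rbme_log_likelihood(jumps, gaps, 0.5, 0.03, 0.01)
        b = rbme_log_likelihood(jumps @ rot.T, gaps, 0.5, 0.03, 0.01)
        assert a == pytest.approx(b, rel=1e-12)

    def test_variance_recovered_from_many_jumps(self):
        # 1e4 simulated jumps at D=1, sigma=0.03: the (D, sigma) grid
        # point with maximal likelihood has per-axis variance within one
        # grid cell of 2 D dt + 2 sigma^2 = 0.0218 um^2
        tracks = simulate_free_tracks([(1.0, 1.0)], 500, 21, 0.01,
                                      localization_error=0.03, seed=0)
        grid = StateGrid.default()
        log_l, counts, _ = likelihood_matrix(tracks, grid, 0.01)
        total = log_l.sum(axis=0)
        k, m = np.unravel_index(np.argmax(total), total.shape)
        v_best = 2 * grid.diffusion[k] * 0.01 + 2 * grid.sigma[m] ** 2
        v_true = 2 * 1.0 * 0.01 + 2 * 0.03**2
        v_neighbors = [
            2 * grid.diffusion[min(k + 1, 99)] * 0.01 + 2 * grid.sigma[m] ** 2,
            2 * grid.diffusion[max(k - 1, 0)] * 0.01 + 2 * grid.sigma[m] ** 2,
        ]
        cell = max(abs(v - v_best) for v in v_neighbors)
        assert abs(v_best - v_true) <= cell

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rbme_log_likelihood(np.zeros((1, 2)), np.array([1]), -1.0, 0.03, 0.01)


class TestLikelihoodMatrix:
    def _track(self, tid=0):
        return pd.DataFrame(
            {
                "trajectory_id": tid,
                "frame": [0, 1, 2],
                "x_um": [0.0, 0.1, 0.15],
                "y_um": [0.0, -0.05, 0.02],
            }
        )

    def test_shape_matches_grid(self):
        log_l, counts, _ = likelihood_matrix(self._track(), StateGrid.default(), 0.01)
        assert log_l.shape == (1, 100, 31)
        assert counts.tolist() == [2]
        assert np.isfinite(log_l).all()

    def test_duplicated_trajectory_gives_identical_rows(self):
        df = pd.concat([self._track(0), self._track(1)], ignore_index=True)
        log_l, _, _ = likelihood_matrix(df, StateGrid.default(), 0.01)
        np.testing.assert_array_equal(log_l[0], log_l[1])

    def test_matches_per_trajectory_loop_oracle(self):
        grid = StateGrid.default(n_diffusion=7, n_sigma=4)
        df = pd.concat(
            [self._track(0), self._track(1).assign(x_um=[0.0, 0.4, 0.9])],
            ignore_index=True,
        )
        log_l, _, tids = likelihood_matrix(df, grid, 0.01)
        for t, tid in enumerate(tids):
            g = df[df["trajectory_id"] == tid].sort_values("frame")
            jumps = np.c_[np.diff(g["x_um"]), np.diff(g["y_um"])]
            gaps = np.diff(g["frame"])
            for k, d in enumerate(grid.diffusion):
                for m, s in enumerate(grid.sigma):
                    expected = rbme_log_likelihood(jumps, gaps, d, s, 0.01)
                    assert log_l[t, k, m] == pytest.approx(expected, rel=1e-9)

    def test_no_jumps_yields_empty_no_data_result(self):
        df = pd.DataFrame(
            {"trajectory_id": [0], "frame": [0], "x_um": [0.0], "y_um": [0.0]}
        )
        log_l, counts, tids = likelihood_matrix(df, StateGrid.default(), 0.01)
        assert log_l.shape[0] == 0 and len(counts) == 0


class TestOccupations:
    def test_uniform_likelihood_is_em_fixed_point(self):
        grid = StateGrid.default(n_diffusion=10, n_sigma=3)
        log_l = np.zeros((5, 10, 3))
        post = infer_occupations(log_l, np.array([3, 3, 3, 3, 3]), grid)
        np.testing.assert_allclose(post.occupations, 1.0 / 30, atol=1e-12)

    def test_mass_normalized(self):
        tracks = simulate_free_tracks([(0.5, 1.0)], 50, 6, 0.01, 0.03, seed=1)
        sa = StateArray().fit(tracks)
        assert sa.posterior_.occupations.sum() == pytest.approx(1.0, abs=1e-9)
        assert sa.posterior_.occupations.min() >= 0

    def test_single_state_mass_concentrates_near_true_d(self):
        tracks = simulate_free_tracks([(0.05, 1.0)], 500, 16, 0.01, 0.03, seed=3)
        sa = StateArray().fit(tracks)
        grid_d = sa.grid_.diffusion
        idx = int(np.argmin(np.abs(np.log(grid_d) - np.log(0.05))))
        window = sa.marginal_[max(idx - 1, 0) : idx + 2].sum()
        assert window >= 0.8

    def test_two_state_bound_occupancy_recovered(self):
        tracks = simulate_free_tracks(
            [(0.05, 0.3), (5.0, 0.7)], 1000, 8, 0.01, 0.03, seed=7
        )
        sa = StateArray().fit(tracks)
        assert sa.bound_fraction_ == pytest.approx(0.30, abs=0.05)

    def test_bound_fraction_monotone_in_simulated_occupancy(self):
        fractions = []
        for occ in (0.1, 0.3, 0.6):
            tracks = simulate_free_tracks(
                [(0.05, occ), (5.0, 1 - occ)], 400, 8, 0.01, 0.03, seed=11
            )
            fractions.append(StateArray().fit(tracks).bound_fraction_)
        assert fractions[0] < fractions[1] < fractions[2]


class TestMarginalAndFractions:
    def test_marginal_is_axis_sum(self, rng):
        occ = rng.uniform(size=(100, 31))
        occ /= occ.sum()
        np.testing.assert_array_equal(marginalize_error(occ), occ.sum(axis=1))
        assert marginalize_error(occ).sum() == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_marginal_is_indicator(self):
        occ = np.zeros((100, 31))
        occ[42, 7] = 1.0
        marginal = marginalize_error(occ)
        assert marginal[42] == 1.0 and marginal.sum() == 1.0

    def test_all_mass_at_lowest_d_is_fully_bound(self):
        grid = StateGrid.default()
        marginal = np.zeros(100)
        marginal[0] = 1.0
        bound, slow, fast = classify_fractions(marginal, grid.diffusion)
        assert (bound, slow, fast) == (1.0, 0.0, 0.0)

    def test_uniform_marginal_fractions_are_band_counts(self):
        grid = StateGrid.default()
        marginal = np.full(100, 0.01)
        bound, slow, fast = classify_fractions(marginal, grid.diffusion)
        assert bound == pytest.approx((grid.diffusion <= 0.1).sum() / 100)
        assert fast == pytest.approx((grid.diffusion >= 1.0).sum() / 100)
        assert bound + slow + fast == pytest.approx(1.0)

    def test_bad_thresholds_rejected(self):
        grid = StateGrid.default()
        with pytest.raises(ValueError):
            classify_fractions(np.full(100, 0.01), grid.diffusion, 2.0, 1.0)

    @given(st.integers(0, 99))
    @settings(max_examples=20, deadline=None)
    def test_mean_of_indicator_is_grid_value(self, k):
        grid = StateGrid.default()
        marginal = np.zeros(100)
        marginal[k] = 1.0
        assert mean_diffusion_coefficient(marginal, grid.diffusion) == pytest.approx(
            grid.diffusion[k]
        )

    def test_mean_of_two_extreme_deltas(self):
        grid = StateGrid.default()
        marginal = np.zeros(100)
        marginal[0] = marginal[-1] = 0.5
        assert mean_diffusion_coefficient(marginal, grid.diffusion) == pytest.approx(
            50.005
        )

    def test_single_state_mean_within_twenty_percent(self):
        tracks = simulate_free_tracks([(1.0, 1.0)], 500, 8, 0.01, 0.03, seed=5)
        sa = StateArray().fit(tracks)
        assert sa.mean_diffusion_ == pytest.approx(1.0, rel=0.2)


def test_state_array_histogram_plot_smoke():
    import matplotlib

    matplotlib.use("Agg")
    from smtkit.plotting import plot_state_array

    grid = StateGrid.default()
    marginal = np.full(100, 0.01)
    ax = plot_state_array(marginal, grid.diffusion, label="FOV 0")
    assert ax.get_xscale() == "log"
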