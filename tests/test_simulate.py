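"""Synthetic-movie generator: motion statistics, rendering, conditions."""

import numpy as np
import pytest

from smtkit import (
    ConditionEffect,
    SimulationConfig,
    make_condition_pair,
    render_movie,
    simulate_fov,
    simulate_nuclei,
    simulate_trajectories,
)
from smtkit.localize import fit_spot, integrated_gaussian_profile
from smtkit.simulate import GroundTruth, NucleusPlacementError, rasterize_nuclei


def _single_state_config(**kw):
    base = dict(
        n_frames=50,
        image_shape=(400, 400),
        n_nuclei=1,
        nucleus_radius_um=15.0,
        states=(dict(diffusion_coefficient=1.0, occupancy=1.0),),
        emitter_density=0.3,
        bleach_survival=1.0,
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_occupancies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                states=(
                    dict(diffusion_coefficient=1.0, occupancy=0.5),
                    dict(diffusion_coefficient=2.0, occupancy=0.4),
                )
            )

    def test_pulse_must_be_shorter_than_frame(self):
        with pytest.raises(ValueError):
            SimulationConfig(frame_interval=1e-4, pulse_width=1e-3)


class TestNuclei:
    def test_zero_nuclei_gives_background_only(self):
        cfg = SimulationConfig(n_nuclei=0, image_shape=(64, 64))
        mask, stain, nuclei = simulate_nuclei(cfg)
        assert mask.max() == 0 and nuclei == []

    def test_two_nuclei_have_labels_one_and_two(self):
        cfg = SimulationConfig(n_nuclei=2, image_shape=(256, 256), seed=4)
        mask, _, _ = simulate_nuclei(cfg)
        assert set(np.unique(mask)) == {0, 1, 2}

    def test_impossible_placement_raises(self):
        cfg = SimulationConfig(n_nuclei=10, image_shape=(64, 64))
        with pytest.raises(NucleusPlacementError):
            simulate_nuclei(cfg)


class TestMotion:
    def test_zero_diffusion_keeps_positions_constant(self):
        cfg = _single_state_config(
            states=(dict(diffusion_coefficient=1e-12, occupancy=1.0),)
        )
        truth = simulate_trajectories(cfg)
        for e in range(truth.n_emitters):
            alive = truth.alive[e]
            pos = truth.positions[e, alive]
            assert np.ptp(pos, axis=0).max() < 1e-4

    def test_squared_displacement_matches_two_d_dt(self):
        # closed form: per-axis jump variance over dt is 2*D*dt
        cfg = _single_state_config(n_frames=101)
        truth = simulate_trajectories(cfg)
        jumps = np.diff(truth.positions, axis=1).reshape(-1, 2)
        jumps = jumps[np.isfinite(jumps).all(axis=1)]
        assert len(jumps) >= 10_000
        expected = 2 * 1.0 * cfg.frame_interval  # 0.02 um^2
        for axis in range(2):
            sample = jumps[:, axis] ** 2
            se = sample.std() / np.sqrt(len(sample))
            assert abs(sample.mean() - expected) < 3 * se

    def test_two_state_occupancy_binomial(self):
        cfg = _single_state_config(
            states=(
                dict(diffusion_coefficient=0.05, occupancy=0.3),
                dict(diffusion_coefficient=5.0, occupancy=0.7),
            ),
            emitter_density=1.0,
        )
        truth = simulate_trajectories(cfg)
        n = truth.n_emitters
        frac = (truth.states[:, 0] == 0).mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_positions_remain_inside_nucleus(self):
        cfg = _single_state_config(
            states=(dict(diffusion_coefficient=10.0, occupancy=1.0),)
        )
        truth = simulate_trajectories(cfg)
        nucleus = truth.nuclei[0]
        px = cfg.pixel_size
        for e in range(truth.n_emitters):
            pos = truth.positions[e][truth.alive[e]]
            u = ((pos[:, 0] / px - nucleus.col) / nucleus.a_col) ** 2 + (
                (pos[:, 1] / px - nucleus.row) / nucleus.a_row
            ) ** 2
            assert (u <= 1.0 + 1e-9).all()

    def test_bleached_emitters_stay_dark(self):
        cfg = _single_state_config(bleach_survival=0.8, n_frames=80)
        truth = simulate_trajectories(cfg)
        for e in range(truth.n_emitters):
            alive = truth.alive[e].astype(int)
            assert (np.diff(alive) <= 0).all()  # once off, never back on

    def test_fixed_seed_reproducible(self):
        cfg = _single_state_config()
        a = simulate_trajectories(cfg)
        b = simulate_trajectories(cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(a.positions), np.nan_to_num(b.positions)
        )
        np.testing.assert_array_equal(a.states, b.states)


class TestRendering:
    def _static_truth(self, cfg, x_um, y_um):
        positions = np.full((1, cfg.n_frames, 2), np.nan)
        positions[0, :, 0] = x_um
        positions[0, :, 1] = y_um
        return GroundTruth(
            positions=positions,
            states=np.zeros((1, cfg.n_frames), dtype=np.int64),
            alive=np.ones((1, cfg.n_frames), dtype=bool),
            nucleus_label=np.array([1]),
            nuclei=[],
            config=cfg,
        )

    def test_zero_photons_is_background_only(self):
        cfg = SimulationConfig(
            n_frames=5, image_shape=(48, 48), photons_per_spot=0.0, seed=8
        )
        truth = self._static_truth(cfg, 24 * cfg.pixel_size, 24 * cfg.pixel_size)
        movie = render_movie(truth, cfg)
        assert abs(movie.mean() - cfg.background) < 1.0

    def test_noise_free_render_is_symmetric_integrated_gaussian(self):
        cfg = SimulationConfig(
            n_frames=1, image_shape=(33, 33), photons_per_spot=1000.0,
            background=100.0, read_noise_sd=0.0, shot_noise=False, seed=0,
        )
        truth = self._static_truth(cfg, 16 * cfg.pixel_size, 16 * cfg.pixel_size)
        frame = render_movie(truth, cfg)[0].astype(float)
        np.testing.assert_array_equal(frame, frame[::-1, :])
        np.testing.assert_array_equal(frame, frame[:, ::-1])
        dx = integrated_gaussian_profile(np.arange(33), 16.0, 1.5)
        expected = 100.0 + 1000.0 * np.outer(dx, dx)
        assert np.abs(frame - np.round(expected)).max() <= 1.0

    def test_spot_photometry_conserves_photons(self):
        cfg = SimulationConfig(
            n_frames=1, image_shape=(33, 33), photons_per_spot=2000.0,
            background=100.0, read_noise_sd=0.0, shot_noise=False, seed=0,
        )
        truth = self._static_truth(cfg, 16.3 * cfg.pixel_size, 15.8 * cfg.pixel_size)
        frame = render_movie(truth, cfg)[0].astype(float)
        assert (frame - 100.0).sum() == pytest.approx(2000.0, rel=0.01)

    def test_rendered_spot_recovered_by_fit(self):
        cfg = SimulationConfig(
            n_frames=1, image_shape=(33, 33), photons_per_spot=2000.0,
            background=100.0, read_noise_sd=0.0, shot_noise=False, seed=0,
        )
        x_px, y_px = 16.31, 15.77
        truth = self._static_truth(cfg, x_px * cfg.pixel_size, y_px * cfg.pixel_size)
        frame = render_movie(truth, cfg)[0].astype(float)
        tile = frame[11:22, 11:22]
        fit = fit_spot(tile)
        assert abs(11 + fit.x0 - x_px) < 0.05
        assert abs(11 + fit.y0 - y_px) < 0.05

    def test_emitter_outside_image_is_clipped_silently(self):
        cfg = SimulationConfig(n_frames=1, image_shape=(32, 32), seed=0,
                               shot_noise=False, read_noise_sd=0.0)
        truth = self._static_truth(cfg, -5 * cfg.pixel_size, -5 * cfg.pixel_size)
        movie = render_movie(truth, cfg)
        assert movie.shape == (1, 32, 32)

    def test_movie_reproducible_for_fixed_seed(self):
        cfg = SimulationConfig(n_frames=5, image_shape=(128, 128), n_nuclei=1, seed=17)
        np.testing.assert_array_equal(simulate_fov(cfg).movie, simulate_fov(cfg).movie)


class TestConditionPair:
    def _config(self, seed=31):
        return SimulationConfig(
            n_frames=10, image_shape=(256, 256), n_nuclei=3, seed=seed,
            states=(
                dict(diffusion_coefficient=0.05, occupancy=0.2),
                dict(diffusion_coefficient=5.0, occupancy=0.8),
            ),
        )

    def test_identity_effect_preserves_everything(self):
        pair = make_condition_pair(self._config(), ConditionEffect())
        assert pair.treated.config.states == pair.control.config.states
        np.testing.assert_array_equal(
            pair.control.truth.states, pair.treated.truth.states
        )

    def test_bound_occupancy_set_by_construction(self):
        pair = make_condition_pair(
            self._config(), ConditionEffect(bound_occupancy=0.5)
        )
        occs = [s.occupancy for s in pair.treated.config.states]
        assert occs[0] == pytest.approx(0.5)
        assert sum(occs) == pytest.approx(1.0)

    def test_density_multiplier_thins_emitters(self):
        counts_c, counts_t = 0, 0
        for seed in range(40, 48):
            pair = make_condition_pair(
                self._config(seed), ConditionEffect(density_multiplier=0.5)
            )
            counts_c += pair.control.truth.n_emitters
            counts_t += pair.treated.truth.n_emitters
        assert counts_t < counts_c
        se = np.sqrt(counts_c * 0.5 * 0.5)
        assert abs(counts_t - 0.5 * counts_c) < 4 * se

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            ConditionEffect(bound_occupancy=1.4)

    def test_treated_bound_set_contains_control_bound_set(self):
        # common random numbers: raising the bound occupancy can only
        # recruit emitters into the bound state, never lose them
        pair = make_condition_pair(
            self._config(), ConditionEffect(bound_occupancy=0.5)
        )
        control_bound = set(
            map(tuple, np.round(pair.control.truth.positions[
                pair.control.truth.states[:, 0] == 0, 0], 6))
        )
        treated_bound = set(
            map(tuple, np.round(pair.treated.truth.positions[
                pair.treated.truth.states[:, 0] == 0, 0], 6))
        )
        assert control_bound <= treated_bound


def test_rasterized_labels_match_request():
    cfg = SimulationConfig(n_nuclei=3, image_shape=(256, 256), seed=9)
    mask, _, nuclei = simulate_nuclei(cfg)
    assert rasterize_nuclei(nuclei, cfg.image_shape).max() == 3
    assert set(np.unique(mask)) == {0, 1, 2, 3}
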