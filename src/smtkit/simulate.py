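"""Ground-truthed synthetic SMT movie generator.

Emulates sparse fluorescent emitters undergoing multi-state 2-D Brownian
motion inside nucleus-shaped regions, imaged stroboscopically as
diffraction-limited integrated-Gaussian spots on a noisy camera
background, with photobleaching.  Every downstream analysis stage
(detection, localization, linking, segmentation, state inference) can be
validated against the ground truth this module records.

Coordinate conventions
----------------------
Pixel ``(i, j)`` covers the unit square centred on integer coordinates
``(i, j)`` (row = y, col = x).  Continuous positions are kept in
micrometres; ``x_um = col * pixel_size``, ``y_um = row * pixel_size``.
The excitation pulse (407 us) is short relative to the frame interval
(10 ms), so positions are sampled at the pulse midpoint and no motion
blur is rendered: even at D = 5 um^2/s the within-pulse RMS displacement
is below 0.07 px.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ConditionEffect, SimulationConfig, StateSpec
from .localize import integrated_gaussian_profile


class NucleusPlacementError(RuntimeError):
    """Raised when the requested nuclei cannot be placed without overlap."""


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned elliptical nucleus in pixel coordinates."""

    row: float
    col: float
    a_row: float  # semi-axis along rows, px
    a_col: float  # semi-axis along cols, px
    label: int

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return ((row - self.row) / self.a_row) ** 2 + (
            (col - self.col) / self.a_col
        ) ** 2 <= 1.0


@dataclass
class GroundTruth:
    """Per-emitter, per-frame truth for one simulated field of view.

    ``positions`` has shape (n_emitters, n_frames, 2) storing (x_um, y_um);
    entries after photobleaching are NaN.  ``states`` indexes into
    ``config.states``; ``alive`` flags frames in which the emitter emits.
    """

    positions: np.ndarray
    states: np.ndarray
    alive: np.ndarray
    nucleus_label: np.ndarray
    nuclei: List[Ellipse]
    config: SimulationConfig

    @property
    def n_emitters(self) -> int:
        return self.positions.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per alive emitter-frame."""
        rows = []
        for e in range(self.n_emitters):
            frames = np.nonzero(self.alive[e])[0]
            if frames.size == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "emitter_id": e,
                        "frame": frames,
                        "x_um": self.positions[e, frames, 0],
                        "y_um": self.positions[e, frames, 1],
                        "state": self.states[e, frames],
                        "nucleus_label": self.nucleus_label[e],
                        "alive": True,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["emitter_id", "frame", "x_um", "y_um", "state", "nucleus_label", "alive"]
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class SimulatedFOV:
    """One simulated field of view: tracking movie, nuclear stain, truth."""

    movie: np.ndarray
    hoechst: np.ndarray
    label_mask: np.ndarray
    truth: GroundTruth
    config: SimulationConfig


@dataclass
class ConditionPair:
    control: SimulatedFOV
    treated: SimulatedFOV


# ---------------------------------------------------------------------------
# nuclei


def _place_nuclei(config: SimulationConfig, rng: np.random.Generator) -> List[Ellipse]:
    rows, cols = config.image_shape
    mean_r_px = config.nucleus_radius_um / config.pixel_size
    nuclei: List[Ellipse] = []
    for label in range(1, config.n_nuclei + 1):
        for _ in range(1000):  # bounded retries
            a_row = mean_r_px * rng.uniform(0.9, 1.1)
            a_col = mean_r_px * rng.uniform(0.9, 1.1)
            r = rng.uniform(a_row + 2, rows - a_row - 2) if rows > 2 * (a_row + 2) else rows / 2
            c = rng.uniform(a_col + 2, cols - a_col - 2) if cols > 2 * (a_col + 2) else cols / 2
            cand = Ellipse(r, c, a_row, a_col, label)
            # non-overlap with a small margin
            ok = all(
                np.hypot(cand.row - n.row, cand.col - n.col)
                > (max(cand.a_row, cand.a_col) + max(n.a_row, n.a_col) + 2)
                for n in nuclei
            )
            if ok:
                nuclei.append(cand)
                break
        else:
            raise NucleusPlacementError(
                f"could not place nucleus {label} of {config.n_nuclei} without overlap"
            )
    return nuclei


def rasterize_nuclei(nuclei: Sequence[Ellipse], image_shape: Tuple[int, int]) -> np.ndarray:
    """Label mask (uint16) for a set of elliptical nuclei; 0 = background."""
    mask = np.zeros(image_shape, dtype=np.uint16)
    rr, cc = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    for n in nuclei:
        mask[n.contains(rr, cc)] = n.label
    return mask


def simulate_nuclei(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, np.ndarray, List[Ellipse]]:
    """Generate a nuclear label mask and a matching Hoechst-like image.

    Returns ``(label_mask, hoechst_image, nuclei)``.  The stain image is
    bright inside nuclei, Gaussian-blurred, with Poisson-like noise — a
    stand-in for the nuclear-stain channel used for segmentation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nuclei = _place_nuclei(config, rng) if config.n_nuclei > 0 else []
    mask = rasterize_nuclei(nuclei, config.image_shape)
    stain = np.full(config.image_shape, 100.0)
    stain[mask > 0] += 900.0
    stain = ndimage.gaussian_filter(stain, sigma=2.0)
    stain = stain + rng.normal(0.0, np.sqrt(np.maximum(stain, 1.0)))
    return mask, np.clip(stain, 0, 65535).astype(np.uint16), nuclei


# ---------------------------------------------------------------------------
# motion


def _reflect_into_ellipse(pos_px: np.ndarray, nucleus: Ellipse) -> np.ndarray:
    """Radial reflection in ellipse-normalized coordinates.

    Maps a point at normalized radius ``u > 1`` to radius ``2 - u``
    (iterated if needed).  Exact reflection for circles; a controlled
    approximation for moderately eccentric ellipses.
    """
    u = np.array(
        [(pos_px[0] - nucleus.col) / nucleus.a_col, (pos_px[1] - nucleus.row) / nucleus.a_row]
    )
    r = float(np.hypot(*u))
    while r > 1.0:
        r_new = abs(2.0 - r)
        if r > 0:
            u = u * (r_new / r)
        r = r_new
        if r == 0:
            break
    return np.array(
        [nucleus.col + u[0] * nucleus.a_col, nucleus.row + u[1] * nucleus.a_row]
    )


def _sample_in_ellipse(nucleus: Ellipse, rng: np.random.Generator) -> np.ndarray:
    """Uniform point inside an ellipse, in px (col, row) order."""
    theta = rng.uniform(0, 2 * np.pi)
    r = np.sqrt(rng.uniform())
    return np.array(
        [nucleus.col + r * np.cos(theta) * nucleus.a_col, nucleus.row + r * np.sin(theta) * nucleus.a_row]
    )


def simulate_trajectories(
    config: SimulationConfig,
    nuclei: Optional[Sequence[Ellipse]] = None,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Simulate multi-state Brownian emitters inside nuclei.

    Per-axis displacement of a state-s emitter over ``dt`` is Gaussian
    with mean 0 and variance ``2 * D_s * dt``.  Emitters reflect at the
    nucleus boundary and stop emitting after photobleaching (geometric
    survival with per-frame probability ``bleach_survival``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if nuclei is None:
        nuclei = _place_nuclei(config, rng) if config.n_nuclei > 0 else []

    d_values = np.array([s.diffusion_coefficient for s in config.states])
    occ = np.array([s.occupancy for s in config.states])
    px = config.pixel_size
    dt = config.frame_interval
    nf = config.n_frames

    emitters: List[Tuple[Ellipse, np.ndarray]] = []
    for nucleus in nuclei:
        area_um2 = np.pi * nucleus.a_row * nucleus.a_col * px * px
        n_emit = rng.poisson(config.emitter_density * area_um2)
        for _ in range(n_emit):
            emitters.append((nucleus, _sample_in_ellipse(nucleus, rng)))

    n = len(emitters)
    positions = np.full((n, nf, 2), np.nan)
    states = np.zeros((n, nf), dtype=np.int64)
    alive = np.zeros((n, nf), dtype=bool)
    labels = np.zeros(n, dtype=np.int64)

    for e, (nucleus, start_px) in enumerate(emitters):
        labels[e] = nucleus.label
        state = int(rng.choice(len(d_values), p=occ))
        pos = start_px.copy()  # (col, row) px
        survives = True  # not yet photobleached
        emitting = True  # blinking dark state (off by default)
        for t in range(nf):
            if config.switching > 0 and t > 0 and rng.uniform() < config.switching:
                state = int(rng.choice(len(d_values), p=occ))
            states[e, t] = state
            alive[e, t] = survives and emitting
            positions[e, t] = pos * px if alive[e, t] else np.nan  # (x_um, y_um)
            if t < nf - 1:
                step_px = rng.normal(0.0, np.sqrt(2 * d_values[state] * dt) / px, size=2)
                pos = _reflect_into_ellipse(pos + step_px, nucleus)
                if survives and rng.uniform() > config.bleach_survival:
                    survives = False
                if config.blink_off_prob > 0 or config.blink_on_prob > 0:
                    flip = config.blink_off_prob if emitting else config.blink_on_prob
                    if rng.uniform() < flip:
                        emitting = not emitting
    return GroundTruth(positions, states, alive, labels, list(nuclei), config)


def simulate_free_tracks(
    states: Sequence[Tuple[float, float]],
    n_tracks: int,
    track_length: int,
    dt: float,
    localization_error: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Unconfined multi-state Brownian trajectories, long format.

    ``states`` is a sequence of ``(D um^2/s, occupancy)`` pairs; each
    track keeps one state for its whole length (static-state mixture).
    ``localization_error`` (um, 1-D RMSD) is added as i.i.d. Gaussian
    noise per coordinate.  Returns columns trajectory_id, frame, x_um,
    y_um, true_state.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    d = np.array([s[0] for s in states])
    occ = np.array([s[1] for s in states])
    occ = occ / occ.sum()
    labels = rng.choice(len(d), size=n_tracks, p=occ)
    steps = rng.normal(
        0.0, 1.0, size=(n_tracks, track_length - 1, 2)
    ) * np.sqrt(2 * d[labels] * dt)[:, None, None]
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    if localization_error > 0:
        pos = pos + rng.normal(0.0, localization_error, size=pos.shape)
    frames = np.tile(np.arange(track_length), n_tracks)
    return pd.DataFrame(
        {
            "trajectory_id": np.repeat(np.arange(n_tracks), track_length),
            "frame": frames,
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
            "true_state": np.repeat(labels, track_length),
        }
    )


# ---------------------------------------------------------------------------
# rendering


def render_movie(
    truth: GroundTruth,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a ground truth into a 16-bit movie stack.

    Each alive emitter deposits ``photons_per_spot`` distributed over the
    integrated-Gaussian point-spread function at its position; shot noise
    is Poisson on signal + background and read noise is additive
    Gaussian.  Emitters outside the image are silently clipped.
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows, cols = config.image_shape
    nf = config.n_frames
    half = int(np.ceil(4 * config.psf_sigma))
    movie = np.empty((nf, rows, cols), dtype=np.uint16)
    for t in range(nf):
        frame = np.full((rows, cols), float(config.background))
        for e in range(truth.n_emitters):
            if not truth.alive[e, t]:
                continue
            x_px = truth.positions[e, t, 0] / config.pixel_size
            y_px = truth.positions[e, t, 1] / config.pixel_size
            r0 = int(np.round(y_px))
            c0 = int(np.round(x_px))
            rlo, rhi = max(0, r0 - half), min(rows, r0 + half + 1)
            clo, chi = max(0, c0 - half), min(cols, c0 + half + 1)
            if rlo >= rhi or clo >= chi:
                continue  # emitter (or its support) off the image
            dx = integrated_gaussian_profile(np.arange(clo, chi), x_px, config.psf_sigma)
            dy = integrated_gaussian_profile(np.arange(rlo, rhi), y_px, config.psf_sigma)
            frame[rlo:rhi, clo:chi] += config.photons_per_spot * np.outer(dy, dx)
        if config.shot_noise:
            frame = rng.poisson(np.maximum(frame, 0)).astype(float)
        if config.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, config.read_noise_sd, size=frame.shape)
        movie[t] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)
    return movie


def simulate_fov(config: SimulationConfig) -> SimulatedFOV:
    """Simulate one field of view end to end (nuclei, motion, rendering).

    Uses independent child streams of ``config.seed`` for geometry,
    motion and camera noise, so the result is bit-reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geo, rng_motion, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    mask, hoechst, nuclei = simulate_nuclei(config, rng_geo)
    truth = simulate_trajectories(config, nuclei, rng_motion)
    movie = render_movie(truth, config, rng_noise)
    return SimulatedFOV(movie, hoechst, mask, truth, config)


def apply_effect(config: SimulationConfig, effect: ConditionEffect) -> SimulationConfig:
    """Derive the treated-condition config from a control config."""
    updates = {}
    if effect.bound_occupancy is not None:
        states = list(config.states)
        if not states:
            raise ValueError("config has no states")
        rest = [s.occupancy for s in states[1:]]
        rest_total = sum(rest)
        new_states = [
            StateSpec(
                diffusion_coefficient=states[0].diffusion_coefficient,
                occupancy=effect.bound_occupancy,
            )
        ]
        leftover = 1.0 - effect.bound_occupancy
        for s in states[1:]:
            share = s.occupancy / rest_total if rest_total > 0 else 1.0 / max(len(rest), 1)
            new_states.append(
                StateSpec(diffusion_coefficient=s.diffusion_coefficient, occupancy=leftover * share)
            )
        updates["states"] = tuple(new_states)
    updates["emitter_density"] = config.emitter_density * effect.density_multiplier
    return config.model_copy(update=updates)


def _realize_condition(
    config: SimulationConfig,
    nuclei: Sequence[Ellipse],
    base: List[Tuple[Ellipse, np.ndarray, float, float, int]],
    keep_fraction: float,
    noise_seed: int,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render one condition from the shared emitter base.

    ``base`` rows are (nucleus, start position px, keep uniform, state
    uniform, per-emitter seed).  An emitter is present when its keep
    uniform falls below ``keep_fraction``; its state comes from the
    shared state uniform through this condition's occupancy thresholds;
    its Brownian steps reuse the per-emitter seed.  Conditions therefore
    differ only through occupancies and density.
    """
    d_values = np.array([s.diffusion_coefficient for s in config.states])
    cum_occ = np.cumsum([s.occupancy for s in config.states])
    px = config.pixel_size
    dt = config.frame_interval
    nf = config.n_frames
    kept = [row for row in base if row[2] < keep_fraction]
    n = len(kept)
    positions = np.full((n, nf, 2), np.nan)
    states = np.zeros((n, nf), dtype=np.int64)
    alive = np.zeros((n, nf), dtype=bool)
    labels = np.zeros(n, dtype=np.int64)
    for e, (nucleus, start_px, _, u_state, emitter_seed) in enumerate(kept):
        labels[e] = nucleus.label
        state = int(np.searchsorted(cum_occ, u_state))
        state = min(state, len(d_values) - 1)
        erng = np.random.default_rng(emitter_seed)
        normals = erng.normal(size=(nf - 1, 2))
        bleach_u = erng.uniform(size=nf - 1)
        step_sd_px = np.sqrt(2 * d_values[state] * dt) / px
        pos = start_px.copy()
        is_alive = True
        for t in range(nf):
            states[e, t] = state
            alive[e, t] = is_alive
            positions[e, t] = pos * px if is_alive else np.nan
            if t < nf - 1:
                pos = _reflect_into_ellipse(pos + normals[t] * step_sd_px, nucleus)
                if is_alive and bleach_u[t] > config.bleach_survival:
                    is_alive = False
    truth = GroundTruth(positions, states, alive, labels, list(nuclei), config)
    movie = render_movie(truth, config, np.random.default_rng(noise_seed))
    return movie, truth


def make_condition_pair(config: SimulationConfig, effect: ConditionEffect) -> ConditionPair:
    """Simulate a control/treated FOV pair differing only in the effect.

    Both conditions share the nucleus geometry, the candidate emitter
    set, the state-assignment uniforms and the per-emitter motion noise
    (common random numbers); the treatment enters only through the
    occupancy shift and a binomial thinning (or super-sampling) of the
    emitter set by the density multiplier.  Observed differences are
    therefore attributable to the effect, not to seed choice.
    """
    treated_cfg = apply_effect(config, effect)
    ss = np.random.SeedSequence(config.seed)
    s_geo, s_emit, s_noise_c, s_noise_t = ss.spawn(4)
    rng_geo = np.random.default_rng(s_geo)
    mask, hoechst, nuclei = simulate_nuclei(config, rng_geo)

    base_density = max(config.emitter_density, treated_cfg.emitter_density)
    rng_emit = np.random.default_rng(s_emit)
    base: List[Tuple[Ellipse, np.ndarray, float, float, int]] = []
    for nucleus in nuclei:
        area_um2 = np.pi * nucleus.a_row * nucleus.a_col * config.pixel_size**2
        n_base = rng_emit.poisson(base_density * area_um2)
        for _ in range(n_base):
            base.append(
                (
                    nucleus,
                    _sample_in_ellipse(nucleus, rng_emit),
                    float(rng_emit.uniform()),
                    float(rng_emit.uniform()),
                    int(rng_emit.integers(0, 2**31 - 1)),
                )
            )
    keep_c = config.emitter_density / base_density if base_density > 0 else 0.0
    keep_t = treated_cfg.emitter_density / base_density if base_density > 0 else 0.0
    noise_c = int(np.random.default_rng(s_noise_c).integers(0, 2**31 - 1))
    noise_t = int(np.random.default_rng(s_noise_t).integers(0, 2**31 - 1))
    movie_c, truth_c = _realize_condition(config, nuclei, base, keep_c, noise_c)
    movie_t, truth_t = _realize_condition(treated_cfg, nuclei, base, keep_t, noise_t)
    return ConditionPair(
        control=SimulatedFOV(movie_c, hoechst, mask, truth_c, config),
        treated=SimulatedFOV(movie_t, hoechst, mask, truth_t, treated_cfg),
    )
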