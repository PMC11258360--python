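"""Configuration models for the simulator and the analysis pipeline.

All physical quantities carry explicit units in their field descriptions:
lengths in micrometres (um) unless the name says pixels (px), times in
seconds, diffusion coefficients in um^2/s.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

from pydantic import BaseModel, Field, model_validator

#: Default pixel size, um/px, derived from the camera field of view
#: (187.14 um across 1728 px).
DEFAULT_PIXEL_SIZE = 187.14 / 1728  # ~0.1083 um/px


class StateSpec(BaseModel):
    """One diffusive state: a diffusion coefficient and its occupancy."""

    diffusion_coefficient: float = Field(gt=0, description="D, um^2/s")
    occupancy: float = Field(ge=0, le=1, description="fraction of molecules")


class SimulationConfig(BaseModel):
    """Ground-truth movie generator settings.

    Defaults reproduce the acquisition geometry of a 100 Hz stroboscopic
    SMT experiment: 150 frames at 10 ms intervals with a 407 us excitation
    pulse, diffraction-limited spots of width 1.5 px on a noisy camera
    background.  The default image is a small field so simulations stay
    cheap; the full-camera field is (1728, 2304).
    """

    n_frames: int = Field(default=150, ge=1)
    frame_interval: float = Field(default=0.01, gt=0, description="s")
    pulse_width: float = Field(default=407e-6, gt=0, description="s")
    pixel_size: float = Field(default=DEFAULT_PIXEL_SIZE, gt=0, description="um/px")
    image_shape: Tuple[int, int] = Field(default=(256, 256), description="(rows, cols) px")
    psf_sigma: float = Field(default=1.5, gt=0, description="px")
    states: Tuple[StateSpec, ...] = Field(
        default=(
            StateSpec(diffusion_coefficient=0.05, occupancy=0.3),
            StateSpec(diffusion_coefficient=5.0, occupancy=0.7),
        )
    )
    switching: float = Field(
        default=0.0, ge=0, le=1,
        description="per-frame probability of re-drawing the state; 0 = static states",
    )
    n_nuclei: int = Field(default=4, ge=0)
    nucleus_radius_um: float = Field(default=4.0, gt=0, description="mean semi-axis, um")
    emitter_density: float = Field(default=0.05, ge=0, description="emitters per um^2 nuclear area")
    photons_per_spot: float = Field(default=800.0, ge=0, description="mean photons per emitter per frame")
    background: float = Field(default=200.0, ge=0, description="camera background, counts")
    read_noise_sd: float = Field(default=5.0, ge=0, description="counts")
    bleach_survival: float = Field(
        default=0.98, ge=0, le=1, description="per-frame survival probability"
    )
    blink_off_prob: float = Field(
        default=0.0, ge=0, le=1,
        description="per-frame P(emitting -> dark); 0 disables blinking",
    )
    blink_on_prob: float = Field(
        default=0.0, ge=0, le=1, description="per-frame P(dark -> emitting)"
    )
    localization_error_target: float = Field(
        default=0.035, gt=0, description="expected 1-D localization RMSD, um"
    )
    shot_noise: bool = Field(default=True, description="apply Poisson noise to signal+background")
    seed: int = Field(default=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.states:
            total = sum(s.occupancy for s in self.states)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"state occupancies must sum to 1, got {total}")
        if not self.frame_interval > self.pulse_width:
            raise ValueError("frame_interval must exceed pulse_width")
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive")
        return self

    @property
    def fov_area_um2(self) -> float:
        r, c = self.image_shape
        return r * c * self.pixel_size**2


class ConditionEffect(BaseModel):
    """Treatment contrast applied to a control simulation.

    ``bound_occupancy`` replaces the occupancy of the first (slowest)
    state; the remaining states share the leftover mass in their original
    proportions.  ``density_multiplier`` scales the emitter density.
    """

    bound_occupancy: Optional[float] = Field(default=None, ge=0, le=1)
    density_multiplier: float = Field(default=1.0, ge=0)


class DetectionConfig(BaseModel):
    window: int = Field(default=11, ge=3)
    sigma: float = Field(default=1.5, gt=0, description="kernel width, px")
    threshold: float = Field(default=14.0, gt=0, description="LLR detection threshold")
    min_separation: int = Field(default=3, ge=1, description="NMS radius, px")


class LocalizationConfig(BaseModel):
    sigma: float = Field(default=1.5, gt=0, description="fixed PSF width, px")
    gamma: float = Field(default=0.3, gt=0, description="LM step damping")
    alpha: float = Field(default=1e-4, gt=0, description="LM regularization")
    max_iterations: int = Field(default=8, ge=1)
    position_tolerance: float = Field(default=1e-4, gt=0, description="px")


class LinkingConfig(BaseModel):
    max_distance: float = Field(default=1.25, gt=0, description="um")
    max_gap: int = Field(default=3, ge=1, description="frames")
    localization_error: float = Field(default=0.035, gt=0, description="um, 1-D RMSD")
    initial_diffusion: float = Field(default=0.5, gt=0, description="um^2/s")
    prune_factor: float = Field(
        default=0.5, ge=0,
        description="links with p below this multiple of the local no-link mass are pruned",
    )
    nolink_rate: float = Field(
        default=0.1, gt=0,
        description="per-frame appearance/disappearance rate scaling the no-link density",
    )


class SegmentationConfig(BaseModel):
    smoothing_sigma: float = Field(default=2.0, gt=0, description="px")
    min_area_um2: float = Field(default=20.0, gt=0)


class StateArrayConfig(BaseModel):
    n_diffusion: int = Field(default=100, ge=2)
    d_min: float = Field(default=0.01, gt=0, description="um^2/s")
    d_max: float = Field(default=100.0, gt=0, description="um^2/s")
    n_sigma: int = Field(default=31, ge=1)
    sigma_min: float = Field(default=0.02, gt=0, description="um, 1-D RMSD")
    sigma_max: float = Field(default=0.08, gt=0, description="um, 1-D RMSD")
    bound_threshold: float = Field(default=0.1, gt=0, description="um^2/s")
    fast_threshold: float = Field(default=1.0, gt=0, description="um^2/s")

    @model_validator(mode="after")
    def _check(self) -> "StateArrayConfig":
        if self.bound_threshold >= self.fast_threshold:
            raise ValueError("bound_threshold must be < fast_threshold")
        if self.d_min >= self.d_max or self.sigma_min >= self.sigma_max:
            raise ValueError("grid bounds must be increasing")
        return self


class PipelineConfig(BaseModel):
    """Parameters for the full detect -> localize -> link -> segment ->
    infer -> summarize pipeline, validated before any stage runs."""

    pixel_size: float = Field(default=DEFAULT_PIXEL_SIZE, gt=0, description="um/px")
    frame_interval: float = Field(default=0.01, gt=0, description="s")
    seed: int = Field(default=0)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    localization: LocalizationConfig = Field(default_factory=LocalizationConfig)
    linking: LinkingConfig = Field(default_factory=LinkingConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    state_array: StateArrayConfig = Field(default_factory=StateArrayConfig)
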