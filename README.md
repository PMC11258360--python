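# smtkit

Single-molecule tracking (SMT) analysis for live-cell, stroboscopic
fluorescence movies, with a ground-truthed synthetic-movie generator so
every stage of the pipeline can be validated without microscope data.

SMT images sparse, dye-labelled proteins (for example HaloTag fusions at
10–40 pM ligand) at high frame rates and reconstructs per-molecule
trajectories. The readouts this package computes per field of view (FOV)
are the ones used to quantify drug-induced chromatin trapping of a
nuclear protein: the distribution of diffusion coefficients, the
chromatin-bound fraction, the occupation-weighted mean diffusion
coefficient, and the nuclear spot density.

## The pipeline

1. **Detection** — every 11×11 pixel tile is tested for a
   diffraction-limited spot with a generalized log-likelihood ratio
   (GLRT) against a white-Gaussian-noise-only hypothesis.  With **G**
   the mean-zero, unit-energy Gaussian kernel (σ_w = 1.5 px) and **X**
   the tile,

   LLR = −(w²/2) · log[ 1 − (ΣXG)² / (ΣX² − (ΣX)²/w²) ]

   computed densely by frequency-domain convolution; tiles with
   LLR ≥ 14 that are local maxima become detections.
2. **Subpixel localization** — each detection is refined by fitting the
   2-D integrated Gaussian spot model f_ij = I·Δx_i·Δy_j + b (the
   Gaussian integrated over each unit pixel, σ_w fixed at 1.5 px) with a
   damped Levenberg–Marquardt update
   θ ← θ + γ(JᵀJ + αI)⁻¹Jᵀ(X − f(θ)), γ = 0.3, α = 10⁻⁴, at most 8
   iterations, initialized by the radial-symmetry method.
3. **Linking** — candidate links join detections within 1.25 µm and up
   to 3 frames; marginal link probabilities are inferred under a
   Brownian-motion model (jointly with per-spot diffusion coefficients),
   and a constrained hill-climb selects a conflict-free link set whose
   connected components are the trajectories.
4. **Nuclear assignment** — the nuclear-stain movie is mean-projected
   and segmented (Gaussian/Otsu/watershed); each trajectory is assigned
   to at most one nucleus by majority vote over its subpixel positions.
5. **State arrays** — trajectory jumps are scored with the RBME
   (regular Brownian motion with localization error) likelihood on a
   fixed grid of 100 log-spaced diffusion coefficients
   (0.01–100 µm²/s) × 31 localization errors (0.02–0.08 µm, 1-D RMSD);
   grid occupations are inferred per FOV and the error axis is
   marginalized to a 1-D distribution over D.  Mass at D ≤ 0.1 µm²/s is
   reported as the chromatin-bound fraction.

Each stage is a scikit-learn-style estimator (`SpotDetector`,
`SpotLocalizer`, `TrajectoryLinker`, `NucleusSegmenter`, `StateArray`)
with plain-function wrappers, so stages compose with sklearn tooling and
are individually testable.

## Worked example

Simulate a paired control/treated experiment in which treatment raises
the bound-state occupancy from 0.2 to 0.5 and lowers emitter density to
60% (the two signatures of a chromatin-trapping inhibitor), then run the
full pipeline on both movies:

```python
from smtkit import (ConditionEffect, PipelineConfig, SimulationConfig,
                    make_condition_pair)
from smtkit.pipeline import process_fov

cfg = SimulationConfig(
    n_frames=100, image_shape=(256, 256), n_nuclei=4, seed=7,
    states=(dict(diffusion_coefficient=0.05, occupancy=0.2),
            dict(diffusion_coefficient=5.0, occupancy=0.8)),
)
pair = make_condition_pair(
    cfg, ConditionEffect(bound_occupancy=0.5, density_multiplier=0.6))
for name, fov in (("control", pair.control), ("treated", pair.treated)):
    s = process_fov(fov.movie, fov.hoechst[None], PipelineConfig(),
                    fov_id=name, condition=name).summary
    print(f"{name}: n_nuclei={s.n_nuclei} n_traj={s.n_trajectories} "
          f"mean_D={s.mean_D:.2f} bound={s.bound_fraction:.3f} "
          f"fast={s.fast_fraction:.3f} density={s.spot_density:.4f}")
```

prints

```
control: n_nuclei=4 n_traj=20 mean_D=2.57 bound=0.298 fast=0.702 density=0.0172
treated: n_nuclei=4 n_traj=6 mean_D=1.71 bound=0.601 fast=0.399 density=0.0106
```

The treated FOV shows the expected phenotype: roughly a two-fold higher
chromatin-bound fraction, a lower mean diffusion coefficient, and a
lower nuclear spot density (spots per µm² of nuclear area per frame).
Single FOVs carry few molecules, so condition-level numbers are the
mean over all FOVs of a condition (`smtkit.aggregate_condition`).

The same pipeline runs from the shell on TIFF stacks:

```bash
smtkit simulate --out fixture/ --n-fovs 2 --seed 7
smtkit run --out results/ \
    --movie fixture/fov_000_tracking.tif --hoechst fixture/fov_000_hoechst.tif
```

which writes per-stage CSVs (detections, localizations, trajectories,
state-array posterior and marginal), label-mask TIFFs, FOV summaries and
a JSON run manifest.

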