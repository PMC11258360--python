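"""End-to-end pipeline: detect -> localize -> link -> segment/assign ->
state inference -> summaries, with file I/O and a run manifest.

Inputs are one tracking movie and one nuclear-stain movie per field of
view (single-channel multi-page TIFF); every intermediate is written as
long-format CSV (TIFF for masks) so each stage's output is independently
inspectable, and a JSON manifest records configuration and artifacts.
Runs are idempotent for fixed inputs, configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import PipelineConfig, SimulationConfig
from .detect import SpotDetector
from .link import TrajectoryLinker
from .localize import SpotLocalizer
from .segment import NucleusSegmenter, assign_to_nuclei, nucleus_table
from .simulate import SimulatedFOV, simulate_fov
from .states import StateArray
from .summarize import spot_density, summarize_fov

logger = logging.getLogger("smtkit")


@dataclass
class FOVInput:
    """Paths (or in-memory arrays) for one field of view."""

    fov_id: str
    movie: Union[str, Path, np.ndarray]
    hoechst: Union[str, Path, np.ndarray]
    plate: str = ""
    well: str = ""
    condition: str = ""


@dataclass
class FOVResult:
    fov_id: str
    detections: pd.DataFrame
    localizations: pd.DataFrame
    trajectories: pd.DataFrame
    mask: np.ndarray
    marginal: np.ndarray
    posterior: pd.DataFrame
    summary: pd.Series


def _load_stack(source: Union[str, Path, np.ndarray]) -> np.ndarray:
    if isinstance(source, np.ndarray):
        return source
    return tifffile.imread(str(source))


def process_fov(
    movie: np.ndarray,
    hoechst: np.ndarray,
    config: PipelineConfig,
    fov_id: str = "",
    plate: str = "",
    well: str = "",
    condition: str = "",
) -> FOVResult:
    """Run all analysis stages on one field of view (in memory)."""
    movie = np.asarray(movie)
    if movie.ndim == 2:
        movie = movie[None]
    px = config.pixel_size
    t0 = time.perf_counter()

    detector = SpotDetector(
        window=config.detection.window,
        sigma=config.detection.sigma,
        threshold=config.detection.threshold,
        min_separation=config.detection.min_separation,
    )
    detections = detector.fit().transform(movie)

    localizer = SpotLocalizer(
        window=config.detection.window,
        sigma=config.localization.sigma,
        gamma=config.localization.gamma,
        alpha=config.localization.alpha,
        max_iterations=config.localization.max_iterations,
        position_tolerance=config.localization.position_tolerance,
        pixel_size=px,
    )
    localizations = localizer.transform(movie, detections)

    linker = TrajectoryLinker(
        dt=config.frame_interval,
        max_distance=config.linking.max_distance,
        max_gap=config.linking.max_gap,
        localization_error=config.linking.localization_error,
        initial_diffusion=config.linking.initial_diffusion,
        prune_factor=config.linking.prune_factor,
        nolink_rate=config.linking.nolink_rate,
    )
    trajectories = linker.transform(localizations)

    segmenter = NucleusSegmenter(
        smoothing_sigma=config.segmentation.smoothing_sigma,
        min_area_um2=config.segmentation.min_area_um2,
        pixel_size=px,
    )
    mask = segmenter.transform(hoechst)
    trajectories = assign_to_nuclei(trajectories, mask, pixel_size=px)
    # trajectories outside all nuclei are excluded from state inference
    nuclear = trajectories[trajectories["trajectory_nucleus"] > 0]

    sa_cfg = config.state_array
    state_array = StateArray(
        dt=config.frame_interval,
        n_diffusion=sa_cfg.n_diffusion,
        d_min=sa_cfg.d_min,
        d_max=sa_cfg.d_max,
        n_sigma=sa_cfg.n_sigma,
        sigma_min=sa_cfg.sigma_min,
        sigma_max=sa_cfg.sigma_max,
        bound_threshold=sa_cfg.bound_threshold,
        fast_threshold=sa_cfg.fast_threshold,
    ).fit(nuclear)

    n_nuclei = int(mask.max())
    density = spot_density(detections, mask, movie.shape[0], px) if n_nuclei else 0.0
    summary = summarize_fov(
        plate=plate,
        well=well,
        fov=fov_id,
        n_nuclei=n_nuclei,
        n_trajectories=int(nuclear["trajectory_id"].nunique()) if len(nuclear) else 0,
        mean_d=state_array.mean_diffusion_,
        bound_fraction=state_array.bound_fraction_,
        slow_fraction=state_array.slow_fraction_,
        fast_fraction=state_array.fast_fraction_,
        density=density,
    )
    summary["condition"] = condition
    logger.info(
        "FOV %s: %d detections, %d trajectories, %d nuclei (%.2f s)",
        fov_id, len(detections), summary["n_trajectories"], n_nuclei,
        time.perf_counter() - t0,
    )
    return FOVResult(
        fov_id=fov_id,
        detections=detections,
        localizations=localizations,
        trajectories=trajectories,
        mask=mask,
        marginal=state_array.marginal_,
        posterior=state_array.posterior_.to_dataframe(),
        summary=summary,
    )


def _write_fov(result: FOVResult, out_dir: Path, config: PipelineConfig) -> List[str]:
    pixel_size = config.pixel_size
    fov_dir = out_dir / result.fov_id
    fov_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = fov_dir / name
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(str(path.relative_to(out_dir)))

    _csv(result.detections, "detections.csv")
    _csv(result.localizations, "localizations.csv")
    _csv(
        result.trajectories[
            [c for c in ("trajectory_id", "frame", "x_um", "y_um", "nucleus_label",
                         "trajectory_nucleus") if c in result.trajectories.columns]
        ],
        "trajectories.csv",
    )
    _csv(result.posterior, "posterior.csv")
    d_axis = np.geomspace(
        config.state_array.d_min, config.state_array.d_max, config.state_array.n_diffusion
    )
    _csv(pd.DataFrame({"D_um2_s": d_axis, "mass": result.marginal}), "marginal.csv")
    _csv(nucleus_table(result.mask, pixel_size), "nuclei.csv")
    mask_path = fov_dir / "mask.tif"
    tifffile.imwrite(str(mask_path), result.mask.astype(np.uint16))
    written.append(str(mask_path.relative_to(out_dir)))
    return written


def run_pipeline(
    config: PipelineConfig,
    fovs: Sequence[FOVInput],
    out_dir: Union[str, Path],
) -> Dict:
    """Process every FOV and write artifacts plus a manifest.

    An unreadable movie is recorded as a per-FOV failure and the run
    continues; the manifest lists successes, failures, configuration and
    the package version.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries: List[pd.Series] = []
    manifest: Dict = {
        "package": "smtkit",
        "version": __version__,
        "config": config.model_dump(),
        "fovs": [],
        "failures": [],
    }
    for fov in fovs:
        try:
            movie = _load_stack(fov.movie)
            hoechst = _load_stack(fov.hoechst)
            result = process_fov(
                movie, hoechst, config,
                fov_id=fov.fov_id, plate=fov.plate, well=fov.well,
                condition=fov.condition,
            )
        except Exception as exc:  # per-FOV failure: log and continue
            logger.warning("FOV %s failed: %s", fov.fov_id, exc)
            manifest["failures"].append({"fov": fov.fov_id, "error": str(exc)})
            continue
        files = _write_fov(result, out_dir, config)
        manifest["fovs"].append({"fov": fov.fov_id, "files": files})
        summaries.append(result.summary)
    if summaries:
        summary_df = pd.DataFrame(summaries)
        summary_df.to_csv(out_dir / "fov_summaries.csv", index=False, float_format="%.6f")
        manifest["summary"] = "fov_summaries.csv"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def write_simulated_fov(
    sim: SimulatedFOV, out_dir: Union[str, Path], fov_id: str = "fov_000"
) -> Dict[str, str]:
    """Write a simulated FOV as pipeline-ready files plus ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "movie": str(out_dir / f"{fov_id}_tracking.tif"),
        "hoechst": str(out_dir / f"{fov_id}_hoechst.tif"),
        "mask": str(out_dir / f"{fov_id}_truth_mask.tif"),
        "truth": str(out_dir / f"{fov_id}_truth.csv"),
        "config": str(out_dir / f"{fov_id}_config.json"),
    }
    tifffile.imwrite(paths["movie"], sim.movie)
    tifffile.imwrite(paths["hoechst"], sim.hoechst[None])
    tifffile.imwrite(paths["mask"], sim.label_mask.astype(np.uint16))
    sim.truth.to_dataframe().to_csv(paths["truth"], index=False, float_format="%.6f")
    with open(paths["config"], "w") as fh:
        fh.write(sim.config.model_dump_json(indent=2))
    return paths


def simulate_fixture(
    config: SimulationConfig, out_dir: Union[str, Path], n_fovs: int = 1
) -> List[Dict[str, str]]:
    """Simulate ``n_fovs`` fields of view and write them to disk."""
    out = []
    for k in range(n_fovs):
        cfg = config.model_copy(update={"seed": config.seed + k})
        out.append(
            write_simulated_fov(simulate_fov(cfg), out_dir, fov_id=f"fov_{k:03d}")
        )
    return out
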