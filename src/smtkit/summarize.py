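"""Per-FOV and per-condition endpoint summaries.

A field of view (FOV) is reduced to: number of nuclei and trajectories,
occupation-weighted mean diffusion coefficient, bound/slow/fast state
fractions, and nuclear spot density (in-nucleus detections per um^2 of
nuclear area per frame).  Condition-level values are the mean over all
FOVs of the condition, optionally normalized to a control condition.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_PIXEL_SIZE

METRICS = (
    "mean_D",
    "bound_fraction",
    "slow_fraction",
    "fast_fraction",
    "spot_density",
    "n_trajectories",
    "n_nuclei",
)


def spot_density(
    detections: pd.DataFrame,
    mask: np.ndarray,
    n_frames: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> float:
    """In-nucleus detections per um^2 of nuclear area per frame.

    Detections are counted at their integer tile centres (row, col);
    raises on an empty mask, where the density is undefined.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    nuclear_px = int((mask > 0).sum())
    if nuclear_px == 0:
        raise ValueError("empty nuclear mask: spot density undefined")
    area_um2 = nuclear_px * pixel_size**2
    if len(detections) == 0:
        return 0.0
    rows = detections["row"].to_numpy(dtype=int)
    cols = detections["col"].to_numpy(dtype=int)
    inside = (
        (rows >= 0)
        & (rows < mask.shape[0])
        & (cols >= 0)
        & (cols < mask.shape[1])
    )
    count = int((mask[rows[inside], cols[inside]] > 0).sum())
    return count / (area_um2 * n_frames)


def normalize_percent_signal(
    t: float, c_pos: float, c_neg: float, conventional: bool = False
) -> float:
    """Plate-normalized percent signal.

    Default implements the printed form %S = (T - C_pos)/(C_pos - C_neg)
    * 100, under which the positive control scores 0 and the negative
    control -100.  With ``conventional=True`` the numerator is
    (T - C_neg), giving the usual 0–100 scale between the controls.
    """
    if c_pos == c_neg:
        raise ZeroDivisionError("C_pos and C_neg must differ")
    numerator = (t - c_neg) if conventional else (t - c_pos)
    return numerator / (c_pos - c_neg) * 100.0


def summarize_fov(
    *,
    plate: str = "",
    well: str = "",
    fov: str = "",
    n_nuclei: int,
    n_trajectories: int,
    mean_d: float,
    bound_fraction: float,
    slow_fraction: float,
    fast_fraction: float,
    density: float,
) -> pd.Series:
    """Assemble one FOVSummary row."""
    for frac in (bound_fraction, slow_fraction, fast_fraction):
        if not (-1e-9 <= frac <= 1 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")
    if density < 0:
        raise ValueError("density must be >= 0")
    return pd.Series(
        {
            "plate": plate,
            "well": well,
            "fov": fov,
            "n_nuclei": n_nuclei,
            "n_trajectories": n_trajectories,
            "mean_D": mean_d,
            "bound_fraction": bound_fraction,
            "slow_fraction": slow_fraction,
            "fast_fraction": fast_fraction,
            "spot_density": density,
        }
    )


def aggregate_condition(
    fov_summaries: pd.DataFrame,
    grouping: str = "condition",
    control: Optional[str] = None,
    metrics: Sequence[str] = METRICS,
) -> pd.DataFrame:
    """Condition-level mean / s.d. / s.e.m. over FOVs.

    Reported condition averages are the mean value over all FOVs of the
    condition.  If ``control`` names a condition, each metric mean is
    additionally normalized to the control condition's mean.
    """
    if len(fov_summaries) == 0:
        raise ValueError("need at least one FOV summary")
    present = [m for m in metrics if m in fov_summaries.columns]
    grouped = fov_summaries.groupby(grouping)[present]
    out = grouped.agg(["mean", "std", "sem", "count"])
    out.columns = [f"{metric}_{stat}" for metric, stat in out.columns]
    if control is not None:
        if control not in out.index:
            raise ValueError(f"control condition {control!r} not found")
        for metric in present:
            ref = out.loc[control, f"{metric}_mean"]
            out[f"{metric}_norm"] = (
                out[f"{metric}_mean"] / ref if ref != 0 else np.nan
            )
    return out
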