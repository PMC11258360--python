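"""Nuclear segmentation of the stain channel and spot-to-nucleus
assignment.

The stain movie is collapsed to a mean projection and segmented with a
classical pipeline — Gaussian smoothing, Otsu threshold, hole filling,
distance-transform watershed to split touching nuclei, small-object
removal.  The contract is simply image -> label mask, so a learned
segmenter can be dropped in unchanged.  Each localization is assigned to
at most one nucleus via the mask pixel containing its subpixel position;
a trajectory takes the majority label of its localizations.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_PIXEL_SIZE
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops_table
from skimage.segmentation import relabel_sequential, watershed
from sklearn.base import BaseEstimator


def mean_projection(movie: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean across frames (accepts a 2-D image)."""
    movie = np.asarray(movie, dtype=float)
    if movie.size == 0:
        raise ValueError("empty movie")
    if movie.ndim == 2:
        return movie
    return movie.mean(axis=0)


def segment_nuclei(
    image: np.ndarray,
    smoothing_sigma: float = 2.0,
    min_area_um2: float = 20.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> np.ndarray:
    """Label mask of nuclei in a stain image (0 = background).

    Components smaller than ``min_area_um2`` are discarded and labels
    re-packed to {1..K}.  A blank (near-constant) image yields an empty
    mask rather than an Otsu failure.
    """
    image = np.asarray(image, dtype=float)
    smooth = gaussian(image, sigma=smoothing_sigma, preserve_range=True)
    if smooth.max() - smooth.min() < 1e-9 * max(abs(smooth.max()), 1.0) + 1e-12:
        return np.zeros(image.shape, dtype=np.int32)
    binary = smooth > threshold_otsu(smooth)
    if not binary.any() or binary.all():
        return np.zeros(image.shape, dtype=np.int32)
    binary = ndimage.binary_fill_holes(binary)
    distance = ndimage.distance_transform_edt(binary)
    min_area_px = min_area_um2 / pixel_size**2
    min_sep = max(3, int(np.sqrt(min_area_px / np.pi)))
    peaks = peak_local_max(distance, min_distance=min_sep, labels=binary)
    markers = np.zeros(image.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-distance, markers, mask=binary)
    # drop sub-minimum components
    for region_label in np.unique(labels):
        if region_label == 0:
            continue
        if (labels == region_label).sum() < min_area_px:
            labels[labels == region_label] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def nucleus_table(mask: np.ndarray, pixel_size: float = DEFAULT_PIXEL_SIZE) -> pd.DataFrame:
    """Per-nucleus label, area (um^2) and centroid (px)."""
    if mask.max() == 0:
        return pd.DataFrame(columns=["label", "area_um2", "centroid_row", "centroid_col"])
    props = regionprops_table(mask, properties=("label", "area", "centroid"))
    return pd.DataFrame(
        {
            "label": props["label"],
            "area_um2": props["area"] * pixel_size**2,
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
        }
    )


def assign_to_nuclei(
    trajectories: pd.DataFrame,
    mask: np.ndarray,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> pd.DataFrame:
    """Assign each localization, then each trajectory, to one nucleus.

    A localization takes the label of the mask pixel containing its
    subpixel position (rounded to the nearest pixel centre; out-of-image
    positions are unassigned, label 0).  A trajectory's label is the
    majority label over its localizations, 0 if the majority is
    background.  Adds ``nucleus_label`` (per localization) and
    ``trajectory_nucleus`` (per row, trajectory majority).
    """
    out = trajectories.copy()
    rows = np.round(out["y_um"].to_numpy() / pixel_size).astype(int)
    cols = np.round(out["x_um"].to_numpy() / pixel_size).astype(int)
    inside = (
        (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    )
    labels = np.zeros(len(out), dtype=np.int64)
    labels[inside] = mask[rows[inside], cols[inside]]
    out["nucleus_label"] = labels
    if "trajectory_id" in out.columns:
        majority = (
            out.groupby("trajectory_id")["nucleus_label"]
            .agg(lambda s: s.value_counts().idxmax())
            .rename("trajectory_nucleus")
        )
        out = out.merge(majority, on="trajectory_id", how="left")
    else:
        out["trajectory_nucleus"] = labels
    return out


class NucleusSegmenter(BaseEstimator):
    """Stain movie -> nuclear label mask (scikit-learn style)."""

    def __init__(
        self,
        smoothing_sigma: float = 2.0,
        min_area_um2: float = 20.0,
        pixel_size: float = DEFAULT_PIXEL_SIZE,
    ):
        self.smoothing_sigma = smoothing_sigma
        self.min_area_um2 = min_area_um2
        self.pixel_size = pixel_size

    def fit(self, X=None, y=None) -> "NucleusSegmenter":
        return self

    def transform(self, movie: np.ndarray) -> np.ndarray:
        projection = mean_projection(movie)
        mask = segment_nuclei(
            projection,
            smoothing_sigma=self.smoothing_sigma,
            min_area_um2=self.min_area_um2,
            pixel_size=self.pixel_size,
        )
        self.mask_ = mask
        self.nuclei_ = nucleus_table(mask, self.pixel_size)
        return mask
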