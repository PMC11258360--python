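"""Spot detection by generalized log-likelihood-ratio (GLRT) testing.

Each w x w tile of a frame is tested for the presence of a
diffraction-limited Gaussian spot against a white-Gaussian-noise-only
hypothesis.  With G the mean-zero, unit-energy Gaussian detection kernel
the log-likelihood ratio for a tile X reduces to

    LLR = -(w^2 / 2) * log[ 1 - (sum X G)^2 / (sum X^2 - (sum X)^2 / w^2) ]

The three tile sums are computed for every tile position at once by
frequency-domain convolution.  Tiles with LLR at or above the detection
threshold (default 14) that are local maxima of the LLR map become
detections.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator

#: floor for the log argument when rounding drives it to zero; the LLR is
#: capped at the (finite, order-preserving) value for this argument.
LOG_ARG_FLOOR = 1e-12


def make_kernel(w: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Mean-zero, unit-energy Gaussian detection kernel.

    A symmetric Gaussian of width ``sigma`` sampled at the w x w pixel
    centres, then mean-subtracted and scaled so that sum(G) = 0 and
    sum(G^2) = 1.
    """
    if w % 2 == 0 or w <= 0:
        raise ValueError("window size must be odd and positive (no unique centre)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    c = (w - 1) / 2.0
    yy, xx = np.mgrid[0:w, 0:w].astype(float)
    g = np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2.0 * sigma * sigma))
    g -= g.mean()
    g /= np.sqrt((g * g).sum())
    return g


def llr_map(frame: np.ndarray, kernel: Optional[np.ndarray] = None) -> np.ndarray:
    """Dense GLRT map: the LLR of the tile centred at every interior pixel.

    Pixels within w//2 of the border (where the tile would not fit) are
    set to 0.  Constant tiles (zero-variance denominator) are defined to
    have LLR 0 — no evidence of a spot; a log argument driven to or below
    zero by rounding is clamped to :data:`LOG_ARG_FLOOR`.
    """
    if kernel is None:
        kernel = make_kernel()
    frame = np.asarray(frame, dtype=float)
    w = kernel.shape[0]
    if frame.shape[0] < w or frame.shape[1] < w:
        raise ValueError(f"frame must be at least {w}x{w}")
    # The LLR is invariant to a global additive offset (sum G = 0);
    # removing the mean keeps the convolutions well conditioned.
    frame = frame - frame.mean()
    ones = np.ones((w, w))
    s1 = fftconvolve(frame, ones, mode="valid")
    s2 = fftconvolve(frame * frame, ones, mode="valid")
    sg = fftconvolve(frame, kernel[::-1, ::-1], mode="valid")
    denom = s2 - (s1 * s1) / (w * w)
    scale = max(float(np.abs(s2).max(initial=0.0)), 1.0)
    valid = denom > 1e-9 * scale
    ratio = np.zeros_like(denom)
    np.divide(sg * sg, denom, out=ratio, where=valid)
    arg = np.clip(1.0 - ratio, LOG_ARG_FLOOR, None)
    llr = -(w * w / 2.0) * np.log(arg)
    llr[~valid] = 0.0
    out = np.zeros_like(frame)
    half = w // 2
    out[half : half + llr.shape[0], half : half + llr.shape[1]] = llr
    return out


def llr_map_direct(frame: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-tile reference evaluation of the LLR (no FFT); test oracle."""
    frame = np.asarray(frame, dtype=float)
    w = kernel.shape[0]
    half = w // 2
    out = np.zeros_like(frame)
    for r in range(half, frame.shape[0] - half):
        for c in range(half, frame.shape[1] - half):
            tile = frame[r - half : r + half + 1, c - half : c + half + 1]
            sg = float((tile * kernel).sum())
            denom = float((tile * tile).sum() - tile.sum() ** 2 / (w * w))
            if denom <= 1e-9 * max(float((tile * tile).sum()), 1.0):
                continue
            arg = max(1.0 - sg * sg / denom, LOG_ARG_FLOOR)
            out[r, c] = -(w * w / 2.0) * np.log(arg)
    return out


def detect_spots(
    llr: np.ndarray,
    threshold: float = 14.0,
    min_separation: int = 3,
    frame_index: int = 0,
    border: int = 5,
) -> pd.DataFrame:
    """Local maxima of an LLR map at or above ``threshold``.

    Detections closer than ``min_separation`` px are deduplicated in
    favour of the stronger peak; nothing is reported within ``border``
    px of the frame edge.  Returns a DataFrame with columns
    frame, row, col, llr sorted by (frame, row, col).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks = peak_local_max(
        llr,
        min_distance=min_separation,
        threshold_abs=threshold,
        exclude_border=border,
    )
    if peaks.size == 0:
        return pd.DataFrame(columns=["frame", "row", "col", "llr"]).astype(
            {"frame": int, "row": int, "col": int, "llr": float}
        )
    df = pd.DataFrame(
        {
            "frame": frame_index,
            "row": peaks[:, 0],
            "col": peaks[:, 1],
            "llr": llr[peaks[:, 0], peaks[:, 1]],
        }
    )
    return df.sort_values(["frame", "row", "col"], ignore_index=True)


class SpotDetector(BaseEstimator):
    """GLRT spot detector over a movie (scikit-learn style transformer).

    ``transform(movie)`` accepts a 2-D frame or a 3-D (frames, rows,
    cols) stack and returns the concatenated detection table.
    """

    def __init__(
        self,
        window: int = 11,
        sigma: float = 1.5,
        threshold: float = 14.0,
        min_separation: int = 3,
    ):
        self.window = window
        self.sigma = sigma
        self.threshold = threshold
        self.min_separation = min_separation

    def fit(self, X=None, y=None) -> "SpotDetector":
        self.kernel_ = make_kernel(self.window, self.sigma)
        return self

    def transform(self, movie: np.ndarray) -> pd.DataFrame:
        if not hasattr(self, "kernel_"):
            self.fit()
        movie = np.asarray(movie)
        if movie.ndim == 2:
            movie = movie[None]
        frames = [
            detect_spots(
                llr_map(frame, self.kernel_),
                threshold=self.threshold,
                min_separation=self.min_separation,
                frame_index=t,
                border=self.window // 2,
            )
            for t, frame in enumerate(movie)
        ]
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["frame", "row", "col"], ignore_index=True)
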