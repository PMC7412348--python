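"""Unthresholded recurrence-plot encoding of force windows.

P(i, j) = |x_i - x_j| / max(x): a normalized pairwise-distance matrix on
the scalar series — no embedding, no delay, no epsilon threshold. For a
nonnegative signal every entry lies in [0, 1]; 0 renders black (similar
states), 1 white. The matrix is resampled to a square gray-level image
(227 x 227 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, resize_local_mean


class DegenerateSignalError(ValueError):
    """Raised when max(x) <= 0 (all-zero or negative window)."""


@dataclass
class RecurrencePlot:
    """Normalized pairwise absolute-difference matrix of one window."""

    P: np.ndarray

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class RPImage:
    """Square gray-level image in [0, 1].

    Orientation: row i = time increasing downward, column j = time
    increasing rightward (recorded in ``meta``).
    """

    pixels: np.ndarray
    meta: dict | None = None

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]


def compute_rp(x: np.ndarray, block_size: int | None = None) -> RecurrencePlot:
    """Compute the unthresholded recurrence plot of ``x``.

    Parameters
    ----------
    x : 1-D nonnegative array, length >= 2, max(x) > 0.
    block_size : int, optional
        Compute the matrix in row blocks of this size to bound peak
        memory. The output is identical for any block size.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("window must have at least 2 samples")
    if np.any(x < 0):
        raise ValueError("window must be nonnegative (vGRF precondition)")
    mx = x.max()
    if mx <= 0:
        raise DegenerateSignalError(
            "max(x) <= 0: all-zero window cannot be normalized"
        )
    n = len(x)
    if block_size is None or block_size >= n:
        P = np.abs(x[:, None] - x[None, :]) / mx
    else:
        P = np.empty((n, n))
        for i0 in range(0, n, block_size):
            i1 = min(i0 + block_size, n)
            P[i0:i1] = np.abs(x[i0:i1, None] - x[None, :]) / mx
    return RecurrencePlot(P=P)


def to_image(
    rp: RecurrencePlot,
    resolution: int = 227,
    method: str = "bilinear",
) -> RPImage:
    """Resample a recurrence plot to a ``resolution`` x ``resolution``
    gray-level image.

    ``bilinear`` (default) avoids aliasing the fine texture;
    ``area`` performs exact local-mean (block-average) resampling.
    Values are clipped back to [0, 1].
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    P = rp.P
    if P.shape == (resolution, resolution):
        pixels = P.copy()
    elif method == "bilinear":
        pixels = resize(
            P, (resolution, resolution),
            order=1, mode="edge", anti_aliasing=False, preserve_range=True,
        )
    elif method == "area":
        pixels = resize_local_mean(P, (resolution, resolution))
    else:
        raise ValueError(f"unknown resize method {method!r}")
    np.clip(pixels, 0.0, 1.0, out=pixels)
    return RPImage(
        pixels=pixels,
        meta={
            "orientation": "row=time-down, col=time-right",
            "source_n": rp.n,
            "method": method,
        },
    )
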