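"""Small numeric helpers shared across the pipeline.

Rounding and line rasterization are pinned down here once so that every
stage (filtering, separation-line cost, masking) is bit-reproducible.
"""
from __future__ import annotations

import numpy as np

__all__ = ["round_half_up", "line_columns", "fit_to_square"]


def round_half_up(x):
    """Round to nearest integer with halves going up (0.5 -> 1, 1.5 -> 2).

    numpy's default round-half-even would make remap tables depend on
    parity; the pipeline uses half-up everywhere.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def line_columns(x_top: int, x_bottom: int, height: int) -> np.ndarray:
    """Integer column index of a near-vertical line at every row.

    The line joins (row 0, ``x_top``) and (row ``height-1``, ``x_bottom``);
    the column at row r is the half-up rounding of the linear interpolation
    between the endpoints.  This is the single rasterization rule used both
    for separation-line cost and for mask membership.
    """
    if height < 1:
        raise ValueError("height must be >= 1")
    if height == 1:
        return np.array([int(round_half_up(x_top))], dtype=np.int64)
    r = np.arange(height, dtype=np.float64)
    x = x_top + (x_bottom - x_top) * r / (height - 1)
    return round_half_up(x)


def fit_to_square(img: np.ndarray, side: int) -> np.ndarray:
    """Aspect-preserving resize of a 2-D image into a ``side`` x ``side``
    canvas, zero-padded equally on the short axis (extra pixel trailing).

    Returns float64 in the input's intensity range.
    """
    from skimage.transform import resize

    h, w = img.shape
    scale = side / max(h, w)
    nh = max(1, int(round(h * scale)))
    nw = max(1, int(round(w * scale)))
    resized = resize(img.astype(np.float64), (nh, nw), anti_aliasing=True,
                     preserve_range=True)
    out = np.zeros((side, side), dtype=np.float64)
    top = (side - nh) // 2
    left = (side - nw) // 2
    out[top:top + nh, left:left + nw] = resized
    return out
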