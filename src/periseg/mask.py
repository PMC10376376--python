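"""Line expansion, out-of-region masking, and single-tooth tile extraction.

Once a tooth's two separation lines are fixed they are pushed outward by
1/30th of the original image width (error tolerance for slightly
misplaced lines, plus a margin of context for the classifier), everything
strictly outside them is set to 0, and the surviving region is cropped
into a :class:`ToothTile` that carries its provenance.

Membership is defined per row through the shared rasterization rule: a
pixel (r, x) is kept iff raster(left, r) <= x <= raster(right, r), with
both boundary columns inclusive.  With a degenerate pair (left == right)
exactly the rasterized line column survives.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import SegLine
from .util import line_columns

__all__ = ["ToothTile", "expand_lines", "apply_mask", "extract_tile"]


@dataclass(eq=False)
class ToothTile:
    pixels: np.ndarray
    source_id: str
    left_line: SegLine
    right_line: SegLine
    threshold_T: int
    label: str = "unknown"
    row0: int = 0          # crop origin in the source image
    col0: int = 0


def expand_lines(left: SegLine, right: SegLine, image_width: int,
                 divisor: int = 30) -> tuple[SegLine, SegLine]:
    """Shift the left line left and the right line right by
    floor(image_width / divisor), clamped to the image bounds."""
    if left.mean_x > right.mean_x:
        raise ValueError("left line lies right of the right line")
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    offset = image_width // divisor
    lo = SegLine(max(0, left.x_top - offset), max(0, left.x_bottom - offset),
                 left.cost)
    hi = SegLine(min(image_width - 1, right.x_top + offset),
                 min(image_width - 1, right.x_bottom + offset), right.cost)
    return lo, hi


def _membership(shape: tuple[int, int], left: SegLine,
                right: SegLine) -> np.ndarray:
    H, W = shape
    xl = line_columns(left.x_top, left.x_bottom, H)[:, None]
    xr = line_columns(right.x_top, right.x_bottom, H)[:, None]
    x = np.arange(W)[None, :]
    return (x >= xl) & (x <= xr)


def apply_mask(img: np.ndarray, left: SegLine, right: SegLine) -> np.ndarray:
    """Zero every pixel outside the band between the two lines.

    Pixels inside the band are bit-identical to the source, so applying
    the mask twice changes nothing.
    """
    img = np.asarray(img)
    keep = _membership(img.shape, left, right)
    out = img.copy()
    out[~keep] = 0
    return out


def extract_tile(img: np.ndarray, left: SegLine, right: SegLine,
                 pad: int = 0, source_id: str = "", threshold_T: int = 0,
                 label: str = "unknown") -> ToothTile:
    """Masked crop of the region between two lines, plus provenance.

    The crop is the bounding box of the kept region grown by ``pad`` and
    clamped to the image.  An empty kept region is an error.
    """
    img = np.asarray(img)
    H, W = img.shape
    keep = _membership(img.shape, left, right)
    # clip membership to the frame (rasterized lines may sit outside it)
    if not keep.any():
        raise ValueError("empty kept region between the two lines")
    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    r0 = max(0, rows[0] - pad)
    r1 = min(H, rows[-1] + 1 + pad)
    c0 = max(0, cols[0] - pad)
    c1 = min(W, cols[-1] + 1 + pad)
    masked = img.copy()
    masked[~keep] = 0
    return ToothTile(pixels=masked[r0:r1, c0:c1], source_id=source_id,
                     left_line=left, right_line=right,
                     threshold_T=threshold_T, label=label, row0=int(r0),
                     col0=int(c0))
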