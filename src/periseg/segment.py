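"""Interdental separation lines: vertical projection of the binary image,
candidate gap columns, and per-line tilt optimization.

Separation lines live in interdental spaces, which binarize to black, so
per-column sums of the binary image dip to near zero at the gaps.  Up to
five teeth fit in one PA frame, and neighbouring gaps must be at least
one tooth width apart, so candidate columns are picked greedily from the
smallest column sums with a minimum spacing.

Instead of rotating the image, each line's two endpoint x-coordinates
(row 0 and row H-1) are shifted independently over a grid; the line whose
rasterized path crosses the fewest white pixels wins.  Rasterization is
the shared rounded-interpolation rule in :mod:`periseg.util`, so costs
are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import line_columns

__all__ = [
    "ProjectionProfile",
    "SegLine",
    "vertical_projection",
    "find_gap_candidates",
    "rotate_tangent",
    "pair_lines_for_tooth",
    "trim_outer_endpoint",
]


@dataclass
class ProjectionProfile:
    sums: np.ndarray     # per-column totals of the binary image
    width: int


@dataclass
class SegLine:
    x_top: int           # column at row 0
    x_bottom: int        # column at row height-1
    cost: int = 0        # white pixels crossed by the rasterized line

    @property
    def mean_x(self) -> float:
        return (self.x_top + self.x_bottom) / 2.0


def vertical_projection(binary: np.ndarray) -> ProjectionProfile:
    """Per-column sums of a {0,1} image."""
    binary = np.asarray(binary)
    sums = binary.sum(axis=0, dtype=np.int64)
    return ProjectionProfile(sums=sums, width=binary.shape[1])


def find_gap_candidates(profile: ProjectionProfile, max_lines: int = 5,
                        min_gap: int | None = None) -> list[int]:
    """Up to ``max_lines`` candidate gap columns, sorted left to right.

    Columns are taken greedily in increasing order of projection sum
    (ties to the leftmost column); a candidate closer than ``min_gap``
    to an already-selected one is discarded.  ``min_gap`` defaults to
    width // 6, one tooth distance for a five-tooth frame.
    """
    if profile.width == 0 or len(profile.sums) == 0:
        raise ValueError("empty projection profile")
    if max_lines < 1:
        raise ValueError("max_lines must be >= 1")
    if min_gap is None:
        min_gap = max(1, profile.width // 6)
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    cols = np.arange(profile.width)
    order = np.lexsort((cols, profile.sums))
    selected: list[int] = []
    for x in order:
        if len(selected) >= max_lines:
            break
        if all(abs(int(x) - s) >= min_gap for s in selected):
            selected.append(int(x))
    return sorted(selected)


def rotate_tangent(binary: np.ndarray, x0: int, shift_range: int,
                   step: int = 1) -> SegLine:
    """Best tilted line through the candidate column ``x0``.

    Evaluates every endpoint pair (x0+a, x0+b) with a, b in
    [-shift_range, +shift_range] (step ``step``) whose endpoints stay in
    the image, and returns the minimum-cost line; ties are broken by
    smaller |a|+|b|, then smaller a, then smaller b, so the vertical line
    wins whenever it is optimal.
    """
    binary = np.asarray(binary)
    H, W = binary.shape
    if not (0 <= x0 < W):
        raise ValueError(f"x0={x0} outside image of width {W}")
    if shift_range < 0:
        raise ValueError("shift_range must be >= 0")
    shifts = np.arange(-shift_range, shift_range + 1, step, dtype=np.int64)
    a = np.repeat(shifts, len(shifts))
    b = np.tile(shifts, len(shifts))
    xt = x0 + a
    xb = x0 + b
    ok = (xt >= 0) & (xt < W) & (xb >= 0) & (xb < W)
    a, b, xt, xb = a[ok], b[ok], xt[ok], xb[ok]
    # rasterize all lines at once: X[r, k] = column of line k at row r
    if H == 1:
        X = xt[None, :].astype(np.int64)
    else:
        r = np.arange(H, dtype=np.float64)[:, None]
        X = np.floor(xt[None, :] + (xb - xt)[None, :] * r / (H - 1) + 0.5).astype(np.int64)
    costs = binary[np.arange(H)[:, None], X].sum(axis=0, dtype=np.int64)
    order = np.lexsort((b, a, np.abs(a) + np.abs(b), costs))
    k = order[0]
    return SegLine(x_top=int(xt[k]), x_bottom=int(xb[k]), cost=int(costs[k]))


def pair_lines_for_tooth(lines: list[SegLine], tooth_index: int,
                         image_width: int) -> tuple[SegLine, SegLine]:
    """Bounding (left, right) lines of the ``tooth_index``-th inter-line
    region; the image borders act as virtual vertical lines at x=0 and
    x=width-1, so n detected lines bound n+1 regions."""
    ordered = sorted(lines, key=lambda s: s.mean_x)
    borders = ([SegLine(0, 0, 0)] + ordered
               + [SegLine(image_width - 1, image_width - 1, 0)])
    if not (0 <= tooth_index < len(borders) - 1):
        raise IndexError(
            f"tooth_index {tooth_index} out of range for {len(ordered)} lines")
    return borders[tooth_index], borders[tooth_index + 1]


def trim_outer_endpoint(line: SegLine, tooth_center_x: float) -> SegLine:
    """Vertical trimming of a separation line relative to its tooth.

    The line is replaced by the vertical line at its outermost x with
    respect to the tooth (leftmost x for a line left of the tooth,
    rightmost otherwise), so the kept region on the tooth side is never
    smaller than under the tilted line and the root is never cut through.
    A vertical line is returned unchanged.
    """
    if line.x_top == line.x_bottom:
        return SegLine(line.x_top, line.x_bottom, line.cost)
    if line.mean_x <= tooth_center_x:     # line left of the tooth
        x = min(line.x_top, line.x_bottom)
    else:
        x = max(line.x_top, line.x_bottom)
    return SegLine(x, x, line.cost)
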