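"""Adaptive histogram-window thresholding for binarizing PA images.

The method assumes a bright-extreme-redistributed 8-bit grayscale image in
which essentially all mass sits at or below gray 170.  From the 256-bin
histogram it takes:

* ``Lmax`` — most-populated gray level in [30, 90] (dark peak:
  background / interdental space),
* ``Rmax`` — most-populated gray level in [91, 170] (bright peak:
  teeth / gingiva),
* ``Zmin`` — least-populated gray level in [60, 120] (the valley),
* ``Zmid = round((Lmax + Rmax) / 2)`` — the initial threshold T0.

A candidate threshold T is accepted only when all of the following hold:
the valley lies near the midpoint (|Zmin - Zmid| < 15, repairing Zmin to
the next-least-populated valley bin when it does not); the mass in
[T, 170] (``Zcheck``) is between 2/3 and 5/6 of all pixels; T is inside
[80, 95]; and the binarized mean is strictly inside (0.6, 0.85).
Candidates are explored outward from Zmid (closest first, ties to the
lower level), so the accepted T is the qualifying level closest to Zmid.
If no candidate qualifies within the iteration budget the result is
flagged unconverged and T falls back to Otsu's threshold.

Ties in every window argmax/argmin go to the lower gray level, which
makes the whole procedure bit-deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HistogramStats",
    "ThresholdResult",
    "DegenerateHistogramError",
    "compute_stats",
    "check_constraints",
    "adaptive_threshold",
    "binarize",
    "otsu_threshold",
    "iterative_mean_threshold",
    "T_WINDOW",
    "MEAN_WINDOW",
]

# Accepted-threshold gray window and binary-mean window.
T_WINDOW = (80, 95)
MEAN_WINDOW = (0.6, 0.85)
_VALLEY_RANGE = (60, 120)
_LEFT_PEAK_RANGE = (30, 90)
_RIGHT_PEAK_RANGE = (91, 170)
_X_DISTANCE = 15
_CHECK_HI = 5.0 / 6.0
_CHECK_LO = 2.0 / 3.0


class DegenerateHistogramError(ValueError):
    """A histogram window required by the method holds no pixels."""


@dataclass
class HistogramStats:
    zmin: int        # valley gray level in [60, 120] (post-repair)
    lmax: int        # dark-peak gray level in [30, 90]
    rmax: int        # bright-peak gray level in [91, 170]
    zmid: int        # round((lmax + rmax) / 2)
    t0: int          # threshold the zcheck field was evaluated at
    ztotal: int      # total pixel count
    zcheck: int      # pixels with gray in [t0, 170]


@dataclass
class ThresholdResult:
    T: int
    stats: HistogramStats
    iterations: int
    converged: bool
    binary_mean: float


def _histogram(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("expected uint8 grayscale image")
    return np.bincount(img.ravel(), minlength=256).astype(np.int64)


def _zcheck(hist: np.ndarray, t: int) -> int:
    return int(hist[t:171].sum())


def compute_stats(img: np.ndarray, t0: int | None = None) -> HistogramStats:
    """Histogram windows, midpoint and check count for ``img``.

    ``t0`` defaults to the midpoint Zmid; ``zcheck`` counts gray levels in
    the closed interval [t0, 170].
    """
    hist = _histogram(img)
    lo, hi = _LEFT_PEAK_RANGE
    if hist[lo:hi + 1].sum() == 0:
        raise DegenerateHistogramError(f"no pixels in gray range {lo}..{hi}")
    lmax = lo + int(np.argmax(hist[lo:hi + 1]))
    lo, hi = _RIGHT_PEAK_RANGE
    if hist[lo:hi + 1].sum() == 0:
        raise DegenerateHistogramError(f"no pixels in gray range {lo}..{hi}")
    rmax = lo + int(np.argmax(hist[lo:hi + 1]))
    lo, hi = _VALLEY_RANGE
    zmin = lo + int(np.argmin(hist[lo:hi + 1]))
    zmid = int(np.floor((lmax + rmax) / 2.0 + 0.5))
    if t0 is None:
        t0 = zmid
    return HistogramStats(zmin=zmin, lmax=lmax, rmax=rmax, zmid=zmid,
                          t0=int(t0), ztotal=int(hist.sum()),
                          zcheck=_zcheck(hist, int(t0)))


def check_constraints(stats: HistogramStats) -> list[str]:
    """Names of the acceptance rules violated by ``stats`` (empty = all pass)."""
    v = []
    if abs(stats.zmin - stats.zmid) >= _X_DISTANCE:
        v.append("valley_distance")
    if stats.zcheck > stats.ztotal * _CHECK_HI:
        v.append("check_fraction_high")
    if stats.zcheck < stats.ztotal * _CHECK_LO:
        v.append("check_fraction_low")
    return v


def binarize(img: np.ndarray, T: int) -> np.ndarray:
    """1 where pixel > T (strict), else 0."""
    if not (0 <= T <= 255):
        raise ValueError("T must be in 0..255")
    return (np.asarray(img) > T).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's between-class-variance threshold (baseline / fallback)."""
    from skimage.filters import threshold_otsu

    img = np.asarray(img)
    if np.unique(img).size < 2:
        raise DegenerateHistogramError("image has a single gray level")
    return int(threshold_otsu(img))


def iterative_mean_threshold(img: np.ndarray, eps: float = 0.5) -> float:
    """Ridler–Calvard iterative-mean threshold (baseline).

    Alternates T <- (mean below + mean above) / 2 until the update is
    smaller than ``eps``.
    """
    x = np.asarray(img, dtype=np.float64).ravel()
    if np.unique(x).size < 2:
        raise DegenerateHistogramError("image has a single gray level")
    t = float(x.mean())
    for _ in range(256):
        lo = x[x <= t]
        hi = x[x > t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = (lo.mean() + hi.mean()) / 2.0
        if abs(t_new - t) < eps:
            return t_new
        t = t_new
    return t


def adaptive_threshold(img: np.ndarray, max_iter: int = 64) -> ThresholdResult:
    """Search for the accepted threshold as described in the module docstring.

    Repair order: first the valley (Zmin re-picked in increasing count
    order until it lies within 15 levels of Zmid), then the threshold
    (candidates T explored outward from Zmid inside [80, 95], lower side
    first on ties).  Every valley re-pick and every candidate evaluation
    counts against ``max_iter``.
    """
    hist = _histogram(img)
    stats0 = compute_stats(img)
    zmid = stats0.zmid
    ztotal = stats0.ztotal
    iterations = 0

    # valley repair: bins in [60, 120] ordered by (count, gray)
    lo, hi = _VALLEY_RANGE
    grays = np.arange(lo, hi + 1)
    order = np.lexsort((grays, hist[lo:hi + 1]))
    zmin = None
    for idx in order:
        g = int(grays[idx])
        if zmin is not None:
            iterations += 1       # a re-pick is one repair step
        zmin = g
        if abs(g - zmid) < _X_DISTANCE or iterations >= max_iter:
            break
    valley_ok = zmin is not None and abs(zmin - zmid) < _X_DISTANCE

    accepted = None
    binary_mean = None
    t_lo, t_hi = T_WINDOW
    max_d = max(abs(zmid - t_lo), abs(t_hi - zmid))
    for d in range(0, max_d + 1):
        if accepted is not None or iterations >= max_iter:
            break
        for t in ([zmid] if d == 0 else [zmid - d, zmid + d]):
            if not (t_lo <= t <= t_hi):
                continue
            if iterations >= max_iter:
                break
            iterations += 1
            zc = _zcheck(hist, t)
            if not (ztotal * _CHECK_LO <= zc <= ztotal * _CHECK_HI):
                continue
            mean = float(hist[t + 1:].sum()) / ztotal
            if MEAN_WINDOW[0] < mean < MEAN_WINDOW[1]:
                accepted, binary_mean = t, mean
                break

    converged = valley_ok and accepted is not None
    if converged:
        T = accepted
    else:
        T = otsu_threshold(img)
        binary_mean = float(hist[T + 1:].sum()) / ztotal
    stats = HistogramStats(zmin=int(zmin), lmax=stats0.lmax, rmax=stats0.rmax,
                           zmid=zmid, t0=int(T), ztotal=ztotal,
                           zcheck=_zcheck(hist, int(T)))
    return ThresholdResult(T=int(T), stats=stats, iterations=iterations,
                           converged=converged, binary_mean=float(binary_mean))
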