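"""Synthetic periapical-radiograph (PA) phantoms with known ground truth.

A phantom emulates the three intensity targets of a PA image — teeth,
gingiva/alveolar band, and background — as flat gray levels: bright
vertical tooth lobes with rounded crowns (one or two roots each), darker
interdental gap strips between neighbouring teeth, a mid-gray gingiva band
across the lower part of the frame, an optional dark furcation wedge
between double roots (the lesion), a global horizontal illumination
gradient, and additive Gaussian noise.  Ground truth (gap columns, tooth
boxes, per-tooth labels) is recorded before gradient and noise are
applied, so it is exact regardless of noise level.

Coordinates are 0-based, row-major, y down; boxes are half-open
(r0, c0, r1, c1).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSpecError",
    "generate_phantom",
    "generate_corpus",
    "write_corpus",
    "DEFAULT_RANGES",
]


class PhantomSpecError(ValueError):
    """A phantom spec violates one of its invariants."""


# Geometry of a rendered tooth, as fractions of image height / slot width.
# Chosen once so that the binary (teeth+gingiva) fraction of a default
# phantom sits near 0.7, the composition a posterior PA is expected to
# have after binarization.
_CROWN_TOP = 0.05
_CROWN_BOTTOM = 0.46      # root bifurcation row
_ROOT_BOTTOM = 0.86
_GINGIVA_TOP = 0.58
_SHOULDER = 0.16          # elliptical crown shoulder height (of H)
_TOOTH_MARGIN = 0.15      # slot fraction left clear on each side
_GAP_HALFWIDTH = 2        # gap strip spans [gap_x-2, gap_x+2]
_SINGLE_ROOT_HALF = 0.27  # of tooth width
_DOUBLE_ROOT_HALF = 0.15  # of tooth width, each root
_DOUBLE_ROOT_OFFSET = 0.32  # root center offset from tooth center, of width
_WEDGE_TOP_PAD = 0.04     # wedge apex sits this far below the bifurcation
_WEDGE_BOTTOM = 0.80      # wedge base row (of H)


@dataclass
class PhantomSpec:
    width: int = 300
    height: int = 220
    n_teeth: int = 3
    roots_per_tooth: list[int] = field(default_factory=lambda: [1, 2, 1])
    lesion_flags: list[bool] = field(default_factory=lambda: [False, False, False])
    background_level: int = 30
    gingiva_level: int = 110
    tooth_level: int = 140
    gap_level: int = 40
    illumination_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_teeth <= 5):
            raise PhantomSpecError("n_teeth must be in 1..5")
        if len(self.roots_per_tooth) != self.n_teeth:
            raise PhantomSpecError("len(roots_per_tooth) must equal n_teeth")
        if len(self.lesion_flags) != self.n_teeth:
            raise PhantomSpecError("len(lesion_flags) must equal n_teeth")
        if any(r not in (1, 2) for r in self.roots_per_tooth):
            raise PhantomSpecError("roots_per_tooth entries must be 1 or 2")
        for name in ("background_level", "gingiva_level", "tooth_level", "gap_level"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise PhantomSpecError(f"{name} must be in 0..255")
        if not (self.gap_level < self.gingiva_level < self.tooth_level):
            raise PhantomSpecError("levels must satisfy gap < gingiva < tooth")
        if self.width < 60 * self.n_teeth:
            raise PhantomSpecError("width must be >= 60 * n_teeth")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    gap_x: list[int]
    tooth_boxes: list[tuple[int, int, int, int]]
    labels: list[str]
    root_counts: list[int]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        d["tooth_boxes"] = [tuple(b) for b in d["tooth_boxes"]]
        return cls(**d)


def _render_tooth(canvas: np.ndarray, spec: PhantomSpec, x0: int, x1: int,
                  roots: int, lesion: bool) -> tuple[int, int, int, int]:
    """Paint one tooth into ``canvas``; return its bounding box."""
    H = spec.height
    r_ct = int(round(_CROWN_TOP * H))
    r_cb = int(round(_CROWN_BOTTOM * H))
    r_rb = int(round(_ROOT_BOTTOM * H))
    tw = x1 - x0
    cx = (x0 + x1 - 1) / 2.0

    # crown: full tooth width with an elliptical shoulder at the top
    cols = np.arange(x0, x1)
    u = np.clip(np.abs(cols - cx) / (tw / 2.0), 0.0, 1.0)
    drop = np.round(_SHOULDER * H * (1.0 - np.sqrt(1.0 - u ** 2))).astype(int)
    for c, d in zip(cols, drop):
        canvas[r_ct + d:r_cb, c] = spec.tooth_level

    # roots
    if roots == 1:
        half = max(2, int(round(_SINGLE_ROOT_HALF * tw)))
        lo = int(round(cx - half))
        hi = int(round(cx + half)) + 1
        canvas[r_cb:r_rb, lo:hi] = spec.tooth_level
    else:
        half = max(2, int(round(_DOUBLE_ROOT_HALF * tw)))
        off = int(round(_DOUBLE_ROOT_OFFSET * tw))
        inner_edges = []
        for s in (-1, +1):
            c0 = int(round(cx + s * off - half))
            c1 = int(round(cx + s * off + half)) + 1
            canvas[r_cb:r_rb, c0:c1] = spec.tooth_level
            inner_edges.append(c1 if s < 0 else c0)
        # furcation region between the roots: alveolar bone when healthy,
        # dark wedge (apex at the bifurcation, widening downward) when not
        f0, f1 = inner_edges
        r_f = r_cb + int(round(_WEDGE_TOP_PAD * H))
        canvas[r_f:r_rb, f0:f1] = spec.gingiva_level
        if lesion:
            r_wb = int(round(_WEDGE_BOTTOM * H))
            max_half = (f1 - f0) / 2.0
            fc = (f0 + f1 - 1) / 2.0
            for r in range(r_f, r_wb):
                frac = (r - r_f) / max(1, (r_wb - 1 - r_f))
                wh = max_half * frac
                lo = int(np.ceil(fc - wh))
                hi = int(np.floor(fc + wh)) + 1
                if hi > lo:
                    canvas[r, lo:hi] = spec.gap_level
    return (r_ct, x0, r_rb, x1)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render one phantom. Deterministic for a fixed ``spec.seed``."""
    spec.validate()
    H, W, n = spec.height, spec.width, spec.n_teeth
    canvas = np.full((H, W), float(spec.background_level))

    # gingiva / alveolar band
    canvas[int(round(_GINGIVA_TOP * H)):, :] = spec.gingiva_level

    # slot boundaries and interdental gap strips (full height)
    bounds = [int(round(W * i / n)) for i in range(n + 1)]
    gap_x = bounds[1:-1]
    for g in gap_x:
        canvas[:, max(0, g - _GAP_HALFWIDTH):min(W, g + _GAP_HALFWIDTH + 1)] = spec.gap_level

    boxes, labels = [], []
    for i in range(n):
        s0 = bounds[i] + (_GAP_HALFWIDTH + 1 if i > 0 else 0)
        s1 = bounds[i + 1] - (_GAP_HALFWIDTH + 1 if i < n - 1 else 0)
        margin = max(3, int(round(_TOOTH_MARGIN * (s1 - s0))))
        x0, x1 = s0 + margin, s1 - margin
        lesion = bool(spec.lesion_flags[i]) and spec.roots_per_tooth[i] == 2
        boxes.append(_render_tooth(canvas, spec, x0, x1,
                                   spec.roots_per_tooth[i], lesion))
        labels.append("lesion" if lesion else "normal")

    truth = PhantomTruth(gap_x=list(map(int, gap_x)), tooth_boxes=boxes,
                         labels=labels, root_counts=list(spec.roots_per_tooth))

    if spec.illumination_slope != 0.0:
        canvas = canvas + spec.illumination_slope * (np.arange(W) - (W - 1) / 2.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    img = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    return img, truth


# Corpus generation ----------------------------------------------------------

DEFAULT_RANGES: dict = {
    "width": (240, 320),
    "height": (180, 240),
    "n_teeth": (2, 4),
    "double_root_prob": 0.5,
    "lesion_fraction": 0.5,
    "noise_sd": (4.0, 4.0),
    "illumination_slope": (-0.04, 0.04),
}


def generate_corpus(n_images: int, spec_ranges: dict | None = None,
                    seed: int = 0) -> list[tuple[np.ndarray, PhantomTruth]]:
    """Draw ``n_images`` phantoms with parameters sampled from ``spec_ranges``.

    Each image gets an independent sub-seed derived from ``seed``, so the
    corpus is reproducible from the master seed alone.  ``lesion_fraction``
    controls the probability that a double-rooted tooth carries a furcation
    lesion (class balance).
    """
    if n_images < 1:
        raise PhantomSpecError("n_images must be >= 1")
    if spec_ranges is not None and len(spec_ranges) == 0:
        raise PhantomSpecError("spec_ranges must not be empty")
    ranges = dict(DEFAULT_RANGES)
    if spec_ranges:
        unknown = set(spec_ranges) - set(DEFAULT_RANGES)
        if unknown:
            raise PhantomSpecError(f"unknown spec_ranges keys: {sorted(unknown)}")
        ranges.update(spec_ranges)

    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2 ** 31 - 1, size=n_images)
    out = []
    for k in range(n_images):
        rng = np.random.default_rng(int(sub_seeds[k]))
        n_teeth = int(rng.integers(ranges["n_teeth"][0], ranges["n_teeth"][1] + 1))
        roots = [2 if rng.random() < ranges["double_root_prob"] else 1
                 for _ in range(n_teeth)]
        flags = [r == 2 and rng.random() < ranges["lesion_fraction"]
                 for r in roots]
        spec = PhantomSpec(
            width=int(rng.integers(ranges["width"][0], ranges["width"][1] + 1)),
            height=int(rng.integers(ranges["height"][0], ranges["height"][1] + 1)),
            n_teeth=n_teeth,
            roots_per_tooth=roots,
            lesion_flags=flags,
            illumination_slope=float(rng.uniform(*ranges["illumination_slope"])),
            noise_sd=float(rng.uniform(*ranges["noise_sd"])),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        out.append(generate_phantom(spec))
    return out


def write_corpus(corpus, out_dir) -> Path:
    """Write PNGs + truth JSON sidecars and a manifest CSV; return manifest path."""
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (img, truth) in enumerate(corpus):
        name = f"phantom_{k:04d}"
        iio.imwrite(out_dir / f"{name}.png", img)
        (out_dir / f"{name}.json").write_text(truth.to_json())
        rows.append({"image": f"{name}.png", "truth": f"{name}.json",
                     "labels": ";".join(truth.labels)})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
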