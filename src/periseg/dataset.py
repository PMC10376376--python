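"""Flip augmentation, stratified train/validation split, and model-input
resizing for tooth tiles.

Augmentation produces the original plus horizontal, vertical and reverse
(180-degree) flips — 4 variants per tile, all inheriting the source label.
The split is decided on SOURCE tiles before any augmentation, so no
variant of a training tile can leak into validation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mask import ToothTile

__all__ = ["TileDataset", "augment", "split", "resize_for_model",
           "materialize"]

_FLIP_SUFFIXES = ("", "#hflip", "#vflip", "#reverse")


@dataclass
class TileDataset:
    tiles: list[ToothTile]
    split_assignment: list[str]          # "train" / "val" per source tile
    seed: int = 0

    def subset(self, which: str) -> list[ToothTile]:
        return [t for t, s in zip(self.tiles, self.split_assignment)
                if s == which]


def _clone(tile: ToothTile, pixels: np.ndarray, suffix: str) -> ToothTile:
    return ToothTile(pixels=pixels, source_id=tile.source_id + suffix,
                     left_line=tile.left_line, right_line=tile.right_line,
                     threshold_T=tile.threshold_T, label=tile.label,
                     row0=tile.row0, col0=tile.col0)


def augment(tile: ToothTile) -> list[ToothTile]:
    """[original, horizontal flip, vertical flip, reverse (180 deg)]."""
    p = tile.pixels
    variants = (p.copy(), np.fliplr(p), np.flipud(p), np.flipud(np.fliplr(p)))
    return [_clone(tile, v, sfx) for v, sfx in zip(variants, _FLIP_SUFFIXES)]


def split(tiles: list[ToothTile], ratio: float = 0.7,
          seed: int = 0) -> TileDataset:
    """Stratified source-tile split.

    The training set holds round(ratio * n) tiles overall; the per-class
    quotas are apportioned by largest remainder, so each class's training
    proportion is within one tile of ``ratio``.  Deterministic for a
    fixed seed.
    """
    if len(tiles) < 2:
        raise ValueError("need at least 2 source tiles")
    labels = sorted({t.label for t in tiles})
    if len(labels) < 2:
        raise ValueError("both classes must be present in the source tiles")
    n = len(tiles)
    n_train = int(np.floor(ratio * n + 0.5))
    by_class = {lab: [i for i, t in enumerate(tiles) if t.label == lab]
                for lab in labels}
    quotas = {lab: ratio * len(ix) for lab, ix in by_class.items()}
    base = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    leftover = n_train - sum(base.values())
    remainders = sorted(labels, key=lambda lab: (-(quotas[lab] - base[lab]), lab))
    for lab in remainders:
        if leftover <= 0:
            break
        if base[lab] < len(by_class[lab]):
            base[lab] += 1
            leftover -= 1
    rng = np.random.default_rng(seed)
    assignment = ["val"] * n
    for lab in labels:
        ix = np.array(by_class[lab])
        rng.shuffle(ix)
        for i in ix[:base[lab]]:
            assignment[int(i)] = "train"
    return TileDataset(tiles=list(tiles), split_assignment=assignment,
                       seed=seed)


def materialize(dataset: TileDataset, augment_train: bool = True,
                augment_val: bool = False) -> dict[str, list[ToothTile]]:
    """Expand the split into concrete per-split tile lists, augmenting the
    requested splits.  Variants inherit their source's split, so there is
    no leakage by construction."""
    out: dict[str, list[ToothTile]] = {"train": [], "val": []}
    for tile, which in zip(dataset.tiles, dataset.split_assignment):
        do_aug = augment_train if which == "train" else augment_val
        out[which].extend(augment(tile) if do_aug else [tile])
    return out


def resize_for_model(tile: ToothTile, side: int = 224) -> np.ndarray:
    """Aspect-preserving resize to ``side`` x ``side`` x 3 (uint8).

    The tile is scaled to fit, zero-padded equally on the short axis, and
    the gray channel is replicated three times.
    """
    from .util import fit_to_square

    if tile.pixels.size == 0:
        raise ValueError("empty tile")
    sq = np.clip(np.floor(fit_to_square(tile.pixels, side) + 0.5), 0, 255)
    return np.repeat(sq.astype(np.uint8)[:, :, None], 3, axis=2)
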