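"""End-to-end orchestration: preprocess -> threshold -> segment -> mask ->
dataset -> classify, with per-stage artifacts written to a run directory.

The per-image flow is: grayscale conversion, Gaussian high-boost
enhancement, bright-extreme redistribution, adaptive thresholding and
binarization, vertical projection, candidate gap columns (candidates whose
projection sum is not clearly interdental — above ``gap_sum_fraction`` of
the median column sum — are dropped before line fitting), tilt
optimization per line, then per tooth region: vertical trimming, outward
line expansion, masking and tile extraction.  When phantom truth sidecars
sit next to the input images the tiles are labelled by truth-box
containment and a classifier is trained and evaluated on the tile corpus.
"""
from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import classify, dataset as dataset_mod, mask as mask_mod
from . import preprocess, segment, threshold
from .config import PipelineConfig
from .phantom import PhantomTruth, generate_corpus, write_corpus

__all__ = ["process_image", "run_pipeline", "make_fixtures",
           "detect_lines", "FIXTURE_PRESETS"]


def detect_lines(binary: np.ndarray, config: PipelineConfig) -> list[segment.SegLine]:
    """Projection-profile candidates, filtered and tilt-optimized."""
    H, W = binary.shape
    profile = segment.vertical_projection(binary)
    cands = segment.find_gap_candidates(profile, config.max_lines,
                                        config.min_gap)
    cutoff = config.gap_sum_fraction * float(np.median(profile.sums))
    kept = [x for x in cands if profile.sums[x] <= cutoff]
    shift = config.shift_range if config.shift_range is not None else W // 10
    return [segment.rotate_tangent(binary, x, shift) for x in kept]


def _label_regions(lines, width: int, truth: PhantomTruth | None) -> dict[int, str]:
    """Region index -> label, by locating each truth tooth-box center."""
    if truth is None:
        return {}
    out: dict[int, str] = {}
    centers = sorted([s.mean_x for s in lines])
    for box, label in zip(truth.tooth_boxes, truth.labels):
        cx = (box[1] + box[3]) / 2.0
        region = sum(1 for c in centers if c < cx)
        out[region] = label
    return out


def process_image(img: np.ndarray, config: PipelineConfig,
                  truth: PhantomTruth | None = None,
                  source_id: str = "img") -> dict:
    """Run the whole per-image flow; returns stage artifacts and stats."""
    gray = preprocess.to_grayscale(img)
    d0 = config.d0 if config.d0 is not None else preprocess.default_cutoff(gray.shape)
    fspec = preprocess.FilterSpec(d0=d0, strength=config.strength)
    enhanced = preprocess.enhance(gray, fspec)
    redistributed = preprocess.redistribute_bright(enhanced, config.bright_cutoff)
    result = threshold.adaptive_threshold(redistributed, config.max_iter)
    binary = threshold.binarize(redistributed, result.T)
    lines = detect_lines(binary, config)

    W = gray.shape[1]
    labels = _label_regions(lines, W, truth)
    tiles = []
    n_regions = len(lines) + 1
    for i in range(n_regions):
        if truth is not None and i not in labels:
            continue                      # region holds no true tooth
        left, right = segment.pair_lines_for_tooth(lines, i, W)
        center = (left.mean_x + right.mean_x) / 2.0
        left = segment.trim_outer_endpoint(left, center)
        right = segment.trim_outer_endpoint(right, center)
        left, right = mask_mod.expand_lines(left, right, W,
                                            config.expansion_divisor)
        try:
            tile = mask_mod.extract_tile(enhanced, left, right,
                                         pad=config.tile_pad,
                                         source_id=f"{source_id}/region{i}",
                                         threshold_T=result.T,
                                         label=labels.get(i, "unknown"))
        except ValueError:
            continue
        tiles.append(tile)
    return {
        "source_id": source_id,
        "enhanced": enhanced,
        "binary": binary,
        "threshold": result,
        "lines": lines,
        "tiles": tiles,
    }


def _write_image_artifacts(out_dir: Path, res: dict) -> list[dict]:
    import imageio.v3 as iio

    stem = Path(res["source_id"]).stem
    iio.imwrite(out_dir / f"{stem}_enhanced.png", res["enhanced"])
    iio.imwrite(out_dir / f"{stem}_binary.png",
                (res["binary"] * 255).astype(np.uint8))
    tr = res["threshold"]
    (out_dir / f"{stem}_report.json").write_text(json.dumps({
        "threshold": asdict(tr.stats) | {
            "T": tr.T, "iterations": tr.iterations,
            "converged": tr.converged, "binary_mean": tr.binary_mean},
        "lines": [asdict(s) for s in res["lines"]],
    }))
    rows = []
    for k, tile in enumerate(res["tiles"]):
        name = f"{stem}_tile{k}"
        iio.imwrite(out_dir / f"{name}.png", tile.pixels)
        (out_dir / f"{name}.json").write_text(json.dumps({
            "source_id": tile.source_id, "label": tile.label,
            "threshold_T": tile.threshold_T,
            "left_line": asdict(tile.left_line),
            "right_line": asdict(tile.right_line),
            "row0": tile.row0, "col0": tile.col0}))
        rows.append({"path": f"{name}.png", "label": tile.label,
                     "source_id": tile.source_id})
    return rows


def run_pipeline(images: list, config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Process image files (with optional phantom-truth JSON sidecars),
    write all artifacts under ``out_dir``, and — when labelled tiles of
    both classes exist — train and evaluate the classifier.

    Returns the machine-readable run report (also written as
    ``run_report.json``)."""
    import imageio.v3 as iio
    import pandas as pd

    config = config or PipelineConfig()
    config.validate()
    out_dir = Path(out_dir) if out_dir is not None else Path("periseg_run")
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    report: dict = {"schema_version": 1, "config": _config_dict(config),
                    "images": [], "errors": []}
    manifest_rows = []
    all_tiles = []
    with open(log_path, "w") as log:
        for path in images:
            path = Path(path)
            t_start = time.monotonic()
            try:
                img = iio.imread(path)
                sidecar = path.with_suffix(".json")
                truth = (PhantomTruth.from_json(sidecar.read_text())
                         if sidecar.exists() else None)
                res = process_image(img, config, truth, source_id=path.name)
                rows = _write_image_artifacts(out_dir, res)
                manifest_rows.extend(rows)
                all_tiles.extend(res["tiles"])
                tr = res["threshold"]
                entry = {"image": path.name, "T": tr.T,
                         "converged": tr.converged,
                         "binary_mean": tr.binary_mean,
                         "n_lines": len(res["lines"]),
                         "n_tiles": len(res["tiles"])}
                report["images"].append(entry)
                log.write(json.dumps({"stage": "image", "id": path.name,
                                      "seconds": time.monotonic() - t_start}
                                     | entry) + "\n")
            except Exception as exc:                       # per-file isolation
                report["errors"].append({"image": path.name, "error": str(exc)})
                log.write(json.dumps({"stage": "image", "id": path.name,
                                      "error": str(exc)}) + "\n")

    labelled = [t for t in all_tiles if t.label in classify.CLASSES]
    if labelled and len({t.label for t in labelled}) == 2:
        try:
            ds = dataset_mod.split(labelled, config.split_ratio, config.seed)
            for row, tile in zip(manifest_rows, all_tiles):
                if tile in ds.tiles:
                    row["split"] = ds.split_assignment[ds.tiles.index(tile)]
            model, train_log = classify.train(ds, config.train)
            train_log.to_csv(out_dir / "train_log.csv", index=False)
            classify.save_model(model, config.train, out_dir / "model.npz")
            cm = classify.evaluate(model, ds.subset("val"))
            metrics = classify.metrics_from_confusion(cm)
            report["confusion_matrix"] = np.asarray(cm.cells).tolist()
            report["metrics"] = metrics.rounded()
            (out_dir / "metrics.json").write_text(json.dumps(report["metrics"]))
        except ValueError as exc:       # corpus too small/skewed to train on
            report["training_error"] = str(exc)
    pd.DataFrame(manifest_rows).to_csv(out_dir / "tiles_manifest.csv",
                                       index=False)
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
    if not report["images"]:
        raise RuntimeError("no image could be processed")
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


FIXTURE_PRESETS = {
    "default": dict(n_images=200, ranges=[{}]),
    "noise-sweep": dict(n_images=50, ranges=[{"noise_sd": (s, s)}
                                             for s in (0.0, 2.0, 4.0, 8.0)]),
    "tooth-count-sweep": dict(n_images=20,
                              ranges=[{"n_teeth": (n, n),
                                       "width": (max(240, 62 * n), 320)}
                                      for n in (1, 2, 3, 4, 5)]),
    "lesion-balance": dict(n_images=20,
                           ranges=[{"lesion_fraction": f,
                                    "double_root_prob": 1.0}
                                   for f in (0.0, 0.25, 0.5, 0.75, 1.0)]),
}


def make_fixtures(out_dir, preset: str = "default", seed: int = 0):
    """Write one of the standard phantom corpora; returns the corpus
    (list of (image, truth)).  Reruns with the same seed are identical."""
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset '{preset}'")
    spec = FIXTURE_PRESETS[preset]
    out_dir = Path(out_dir)
    corpus = []
    for k, ranges in enumerate(spec["ranges"]):
        corpus.extend(generate_corpus(spec["n_images"],
                                      ranges if ranges else None,
                                      seed=seed + k))
    write_corpus(corpus, out_dir)
    return corpus
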