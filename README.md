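# periseg

Automated processing of periapical dental radiographs (PAs): contrast
enhancement, adaptive binarization, per-tooth segmentation, single-tooth
masking/cropping, and a small CNN harness that classifies each tooth tile
as *normal* or *furcation lesion* (periodontal bone loss between the
roots of a multi-rooted tooth, visible as a dark region at the
bifurcation).  It is aimed at researchers building or evaluating
radiograph-analysis pipelines who need every stage reproducible and
testable without access to clinical images: a synthetic phantom
generator with exact ground truth ships as a first-class module.

## The method

1. **High-boost enhancement.**  The image spectrum is multiplied by the
   Gaussian high-pass transfer function
   `H(u,v) = 1 − exp(−D²(u,v) / (2·D0²))` and the scaled high-frequency
   component is added back (`img + k·HP(img)`), sharpening tooth
   contours while leaving flat regions untouched.
2. **Bright redistribution.**  Gray levels above 170 are remapped into
   (140, 170] so lighting extremes cannot distort the histogram.
3. **Adaptive threshold.**  With `Lmax` / `Rmax` the modal gray levels
   in [30, 90] / [91, 170] and `Zmin` the histogram valley in [60, 120],
   the initial threshold is `Zmid = (Lmax + Rmax)/2`; a threshold `T` is
   accepted only if `|Zmin − Zmid| < 15`, the pixel mass in `[T, 170]`
   lies in `[2/3, 5/6]` of the total, `T ∈ [80, 95]`, and the binarized
   mean is in (0.6, 0.85), iterating (valley re-pick, then nearest
   candidates around `Zmid`) until the constraints hold.  Otsu and
   iterative-mean thresholds are included as baselines and fallback.
4. **Segmentation.**  Per-column sums of the binary image dip at the
   interdental spaces; the smallest sums (spaced at least one tooth
   width apart) seed separation lines whose endpoint x-coordinates are
   shifted independently to minimize the white pixels crossed — rotating
   the line instead of the image.
5. **Mask & crop.**  Each tooth's two lines are trimmed vertically,
   pushed outward by `width/30`, everything outside is blanked, and the
   tooth tile is cropped with full provenance.
6. **Classification.**  Tiles are flip-augmented (×4), split 7:3 before
   augmentation, and a pluggable backbone is trained with SGDM
   (lr 1e-4, ×0.2 every 5 epochs, batch 32) and evaluated via a 2×2
   confusion matrix (accuracy, precision, recall, F1; lesion positive).

See `docs/methods.md` for assumptions, parameter defaults, tie-break
rules and limitations.

## Worked example

```python
from pathlib import Path
from periseg import (generate_corpus, write_corpus, run_pipeline,
                     PipelineConfig, TrainConfig)

corpus = generate_corpus(60, {"double_root_prob": 1.0,
                              "lesion_fraction": 0.5}, seed=3)
write_corpus(corpus, "corpus")
cfg = PipelineConfig(train=TrainConfig(max_epoch=10, seed=3))
report = run_pipeline(sorted(Path("corpus").glob("phantom_*.png")),
                      cfg, "run")
print(report["images"][0])
print(report["metrics"], report["confusion_matrix"])
```

prints (about 7 s on one CPU):

```
{'image': 'phantom_0000.png', 'T': 87, 'converged': True,
 'binary_mean': 0.7035697272835536, 'n_lines': 3, 'n_tiles': 4}
{'accuracy': 94.3, 'recall': 87.0, 'precision': 100.0, 'f1': 93.0}
[[30, 3], [0, 20]]
```

For the first phantom the adaptive threshold accepted `T = 87`
(converged, binarized mean 0.70 — inside the (0.6, 0.85) window), three
separation lines were found between its four teeth, and four labelled
tiles were cropped.  Over the 60-image corpus, 176 tiles were extracted
and the classifier reached 94.3% validation accuracy; the confusion
matrix (rows = predicted normal/lesion, columns = actual) shows 3
lesions missed and no false alarms.  The run directory holds the
enhanced and binary PNGs, line and threshold reports, tile PNGs with
JSON sidecars, the tile manifest, training log and saved model.

The same flow is available from the shell:

```sh
periseg make-fixtures corpus --preset default --seed 3
periseg run corpus/phantom_00*.png --out-dir run
periseg threshold corpus/phantom_0000.png --out bin.png --report t.json
```

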