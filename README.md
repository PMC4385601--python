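# cervicell

Morphometric feature quantification and rule-based abnormality grading for
cervical squamous epithelial cells.

Given an RGB microscopy image plus two label masks (cell regions and nucleus
regions, produced by any segmentation), the package:

1. **regions** — cleans the masks with binary morphology, extracts labeled
   regions (area, chain-code perimeter, sub-pixel centroid, traced outer
   boundary) and pairs each nucleus with its owner cell by minimum centroid
   distance;
2. **features** — quantifies per-cell descriptors: nucleus size ratio
   `grad_A`, nucleus/cytoplasm ratio `P` and its ratio to normal `grad_P`,
   circularity `C` (isoperimetric quotient), compactness `E` (unit-square
   convex-hull solidity), the radial-signature shape descriptor `N`
   (significant peaks + valleys of the centroid-to-boundary distance curve,
   smoothed with a truncated Fourier series), and mean RGB color strength
   per compartment;
3. **decision** — flags abnormal cells with five criteria evaluated in the
   order 1, 4, 5, 2, 3 (size ratios; jacinth cytoplasm bands; dark nucleus
   bounds; shape floors; boundary extrema), grades abnormal cells
   LSIL/HSIL/SCC with strict-inequality rules (SCC checked before LSIL),
   and evaluates predicted vs reviewed grades (confusion matrix, accuracy,
   severity-tolerant misclassification split);
4. **apcluster** — deterministic affinity propagation over per-feature
   values to derive exemplars ("sample centers"), per-cluster value ranges
   and gap-midpoint threshold suggestions;
5. **synthetic** — generates stained-cell scenes (elliptical-to-lobed nuclei
   inside cytoplasm blobs, per-stage color/size profiles, Gaussian channel
   noise) with exact rasterized ground truth, so the whole pipeline is
   testable without clinical images.

All thresholds live in `NormalReference` / `GradingRules` and can be
overridden from a YAML config; nothing is hard-coded.

## CLI

```bash
cervicell simulate --out-dir scene/ --n 40 --mix 0.1,0.3,0.3,0.3 --seed 7
cervicell extract  --image scene/image.png --cell-mask scene/cell_mask.png \
                   --nucleus-mask scene/nucleus_mask.png --out features.csv
cervicell detect   --features features.csv --out detected.csv
cervicell grade    --features features.csv --out graded.csv
cervicell cluster  --features features.csv --column grad_A --out clusters.json
cervicell evaluate --predicted pred.csv --actual actual.csv --out eval.json
```

Every subcommand accepts `--config cfg.yaml` with blocks `reference`,
`features`, `rules`, `ap` (see `cervicell.cli.RunConfig`).  CSV floats are
written with 4 decimals so reruns are byte-identical; malformed input exits
with status 2.

## Conventions

* 0-based `(row, col)` pixel indexing; centroids sub-pixel; tabular output
  uses `centroid_x = col`, `centroid_y = row`.
* 8-connectivity for labeling; clockwise Moore tracing for boundaries; the
  perimeter uses a corner-corrected chain-code estimator.
* All criterion and grading inequalities are strict: values exactly at a
  threshold do not trigger.
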