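# lobulescan

Object-based analysis of brightfield whole-slide images of breast tissue:
detects normal mammary lobules and the coherent tumor mass at low
resolution, quantifies ER/PR nuclear positivity per lobule at full
resolution, and relates positivity to each lobule's distance from the
tumor border.

## What it does

1. **Preprocess** — downsample to a working resolution (default 10%,
   0.56 → 5.6 µm/pixel, nearest neighbor), derive a texture layer
   (per-pixel standard deviation to the 8-neighborhood of the blue channel,
   median 3×3 + Gaussian 11×11), and separate tissue from background
   (Otsu on smoothed brightness, small enclosed islands reclassified).
2. **Segment** — texture-weighted multiresolution region merging from
   single pixels, one merge tree cut at scales 100, 80, 60, 40, 20
   (cost threshold = scale²), giving five strictly nested levels with
   per-segment spectral, geometric and relational features. The texture
   channel is weighted twice as much as R, G, B.
3. **Classify lobules** — candidates at the four coarsest levels must meet
   *all* of: mean stddev-n in 15–36, area 2000–14000 px²
   (0.0627–0.439 mm²), roundness ≤ 1.3, difference of means ≥ 5, border
   contrast ≥ 0.4. Candidates are then refined coarse→fine through the
   hierarchy: divergent sub-segments drop a candidate, failing peripheral
   sub-segments are trimmed, and a final pass merges adjacent
   reduced-criteria segments. Optional pathologist review (TP/FP/FN)
   gates the downstream evaluation.
4. **Detect tumor** — seeded region growing over non-lobule segments:
   seeds within ±0.1 of the median mean stddev-n, neighbors join while
   within 2 units of the running region mean and sharing ≥ 20% of their
   border; holes closed and components < 1/3 of the largest removed.
5. **Count nuclei** — per lobule at full resolution: hue-saturation-density
   color deconvolution into DAB and hematoxylin densities, thresholding at
   0.2 with stain dominance, watershed splitting, cuts at concave dents
   > 30°, border smoothing and a minimum-area filter.
6. **Spatial analysis** — distance from lobule center to the nearest tumor
   border pixel, binned as adjacent (< 0.5 mm), intermediate (0.5–2 mm),
   distant (> 2 mm); per-case six-column summary table, OLS regression of
   positivity (%) on distance (mm), and a scatter plot.

A fully synthetic slide generator (`lobulescan.synthetic`) renders
calibrated fixtures — tubule-ring lobules, a dense tumor sheet, textured
stroma, Beer–Lambert stain mixing — with exact ground truth, so the whole
pipeline is testable without clinical data.

## CLI

```sh
lobulescan synth -o fixtures/ --seed 0          # synthetic slide + ground truth
lobulescan run fixtures/slide.tif -o out/ --pixel-size-um 0.56
lobulescan review out/ review.csv               # apply TP/FP labels, re-summarize
lobulescan report out/                          # rebuild the summary CSV
```

`run` writes per-level label TIFFs and a feature CSV, the lobule label
image and table, the tumor mask and border, a per-nucleus CSV, the
six-column case summary, regression JSON, a scatter PNG, and a JSON run
report with per-stage timings and counts. Configuration is YAML
(`lobulescan.config.PipelineConfig`); every threshold defaults to the
published rule set.

## Layout

| module | role |
| --- | --- |
| `lobulescan.rasters` | calibrated raster types, TIFF/PNG I/O |
| `lobulescan.preprocess` | downsampling, texture layer, tissue mask |
| `lobulescan.mrseg` | multiresolution region merging, hierarchy, features |
| `lobulescan.lobule_classify` | candidate rules, hierarchical refinement, review |
| `lobulescan.tumor_detect` | seeded growth of the coherent tumor mass |
| `lobulescan.stain_nuclei` | HSD deconvolution, watershed, dent cuts, counts |
| `lobulescan.spatial_analysis` | distance bins, summaries, regression |
| `lobulescan.synthetic` | ground-truth slide generator |
| `lobulescan.pipeline` / `lobulescan.cli` | orchestration and commands |
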