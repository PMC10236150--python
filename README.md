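# slicetrack

Quantitative analysis of immune-cell migration in living tumor-slice
time-lapse stacks, plus 3D Matrigel invasion quantification and the
closed-form cytotoxicity/tumor-volume assay formulas.

The package covers the full measurement chain for two-compartment
(tumor-islet vs ECM) multichannel confocal movies:

| module | what it does |
| --- | --- |
| `slicetrack.synth` | synthetic slice movies and Matrigel Z-stacks with known ground truth (tracks, region masks, drift) |
| `slicetrack.image_io` | calibrated OME-TIFF stack I/O, per-plane region masks, mask derivation from the ECM (fibronectin) channel |
| `slicetrack.preprocess` | sample-drift correction from the ECM channel (feature matching with phase-correlation fallback), bleed-through/background correction, median smoothing |
| `slicetrack.detect` | per-frame intensity segmentation, size filtering, Z-collapse to the maximal-area plane |
| `slicetrack.track` | frame-to-frame linking (optimal assignment with gap memory), fragment merging (<10 µm and <2 frames apart), minimum-length filter |
| `slicetrack.metrics` | momentary speeds, pixel-overlap tumor/ECM localization, dwell fractions, per-acquisition summaries |
| `slicetrack.matrigel` | 3D nuclei segmentation (Otsu + distance-transform watershed), centroid invasion distances with 10th-percentile baseline, threshold fractions |
| `slicetrack.assays` | percent specific lysis (bioluminescence and ⁵¹Cr modalities), caliper tumor volume |
| `slicetrack.pipeline` / `slicetrack.cli` | end-to-end runs with provenance sidecars |

Because no raw imaging data are publicly available, the synthetic generator
is a first-class, tested component: cells move as persistent random walks
with compartment-dependent step length, the scene drifts globally, the ECM
channel bleeds into the cell channel, and Poisson-Gaussian noise is added
last; ground truth is emitted in specimen (drift-free) coordinates.

## CLI

```bash
# generate a synthetic slice movie (config keys mirror SceneConfig fields)
slicetrack simulate-slice --config scene.toml --seed 1 --out-dir scene/

# analyze it end to end (drift -> masks -> detect -> track -> metrics)
slicetrack analyze-slice --stack scene/stack.ome.tif \
    --masks-dir scene/masks --out-dir results/

# Matrigel invasion
slicetrack simulate-matrigel --n-cells 100 --seed 1 --out-dir mg/
slicetrack analyze-matrigel --stack mg/stack.tif --pixel-size 1.0 \
    --z-step 2.0 --out-dir mg_results/

# specific lysis from a per-well CSV (sample, modality, test, spontaneous, maximum)
slicetrack lysis --input wells.csv --out lysed.csv
```

Parameter precedence is default < TOML config < CLI flag; every effective
parameter is recorded in the `provenance.json` written beside the results.
Exit codes: 0 success, 2 configuration error, 3 data error.

Calibration (µm/px, z spacing, frame interval) is read from OME metadata
when present and must otherwise be supplied explicitly — it is never
silently defaulted.

## Conventions

- Pixel indices are 0-based; the physical position of a pixel center is
  `(index + 0.5) * pixel_size`. Plane `k` sits at `z = k * z_spacing`.
- Tracking distances are Euclidean in µm in the drift-corrected frame.
- Track merging is strict: gap of exactly 1 frame merges, 2 does not;
  distance of exactly 10 µm does not merge.
- A track is "high dwell" when ≥ 50% of its observed frames are
  tumor-localized; a single ECM-overlapping pixel makes a frame non-tumor.
- Percentiles use linear interpolation between order statistics.
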