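# amineblot

Calibrated quantification of free-amine blot papers from flatbed scans.

Colorimetric indicator papers blotted against seedling roots develop purple
spots wherever free amines (amino-acid exudates) were present. This package
turns scanned images of those papers into calibrated, per-pixel free-amine
concentration maps:

- **core_image** — 8-bit RGB / real-valued gray containers; the weighted
  grayscale conversion `0.30 R + 0.59 G + 0.11 B`; multiply blending;
  PNG/TIFF I/O.
- **spot_analysis** — magic-wand style tolerance-bounded flood fill, spot
  statistics, and automatic detection of the 3×3 calibration grid.
- **calibration** — Tukey-fence outlier-spot/outlier-paper rejection
  (fences `[Q1 − 0.5·IQR, Q3 + 0.5·IQR]` pooled per standard concentration),
  OLS calibration `intensity = slope·conc + intercept` with confidence
  intervals, inverse prediction with clamping, and resolution estimation.
- **visualization** — false-color concentration heatmaps on a standardized
  scale with a legend strip, and manual-registration root/blot multiply
  overlays.
- **phenotype_recipe** — segmented-line root lengths, two-day growth rates
  `R_D = (L_{D+2} − L_D)/2`, and mock-exudate free-amine accounting (the
  shipped 70X recipe totals 23.9 mM).
- **stats** — two-factor ANOVA (concentration/day + paper) with Tukey HSD
  pairwise comparisons and limit-of-detection determination vs the water
  control.
- **synthetic_fixtures** — ground-truthed synthetic calibration batches,
  blot images (exact weighted-intensity encoding with a purple tint), and
  partner root scans; every generator is deterministic per seed.

## CLI

One executable, `amineblot`, with subcommands mirroring the workflow
(exit codes: 0 success, 2 usage/config error, 3 data/validation error):

```bash
# generate a ground-truthed synthetic batch + blot + root scan
amineblot synth --out-dir demo --seed 1

# reject outlier papers and fit the calibration line
amineblot calibrate demo/batch.csv --out demo/model.json --report demo/report.json

# per-pixel concentration heatmap (legend ticks at the standards)
amineblot quantify demo/blot.png demo/model.json --out demo/heatmap.png --stats-csv demo/stats.csv

# multiply-blend the blot onto the desaturated root scan
amineblot overlay demo/root.png demo/blot.png --offset 0 0 --rotation 0 --out demo/overlay.png

# two-day growth rates from a length table
amineblot growth lengths.csv --out rates.csv

# limit of detection from intensity observations
amineblot lod observations.csv --alpha 0.01 --out lod.json
```

Configuration (grid geometry, standards, fence parameters, CI level,
colormap, magic-wand tolerance) is supplied as JSON or YAML via `--config`;
unknown keys are rejected.

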