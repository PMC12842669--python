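# radnorm

Adaptive normalization toolkit for 8-bit grayscale radiographs, with a
benchmarking harness and non-parametric comparison framework.

The core pipeline combines two steps:

1. **CDF-guided ROI cropping** — each axis of the image is projected into a
   grayscale-sum profile; the normalized cumulative mass places percentile
   cutoffs (defaults: 5–95% horizontally, 15–95% vertically) that discard
   low-density lateral background and the bright band above the clavicles.
2. **Histogram standardization** — a per-image affine transform matching the
   ROI's mean and standard deviation to fixed targets
   (0.4776·255 = 121.788 and 0.2238·255 = 57.069 on the 8-bit scale).

Baselines (fixed-range min–max scaling, dataset-level z-score), the partial
crop-only / histogram-only pipelines, evaluation metrics, a Friedman /
Nemenyi / exact-Wilcoxon comparison stage, and a deterministic synthetic
multi-domain radiograph phantom generator round out the package so the full
benchmark runs end-to-end without any external data.

## Modules

| module | contents |
| --- | --- |
| `radnorm.image_io` | `GrayImage` contract, PNG/JPEG grayscale I/O, CSV dataset manifests |
| `radnorm.roi_crop` | axis profiles, mass CDFs, percentile windows, `cdf_crop` |
| `radnorm.intensity_norm` | `minmax_scale`, `zscore_fit/apply`, `histogram_standardize`, `adaptive_normalize`, ablation variants, bilinear resize |
| `radnorm.phantom` | configurable multi-site chest-phantom generator with lesion labels |
| `radnorm.eval_metrics` | confusion counts, accuracy/precision/recall/F1/sensitivity/specificity |
| `radnorm.stats_compare` | exact Wilcoxon signed-rank, tie-corrected Friedman, Nemenyi critical difference, `compare_methods` |
| `radnorm.bench_harness` | patient-level stratified splits, geometric augmentation, classifier contract, factorial `run_matrix`, ablation report |

## CLI

```sh
radnorm phantom --n 50 --seed 0 --out data/            # synthetic dataset + manifest.csv
radnorm crop --report IN.png OUT.png                   # percentile ROI crop
radnorm normalize --method adaptive IN.png ... OUTDIR  # any normalization method
radnorm bench --config bench.yaml --out rundir/        # factorial benchmark
radnorm stats --scores rundir/results.csv --metric f1 --out report.csv
```

A minimal `bench.yaml`:

```yaml
datasets:
  phantom: data/manifest.csv
methods: [scaling, zscore, adaptive]
models: [logistic]
config:
  seeds: [42, 123, 456]
  input_size: [64, 64]
```

## Conventions

* Images are row-major with origin top-left; row = vertical axis (y), column
  = horizontal axis (x); crop windows are 0-based inclusive index ranges.
* Population (divide-by-N) standard deviations everywhere.
* Percentile retention rule: keep index `i` iff `lo < cdf[i] <= hi`; a
  degenerate axis falls back to its full extent and is flagged, never fatal.
* Histogram-standardized outputs are clipped to [0, 255]; quantization
  rounds half away from zero. Pre-clip values are available via
  `histogram_standardize(..., clip=False)`.
* PNG round trips are bit-exact; JPEG is read-only.
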