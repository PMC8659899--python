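# roipulse

Anatomy-aware region-of-interest (ROI) assessment for facial-video remote
photoplethysmography (rPPG). The package bundles:

- **anatomy tables** — a 39-site facial skin-thickness table (mean epidermal
  and dermal thickness with relative ratios eRT/dRT/RT normalised by the
  thinnest site) and the mapping onto 31 evaluation regions, shipped as CSV
  resources;
- **ROI geometry** — even-odd polygon rasterization over pixel centers, 31
  region masks from a 468-point face-mesh landmark set (file-based landmark
  provider; no face-tracking dependency), per-region mean-RGB trace
  extraction, region-union combination, and a chrominance-threshold skin
  mask;
- **seven pulse-extraction methods** — GREEN, ICA (JADE, implemented here),
  CHROM, POS, SSR, PBV and LGI, plus shared detrend/band-pass preprocessing
  and Welch-peak windowed BPM estimation;
- **evaluation metrics** — MAE / RMSE / PCC, the composite rBS score
  `(ln(maxMAE−MAE+e) + ln(maxRMSE−RMSE+e))·|PCC|` with median ranking,
  TOP-k/BOT-k selection, and thickness / pixel-count rank correlations;
- **synthetic scenes** — seeded facial scenes with a planted blood-volume
  pulse whose per-region amplitude decreases with a configured skin-thickness
  parameter, plus illumination flicker, specular (achromatic) noise, sensor
  noise, skin texture, mask jitter and quantization; written in a
  UBFC-style on-disk layout (PNG frames + 3-line ground-truth text);
- **a pipeline/CLI** that runs dataset → masks → methods → BPM → metrics →
  rBS → ranking → summary tables.

## CLI

```sh
roipulse synth  --out scratch/ds --subjects 3 --preset mild --seed 1
roipulse run    --dataset scratch/ds --out scratch/results --methods POS,CHROM --combos
roipulse rank   --metrics scratch/results/metrics.csv --out scratch/ranked.csv
roipulse report --results scratch/results --out scratch/report
roipulse extract --subject scratch/ds/subject1 --out scratch/traces.csv
```

## Layout

```
src/roipulse/
  anatomy.py      thickness tables, relative ratios, 31 proposed regions
  geometry.py     landmarks, rasterization, masks, RGB traces, skin mask
  rppg/           jade.py (JADE ICA), methods.py (7 methods, BPM estimator)
  metrics.py      MAE/RMSE/PCC, rBS, median ranking, correlations
  synth.py        scene generator, noise presets, dataset writer
  datasets.py     subject-directory adapter (frames + ground truth)
  pipeline.py     orchestration, manifests, summary tables
  cli.py          click CLI
  data/           packaged CSV/JSON resources
```

Notes:

- The region→landmark polygon map (`data/region_polygons.json`) and the
  canonical frontal layout (`data/canonical_landmarks.csv`) are a stylised
  approximation of a frontal face over the 468-point topology; they are data
  files and can be replaced without code changes.
- `data/reference_region_scores.csv` holds published per-region benchmark
  medians, ranks and pixel counts used for regression checks and the
  acceptance report.
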