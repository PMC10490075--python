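# seedmorph

Seed morphometrics from RGB photographs of seeds on a dark background:
per-seed **length, width, projected area, and aspect ratio**, **seed
counting**, **pixel→millimetre calibration** from two points a known
distance apart, and **method-comparison statistics** (RMSE, MAE, RSE,
percent errors, linear-fit R²/slope/intercept). A synthetic scene
generator with analytic ground truth makes every stage testable with no
image downloads.

## How it works

* **Measurement** (`measure`): RGB → grayscale (BT.601) → global
  threshold 140/255 → one contour per 8-connected region → keep the
  *n* largest (small noise regions drop out automatically) → rotated
  bounding rectangle per seed (principal-axis oriented, minimum-area
  fallback; axis-aligned available via `--axis-aligned`). Projected
  area is the foreground pixel count of the stricter 170/255 mask
  inside each seed's contour. Pixel values convert to mm via the
  calibration scale.
* **Counting** (`count`): grayscale → 3×3 dilation → threshold 170/255
  → contour count above a 25 px noise floor. Overlapping seeds merge
  into one contour and are counted as one — a documented limitation,
  pinned by tests.
* **Calibration** (`calibrate`): pixels-per-mm = Euclidean pixel
  distance between two points / known mm (e.g. two ruler ticks 10 mm
  apart), persisted as JSON.
* **Validation** (`validate`): compares two measurement methods from a
  paired CSV; RSE uses df = n−2 by default and percent metrics are
  normalized by mean(standard) × 100.

## CLI

```bash
# calibrate from two points 250 px apart spanning 10 mm  -> 25 px/mm
seedmorph calibrate --p1 10,10 --p2 10,260 --mm 10 --out calib.json

# measure 5 seeds per image
seedmorph measure imgs/*.png --calib calib.json --n-seeds 5 --out measurements.csv

# count seeds per image
seedmorph count imgs/*.png --out counts.csv

# compare methods (CSV with 'observed' and 'standard' columns)
seedmorph validate length.csv --out report.csv --plot plots/

# generate synthetic ground-truth scenes
seedmorph synth --n-scenes 10 --seed 1 --out-dir synth/
```

Without `--calib`, `measure` still runs and leaves the mm columns
empty. A flat `key = value` config file can be passed with `--config`;
explicit flags win. Re-running any command on identical inputs yields
byte-identical CSVs (fixed 4-decimal formatting, deterministic
ordering).

Measurement CSV columns:
`image, seed_index, length_px, width_px, area_px, length_mm, width_mm,
area_mm2, aspect_ratio`.

## Package layout

| Module | Role |
| --- | --- |
| `seedmorph.imaging` | raster I/O, grayscale, dilation, thresholding |
| `seedmorph.morphometry` | contours, max-area selection, rectangles, projected area, `measure_seeds` |
| `seedmorph.calibration` | two-point px/mm calibration and conversions |
| `seedmorph.counting` | dilate→threshold→contour-count chain |
| `seedmorph.validation` | RMSE/MAE/RSE, percent metrics, OLS fit, prediction bands |
| `seedmorph.synthetic` | ground-truth scene generation and rendering |
| `seedmorph.cli` | `seedmorph` command group, config handling, CSV writers |
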