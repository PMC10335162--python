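# facemetrics

Landmark-based 2D facial anthropometry from frontal photographs.

The package turns named facial landmark sets (produced by any detector) into
absolute facial measurements by using the corneal white-to-white (WTW)
diameter as an in-image metric ruler:

- **`landmarks`** — landmark naming schema, CSV/JSON I/O, cohort tables.
- **`calibration`** — canthus-seeded region-based active-contour iris
  segmentation, least-squares circle fitting (Kåsa + Gauss-Newton
  refinement), left/right WTW averaging, and the pixel→millimeter
  calibration pinned to a reference corneal diameter (11.71 mm).
- **`measures`** — the per-subject battery: facial height/widths, nose and
  brow geometry, interpupillary distance, in-plane head-rotation correction,
  rotation-corrected canthal tilt, horizontal/vertical facial thirds
  (proportions sum to exactly 1), scleral show, and facial ratios.
- **`group_stats`** — cohort summaries (mean ± SD), two-group comparison
  tables (Welch/Student t, Mann-Whitney), and a paired-validation Wilcoxon
  signed-rank test that is exact (tie-aware) for n ≤ 25.
- **`synthetic`** — a synthetic-subject generator with known millimeter
  ground truth under random pixel scale and in-plane rotation, plus
  rasterized eye crops with known iris geometry, used as the test bed for
  every stage.
- **`cli`** — `facemetrics simulate | measure | compare`.

## CLI

Generate a synthetic two-group cohort (landmark CSVs, eye PNGs, ground-truth
tables, cohort manifest):

```sh
facemetrics simulate -n 21 --seed 1 --out out/sim
```

Measure every subject in a cohort table (WTW is segmented from the eye
crops; a `wtw_px_left/right` column pair in the cohort CSV is accepted as a
fallback when no images are available):

```sh
facemetrics measure --cohort out/sim/cohort.csv --out out/meas
```

Compare two record files into a two-group report (CSV + Markdown):

```sh
facemetrics compare --records-a f.csv --records-b m.csv \
    --label-a F --label-b M --out out/cmp
```

Each command writes its resolved configuration (`run_config.json`) next to
its outputs. Configuration keys: `wtw_reference_mm`,
`segmentation_iterations`, `segmentation_smoothing`,
`segmentation_trim_occlusion`, `statistics_method`, `seed`, `log_level`.

## Formats

- Landmark CSV: header `name,x,y`, one row per landmark; JSON: flat
  `name -> [x, y]` map. Image coordinates, origin top-left, y down;
  `_L`/`_R` suffixes are anatomical (subject's own) sides.
- Cohort CSV: `subject_id,group,landmarks_path,eye_left_path,eye_right_path`
  (+ optional `wtw_px_left,wtw_px_right`).
- Records CSV: one row per subject, columns per measurement (lengths cm,
  angles degrees, scleral show mm).
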