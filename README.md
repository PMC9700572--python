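# boxfd

Box-counting fractal dimension (FD) of segmented lumen borders in calibrated
CT slice images, with a synthetic-data generator and a cohort-statistics
layer, so the whole measurement chain can be exercised end to end against
known ground truth.

The pipeline mirrors a semi-automatic annulus/LVOT morphometry workflow:

1. **synthetic** — analytic test contours with known dimension (circles,
   Koch snowflakes, radially perturbed circles with tunable roughness),
   rendering of HU-like 16-bit TIFF slices (bright lumen, darker tissue,
   optional calcium foci that indent the border, a burned-in compass ring
   of known diameter), and whole seeded cohorts with plantable group
   contrasts.
2. **segmentation** — suitability gate on luminal attenuation (default
   > 300 HU), pixel→mm calibration from the compass ring, threshold
   region-growing from a seed point, and sub-pixel marching-squares tracing
   of the closed outer border (pixel-chain mode behind a switch). Manual
   corrections enter through `override_contour` / contour CSV files.
3. **fractal** — fixed-grid box counting over physical calibers (default 10
   log-spaced values in [0.8, 6.75] mm) using exact segment–box clipping
   (closed boxes; a segment on a shared edge counts for both neighbours),
   then an OLS fit of ln(count) on ln(caliber); FD is the absolute slope.
4. **geometry** — shoelace area, perimeter, Feret min/max diameters via
   rotating calipers, eccentricity `100·(d_max − d_min)/d_max`, and LVOT
   non-tubularity `(annulus − LVOT)/annulus`.
5. **cohort_stats** — Mann–Whitney U (exact for small tie-free samples),
   Pearson correlation, ROC with Hanley–McNeil 95% CI and Youden cutoff,
   Cronbach's alpha and ICC(A,1) agreement, and per-plane×phase group
   comparison with listwise missing-data exclusion.
6. **cli / simulate** — orchestration with config echo, per-image audit
   logging, the accounting identity `n_input = n_analyzed + n_excluded`,
   and Monte-Carlo inference-recovery simulations.

## CLI

```sh
boxfd demo --out demo_run --seed 1          # generate + analyze a demo cohort
boxfd generate --out data --seed 1          # synthetic cohort (TIFFs + manifest)
boxfd run data/manifest.csv --out results   # full pipeline on a manifest
boxfd segment slice.tif --out border.csv --mm-per-pixel 0.1
boxfd fd border.csv                         # FD of a contour CSV
boxfd measure border.csv                    # geometry of a contour CSV
boxfd stats results/results.csv             # cohort statistics from results
```

A run writes `results.csv` (per image: gate value, FD, fit quality,
geometry), `curves.csv` (box-count curves for audit), `stats.json` (group
medians/IQRs, Mann–Whitney p per plane×phase, ROC on the target contrast),
`run_config.json` (echoed config; re-running from it reproduces outputs
byte-identically) and `run.log`.

Manifest columns: `subject_id, plane, phase, image_path, group, pvr_grade,
composite_endpoint` plus optional `mm_per_pixel, seed_x, seed_y`. When
`mm_per_pixel` is absent the compass ring is used (configure its physical
diameter), and images failing the attenuation gate or segmentation are
excluded with machine-readable reasons.

## Notes

- All generators are pure functions of (parameters, seed); same seed and
  config ⇒ byte-identical numeric outputs.
- Whether the reference workstation uses Feret or centroid-ray diameters is
  undocumented; Feret is used and recorded in the output metadata.
- Fixed-grid box counting is translation-sensitive through count
  quantization at the coarse calibers (observed up to ~0.09 in FD for
  r = 12 mm contours); an origin-averaging mode exists for sensitivity
  analysis but is off by default.
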