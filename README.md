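# targetmet

Targeted LC-MS quantification pipeline for thyroid hormones (T3/T4) and
polar metabolites in small-volume biofluids, exercised end to end on
synthetic data with known ground truth.

The pipeline chain:

1. **Targeted extraction** — extracted ion chromatograms at a 5 ppm mass
   tolerance from centroided mzML, trapezoidal peak integration inside
   retention-time windows (`targetmet.xic`).
2. **Internal-standard normalization** — per-sample factors averaged over
   mean-centered isotope-labeled IS peak areas (`targetmet.normqc`).
3. **Pooled-QC filtering** — per-compound CV from pool reinjections and
   R² from 3-/10-fold pool dilutions; compounds kept only with
   CV < 30% and R² > 0.95 (strict, configurable).
4. **Total-signal normalization** — biological-material correction by the
   total integrated area of the high-confidence compounds.
5. **Isotope-dilution TH ratios** — analyte / ¹³C-labeled-IS area ratios,
   invariant to per-sample matrix effects (`th_relative_abundance`).
6. **Calibration** — linear dynamic range and limit of detection
   (blank + 3σ within the linear segment) from standard dilution series
   (`targetmet.calibration`).
7. **Profiling statistics** — half-minimum imputation, log₁₀ + Pareto
   scaling, PCA, Welch/ANOVA group comparisons with Benjamini–Hochberg
   correction, top-N ranking (`targetmet.stats`).
8. **Synthetic data** — a simulator (`targetmet.simulate`) that emits peak
   tables and raw centroided mzML with serialized ground truth: matrix
   factors, IS spikes, pool dilutions, planted group effects
   (embryo-elevated T3, pregnancy-elevated T4, freeze-labile compounds)
   and planted QC failures.

Retention times are minutes everywhere; missing values are empty CSV
cells (and zeros are treated as missing at analysis time), never 0.

## CLI

```sh
# synthesize a study (peaks.csv, meta.csv, library.csv, truth.json [+ mzML])
targetmet simulate --scenario default --seed 17 --out sim/

# quantify library compounds in raw runs
targetmet quantify --mzml run.mzML --library sim/library.csv --out peaks.csv

# IS normalization + QC filter + total-signal normalization
targetmet normalize --peaks sim/peaks.csv --meta sim/meta.csv \
    --library sim/library.csv --out norm.csv --qc-report qc.json

# LOD / linear range from a dilution-series CSV
targetmet lod --series series.csv --out calib.json

# scaling, PCA, group comparison, top-25
targetmet stats --norm norm.csv --meta sim/meta.csv --out stats_dir/

# the full chain
targetmet run-all --in sim/ --out out/ --seed 17
```

Exit codes: 0 success, 1 stage failure, 2 bad input. Every run writes a
`MANIFEST.json` with the tool version, resolved-config hash and seed.
Config defaults (JSON, `--config`): 5 ppm tolerance, RSQ > 0.95,
CV < 30%, full scan m/z 70–1000, narrow TH scan 600–800.

## Notes / non-goals

Untargeted peak picking, PLS-DA, vendor raw formats, profile-mode
centroiding, pathway enrichment and absolute study-sample concentrations
are out of scope. Simulator effect sizes are free parameters, not
literature claims.
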