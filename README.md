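# ctdoseaudit

Tools for computing CT dose metrics from per-series dose records and for
auditing a dose-monitoring system's region handling.

What it computes:

* **ED** — effective dose as `f(region) × DLP`, with region-specific
  DLP-to-ED conversion-factor tables (two shipped defaults with distinct
  provenance, fully overridable via YAML).
* **wkg / SED** — a dimensionless quadratic weight-correction factor and
  the weight-corrected (size-specific) effective dose `SED = wkg × ED`.
* **SSDE** — size-specific dose estimate from CTDIvol and patient
  effective diameter via per-phantom exponential conversion factors, plus
  an optional explicit linear re-basing onto the water-equivalent-diameter
  scale for chest-type regions.
* **SED from SSDE** — via published per-region linear regression segments,
  each valid only inside its calibrated scan-length window.
* **Fixed-region misassignment emulation** — reproduces the failure mode in
  which a monitoring system stamps the region of the last series onto every
  series of a multi-region study, inflating the study's ED.
* **Slope comparison** — region/scanner-stratified OLS fits of SED-vs-SSDE
  and ED-vs-SSDE, absolute percent differences against reference slopes
  (magnitude-based, round-half-away-from-zero), summary means, and
  box-plot statistics (1.5·IQR whiskers).
* **Synthetic cohorts** — a fully seeded two-scanner, two-view generator
  (correct-region view + misassigned "commercial" view) so the entire
  pipeline is testable without any external data.

## CLI

The console script is `ctdose`:

```sh
# seeded synthetic cohort: correct view, misassigned view, truth ledger
ctdose generate --n 500 --seed 1 --out cohort/

# full audit: per-study metrics, slope table, box stats, exclusion log
ctdose audit --synthetic 500 --seed 1 --out report/
ctdose audit --input cohort/dw_view.csv --out report/

# print the active constant tables (factors, SSDE coefficients, segments,
# protocol-classification rules)
ctdose tables --as-json

# per-region scatter + fitted-line plots from an exported series table
ctdose plot --input report/series_export.csv --out plots/
```

`audit` accepts `--factors-dms/--factors-dw` (named default table or a
YAML path), `--segments`, `--rules`, `--min-age` and `--no-misassignment`.
Logs go to stderr (`--log-json` for machine-readable lines). The report
bundle is deterministic: the same configuration yields byte-identical
artifacts.

## Library

```python
from ctdoseaudit import (
    CohortConfig, generate_cohort, run_audit, RunConfig,
    compute_ed, compute_sed, compute_wkg, ssde_from_deff, sed_from_ssde,
    fit_linear, slope_pct_diff, mean_abs_pct_diff,
)
```

Modules: `records` (data model, CSV/JSONL I/O, cohort filtering, series
matching), `regions` (protocol classification, study alias, fixed-region
emulation), `metrics` (the dose-metric engine), `compare` (fits and slope
comparison), `synthetic` (seeded cohorts), `pipeline`/`cli`
(orchestration).

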