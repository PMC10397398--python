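# excessscan

Detection of geographic clusters of **higher-than-expected mortality** at
the municipality level, combining model-based expected rates with a
Kulldorff circular spatial scan statistic.

## The problem

Disease mortality varies strongly over space, but much of that variation is
explained by local sociodemographic composition. A raw hotspot map
therefore mostly re-draws the map of poverty, age structure and healthcare
access. The question an eco-epidemiologist actually wants answered is:
*where is mortality higher than local characteristics predict?* Those are
the places worth field investigation — environmental exposures, cultural
risk factors, registry artifacts.

`excessscan` implements the two-stage design used for national cancer
mortality analyses:

1. **Expected-rate surface.** Each unit's directly age-standardized
   mortality rate (ASR, deaths per 100,000, standardized against the WHO
   world standard population) is predicted from a block of sociodemographic
   covariates by a machine-learning regressor. Candidate families (gradient
   boosted trees, random forests, polynomial/linear SVM, LASSO, ridge,
   linear regression, CART and a pruned-tree analog of conditional
   inference trees) are ranked by repeated 10-fold cross-validated R² on a
   70% train split, tuned by random search, and the final surface is the
   **out-of-fold (OOF)** prediction from whole-set 10-fold CV: every unit's
   expected rate comes from a model that never saw it. Missing covariate
   cells are KNN-imputed and features min–max scaled *inside each training
   fold* (no leakage).

2. **Spatial scan.** Observed pseudo-counts `c_i = ASR_i · pop_i / 10⁵` and
   model-based expected counts `μ_i = predicted_i · pop_i / 10⁵` (rescaled
   so `Σμ = Σc = C`) feed a from-scratch Kulldorff circular Poisson scan.
   Windows grow around each centroid by haversine distance up to a
   population bound (default 0.3% of the national total); each window scores

   ```
   LLR = c ln(c/μ) + (C−c) ln((C−c)/(C−μ))   if c > μ, else 0
   ```

   The maximizing window is the most likely cluster; significance comes
   from Monte Carlo replication under the multinomial (or Poisson) null,
   with a p-value floor of 1/(R+1) — 0.001 at the default R = 999.
   Secondary clusters are reported greedily with zero membership overlap.

The reporting stage computes the quantities such analyses publish: residual
rates (observed − predicted), additional cases (residual × population /
100,000), excess percentages ((obs − exp)/exp × 100), expected-case-weighted
summaries, and cross-model cluster overlap groups.

A fully seeded synthetic-data generator (`excessscan.synthetic`) emulates
the study design — ~5,565 units, 40 census-style covariates, log-normal
populations split into 18 five-year age bands, covariate-driven baseline
ASRs near 98.5 per 100,000, Poisson deaths, planted excess-risk disks and
MCAR missingness — so the whole pipeline is testable without any data
download.

## Worked example

The package bundles a published municipal summary of three Brazilian
excess-cancer-mortality clusters (2007–2016) as example data. Reproducing
its arithmetic:

```python
from excessscan.datasets import load_brazil_cluster_municipalities
from excessscan.report import residual_rate, additional_cases

t = load_brazil_cluster_municipalities().set_index("municipality")
row = t.loc["Rio Grande"]
res = residual_rate(row["adjusted_rate"], row["predicted_rate"])
print(res, additional_cases(res, row["population_thousands"] * 1e3))
```

prints `35.5 72.846`: Rio Grande's observed ASR of 160.0 exceeds its
covariate-predicted 124.5 by 35.5 deaths per 100,000 — about 72.8 deaths
per year above expectation for its 205,200 residents. Aggregating the
16 municipalities of that cluster by population-weighted rates gives a
cluster residual of 28.6 per 100,000 (154.1 additional cases).

An end-to-end synthetic demo from the shell:

```bash
excessscan run --seed 1 --out-dir demo_out
```

simulates 300 units with one planted relative-risk-2 disk, fits a gradient
boosted trees OOF surface, scans with 999 replicates and writes
`units.csv`, `expected_surface_*.csv`, `clusters_*.csv`,
`clusters_report_*.csv`, `overlap_report.csv`, `summary.json` and
`manifest.json`. A typical report row

```
cluster,municipality,adjusted_rate,predicted_rate,residual_rate,population_thousands,additional_cases,p_value
Cluster 1,(all members),153.2,115.8,37.4,476.9,178.6,0.001
```

reads: the primary cluster's population-weighted observed ASR is 153.2
against a predicted 115.8, i.e. 37.4 excess deaths per 100,000
(178.6 additional cases over its 476,900 residents), significant at the
Monte Carlo floor p = 0.001.

Stage-by-stage verbs (`simulate`, `standardize`, `expect`, `scan`,
`report`) expose the same pipeline over CSV files; see `excessscan --help`.

## Layout

- `src/excessscan/synthetic.py` — seeded synthetic municipality generator
- `src/excessscan/standardize.py` — direct age standardization (WHO weights bundled)
- `src/excessscan/expected.py` — model selection, tuning, OOF surfaces
- `src/excessscan/scan.py` — circular Poisson scan statistic, Monte Carlo inference
- `src/excessscan/report.py` — excess-mortality tables, overlap groups, GeoJSON
- `src/excessscan/pipeline.py`, `cli.py` — orchestration and CLI
- `src/excessscan/evaluate.py` — calibration/recovery validation harnesses
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
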