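# Methods

This note records the model, the conventions the implementation commits
to, and what the synthetic validation does and does not demonstrate.

## Direct age standardization

A unit's age-standardized rate is `ASR = Σ_b w_b (d_b / n_b) · 10⁵` over
age bands *b* with deaths `d_b`, person-years `n_b` and standard weights
`w_b`. The bundled standard is the WHO world standard population in 18
five-year bands (0–4 … 85+); its canonical weights sum to 100.03 and are
renormalized on load (any supplied weight vector is renormalized the same
way, with a logged warning). Conventions: a band with zero person-years
and zero deaths contributes 0 (the limit of the rate is taken as 0, the
usual registry practice); deaths in a band with no person-years are a
data error, not a silent zero. Periods are aggregated by summing deaths
and person-years across years *before* standardizing. Rates are carried
at full precision; rounding to one decimal happens only in the report
layer. No confidence intervals are attached to ASRs.

## Expected-rate surfaces

The covariate block is min–max scaled to [0, 1] and missing cells are
imputed by K-nearest neighbours (k = 5 by default; NaN-aware Euclidean
distances on the scaled features, uniform weights). Both transforms live
inside the model pipeline, so in every cross-validation split their
statistics come from the training fold only. A `preprocess_scope="global"`
option reproduces the common but leak-prone preprocess-once workflow for
comparison; the default is fold-wise.

Model selection ranks candidate families by mean R² under repeated k-fold
CV (default 3×10) on a 70% train split, with a 95% CI from the normal
approximation over fold-level R² values — a convention chosen for
simplicity; fold R² values are not independent, so the CI is descriptive.
Hyperparameters are tuned by random search over per-family grids declared
in `expected.FAMILIES`; ties break by lower RMSE, then lexicographic
parameter order, so the winner is deterministic given the seed.

The final surface is the pooled out-of-fold prediction from whole-set
k-fold CV (default k = 10, shuffled, seeded): each unit's expected rate
comes from a model whose training folds excluded it. Negative predictions
(possible for linear families) are clipped to 0 because they feed
expected counts; a constant outcome makes R² undefined and is reported
as 0 with a warning. Nine families map onto scikit-learn and XGBoost
estimators; conditional inference trees have no Python implementation, so
that family is backed by a cost-complexity-pruned CART, the nearest
available analog. The variable-importance hook uses permutation
importance on the fitted pipeline.

## The scan statistic

Observed pseudo-counts are `c_i = ASR_i · pop_i / 10⁵` and expected counts
`μ_i = predicted_i · pop_i / 10⁵`, rescaled so `Σμ = Σc = C` (the Poisson
scan conditions on the total). Because the observed quantity is an
age-adjusted *rate*, the pseudo-counts are real-valued; the Poisson
log-likelihood ratio is evaluated on them directly (the formula is
well-defined for non-integer arguments) and only the Monte Carlo null
rounds C to an integer. This is a deliberate and prominent choice: the
scan targets adjusted rates, not raw counts, and the replicate-based
inference absorbs the non-integrality.

Windows grow around every centroid in order of haversine distance
(Earth radius 6,371 km; planar Euclidean is available for small test
grids), with ties broken by the center first, then ascending unit id, and
every prefix whose cumulative population stays within `max_pop_fraction`
of the total is a candidate window. Windows identical as member sets are
deduplicated across centers. The default bound is 0.3% of the total
population — suited to a sparsely populated national territory where
larger windows produce territorially meaningless clusters; the classical
rule of thumb allows up to 50%, and the bound is freely configurable.

The scan is one-sided (high-rate): windows with `c ≤ μ` score 0, with the
convention 0·ln 0 = 0 covering `c = C`. Clusters are ranked by LLR;
secondary clusters are reported greedily subject to zero membership
overlap with higher-ranked clusters, the standard convention. All
reported clusters are compared against the same null distribution of the
*maximum* LLR over all windows, from R Monte Carlo replicates (default
999, p-floor 0.001) that redistribute the C cases either multinomially
with probabilities `μ_i / C` (default, conditioning on the total) or as
independent Poissons with means `μ_i`.

## Synthetic data

The generator emulates the target study design: coordinates uniform in a
Brazil-sized bounding box, populations log-normal (log-mean 9.8, log-sd
1.2 → median ≈ 18k, total ≈ 200M at 5,565 units), person-years split into
18 bands by a Dirichlet draw around a declining national pyramid
(largest-remainder rounding, so bands sum exactly to the population),
and covariates as block-correlated Gaussians (exchangeable ρ = 0.5 in
blocks of 5) pushed through the normal CDF onto [0, 1], mimicking bounded,
mutually correlated census proportions. Baseline ASRs are a linear or
saturating function of the first ten covariates calibrated to a national
mean near 98.5 per 100,000 with a spread of roughly ±17; age-specific
rates rise exponentially with age and are normalized against the WHO
weights so each unit's true ASR equals its baseline exactly. Deaths are
Poisson per band; planted disks multiply the rate by a known relative
risk inside a great-circle radius. Missingness is MCAR only (exactly
`round(f · n_cells)` covariate cells), since no mechanism is specified
for real extracts; the missing fraction is a free parameter.

For model-performance studies, `regression_outcome` builds an outcome
whose empirical signal fraction is calibrated exactly: the best
attainable OOF R² equals the requested fraction, giving a generative
oracle for criterion-style checks.

What the generator does **not** emulate: real census marginals, municipal
polygons (points only), spatially autocorrelated covariates, non-MCAR
missingness, or registry undercounting. Passing tests therefore
demonstrate the correctness and calibration of the *methods*, not that
any particular real-world cluster is reproducible.

## Validation harnesses and problem sizes

The acceptance-style studies (in `excessscan.evaluate`) use desk-scale
problem sizes chosen as the package's own test design: oracle agreement
on 5–15-unit instances against exhaustive enumeration; null calibration
with 30 units and 99 replicates over hundreds of runs; planted-disk
recovery with 400 units and an 8-unit relative-risk-2 disk; OOF studies
at n = 250 (noise) and n = 3,000 (signal fraction 0.6). In the recovery
harness the window bound is 0.05 rather than the 0.3% default, because an
8-unit disk of average-population units holds ~2% of a 400-unit total —
the bound is the scan's one free parameter and must admit the target
cluster. Recovery uses the true baseline surface as the expected rates to
isolate the scan stage; the modeling stage is validated separately by the
OOF studies.

## Known limitations and discrepancies

- The published summary tables bundled as example data are internally
  rounded; most rows reproduce exactly, but some aggregate quantities
  (e.g. the expected-case-weighted SD of excess percentages for
  non-specified-site cancer) cannot be recovered from the rounded
  entries, implying unrounded internals upstream. The report layer keeps
  full precision in machine-readable outputs and rounds only for display.
- When the expected surface comes from an imperfect model, residual
  model misfit adds unit-level dispersion beyond the multinomial null,
  so end-to-end p-values on poorly fitting surfaces are anticonservative
  — a property of the model-based scan design itself, worth remembering
  when interpreting marginal clusters. Calibration is exact when the
  surface equals the generative expectation (the null-calibration study).
- SVM families scale quadratically in n and are impractical beyond a few
  thousand units; tree ensembles are the intended default at national
  scale.
- Scanning at the national default of ~5,565 units with 999 replicates is
  an O(windows × replicates) computation; the implementation vectorizes
  over replicates but a full national run takes minutes, not seconds.
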