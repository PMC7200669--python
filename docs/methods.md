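# Methods

This note records the statistical model, the generative assumptions of the
synthetic census, the numerical choices, and the known limits of what the
test suite demonstrates.

## Infestation model

The response is per-cell, per-year MPB presence/absence. Presence
probability follows a logistic regression on the cell-year covariates; the
observation unit is one 100 m grid cell in one census year. Within a year,
conditional on the previous year's infestation map and the current
covariates, cells are treated as independent — beetle pressure (`I_c`,
`I_u`) is the only spatial coupling, and it enters as an ordinary
covariate computed from the year before. Because the beetle is univoltine,
states two or more years back never enter.

### Neighborhood rings

`I_c`/`I_u` weight the focal cell at 1, and rings 1–3 at 0.5 / 0.25 /
0.125. Rings are defined as Euclidean center-to-center distance bands
r − 1 < d ≤ r in cell units: this is the unique simple rule that yields
the canonical 4 / 8 / 16 adjacent-cell counts, and tests pin it against a
brute-force enumeration of all offsets with d ≤ 3. Off-grid neighbors
contribute zero — no wraparound, no edge renormalization — because the
census grid is a complete rectangle. The saturated neighborhood gives the
upper bound 1 + 0.5·4 + 0.25·8 + 0.125·16 = 7.

### Other derived covariates

`Dist` is the minimum Euclidean distance from the cell center to an
arbitrary border polyline (any vertex chain in meters; which stretch of
boundary to use is configuration, not code). Aspect enters as
northerness/easterness, N = cos(azimuth), E = sin(azimuth), azimuth in
degrees clockwise from north wrapped modulo 360. Grid indexing is 0-based
with row 0 the southern edge; all distances use cell centers.

## Phenology

Two degree-day clocks with daily mean temperature as the accumulation
input (daily means are the common choice when sub-daily data are absent):

* **Emergence peak**: accumulation above 2 °C starting Julian day 150; the
  `Peak` covariate is the first day the running sum reaches
  `dd_median_emergence`. That threshold is the one free parameter — the
  published flight-period model this stands in for has unpublished
  parameters — and defaults to 1000 DD, which under sinusoidal mid-summer
  daily means peaking near 19.5 °C lands the peak in the observed Julian
  205–232 window. A series that never reaches the threshold returns an
  explicit sentinel (−1), never a fabricated day.
* **Univoltinism**: a season supports one generation per year when
  degree-days above 5.5 °C reach 833; exactly 833 counts as feasible
  ("minimum of" read inclusively).

Peak is monotone in temperature (warming can never delay it); this is a
property test.

## Synthetic census generator

The generator emulates the statistical structure of an intensively managed
outbreak census; it is a study-system stand-in, not a fit to any real
landscape.

* **Covariate surfaces** are Gaussian-blurred standard-normal fields
  rescaled (min–max, hence monotone affine) into each covariate's observed
  range; the blur radius is the autocorrelation length in cells (0 = i.i.d.
  values). Vegetation and topography surfaces are static; weather surfaces
  redraw yearly.
* **Built-in collinearity** gives the screening stage realistic work:
  `Height` and `Age` share a latent stand field (ρ ≈ 0.95–0.98), and
  `T_max`, `SMI`, `Peak` derive from one latent thermal field with unit
  independent noise on `SMI` and `Peak`, giving ρ(T_max, SMI) ≈
  ρ(T_max, Peak) ≈ −0.7 but ρ(SMI, Peak) ≈ +0.5 — so screening removes
  `T_max` alone, and both moisture and phenology survive.
* **Dynamics**: year 1 is seeded near the southern border (cells within
  400 m of the border polyline infested with probability
  `border_pressure` = 0.05; the border sits 50 m south of the grid so all
  distances stay inside the observed range). Each later year draws
  infestation from the logistic model on that year's covariates plus
  `I_c`/`I_u` from the previous year's states, then classifies each
  infested cell as fully controlled with probability `p_detect` = 0.65
  (zero-tolerance management detects most infestations; partially
  controlled cells are collapsed into the controlled/uncontrolled
  dichotomy the pressure indices count). Logits are clipped at ±30 before
  the link purely as overflow protection.
* **Forcing**: a per-year scalar added to the logit is the exogenous knob
  that produces the rise–plateau–collapse trajectory; the real outbreak
  history is observed, not mechanistically modeled, so the schedule is
  configuration. The default schedule and generative coefficients
  (`I_u` 2.2, `I_c` 0.35, `SMI` 0.018 /mm, `Dist` −3·10⁻⁴ /m, `Cover`
  0.009 /%, `T_min` 0.05 /°C, intercept −7.4) were calibrated once so the
  default 50×50, 2006–2018 run shows the conditions the analysis assumes:
  counts rising to a 2012–2013 plateau then collapsing, overall positive
  prevalence inside the 1:95–1:40 band, and uncontrolled beetle pressure
  as the dominant single predictor in every phase.
* **Randomness**: one seeded `numpy` generator threads through every draw
  in a documented order (static fields; yearly weather in calendar order;
  first-year seeding; then per year the infestation draw followed by the
  detection draw), so a fixed config reproduces a byte-identical census.

What the generator does **not** emulate: the real park's two-block
geometry and irregular outline (the grid is a single rectangle), tree-level
infestation counts (presence/absence only), beetle dispersal beyond the
3-cell pressure neighborhood, observation error in the covariates, and any
feedback from infestation onto the host covariates. Passing tests
therefore demonstrate that the machinery is correct and consistent, not
that the real system satisfies the model.

## Fitting and selection

* **IRLS**: maximum likelihood via iteratively reweighted least squares
  with an intercept always included; convergence when the largest absolute
  coefficient change falls below 1e−8 (at most 100 iterations), with a
  deviance-change fallback (relative change < 1e−10) for ill-conditioned
  designs where coefficient steps are dominated by round-off. Steps that
  would decrease the log-likelihood are halved until they do not
  (the same safeguard R's `glm.fit` uses). Likelihoods are computed via
  `log1p`/`logaddexp` forms; no clipping inside the optimization.
  Rank-deficient designs and one-class responses raise named errors;
  quasi-complete separation (any standardized |β| > 15) is flagged on the
  fit and such models are never eligible as overall best, but enumeration
  continues.
* **BIC** = k·ln(n) − 2·logLik with k counting the intercept. Counting
  the intercept shifts every model's BIC by the same amount within a
  dataset, so ΔBIC and the selected subsets are unaffected by the
  convention. ΔBIC ≤ 2 is flagged indistinguishable and ≥ 8 strong
  evidence.
* **Screening** is iterative within thematic categories (weather,
  vegetation, topography, beetle): while any within-category pair has
  |ρ| > 0.6, the lowest-priority covariate involved in a violating pair is
  dropped. The iterative rule (rather than one-per-connected-component)
  matters: when `T_max` correlates with both `SMI` and `Peak` but those
  two do not correlate with each other, only `T_max` is removed. The
  survivor priority is configuration; the default prefers process-based
  indices over the raw temperature extreme and stand height over age.
* **VIF** is computed per candidate subset (matching the per-model
  VIF_max column of the usual report tables), as 1/(1 − R²) from OLS of
  each covariate on the others; VIF_max > 10 marks the model excluded.
  The exclusion is a posteriori: enumeration still reports such models.
* **Standardized estimates** z-score covariates on the phase's training
  rows only, then sort by |β| descending with alphabetical tie-break.
* Enumeration refuses more than 20 candidates (2^p fits) with guidance to
  screen first.

## Validation

Folds are whole census years within a phase: train on the other years,
score the held-out year. AUROC is the tie-averaged Mann–Whitney statistic;
AUPR uses the step (average-precision) integration with tied scores
crossing thresholds together — the only convention under which a constant
classifier scores exactly the positive prevalence, which is the null
reference the analysis relies on. Folds whose held-out year has no
positives have undefined AUPR and are dropped from the mean with a logged
warning, never imputed. All models reported in one selection table share
the identical fold scheme. Risk maps evaluate a fitted model over one
year's covariate rows and serialize as an ESRI-ASCII-style text raster
(plain-text header, row-major from the northern edge, 6 significant
digits, −9999 for missing cells).

## Problem sizes in the test suite

The suite exercises the pipeline at sizes chosen to make the statistical
assertions sharp while staying desk-scale: the end-to-end scenario uses
2 500 cells × 13 years (~30 k cell-years); parameter recovery uses a
62×62 grid (~46 k modeled cell-years) over 50 seeded replicates with a
constant forcing schedule so the single-intercept fitted model is
correctly specified; selection consistency uses n = 100 000 i.i.d.
observations with a known 3-covariate support over 20 replicates; the
census I/O scale check uses the full surveyed magnitude (18 360 cells ×
13 years). Metric implementations are checked against exhaustive
O(n²)/threshold-sweep oracles and scikit-learn; the IRLS fit against
closed forms, statsmodels GLM, and direct likelihood optimization.

## Known limitations

* Phases are park-wide, never per-cell; a cell newly infested during the
  collapse still belongs to the collapse dataset.
* The automatic phase rule (maximal run of years ≥ 0.8 of the trajectory
  maximum) is a labeled heuristic; explicit year ranges are the primary
  path and always take precedence.
* No spatial random effects, no penalized fits, and no AIC-based
  selection path: BIC is the criterion throughout because the goal is
  identifying the governing factors, not maximizing predictive reuse.
* ROC/PR tie and interpolation conventions differ across software; the
  conventions here are documented above and pinned by tests rather than
  assumed to match any particular package.
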