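# Methods

This document specifies the statistical methods implemented by
`clrmediate`, the design of the synthetic-cohort generator, numerical
choices, and known limitations.

## 1. Compositional preprocessing

**Input.** A subjects × genera matrix of non-negative integer read counts
and a cohort table with a group label and covariates (age, sex, BMI, total
energy intake, recent antibiotic use).

**Prevalence filter.** A genus is retained only if it is present
(count > 0) in at least a fraction `prevalence_threshold` (default 0.5) of
the subjects of **every** group. Requiring the threshold within each group,
rather than overall, prevents a genus common in one large group but absent
elsewhere from entering between-group models where many groups contribute
only zeros.

**CLR transform.** Retained counts are shifted by a uniform pseudocount
(default 1.0) and mapped to centered log-ratios:
`clr(x)_j = ln(x_j) − mean_k ln(x_k)` per subject (computed via
scikit-bio). Rows sum to zero and the transform is invariant to per-sample
scaling (sequencing depth). By default the filter is applied **before** the
CLR so the geometric mean is taken over the retained panel; setting
`clr_before_filter=True` computes CLR over all genera first and subsets
afterwards.

## 2. Dietary factors and adjusted group profiles

Fifteen built-in factors in three classes:

- **index** — overall diet-quality score (`hei2015`, 0–100 points, not
  log-transformed);
- **adequacy** — components where more is better (fruits, vegetables, nuts/
  seeds/legumes, whole grains, dairy, fish, MUFA:SFA ratio);
- **moderation** — components where less is better (alcohol, red meat,
  refined grains, added sugars, sugar-sweetened beverages, saturated fat,
  sodium).

Adjusted group means are linear-model estimates of each group's mean at the
grand mean of the descriptive covariates (age, sex, energy, BMI), with
t-based 95% confidence intervals and a joint F-test p-value for any group
difference (statsmodels OLS). Factors modelled on the log scale are
back-transformed, so the reported quantities are covariate-adjusted
geometric means. A factor with non-positive values under a log
specification is an error; the caller must supply an offset or exclude it.

**Reference-group selection.** For each factor independently, the reference
group is the one with the most desirable adjusted mean: highest for index
and adequacy factors, lowest for moderation factors, ties broken
lexicographically.

## 3. Natural effect mediation models

For exposure group `X` (reference + L−1 comparison levels), mediator `M`
(log intake, except index scores which stay on their native scale),
outcome `Y` (CLR abundance of one genus), and confounders `C` (age, sex,
BMI, energy, antibiotic use), the imputation approach proceeds:

1. Fit the working model `Y ~ 1 + dummies(X) + M + C` by OLS.
2. Expand each subject over all L hypothetical exposure levels `x0`,
   keeping `x1` (the level governing the mediator) at the observed group,
   and impute `Ŷ(x0, x1)` from the working model.
3. Fit the natural effect model
   `Ŷ ~ 1 + dummies(x0) + dummies(x1) + C` on the n·L expanded rows.

The `x0` coefficients are natural direct effects, the `x1` coefficients
natural indirect effects, and TE = NDE + NIE holds exactly by construction
(asserted at 1e-10). In this linear, no-interaction case the estimator is
algebraically identical to the product-of-coefficients decomposition
(NIE = βm·αx from `M ~ X + C`; TE equals the `X` coefficients of
`Y ~ X + C` by the omitted-variable identity); the test suite verifies
agreement to ~1e-15 and uses it as the correctness oracle.

**Mediator transform.** Intake mediators are log-transformed. If a factor
contains zeros, a uniform offset of half the smallest positive value is
added before the log; negative intakes are rejected.

**Bootstrap inference.** Subjects are resampled with replacement, stratified
by group (so every exposure level stays represented; non-stratified
resampling redraws up to `max_redraw` times if a level vanishes). The whole
two-stage estimator is recomputed per replicate (B = 100 by default);
SE = SD across replicates, and two-sided p-values use the normal
approximation z = estimate/SE. Percent mediated is 100·NIE/TE, reported as
NaN when |TE| < 1e-12.

**Multiplicity.** The grid of G genera × D factors × (L−1) comparisons is
controlled by Bonferroni: NIE p-values are compared to
`alpha / (G·D·(L−1))`. For the full 63 × 15 × 4 design at alpha = 0.05 this
is 1.32e-5 over 945 models (3780 tests).

## 4. Synthetic cohort generator

`SimulationConfig` specifies group sizes, per-group covariate distributions,
per-factor baseline intake distributions, the genus panel size, sequencing
depth, and noise scales. `SimulationTruth` holds the structural
coefficients: `alpha` (factor × non-reference-group log-intake shifts),
`gamma` (genus × factor mediator→outcome slopes), `beta` (genus ×
non-reference-group direct effects). Group differences in diet live
**only** in `alpha`; `diet_params` hold baseline (reference-group)
distributions, avoiding double specification.

- **Diet:** `log M_f = μ_f + alpha[f, group] + loadings·z(C) + noise`,
  i.e. log-normal intakes with fixed standardization constants for the
  covariate loadings so draws are reproducible across configurations.
- **sem mode:** outcomes are generated directly on the CLR-like scale,
  `Y_g = beta[g, group] + Σ_f gamma[g, f]·log M_f + loadings·z(C) + ε`,
  with `ε ~ N(0, noise_sd)`. Implied true effects are exactly
  NIE = gamma·alpha, NDE = beta, TE = their sum.
- **counts mode:** the same latent log-abundances (plus a baseline
  `N(0, base_logabund_sd)` per genus) are pushed through a softmax and a
  multinomial draw at the configured sequencing depth, producing realistic
  zero-inflated integer counts. Planted effects are on the *latent* scale;
  after closure and CLR the recoverable effect is attenuated and partially
  redistributed (see §6).

Random streams are spawned from a `SeedSequence` per component
(covariates, diet, noise, counts), so enlarging the genus panel does not
perturb covariate or diet draws. `default_config(scale=...)` provides a
realistic five-group cohort (group sizes 918/750/684/1969/946 at
scale = 1, Table-1-like covariate distributions) and `default_truth`
derives `alpha` from realistic per-group intake profiles. These defaults
are a package choice of a plausible observational design, not a claim
about any particular study.

## 5. Validation studies

`clrmediate.validation` packages five Monte-Carlo studies used by the
acceptance checks (`tests/test_acceptance.py`, `scripts/acceptance.py`):

1. **Oracle equivalence** — maximum relative difference between the
   expanded-data estimates and the closed form over random cohorts
   (observed ~3e-15; asserted < 1e-8).
2. **Recovery** — bias and 95% CI coverage of NIE/NDE/TE on sem-mode
   cohorts with one planted cell (NIE = 0.5, NDE = 0.3, TE = 0.8);
   asserted |bias| < 0.05 and coverage in [0.92, 0.98].
3. **Null calibration** — type-I error of the per-contrast NIE test with
   all group diets shifted (alpha ≠ 0) but no mediator→outcome path
   (gamma = 0); asserted in [0.03, 0.08] at the 0.05 level.
4. **Familywise error** — fraction of global-null count-mode grids with any
   Bonferroni-flagged NIE; asserted ≤ 0.10.
5. **Planted detection** — end-to-end count-pipeline runs with a single
   strong planted cell; asserted that the planted cell is flagged, and is
   the *only* flagged cell, in ≥ 95% of runs.

## 6. Numerical and design notes

- **OLS solver.** The mediation hot path solves normal equations by
  Cholesky factorization, falling back to pivoted QR (which also names the
  collinear columns in the error) when the Gram matrix is not positive
  definite. The bootstrap uses a label-free NumPy core that skips pandas
  bookkeeping.
- **Double-null conservatism.** When *both* the exposure→mediator and
  mediator→outcome paths are null, the NIE estimator is a product of two
  near-zero terms; its distribution is non-normal and the Wald test is far
  more conservative than nominal (a well-known property of product-type
  indirect effects). The null-calibration study therefore keeps the
  exposure→mediator path active, which is also the realistic regime: group
  diets do differ. Under the double null the test only becomes *more*
  conservative, never anticonservative.
- **Bootstrap tail behaviour.** With B = 100 replicates, z = est/SE behaves
  approximately like a t with ~B−1 degrees of freedom, so deep-tail
  normal-approximation p-values (at Bonferroni thresholds ~1e-5) are
  somewhat anticonservative — roughly a 1.4–1.6× inflation of nominal
  deep-tail error. The familywise-error study shows the realized FWER
  still stays near the nominal 5% for the tested grid sizes.
- **Compositional closure spillover.** A planted count-scale effect on one
  genus mechanically shifts every other genus's CLR value by about
  −gamma·alpha/G. With small panels (G ≲ 10) this *real* induced indirect
  effect can itself reach significance; the planted-detection study uses a
  40-genus panel so the spillover (~0.014 per genus there) stays well below
  the detection threshold. This is a property of compositional data, not an
  estimator artifact.
- **Exact planted-cell detection is intrinsically borderline.** With 320
  Bonferroni tests per run and slightly anticonservative deep-tail
  p-values, the expected number of false extras per run is on the order of
  0.05–0.1, so requiring *exactly* one flagged cell in ≥ 95% of runs sits
  near the edge of what a perfectly calibrated procedure achieves;
  empirically the bootstrap SEs are mildly conservative and the observed
  exact rate has been 1.0.

## 7. Known limitations

- The working model is linear with no exposure–mediator interaction;
  natural effects are identified only under the usual cross-world
  no-unmeasured-confounding assumptions, which are untestable.
- One mediator is modelled at a time; correlated dietary factors are not
  jointly decomposed (the optional `hei_adjust` flag adds overall diet
  quality as a confounder for component mediators, mirroring common
  sensitivity analyses).
- Bootstrap p-values use a normal approximation with B = 100; deep-tail
  p-values are approximate (see §6).
- The count generator uses a single multinomial draw per subject; it does
  not model overdispersion beyond the log-normal latent layer, nor
  taxon-specific sequencing bias.
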