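# Methods

## The estimand and the revision policy

For each patient the clinician orders an initial warfarin dose (IDP,
mg/day); the label is the therapeutic dose (TD, mg/day), the dose that
eventually produced two consecutive in-range INRs at least 14 days apart.
The model estimates the signed percentage error of the order,

    e = (IDP − TD) / TD,

a dimensionless fraction, positive for overdoses. The therapeutic-dose
denominator is the package default (`error_denominator="therapeutic"`):
it is the only convention under which errors far above +1 — which the
summary statistics of real cohorts show — are possible, and it matches the
fractional threshold grid 0.1–0.4 used throughout. The IDP-denominator
convention is available as a switch.

The error is regressed on the encoded covariates plus the order itself with
an L1-penalized linear model in the Lagrangian form

    (1/2n) Σ (eᵢ − b0 − xᵢᵀb)² + λ Σⱼ|bⱼ|,

equivalent to the constrained form `Σ|bⱼ| ≤ t` through the usual bijection
between t and λ. Given an estimate ê and a threshold τ (the institution's
definition of a clinically significant percentage difference), the policy
keeps the order when |ê| ≤ τ and otherwise revises it. Two revision
formulas ship:

* `printed_eq3` (default): `revised = (1 − ê) · IDP` — the linear
  correction, faithful to the published rule with its percent scale read as
  fractions;
* `exact_inversion`: `revised = IDP / (1 + ê)` — the algebraic inverse of
  the TD-denominator error, so an oracle ê recovers TD exactly.

The two differ at second order: with ê equal to the true error the linear
rule leaves a relative residual of exactly ê². They are not interchangeable
for large |ê| (the linear rule goes non-positive past ê = 1 and is floored
at 0.5 mg/day with a warning). The threshold is applied two-sided —
underdoses and overdoses both warrant correction.

## Pipeline

1. **Popular-dose focus.** Only patients ordered one of {2.5, 4, 5, 7.5,
   10} mg/day (matched after rounding the order to 0.1 mg) enter the
   analysis, mirroring the study's restriction to the discrete doses
   clinicians predominantly order. This happens before the split: it is a
   dataset-level scoping decision, not a fitted transform.
2. **Label cleanup.** Rows without an observed therapeutic dose are dropped
   (rows without an IDP never pass the popular-dose filter).
3. **Imbalance screen.** Two-level categoricals whose minority level is
   rarer than 10% of observed values (strict inequality; exactly 10% is
   kept) are recorded at the dataset level and excluded from the *modeling*
   table. The clinical comparator still reads the full covariate set — its
   equation needs amiodarone, which this screen removes from the design.
4. **Split.** A seeded 60/40 shuffle into derivation and validation
   cohorts; `round(n × 0.6)` rows (half-up) derive.
5. **Imputation.** Missing cells are filled by K-nearest-neighbours (K=5)
   under a Gower-style mixed distance: the mean over variables observed in
   both rows of the squared sd-standardized difference (continuous) or the
   0/1 mismatch (categorical). Continuous imputations are the neighbour
   mean, categorical the neighbour mode with ties broken by level order.
   Validation rows use derivation rows as their only reference — no
   leakage, and validation rows never inform one another.
6. **Encoding.** k-level categoricals become k−1 indicators against the
   most frequent level; continuous covariates (and IDP, unless the
   order-blind configuration is requested) are standardized with means/sds
   fitted on derivation rows only. Unseen levels at transform time encode
   as the reference with a warning.
7. **Correlation screen.** On the encoded derivation matrix, while any
   column pair has |Pearson r| ≥ 0.85 (the most correlated pair first), the
   member with the larger mean absolute correlation to the rest is dropped
   (ties toward the later column). Constant columns are dropped first with
   a warning. The validation matrix keeps exactly the surviving columns.
8. **Fit and select.** Coordinate descent over 100 log-spaced penalties
   from λ_max (= maxⱼ|xⱼᵀe|/n on the internally standardized problem, the
   smallest penalty with an all-zero slope vector) down to 0.001·λ_max,
   warm-started. λ is selected by 10-fold cross-validation (seeded shuffle,
   near-equal folds, unweighted mean of fold MSEs) at the CV minimum, ties
   resolved toward the larger — sparser — penalty; the final model refits
   on all derivation rows.
9. **Evaluate.** On validation rows, four strategies are scored by RMSE
   against the therapeutic dose per threshold: the revised orders, the
   untouched orders, a configurable Gage-style clinical equation, and the
   order-blind model's implied dose. The order-blind model has no "keep"
   notion of its own, so its estimate is always applied (threshold 0) —
   the minimal consistent way to turn an error model without the order
   into a dose prediction; it is isolated in one place so alternates can
   be swapped. The Gage and original-order columns do not depend on τ; the
   published table shows small per-threshold jitter in those columns that
   a fixed-split design cannot and does not reproduce.

## Solver details

Coordinate descent runs on the Gram matrix (each update is O(p)) with the
standard active-set iteration: a full pass over all coordinates, then
refinement on the nonzero set until stable. Columns are standardized
internally (population sd; zero-variance columns are held at zero) and
coefficients are returned on the input scale with the intercept absorbing
the centering. Convergence is declared when the largest coefficient change
in a full pass falls below 1e−7 (`max_iter` 10 000 sweeps, non-convergence
warns and flags). The objective is non-increasing across sweeps; solutions
match an independent reference implementation to ~1e−9 at matched penalty.
Prediction aligns columns by name, never by position.

## The synthetic cohort generator

The generator is the package's stand-in for an unavailable 150-patient
cohort; it reproduces the structure the analysis assumes, not the true
joint distribution.

* **Covariate marginals.** Eight continuous covariates (age, height,
  weight, CrCl, albumin, AST, ALT, baseline INR) and ~35 categoricals
  (race, gender, indication, comorbidities, medications, ...) are drawn
  independently with marginals transcribed from the published summary
  tables. Continuous variables are sampled from *moment-matched truncated*
  distributions: a truncated normal for near-symmetric variables, a
  shifted lognormal truncated at the observed maximum when
  sd/(mean − min) > 0.6 signals heavy skew (plain truncated normals cannot
  reach the printed lab moments — AST's sd exceeds its mean's distance to
  the observed minimum). Underlying parameters are solved numerically so
  the truncated mean and sd hit the printed values; empirical means at
  n = 10 000 sit within 3 standard errors.
* **Missingness** is injected missing-completely-at-random per variable at
  the published missing-count rates (e.g. AST 22/150). Only counts were
  published; no MAR/MNAR mechanism is modelled.
* **Therapeutic dose.** `log TD = intercept + Σ βⱼxⱼ + N(0, 0.2)`,
  exponentiated and clipped to the observed dose range. The default
  coefficients are five clinically-signed effects (age −, weight +,
  albumin +, African-American +, amiodarone −), concentrated so a sparse
  fit can find them, and scaled so the covariates carry most (~80%) of the
  log-dose variance. That share is deliberately at the optimistic end of
  clinical dosing models: the study this harness emulates demonstrated a
  strongly *predictable* dosing error, which mathematically requires the
  therapeutic dose to be predictable from what was recorded. The intercept
  targets the printed mean dose via the lognormal mean formula; the
  simulated dose marginal is ≈ 5.7 ± 2.8 mg/day against the printed
  5.68 ± 2.87.
* **Clinician model.** `raw = TD·(1 + N(0, 0.3))` is blended with a
  population-typical anchor of 7.5 mg/day at signal weight 0.8, then
  snapped to the popular grid with probability 0.75 (else to the nearest
  non-popular value of a fuller order grid, so the popular fraction is
  exact). The anchor above the mean dose reproduces the published pattern
  of orders running high (IDP mean 6.12 vs TD mean 5.68). The recorded
  ground-truth error is computed before any masking.

**What passing tests on this generator do and do not show.** Covariates
are independent (the real cohort's correlation structure — e.g.
weight/BSA/CrCl — is not modelled beyond what the dose model induces);
clinician error is Gaussian-multiplicative and cannot produce the extreme
overdoses (errors up to ~5× the therapeutic dose) present in the real
cohort's error summary, whose dispersion (sd ≈ 0.7) is roughly double what
this clinician model yields; and the strong covariate share of dose
variance is an emulation choice, not an epidemiological claim. Directional
results on this generator demonstrate that the pipeline's machinery is
sound, not that revision would achieve any particular RMSE on real
patients.

## The clinical comparator

The Gage-style equation is fully config-driven (`GageConfig`): intercept
plus coefficients over {BSA, age, target INR, current smoking, African
American race, amiodarone, VTE indication}, log or identity link, mg/day
or mg/wk output, age in years or decades, Mosteller (default) or DuBois
BSA. The bundled config is a **synthetic placeholder** — a deliberately
coarsened projection of the generator's own dose model onto that factor
set, so the comparator behaves like a reasonable-but-imperfect clinical
equation in tests. The published equation's coefficients are not
reproduced here; users should transcribe them into a config for real use.

## Numerical and design choices

* Seeds control everything: cohort generation, missingness, split, CV
  folds. Identical settings give byte-identical report JSON.
* CSV round-trips are exact (`float_precision="round_trip"`; the literal
  level name "None" is preserved against NA parsing; missing cells are
  empty fields).
* Revised doses are floored at 0.5 mg/day with a warning; `exact_inversion`
  refuses ê ≤ −1.
* Degenerate inputs: imputation falls back to all available neighbours
  (warning) or the reference marginal when a row shares no observed
  variable with any reference row; CV rejects more folds than rows;
  an empty design yields an intercept-only fit.
* Display rounding in the markdown table is 3 decimals for RMSE and 1 for
  percent changes; tests and the JSON report use unrounded values.

## Known limitations

* The evaluation's sample sizes follow the emulated study (n = 150, ~75%
  popular-dose, 60/40 split), so validation cohorts are small (~45
  patients) and per-seed RMSE comparisons are noisy; replication fractions
  over 20 seeded cohorts are the stable summary.
* At thresholds near 0.4, the estimated errors of a cross-validated sparse
  model rarely exceed the threshold under this generator's Gaussian
  clinician noise, so the revised and original strategies frequently
  coincide there.
* The order-blind comparator inherits whatever covariate signal the
  generator provides; in strong-covariate worlds it is a genuinely useful
  model rather than the worst strategy.
* No inference (standard errors, p-values) on coefficients; no ridge or
  elastic-net variants; no modelling of clinician acceptance of revision
  alerts.
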