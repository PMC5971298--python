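# warfrev

Revision of clinician-chosen warfarin initiation doses.

Warfarin has a narrow therapeutic index and wide inter-patient variability,
and the first dose a clinician orders is often far from the maintenance dose
the patient eventually stabilizes on. Rather than replacing the clinician's
order with a model prediction, this package estimates *how wrong the order
is* — the signed percentage error

```
e = (IDP − TD) / TD
```

where IDP is the Initial Dose Prescribed by the physician and TD the
therapeutic dose (both mg/day; `e > 0` is an overdose, `e < 0` an
underdose) — from standard clinical covariates **plus the order itself**,
using an L1-penalized linear model (LASSO, fitted by cyclic coordinate
descent with the penalty chosen by 10-fold cross-validation):

```
min over (b0, b) of  (1/2n) Σᵢ (eᵢ − b0 − xᵢᵀb)²  +  λ ‖b‖₁
```

When the estimated error ê exceeds a significance threshold τ, the order is
revised, by default with the linear rule `revised = (1 − ê) · IDP`
(an exact inversion `IDP / (1 + ê)` is also available). The package
evaluates the revised doses against three comparators — the untouched
orders, a Gage-style clinical dosing equation, and the same error model
fitted *without* the order — as RMSE against the therapeutic dose on a
held-out 40% validation cohort, across a grid of thresholds.

Because no patient-level data were released, the package includes a
first-class synthetic cohort generator that emulates the published cohort
structure: covariate marginals transcribed from the study's summary tables,
per-variable missingness at the published rates, a discrete "popular dose"
order grid ({2.5, 4, 5, 7.5, 10} mg/day covering 75% of orders), and a
clinician model in which the order carries noisy signal about the
therapeutic dose. It is intended for audiences in clinical decision support
and dosing-model research who want a fully reproducible harness for this
class of revision policies.

## Worked example

```
warfrev evaluate --n 150 --seed 5
```

simulates a 150-patient cohort (with table-derived missingness), runs the
full pipeline — popular-dose focus, label cleanup, KNN (K=5) imputation,
dummy coding, imbalance and correlation screens, 60/40 split, CV-LASSO —
and prints:

```
| Threshold | RMSE revised IDP | RMSE original IDP (% change) | RMSE clinical model (% change) | RMSE no-IDP model (% change) |
|---|---|---|---|---|
| 0.1 | 1.357 | 1.607 (15.6%) | 1.606 (15.5%) | 1.402 (3.3%) |
| 0.15 | 1.380 | 1.607 (14.1%) | 1.606 (14.1%) | 1.402 (1.6%) |
| 0.2 | 1.405 | 1.607 (12.6%) | 1.606 (12.5%) | 1.402 (-0.2%) |
| 0.25 | 1.453 | 1.607 (9.6%) | 1.606 (9.5%) | 1.402 (-3.6%) |
| 0.3 | 1.538 | 1.607 (4.3%) | 1.606 (4.2%) | 1.402 (-9.7%) |
| 0.35 | 1.544 | 1.607 (3.9%) | 1.606 (3.9%) | 1.402 (-10.1%) |
| 0.4 | 1.619 | 1.607 (-0.7%) | 1.606 (-0.8%) | 1.402 (-15.5%) |
```

Each row is one significance threshold τ. `RMSE revised IDP` is the error
(mg/day, against the therapeutic dose) of the orders after revising every
validation patient with |ê| > τ; the other columns show each comparator's
RMSE with, in parentheses, the percentage decrease in RMSE achieved by
revision relative to that comparator. On this cohort, revising at τ = 0.1
cuts the dosing error by 15.6% relative to leaving the orders untouched;
by τ = 0.4 almost nothing is revised and the two strategies coincide. The
threshold is the institution's choice of how large an estimated error has
to be before the clinician is interrupted.

The clinical-model column uses the bundled `gage_config_synthetic.json`,
whose coefficients are **synthetic placeholders** (the published equation's
coefficients are not shipped); substitute your own transcription via
`--gage-config` for real comparisons. `warfrev simulate` writes cohorts as
CSV + JSON schema sidecars, and `warfrev gage-show` validates and
pretty-prints a dosing-equation config.

From Python, the same pipeline is three calls:

```python
from warfrev import default_spec_from_tables, generate_cohort, inject_missingness, run_experiment

spec = default_spec_from_tables(n_patients=150, seed=5)
cohort = inject_missingness(generate_cohort(spec), spec.missingness_rates, seed=6)
report = run_experiment(cohort)
print(report.to_markdown())
```

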