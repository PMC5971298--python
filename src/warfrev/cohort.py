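"""Synthetic warfarin cohorts.

The real study cohort (150 warfarin-treated inpatients with the clinician's
initial order, the eventual therapeutic dose, and a few dozen clinical
covariates) was never deposited.  This module generates seeded synthetic
cohorts with the same statistical skeleton: covariate marginals transcribed
from the published summary tables, a log-linear therapeutic-dose model, and a
clinician model that produces an Initial Dose Prescribed (IDP) carrying noisy
signal about the therapeutic dose, snapped to the discrete doses clinicians
actually order.

Every downstream stage (preprocessing, LASSO, revision, evaluation) is
exercised against these cohorts, so generation is fully deterministic given a
spec and seed.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VariableDef",
    "SyntheticSpec",
    "CohortTable",
    "generate_cohort",
    "inject_missingness",
    "default_spec_from_tables",
]

LABEL_COL = "therapeutic_dose"
IDP_COL = "idp"
TRUTH_COL = "true_percentage_error"


# ---------------------------------------------------------------------------
# schema / container types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableDef:
    """Schema entry for one cohort variable."""

    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] | None = None
    reference_level: str | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError("categorical variable needs levels")
            if self.reference_level is not None and self.reference_level not in self.levels:
                raise ValueError("reference level not among levels")


@dataclass(frozen=True)
class ContinuousMarginal:
    """Target moments and support for one continuous covariate."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min < self.mean < self.max):
            raise ValueError("mean must lie inside [min, max]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class DoseModel:
    """Log-linear model for the therapeutic dose.

    ``log(TD) = intercept + sum_j coef_j * x_j + Normal(0, noise_sd)``,
    exponentiated and truncated to the therapeutic-dose support.  Continuous
    coefficients are keyed by variable name, categorical ones by
    ``"variable=level"`` (indicator coding on the raw levels).
    """

    intercept: float
    coefficients: Mapping[str, float]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class ClinicianModel:
    """How the ordering clinician arrives at the IDP.

    ``raw = TD * (1 + Normal(0, noise_sd))`` is blended with a
    population-typical dose, ``signal_weight * raw + (1 - signal_weight) *
    typical_dose``, then snapped to the popular dose grid with probability
    ``popular_prob`` (else to the nearest value of the full order grid).
    """

    signal_weight: float
    noise_sd: float
    popular_grid: tuple[float, ...]
    popular_prob: float
    full_grid: tuple[float, ...]
    typical_dose: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_weight <= 1.0:
            raise ValueError("signal_weight must be in [0, 1]")
        if not 0.0 <= self.popular_prob <= 1.0:
            raise ValueError("popular_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.popular_grid or not self.full_grid:
            raise ValueError("dose grids must be nonempty")
        if any(g <= 0 for g in self.full_grid) or any(g <= 0 for g in self.popular_grid):
            raise ValueError("all grid doses must be positive")
        if not set(self.popular_grid) <= set(self.full_grid):
            raise ValueError("popular_grid must be a subset of full_grid")


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for a synthetic cohort."""

    n_patients: int
    seed: int
    continuous_marginals: Mapping[str, ContinuousMarginal]
    categorical_marginals: Mapping[str, Mapping[str, float]]
    dose_model: DoseModel
    clinician_model: ClinicianModel
    missingness_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, marg in self.categorical_marginals.items():
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities for {name!r} sum to {total}, not 1")
            if any(p < 0 for p in marg.values()):
                raise ValueError(f"negative probability in {name!r}")
        for name, rate in self.missingness_rates.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1)")

    def schema(self) -> dict[str, VariableDef]:
        """Variable schema implied by the spec (covariates + doses)."""
        schema: dict[str, VariableDef] = {}
        for name, marg in self.continuous_marginals.items():
            schema[name] = VariableDef(kind="continuous", units=_UNITS.get(name))
        for name, marg in self.categorical_marginals.items():
            levels = tuple(marg)
            ref = max(marg, key=lambda lev: (marg[lev], lev))
            schema[name] = VariableDef(kind="categorical", levels=levels, reference_level=ref)
        schema[IDP_COL] = VariableDef(kind="continuous", units="mg/day")
        schema[LABEL_COL] = VariableDef(kind="continuous", units="mg/day")
        schema[TRUTH_COL] = VariableDef(kind="continuous", units="fraction")
        return schema


@dataclass
class CohortTable:
    """A cohort: one row per patient, plus schema and missingness mask.

    ``data`` holds missing cells as NaN/pd.NA; ``missing_mask`` exposes them
    as booleans.  Row index is the patient id (unique strings).
    """

    data: pd.DataFrame
    schema: dict[str, VariableDef]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        unknown = set(self.data.columns) - set(self.schema)
        if unknown:
            raise ValueError(f"columns missing from schema: {sorted(unknown)}")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, ids: Sequence) -> "CohortTable":
        return CohortTable(self.data.loc[list(ids)].copy(), dict(self.schema))

    def drop_variables(self, names: Sequence[str]) -> "CohortTable":
        keep = [c for c in self.data.columns if c not in set(names)]
        schema = {k: v for k, v in self.schema.items() if k not in set(names)}
        return CohortTable(self.data[keep].copy(), schema)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path_or_buf=None) -> str | None:
        return self.data.to_csv(path_or_buf, index=True, index_label="id", na_rep="")

    def schema_json(self) -> str:
        payload = {
            name: {
                "kind": d.kind,
                "levels": list(d.levels) if d.levels else None,
                "reference_level": d.reference_level,
                "units": d.units,
            }
            for name, d in self.schema.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_csv(cls, csv_text_or_path, schema_json: str) -> "CohortTable":
        payload = json.loads(schema_json)
        schema = {
            name: VariableDef(
                kind=d["kind"],
                levels=tuple(d["levels"]) if d.get("levels") else None,
                reference_level=d.get("reference_level"),
                units=d.get("units"),
            )
            for name, d in payload.items()
        }
        if isinstance(csv_text_or_path, str) and "\n" in csv_text_or_path:
            csv_text_or_path = io.StringIO(csv_text_or_path)
        dtypes = {n: object for n, d in schema.items() if d.kind == "categorical"}
        # "None" is a legitimate categorical level (no statin), so only the
        # empty field marks a missing cell; round_trip keeps floats exact
        df = pd.read_csv(
            csv_text_or_path,
            index_col="id",
            dtype=dtypes,
            keep_default_na=False,
            na_values=[""],
            float_precision="round_trip",
        )
        df.index = df.index.astype(str)
        return cls(df, schema)


_UNITS = {
    "age": "years", "height": "cm", "weight": "kg", "crcl": "ml/min",
    "albumin": "g/dl", "ast": "u/L", "alt": "u/L", "baseline_inr": None,
}


# ---------------------------------------------------------------------------
# moment-matched truncated sampling
# ---------------------------------------------------------------------------
# Plain truncated normals cannot reproduce the published lab marginals: AST
# has sd 41 against a mean only 25 above its observed minimum, which no
# truncated normal (or exponential) can achieve.  We therefore match each
# variable's *truncated* mean and sd by solving for underlying parameters:
# a truncated normal for near-symmetric variables, a shifted lognormal
# (truncated at the observed max) when sd/(mean - min) marks heavy skew.

_SKEW_CUTOFF = 0.6


def _truncnorm_params(m: ContinuousMarginal) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [min,max]-truncation has the target moments."""

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (m.min - mu) / sigma, (m.max - mu) / sigma
        mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(mean) - m.mean, math.sqrt(float(var)) - m.sd]

    sol = optimize.root(moments, [m.mean, math.log(m.sd)], method="hybr")
    mu, log_sigma = sol.x
    if not sol.success:  # fall back to naive parameters; shift is modest here
        return m.mean, m.sd
    return float(mu), float(math.exp(log_sigma))


def _shifted_lognorm_params(m: ContinuousMarginal) -> tuple[float, float]:
    """(mu, sigma) of log(X - min) with X truncated at max, matched to moments."""
    b = math.log(m.max - m.min)
    t_mean, t_sd = m.mean - m.min, m.sd

    def trunc_moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        z = (b - mu) / sigma
        denom = stats.norm.cdf(z)
        if denom < 1e-12:
            return [1e6, 1e6]
        m1 = math.exp(mu + sigma**2 / 2) * stats.norm.cdf(z - sigma) / denom
        m2 = math.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(z - 2 * sigma) / denom
        var = max(m2 - m1**2, 1e-12)
        return [m1 - t_mean, math.sqrt(var) - t_sd]

    cv2 = (t_sd / t_mean) ** 2
    sigma0 = math.sqrt(math.log1p(cv2))
    mu0 = math.log(t_mean) - sigma0**2 / 2
    sol = optimize.root(trunc_moments, [mu0, math.log(sigma0)], method="hybr")
    if not sol.success:
        return mu0, sigma0
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _sample_continuous(m: ContinuousMarginal, n: int, rng: np.random.Generator) -> np.ndarray:
    if m.sd / (m.mean - m.min) > _SKEW_CUTOFF:
        mu, sigma = _shifted_lognorm_params(m)
        b = (math.log(m.max - m.min) - mu) / sigma
        z = stats.truncnorm.ppf(rng.uniform(size=n), -np.inf, b)
        return m.min + np.exp(mu + sigma * z)
    mu, sigma = _truncnorm_params(m)
    a, b = (m.min - mu) / sigma, (m.max - mu) / sigma
    return stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=mu, scale=sigma)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _snap(values: np.ndarray, grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(sorted(grid), dtype=float)
    idx = np.abs(values[:, None] - g[None, :]).argmin(axis=1)
    return g[idx]


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Draw a full synthetic cohort (covariates, therapeutic dose, IDP).

    Deterministic: identical spec (including seed) gives a bit-identical
    table.  Missingness is *not* injected here; see :func:`inject_missingness`.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    cols: dict[str, np.ndarray | list] = {}

    for name, marg in spec.continuous_marginals.items():
        if name in (LABEL_COL, IDP_COL):
            continue  # generated by the dose / clinician models below
        cols[name] = _sample_continuous(marg, n, rng)

    for name, marg in spec.categorical_marginals.items():
        levels = list(marg)
        probs = np.asarray([marg[lev] for lev in levels], dtype=float)
        draws = rng.choice(len(levels), size=n, p=probs / probs.sum())
        cols[name] = [levels[i] for i in draws]

    # therapeutic dose: log-linear in the covariates
    lp = np.full(n, spec.dose_model.intercept, dtype=float)
    for key, coef in spec.dose_model.coefficients.items():
        if "=" in key:
            var, level = key.split("=", 1)
            x = np.asarray([1.0 if v == level else 0.0 for v in cols[var]])
        else:
            x = np.asarray(cols[key], dtype=float)
        lp += coef * x
    lp += rng.normal(0.0, spec.dose_model.noise_sd, size=n)
    td_marg = spec.continuous_marginals[LABEL_COL]
    td = np.clip(np.exp(lp), td_marg.min, td_marg.max)

    # clinician model: noisy multiplicative read of TD, blended with a
    # population-typical dose, then snapped onto a discrete order grid
    cm = spec.clinician_model
    raw = td * (1.0 + rng.normal(0.0, cm.noise_sd, size=n))
    blended = cm.signal_weight * raw + (1.0 - cm.signal_weight) * cm.typical_dose
    use_popular = rng.uniform(size=n) < cm.popular_prob
    # the unpopular branch snaps to the *non-popular* grid values so that the
    # popular-dose fraction is popular_prob exactly, mirroring the Pareto
    # structure of real order data
    alt_grid = tuple(g for g in cm.full_grid if g not in cm.popular_grid) or cm.popular_grid
    idp = np.where(
        use_popular,
        _snap(blended, cm.popular_grid),
        _snap(blended, alt_grid),
    )

    cols[LABEL_COL] = td
    cols[IDP_COL] = idp
    cols[TRUTH_COL] = (idp - td) / td

    index = pd.Index([f"P{i:04d}" for i in range(n)], name="id")
    order = (
        [c for c in spec.continuous_marginals if c not in (LABEL_COL, IDP_COL)]
        + list(spec.categorical_marginals)
        + [IDP_COL, LABEL_COL, TRUTH_COL]
    )
    df = pd.DataFrame(cols, index=index)[order]
    return CohortTable(df, spec.schema())


def inject_missingness(
    cohort: CohortTable,
    rates: Mapping[str, float],
    seed: int,
) -> CohortTable:
    """Mask cells missing-completely-at-random at per-variable rates."""
    for name, rate in rates.items():
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"missingness rate for {name!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    for name in cohort.data.columns:  # fixed iteration order => reproducible
        rate = rates.get(name, 0.0)
        if rate <= 0.0:
            continue
        mask = rng.uniform(size=len(df)) < rate
        if cohort.schema[name].kind == "categorical":
            col = df[name].astype(object)
            col[mask] = pd.NA
            df[name] = col
        else:
            df.loc[mask, name] = np.nan
    return CohortTable(df, dict(cohort.schema))


# ---------------------------------------------------------------------------
# default spec transcribed from the published summary tables
# ---------------------------------------------------------------------------

_N_SOURCE = 150  # size of the original study cohort

# categorical marginals as (observed-level counts, missing count)
_CATEGORICAL_COUNTS: dict[str, tuple[dict[str, int], int]] = {
    "race": ({"AfricanAmerican": 79, "Hispanic": 34, "White": 18, "Asian": 4, "Others": 15}, 0),
    "gender": ({"Male": 67, "Female": 83}, 0),
    "liver_disease": ({"Yes": 3, "No": 125}, 22),
    "warfarin_indication": (
        {"A.fib": 25, "DVT": 53, "PE": 34, "TKA/THA": 13, "MVR": 1, "CVA": 4, "Others": 20}, 0),
    "goal_inr": ({"2-3": 136, "2.5-3.5": 3, "1.8-2.5": 11}, 0),
    "amiodarone": ({"Yes": 5, "No": 144}, 1),
    "bactrim": ({"Yes": 1, "No": 148}, 1),
    "azole": ({"Yes": 1, "No": 148}, 1),
    "statin": ({"None": 93, "Simva": 14, "Atorva": 23, "Prava": 7, "Lova": 8, "Rosuva": 4}, 1),
    "dialysis": ({"Yes": 8, "No": 142}, 0),
    "rheumatoid_arthritis": ({"Yes": 1, "No": 149}, 0),
    "collagen_vascular_disease": ({"Yes": 2, "No": 148}, 0),
    "dvt_history": ({"Yes": 10, "No": 140}, 0),
    "smoking": ({"Current smoker": 13, "Never smoker": 107, "Ex-smoker": 30}, 0),
    "etoh": ({"Yes": 24, "No": 119}, 7),
    "illicit": ({"Yes": 6, "No": 144}, 0),
    "hypertension": ({"Yes": 86, "No": 64}, 0),
    "angina": ({"Yes": 1, "No": 149}, 0),
    "myocardial_infarction": ({"Yes": 3, "No": 147}, 0),
    "pci": ({"Yes": 6, "No": 144}, 0),
    "cabg": ({"Yes": 5, "No": 145}, 0),
    "afib_flutter": ({"Yes": 11, "No": 139}, 0),
    "dm": ({"Yes": 48, "No": 102}, 0),
    "stroke": ({"Yes": 11, "No": 139}, 0),
    "chronic_renal_insufficiency": ({"Yes": 15, "No": 135}, 0),
    "copd": ({"Yes": 7, "No": 143}, 0),
    "asthma": ({"Yes": 18, "No": 132}, 0),
    "valvular_heart_disease": ({"Yes": 1, "No": 149}, 0),
    "sickle_cell": ({"Yes": 3, "No": 147}, 0),
    "cancer_history": ({"Yes": 12, "No": 138}, 0),
    "pe_history": ({"Yes": 5, "No": 144}, 1),
    "dyslipidemia": ({"Yes": 53, "No": 97}, 0),
    "heart_failure": ({"Yes": 15, "No": 135}, 0),
    "pvd": ({"Yes": 7, "No": 143}, 0),
}

# continuous marginals: mean, sd, min, max (+ missing count)
_CONTINUOUS_ROWS: dict[str, tuple[float, float, float, float, int]] = {
    LABEL_COL: (5.68, 2.87, 0.9, 16.8, 0),
    IDP_COL: (6.12, 2.59, 1.0, 16.0, 2),
    "age": (54.29, 17.82, 18.0, 91.0, 0),
    "height": (168.28, 10.35, 142.2, 195.0, 0),
    "weight": (89.9, 31.12, 40.0, 220.0, 0),
    "crcl": (64.79, 36.32, 3.6, 146.5, 2),
    "albumin": (3.12, 0.65, 1.4, 4.3, 17),
    "ast": (33.56, 41.04, 9.0, 379.0, 22),
    "alt": (25.88, 24.85, 5.0, 199.0, 22),
    "baseline_inr": (1.18, 0.14, 1.0, 1.8, 1),
}

POPULAR_GRID = (2.5, 4.0, 5.0, 7.5, 10.0)
FULL_GRID = (
    1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5,
    8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0,
)

# defaults for the stand-in dose model: a handful of clinically-signed
# effects on log dose, concentrated in few covariates so a sparse model can
# recover them at realistic cohort sizes.  Effect sizes put most of the
# log-dose variance on the recorded covariates: the study this emulates
# demonstrated a highly predictable dosing error, which requires the
# therapeutic dose itself to be predictable from what was recorded.  Total
# log-dose sd ~0.44 approximates the printed dose marginal (mean 5.68,
# sd 2.87).
_DEFAULT_DOSE_COEFS = {
    "age": -0.010,
    "weight": 0.010,
    "albumin": 0.10,
    "race=AfricanAmerican": 0.20,
    "amiodarone=Yes": -0.50,
}
_DEFAULT_DOSE_NOISE_SD = 0.2
# clinician anchor 7.5 mg/day reproduces the printed IDP mean (6.12 vs
# therapeutic 5.68: clinicians run high) at signal weight 0.8
_DEFAULT_CLINICIAN = dict(
    signal_weight=0.8, noise_sd=0.3, popular_prob=0.75, typical_dose=7.5
)


def default_spec_from_tables(n_patients: int = 150, seed: int = 0) -> SyntheticSpec:
    """Spec transcribing the published cohort summaries.

    Continuous marginals and per-variable missingness rates come straight
    from the printed summary rows; categorical marginals are the printed
    level frequencies normalized over observed values.  The dose and
    clinician models are this package's stand-in for the unavailable
    data-generating process (see the methods note).
    """
    cat = {
        name: {lev: cnt / sum(counts.values()) for lev, cnt in counts.items()}
        for name, (counts, _miss) in _CATEGORICAL_COUNTS.items()
    }
    cont = {
        name: ContinuousMarginal(mean=m, sd=s, min=lo, max=hi)
        for name, (m, s, lo, hi, _miss) in _CONTINUOUS_ROWS.items()
    }
    missing = {
        name: miss / _N_SOURCE for name, (_c, miss) in _CATEGORICAL_COUNTS.items() if miss
    }
    missing.update(
        {name: miss / _N_SOURCE for name, (*_m, miss) in _CONTINUOUS_ROWS.items() if miss}
    )

    # intercept set so E[log TD] targets the printed mean dose after
    # accounting for covariate and noise variance (lognormal mean formula);
    # covariates are independent in this generator, so the linear-predictor
    # variance is the sum of per-term variances
    coef_mean = 0.0
    var_lp = 0.0
    for key, coef in _DEFAULT_DOSE_COEFS.items():
        if "=" in key:
            var, level = key.split("=", 1)
            p = cat[var][level]
            coef_mean += coef * p
            var_lp += coef**2 * p * (1.0 - p)
        else:
            coef_mean += coef * cont[key].mean
            var_lp += coef**2 * cont[key].sd ** 2
    target = math.log(5.68) - 0.5 * (var_lp + _DEFAULT_DOSE_NOISE_SD**2)
    intercept = target - coef_mean

    return SyntheticSpec(
        n_patients=n_patients,
        seed=seed,
        continuous_marginals=cont,
        categorical_marginals=cat,
        dose_model=DoseModel(
            intercept=intercept,
            coefficients=dict(_DEFAULT_DOSE_COEFS),
            noise_sd=_DEFAULT_DOSE_NOISE_SD,
        ),
        clinician_model=ClinicianModel(
            popular_grid=POPULAR_GRID,
            full_grid=FULL_GRID,
            **_DEFAULT_CLINICIAN,
        ),
        missingness_rates=missing,
    )


def respec(spec: SyntheticSpec, **changes) -> SyntheticSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **changes)
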