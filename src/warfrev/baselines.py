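"""Comparator dosing models.

Two comparators frame the evaluation besides the clinician's untouched
order: a Gage-style clinical dosing equation (body surface area, age, target
INR, race, smoking, amiodarone, VTE indication) whose coefficients are
loaded from a config file, and a percentage-error model fitted without the
clinician's initial dose.

The shipped config ``data/gage_config_synthetic.json`` contains SYNTHETIC
placeholder coefficients with clinically plausible signs and scale — it is
NOT the published 2008 equation.  Users evaluating against the real model
should transcribe the published coefficients into their own config.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable

__all__ = [
    "GageConfig",
    "body_surface_area",
    "gage_clinical_dose",
    "gage_doses",
    "load_gage_config",
    "synthetic_gage_config_path",
]

KNOWN_FACTORS = (
    "bsa", "age", "target_inr", "smoker", "african_american", "amiodarone",
    "vte_indication",
)

# how the cohort's goal-INR categories map onto a numeric target
GOAL_INR_MIDPOINTS = {"2-3": 2.5, "2.5-3.5": 3.0, "1.8-2.5": 2.15}


def body_surface_area(height: float, weight: float, formula: str = "mosteller") -> float:
    """Body surface area in m² from height (cm) and weight (kg)."""
    if np.any(np.asarray(height) <= 0) or np.any(np.asarray(weight) <= 0):
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return np.sqrt(np.asarray(height) * np.asarray(weight) / 3600.0)
    if formula == "dubois":
        return 0.007184 * np.asarray(height) ** 0.725 * np.asarray(weight) ** 0.425
    raise ValueError(f"unknown BSA formula {formula!r}")


@dataclass(frozen=True)
class GageConfig:
    """A linear clinical dosing equation over the Gage factor set."""

    intercept: float
    coefficients: Mapping[str, float]
    age_unit: str = "years"          # "years" | "decades"
    link: str = "log"                # "log" | "identity"
    output_unit: str = "mg/day"      # "mg/day" | "mg/wk"
    bsa_formula: str = "mosteller"
    label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(KNOWN_FACTORS)
        if unknown:
            raise ValueError(f"unknown Gage factor(s): {sorted(unknown)}")
        if self.age_unit not in ("years", "decades"):
            raise ValueError("age_unit must be 'years' or 'decades'")
        if self.link not in ("log", "identity"):
            raise ValueError("link must be 'log' or 'identity'")
        if self.output_unit not in ("mg/day", "mg/wk"):
            raise ValueError("output_unit must be 'mg/day' or 'mg/wk'")

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": dict(self.coefficients),
                "age_unit": self.age_unit,
                "link": self.link,
                "output_unit": self.output_unit,
                "bsa_formula": self.bsa_formula,
                "label": self.label,
            },
            indent=2,
        )

    @classmethod
    def from_mapping(cls, d: Mapping) -> "GageConfig":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            age_unit=d.get("age_unit", "years"),
            link=d.get("link", "log"),
            output_unit=d.get("output_unit", "mg/day"),
            bsa_formula=d.get("bsa_formula", "mosteller"),
            label=d.get("label", ""),
        )

    def describe(self) -> str:
        """The parsed equation in human-readable form."""
        terms = " + ".join(f"{c:+g}*{k}" for k, c in self.coefficients.items())
        lp = f"{self.intercept:g} {terms}" if terms else f"{self.intercept:g}"
        rhs = f"exp({lp})" if self.link == "log" else lp
        note = f"  [{self.label}]" if self.label else ""
        return f"dose[{self.output_unit}] = {rhs}  (age in {self.age_unit}){note}"


def load_gage_config(path) -> GageConfig:
    text = open(path).read()
    d = yaml.safe_load(text)  # YAML is a superset of JSON
    return GageConfig.from_mapping(d)


def synthetic_gage_config_path():
    """Path to the bundled synthetic placeholder config."""
    return resources.files("warfrev").joinpath("data/gage_config_synthetic.json")


def _factors_from_row(row: pd.Series, config: GageConfig) -> dict[str, float]:
    needed = set(config.coefficients)
    out: dict[str, float] = {}

    def require(col):
        if col not in row.index or pd.isna(row[col]):
            raise ValueError(f"missing covariate {col!r} required by the Gage config")
        return row[col]

    if "bsa" in needed:
        out["bsa"] = float(
            body_surface_area(require("height"), require("weight"), config.bsa_formula)
        )
    if "age" in needed:
        age = float(require("age"))
        out["age"] = age / 10.0 if config.age_unit == "decades" else age
    if "target_inr" in needed:
        goal = require("goal_inr")
        if goal not in GOAL_INR_MIDPOINTS:
            raise ValueError(f"unmapped goal INR category {goal!r}")
        out["target_inr"] = GOAL_INR_MIDPOINTS[goal]
    if "smoker" in needed:
        out["smoker"] = 1.0 if require("smoking") == "Current smoker" else 0.0
    if "african_american" in needed:
        out["african_american"] = 1.0 if require("race") == "AfricanAmerican" else 0.0
    if "amiodarone" in needed:
        out["amiodarone"] = 1.0 if require("amiodarone") == "Yes" else 0.0
    if "vte_indication" in needed:
        out["vte_indication"] = 1.0 if require("warfarin_indication") in ("DVT", "PE") else 0.0
    return out


def gage_clinical_dose(record: pd.Series | Mapping, config: GageConfig) -> float:
    """Deterministic clinical dose (mg/day) for one patient row."""
    row = record if isinstance(record, pd.Series) else pd.Series(dict(record))
    factors = _factors_from_row(row, config)
    lp = config.intercept + sum(
        coef * factors[name] for name, coef in config.coefficients.items()
    )
    dose = math.exp(lp) if config.link == "log" else lp
    if dose <= 0:
        raise ValueError(f"non-positive dose {dose:g} from identity-link config")
    if config.output_unit == "mg/wk":
        dose /= 7.0
    return float(dose)


def gage_doses(cohort: CohortTable, config: GageConfig) -> np.ndarray:
    """Vectorized :func:`gage_clinical_dose` over a cohort (mg/day)."""
    return np.array(
        [gage_clinical_dose(row, config) for _, row in cohort.data.iterrows()]
    )


def fit_no_idp_model(train: CohortTable, test: CohortTable, settings=None):
    """The comparator error model fitted without the clinician's order.

    Identical pipeline to the with-IDP model except that no IDP-derived
    column enters the design; the returned fit is flagged ``uses_idp=False``.
    """
    from .evaluation import ExperimentSettings, fit_error_model

    settings = settings or ExperimentSettings()
    fit, preds, test_mat = fit_error_model(train, test, settings, include_idp=False)
    return fit, preds, test_mat
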