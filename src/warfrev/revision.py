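"""Turning an estimated percentage error into a revise/keep decision.

Given the clinician's order (IDP) and an estimated percentage error e-hat
(a fraction; +0.25 means the order looks 25% above the therapeutic dose),
the order is revised only when |e-hat| exceeds the institution's
significance threshold tau.  Two revision formulas are available:

* ``printed_eq3`` — revised = (1 - e-hat) * IDP, the published linear
  correction (with its percent scale converted to fractions);
* ``exact_inversion`` — revised = IDP / (1 + e-hat), which exactly inverts
  the therapeutic-dose-denominator error definition.

The two agree to first order in e-hat; they are not identical because the
linear correction does not exactly invert the error definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["RevisionDecision", "decide", "batch_revise", "VARIANTS"]

VARIANTS = ("printed_eq3", "exact_inversion")
DEFAULT_MIN_DOSE = 0.5  # mg/day floor for a revised order


@dataclass(frozen=True)
class RevisionDecision:
    patient_id: str
    idp: float
    estimated_error: float
    threshold: float
    revised: bool
    revised_dose: float
    variant: str

    def __post_init__(self) -> None:
        if self.revised_dose <= 0:
            raise ValueError("revised dose must be positive")
        if not self.revised and self.revised_dose != self.idp:
            raise ValueError("kept orders must retain the IDP exactly")


def decide(
    idp: float,
    estimated_error: float,
    threshold: float,
    variant: str = "printed_eq3",
    patient_id: str = "",
    min_dose: float = DEFAULT_MIN_DOSE,
) -> RevisionDecision:
    """Revise the order iff |estimated_error| > threshold."""
    if idp <= 0:
        raise ValueError("idp must be positive")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")

    e = float(estimated_error)
    if abs(e) <= threshold:
        return RevisionDecision(patient_id, idp, e, threshold, False, float(idp), variant)

    if variant == "printed_eq3":
        dose = (1.0 - e) * idp
        if dose <= 0:
            warnings.warn(
                f"revision formula gave non-positive dose for e={e:g}; "
                f"flooring at {min_dose} mg/day"
            )
            dose = min_dose
    else:
        if e <= -1.0:
            raise ValueError("estimated error <= -1 cannot be inverted")
        dose = idp / (1.0 + e)
    if dose < min_dose:
        warnings.warn(f"revised dose {dose:g} below floor; using {min_dose} mg/day")
        dose = min_dose
    return RevisionDecision(patient_id, idp, e, threshold, True, float(dose), variant)


def batch_revise(
    ids: Sequence[str],
    idp: Sequence[float],
    predictions: Sequence[float],
    threshold: float,
    variant: str = "printed_eq3",
    min_dose: float = DEFAULT_MIN_DOSE,
) -> list[RevisionDecision]:
    """Elementwise :func:`decide`, order preserved."""
    idp = np.asarray(idp, dtype=float)
    preds = np.asarray(predictions, dtype=float)
    if len(idp) != len(preds) or len(ids) != len(idp):
        raise ValueError("ids, idp and predictions must have equal length")
    return [
        decide(d, e, threshold, variant=variant, patient_id=str(pid), min_dose=min_dose)
        for pid, d, e in zip(ids, idp, preds)
    ]


def revised_doses(decisions: Sequence[RevisionDecision]) -> np.ndarray:
    return np.array([d.revised_dose for d in decisions])


def revision_counts(decisions: Sequence[RevisionDecision]) -> dict[str, int]:
    n_rev = sum(d.revised for d in decisions)
    return {"revised": int(n_rev), "kept": int(len(decisions) - n_rev)}


def decisions_to_csv(decisions: Sequence[RevisionDecision]) -> str:
    lines = ["id,idp,estimated_error,threshold,revised,revised_dose,variant"]
    for d in decisions:
        lines.append(
            f"{d.patient_id},{d.idp!r},{d.estimated_error!r},{d.threshold!r},"
            f"{int(d.revised)},{d.revised_dose!r},{d.variant}"
        )
    return "\n".join(lines) + "\n"
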