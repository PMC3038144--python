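"""Infant energy-requirement prediction equations.

Eleven published linear equations estimate a daily metabolic rate from an
infant's weight (and optionally length): six chamber-derived equations
(EMTAC*, applicable to either sex, targeting 24-h energy expenditure, resting
or sleeping metabolic rate) and five classical basal-rate equations (WHO,
Schofield and Oxford, one formula per sex).  All formulas produce whole-body
kcal/d; the conventional reporting unit kcal/kg/d is obtained by dividing by
body weight, and this module exposes both.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .records import FEMALE, MALE, InfantRecord

__all__ = [
    "EquationSpec",
    "EnergyPrediction",
    "CohortPrediction",
    "EQUATION_NAMES",
    "load_registry",
    "select_equation",
    "evaluate_equation",
    "cohort_apply",
    "UnknownEquationError",
    "SexMismatchError",
    "MissingLengthError",
]

ANY_SEX = "any"

#: canonical registry order of the 11 equation names
EQUATION_NAMES = (
    "EMTACEE-WT",
    "EMTACEE-LWT",
    "EMTACRMR-WT",
    "EMTACRMR-LWT",
    "EMTACSMR-WT",
    "EMTACSMR-LWT",
    "WHO",
    "SCH-WT",
    "SCH-LWT",
    "OXFORD-WT",
    "OXFORD-LWT",
)


class UnknownEquationError(KeyError):
    """Raised for an equation name absent from the registry."""


class SexMismatchError(ValueError):
    """Raised when a sex-specific equation is applied to the wrong sex."""


class MissingLengthError(ValueError):
    """Raised when a length-weight equation is applied without a length."""


@dataclass(frozen=True)
class EquationSpec:
    """One linear prediction equation: ``weight_coef*WT + length_coef*L + intercept`` (kcal/d)."""

    name: str
    sex: str  # male | female | any
    target: str  # EE24 | RMR | SMR
    weight_coef: float  # kcal/d per kg
    length_coef: float  # kcal/d per cm; 0 when the equation is weight-only
    intercept: float  # kcal/d

    @property
    def uses_length(self) -> bool:
        return self.length_coef != 0.0


@dataclass(frozen=True)
class EnergyPrediction:
    """Whole-body and weight-normalised prediction for one infant."""

    total_kcal_d: float
    per_kg: float  # kcal/kg/d


@dataclass(frozen=True)
class CohortPrediction:
    """Per-infant kcal/kg/d values for one equation over a cohort."""

    name: str
    values: np.ndarray  # kcal/kg/d, cohort order
    mean: float
    sd: float  # sample SD (n-1); 0.0 for n == 1


@lru_cache(maxsize=1)
def load_registry() -> tuple[EquationSpec, ...]:
    """Load the shipped equation registry (one spec per Table row)."""
    text = resources.files("infant_ee").joinpath("data/equations.yaml").read_text()
    raw = yaml.safe_load(text)
    specs = tuple(
        EquationSpec(
            name=row["name"],
            sex=row["sex"],
            target=row["target"],
            weight_coef=float(row["weight_coef"]),
            length_coef=float(row["length_coef"]),
            intercept=float(row["intercept"]),
        )
        for row in raw["equations"]
    )
    return specs


def select_equation(name: str, sex: str) -> EquationSpec:
    """Return the spec for ``name`` appropriate for an infant of ``sex``.

    Sex-neutral equations are returned regardless of ``sex``; sexed equations
    return the matching variant.
    """
    found = [s for s in load_registry() if s.name == name]
    if not found:
        raise UnknownEquationError(
            f"unknown equation {name!r}; known: {', '.join(EQUATION_NAMES)}"
        )
    if len(found) == 1 and found[0].sex == ANY_SEX:
        return found[0]
    for spec in found:
        if spec.sex == sex:
            return spec
    raise SexMismatchError(
        f"equation {name!r} has no variant for sex {sex!r}"
    )


def equation_target(name: str) -> str:
    """The measured quantity (EE24/RMR/SMR) an equation estimates."""
    for s in load_registry():
        if s.name == name:
            return s.target
    raise UnknownEquationError(f"unknown equation {name!r}")


def evaluate_equation(spec: EquationSpec, infant: InfantRecord) -> EnergyPrediction:
    """Evaluate one equation on one infant.

    Returns the whole-body rate (kcal/d) and the same rate divided by the
    infant's weight (kcal/kg/d).  Raises :class:`SexMismatchError` if the
    equation is sex-specific and does not match, and
    :class:`MissingLengthError` if a length term is needed but no length is
    available.
    """
    if spec.sex != ANY_SEX and spec.sex != infant.sex:
        raise SexMismatchError(
            f"equation {spec.name!r} is for {spec.sex} infants; "
            f"infant {infant.id!r} is {infant.sex}"
        )
    if spec.uses_length and not infant.length_cm > 0:
        raise MissingLengthError(
            f"equation {spec.name!r} needs a length for infant {infant.id!r}"
        )
    total = (
        spec.weight_coef * infant.weight_kg
        + spec.length_coef * infant.length_cm
        + spec.intercept
    )
    return EnergyPrediction(total_kcal_d=total, per_kg=total / infant.weight_kg)


def cohort_apply(name: str, cohort: list[InfantRecord]) -> CohortPrediction:
    """Apply one named equation to every infant of a cohort (kcal/kg/d).

    The sex-appropriate variant is chosen per infant.  SD uses the sample
    (n-1) denominator, 0.0 for a single infant.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    values = np.array(
        [
            evaluate_equation(select_equation(name, infant.sex), infant).per_kg
            for infant in cohort
        ]
    )
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return CohortPrediction(
        name=name, values=values, mean=float(np.mean(values)), sd=sd
    )
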