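"""Subject records and anthropometric helpers.

An :class:`InfantRecord` carries the sex and body-size measurements that the
prediction equations consume: length (cm), weight (kg) and BMI (kg/m^2).
Reference cohorts are often published with length and BMI but without raw
weight, so weight may be derived from BMI when absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "InfantRecord",
    "weight_from_bmi",
    "bmi_from_weight",
    "MALE",
    "FEMALE",
    "SEXES",
]

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: relative tolerance for declaring weight and BMI mutually consistent
BMI_CONSISTENCY_RTOL = 0.01


def weight_from_bmi(bmi: float, length_cm: float) -> float:
    """Body weight (kg) from BMI (kg/m^2) and recumbent length (cm).

    ``weight = bmi * (length/100)**2``; both inputs must be positive.
    """
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi!r}")
    if not length_cm > 0:
        raise ValueError(f"length_cm must be positive, got {length_cm!r}")
    return bmi * (length_cm / 100.0) ** 2


def bmi_from_weight(weight_kg: float, length_cm: float) -> float:
    """BMI (kg/m^2) from weight (kg) and length (cm)."""
    if not weight_kg > 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg!r}")
    if not length_cm > 0:
        raise ValueError(f"length_cm must be positive, got {length_cm!r}")
    return weight_kg / (length_cm / 100.0) ** 2


@dataclass
class InfantRecord:
    """One subject's sex and anthropometrics.

    Exactly one of ``weight_kg`` / ``bmi`` may be omitted; the missing one is
    derived from the other plus ``length_cm``.  When both are given but
    disagree by more than 1% the measured weight wins and a warning is issued.
    """

    id: str
    sex: str
    age_months: float
    length_cm: float
    weight_kg: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.length_cm > 0:
            raise ValueError("length_cm must be positive")
        if self.age_months < 0:
            raise ValueError("age_months must be non-negative")
        if self.weight_kg is None and self.bmi is None:
            raise ValueError("at least one of weight_kg or bmi is required")
        if self.weight_kg is None:
            self.weight_kg = weight_from_bmi(self.bmi, self.length_cm)
        elif self.bmi is None:
            self.bmi = bmi_from_weight(self.weight_kg, self.length_cm)
        else:
            implied = weight_from_bmi(self.bmi, self.length_cm)
            if abs(implied - self.weight_kg) > BMI_CONSISTENCY_RTOL * self.weight_kg:
                warnings.warn(
                    f"infant {self.id!r}: BMI {self.bmi:.2f} implies weight "
                    f"{implied:.3f} kg but measured weight is "
                    f"{self.weight_kg:.3f} kg; keeping measured weight",
                    stacklevel=2,
                )
        if not self.weight_kg > 0:
            raise ValueError("weight_kg must be positive")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "sex": self.sex,
            "age_months": self.age_months,
            "length_cm": self.length_cm,
            "weight_kg": self.weight_kg,
            "bmi": self.bmi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InfantRecord":
        return cls(
            id=str(d["id"]),
            sex=d["sex"],
            age_months=float(d["age_months"]),
            length_cm=float(d["length_cm"]),
            weight_kg=None if d.get("weight_kg") is None else float(d["weight_kg"]),
            bmi=None if d.get("bmi") is None else float(d["bmi"]),
        )
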