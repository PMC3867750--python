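"""Per-subject energy expenditure: BMR, AEE and their assembly into TEE.

Total energy expenditure (TEE) is built from three components:

* basal metabolic rate (BMR), predicted from sex, age, weight and height
  with age-banded linear coefficients (Schofield-type equations as revised
  by Henry; the coefficient table is injected, a transcription ships as
  package data);
* activity energy expenditure (AEE), predicted from mean accelerometer
  counts per minute with a sex-specific linear equation calibrated on
  free-living European children;
* diet-induced thermogenesis (DIT), taken to be 10% of TEE.

Because DIT is defined as a fraction of TEE itself, TEE = AEE + BMR + DIT
is closed algebraically: TEE = (AEE + BMR) / 0.9.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Sequence

import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

#: MJ per kcal (thermochemical calorie).
KCAL_TO_MJ = 4.184e-3

#: Fraction of total energy expenditure attributed to diet-induced thermogenesis.
DIT_FRACTION = 0.10

# Coefficients of the AEE prediction equation, kcal/day.
AEE_INTERCEPT_KCAL = 66.847
AEE_SLOPE_KCAL_PER_CPM = 0.953
AEE_GENDER_KCAL = 176.91


@dataclass(frozen=True)
class Subject:
    """Anthropometrics and covariates for one child.

    ``sex`` is ``"M"`` or ``"F"``; ``education`` is the 4-level parental
    education code (1 basic school, 2 vocational, 3 short further,
    4 medium/long further education). BMI is derived from weight and height
    rather than stored, so the three can never disagree.
    """

    subject_id: str
    sex: str
    age: float          # years
    weight: float       # kg
    height: float       # cm
    education: int = 2

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if not 5 <= self.age <= 18:
            warnings.warn(
                f"subject {self.subject_id}: age {self.age} outside the "
                "supported 5-18 y range",
                stacklevel=2,
            )
        if self.education not in (1, 2, 3, 4):
            raise ValueError(f"education must be in 1..4, got {self.education}")

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2."""
        return self.weight / (self.height / 100.0) ** 2

    @property
    def gender_code(self) -> int:
        """Sex coding of the AEE equation: 0 = boy, 1 = girl."""
        return 0 if self.sex == "M" else 1


@dataclass(frozen=True)
class BmrRow:
    sex: str
    age_min: float
    age_max: float
    c_weight: float      # MJ/day per kg
    c_height: float      # MJ/day per m
    c_intercept: float   # MJ/day


@dataclass
class BmrCoefficientTable:
    """Age-banded linear BMR coefficients, keyed by (sex, age band).

    Bands are half-open ``[age_min, age_max)`` and must not overlap within
    a sex.
    """

    rows: Sequence[BmrRow]
    source: str = ""

    def __post_init__(self) -> None:
        for sex in ("M", "F"):
            bands = sorted(
                (r for r in self.rows if r.sex == sex), key=lambda r: r.age_min
            )
            for a, b in zip(bands, bands[1:]):
                if b.age_min < a.age_max:
                    raise ConfigError(
                        f"BMR age bands overlap for sex {sex}: "
                        f"[{a.age_min},{a.age_max}) and [{b.age_min},{b.age_max})"
                    )

    def lookup(self, sex: str, age: float) -> BmrRow:
        for row in self.rows:
            if row.sex == sex and row.age_min <= age < row.age_max:
                return row
        raise ConfigError(
            f"no BMR coefficients cover sex={sex}, age={age}"
        )

    @classmethod
    def from_yaml(cls, path) -> "BmrCoefficientTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "BmrCoefficientTable":
        try:
            rows = [BmrRow(**r) for r in raw["rows"]]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed BMR coefficient table: {exc}") from exc
        return cls(rows=rows, source=raw.get("source", ""))

    @classmethod
    def henry(cls) -> "BmrCoefficientTable":
        """The bundled Henry weight-and-height coefficient table."""
        raw = yaml.safe_load(
            files("dietval.data").joinpath("henry_bmr.yaml").read_text()
        )
        return cls._from_mapping(raw)


@dataclass(frozen=True)
class EnergyComponents:
    """BMR, AEE, DIT and TEE (all MJ/day) for one subject-period."""

    subject_id: str
    period: str
    bmr: float
    aee: float
    dit: float
    tee: float

    def __post_init__(self) -> None:
        if not math.isclose(self.tee, self.aee + self.bmr + self.dit,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("TEE must equal AEE + BMR + DIT")
        if not math.isclose(self.dit, DIT_FRACTION * self.tee,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("DIT must be 10% of TEE")


def bmr_henry(subject: Subject, table: BmrCoefficientTable | None = None) -> float:
    """Predict basal metabolic rate in MJ/day.

    BMR = c_w * weight_kg + c_h * height_m + c_0 for the (sex, age band)
    row of ``table`` (the bundled Henry table if none is given).
    """
    if table is None:
        table = BmrCoefficientTable.henry()
    row = table.lookup(subject.sex, subject.age)
    return (
        row.c_weight * subject.weight
        + row.c_height * subject.height / 100.0
        + row.c_intercept
    )


def aee_ekelund(mean_cpm: float, gender_code: int) -> float:
    """Predict activity energy expenditure in kcal/day from mean cpm.

    AEE (kcal/day) = 66.847 + 0.953 * cpm - 176.91 * gender, where gender
    is 0 for boys and 1 for girls. The equation is evaluated exactly as
    printed; at very low cpm the girls' prediction can go negative, which
    is reported as-is with a warning.
    """
    if gender_code not in (0, 1):
        raise ValueError(f"gender_code must be 0 or 1, got {gender_code!r}")
    if mean_cpm < 0:
        raise ValueError(f"mean_cpm must be >= 0, got {mean_cpm}")
    aee = (
        AEE_INTERCEPT_KCAL
        + mean_cpm * AEE_SLOPE_KCAL_PER_CPM
        - AEE_GENDER_KCAL * gender_code
    )
    if aee < 0:
        logger.warning(
            "negative predicted AEE (%.2f kcal/day) at cpm=%.1f, gender=%d",
            aee, mean_cpm, gender_code,
        )
    return aee


def kcal_to_mj(x: float) -> float:
    """Convert kcal to MJ (1 kcal = 4.184 kJ)."""
    return x * KCAL_TO_MJ


def assemble_tee(aee: float, bmr: float, *, subject_id: str = "",
                 period: str = "") -> EnergyComponents:
    """Assemble total energy expenditure from AEE and BMR (both MJ/day).

    DIT is 10% of TEE, so TEE = (AEE + BMR) / 0.9.
    """
    if not bmr > 0:
        raise ValueError(f"bmr must be positive, got {bmr}")
    if aee + bmr <= 0:
        raise ValueError(f"AEE + BMR must be positive, got {aee + bmr}")
    tee = (aee + bmr) / (1.0 - DIT_FRACTION)
    return EnergyComponents(
        subject_id=subject_id, period=period,
        bmr=bmr, aee=aee, dit=DIT_FRACTION * tee, tee=tee,
    )


def tee_from_cpm(subject: Subject, mean_cpm: float,
                 table: BmrCoefficientTable | None = None,
                 period: str = "") -> EnergyComponents:
    """Full chain from mean cpm and anthropometrics to energy components."""
    bmr = bmr_henry(subject, table)
    aee_mj = kcal_to_mj(aee_ekelund(mean_cpm, subject.gender_code))
    return assemble_tee(aee_mj, bmr, subject_id=subject.subject_id, period=period)
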