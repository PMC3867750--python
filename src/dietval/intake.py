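"""Daily dietary energy records and mean intake under recording-validity rules.

A subject-period is an acceptable diet recording when at least three
weekdays and one weekend day were completed; incomplete days are excluded
from the mean rather than imputed. Energies are recorded in kJ/day and
summarized in MJ/day.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import pandas as pd

from .accelerometry import PERIODS
from .errors import ValidationError

DEFAULT_MIN_WEEKDAYS = 3
DEFAULT_MIN_WEEKEND_DAYS = 1


@dataclass(frozen=True)
class DietDay:
    """One recorded day of dietary energy for one subject-period."""

    subject_id: str
    period: str
    date: date
    energy_kj: float
    complete: bool = True
    illness: bool = False
    unusual: bool = False

    def __post_init__(self) -> None:
        if self.energy_kj < 0:
            raise ValidationError(
                f"negative energy ({self.energy_kj} kJ) for "
                f"{self.subject_id}/{self.period} on {self.date}"
            )
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")

    @property
    def is_weekend(self) -> bool:
        return self.date.weekday() >= 5


@dataclass(frozen=True)
class IntakeSummary:
    """Mean daily energy intake and validity for one subject-period."""

    subject_id: str
    period: str
    n_days: int
    n_weekdays: int
    n_weekend_days: int
    mean_ei: float          # MJ/day, NaN when no complete day exists
    illness_affected: bool
    meets_criteria: bool


def parse_diet(path) -> list[DietDay]:
    """Read a diet CSV (subject_id, period, date, energy_kj, complete,
    illness, unusual) into day records, validating as it goes."""
    try:
        df = pd.read_csv(
            path, dtype={"subject_id": str}, float_precision="round_trip"
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"cannot parse diet CSV {path}: {exc}") from exc
    required = {"subject_id", "period", "date", "energy_kj"}
    if missing := required - set(df.columns):
        raise ValidationError(f"diet CSV missing columns: {sorted(missing)}")
    days = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            days.append(
                DietDay(
                    subject_id=str(row["subject_id"]),
                    period=str(row["period"]),
                    date=pd.Timestamp(row["date"]).date(),
                    energy_kj=float(row["energy_kj"]),
                    complete=bool(int(row.get("complete", 1))),
                    illness=bool(int(row.get("illness", 0))),
                    unusual=bool(int(row.get("unusual", 0))),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"diet CSV line {line}: {exc}") from exc
    return days


def summarize_intake(
    days: Sequence[DietDay],
    subject_id: str = "",
    period: str = "",
    min_weekdays: int = DEFAULT_MIN_WEEKDAYS,
    min_weekend_days: int = DEFAULT_MIN_WEEKEND_DAYS,
) -> IntakeSummary:
    """Summarize complete diet days into mean EI (MJ/day) and validity.

    Only complete days count toward the mean, the weekday/weekend tallies
    and the validity rule. ``illness_affected`` is true when illness was
    reported on any complete day.
    """
    complete = [d for d in days if d.complete]
    if days:
        subject_id = subject_id or days[0].subject_id
        period = period or days[0].period
    n_weekdays = sum(not d.is_weekend for d in complete)
    n_weekend = sum(d.is_weekend for d in complete)
    mean_ei = (
        sum(d.energy_kj for d in complete) / len(complete) / 1000.0
        if complete
        else float("nan")
    )
    return IntakeSummary(
        subject_id=subject_id,
        period=period,
        n_days=len(complete),
        n_weekdays=n_weekdays,
        n_weekend_days=n_weekend,
        mean_ei=mean_ei,
        illness_affected=any(d.illness for d in complete),
        meets_criteria=(n_weekdays >= min_weekdays and n_weekend >= min_weekend_days),
    )


def ei_bmr_ratio(mean_ei: float, bmr: float) -> float:
    """EI:BMR, a BMR-denominated plausibility ratio for reported intake."""
    if bmr <= 0:
        raise ValueError(f"bmr must be positive, got {bmr}")
    return mean_ei / bmr
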