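"""Minute-epoch accelerometer processing: non-wear excision, valid days, cpm.

Streams are vertical-axis counts at a fixed 60-second epoch. Processing
follows the standard children's wear-time protocol: every run of at least
20 consecutive zero-count minutes is treated as monitor-off (or sleep) and
excised; a day is valid with at least 13 h (780 min) of wear; a recording
is acceptable with at least four valid days including three weekdays and
one weekend day.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default non-wear definition: >= 20 consecutive zero-count minutes.
DEFAULT_NONWEAR_RUN_MINUTES = 20
#: Default valid-day wear requirement: 13 h.
DEFAULT_MIN_WEAR_MINUTES = 13 * 60
#: Default successful-recording criteria.
DEFAULT_MIN_VALID_DAYS = 4
DEFAULT_MIN_VALID_WEEKDAYS = 3
DEFAULT_MIN_VALID_WEEKEND_DAYS = 1

PERIODS = ("baseline", "intervention")


@dataclass
class CountStream:
    """Ordered minute-epoch counts for one subject-period.

    Timestamps must be strictly increasing with uniform 60-s spacing and
    counts must be non-negative integers; producers encode missing minutes
    as zeros rather than gaps.
    """

    subject_id: str
    period: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts)
        if self.period not in PERIODS:
            raise ValidationError(
                f"unknown period {self.period!r} (expected one of {PERIODS})"
            )
        if len(self.timestamps) != len(self.counts):
            raise ValidationError("timestamps and counts differ in length")
        if len(self.timestamps) == 0:
            raise ValidationError("empty count stream")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValidationError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            bad = int(np.argmax(self.counts < 0))
            raise ValidationError(
                f"negative counts at epoch {bad} "
                f"({self.timestamps[bad].isoformat()})"
            )
        deltas = np.diff(self.timestamps.asi8)
        if len(deltas) and not (deltas == 60_000_000_000).all():
            bad = int(np.argmax(deltas != 60_000_000_000))
            raise ValidationError(
                "timestamps must be strictly increasing at 60-s spacing; "
                f"violated after {self.timestamps[bad].isoformat()}"
            )

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class WearDay:
    """One calendar day of one stream after non-wear excision."""

    date: date
    is_weekend: bool
    wear_minutes: int
    total_counts: int
    cpm: float          # NaN when wear_minutes == 0
    valid: bool


@dataclass(frozen=True)
class ActivitySummary:
    """Per-subject-period wear/validity summary and mean cpm."""

    subject_id: str
    period: str
    n_valid_days: int
    n_valid_weekdays: int
    n_valid_weekend_days: int
    mean_cpm: float     # NaN when no valid day exists
    meets_criteria: bool


def parse_counts(path) -> list[CountStream]:
    """Read a counts CSV (subject_id, period, timestamp, counts) into streams.

    One stream is returned per (subject_id, period) pair, ordered as first
    seen in the file. Negative counts, duplicate timestamps and non-monotone
    or non-uniform timestamps are rejected.
    """
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"cannot parse counts CSV {path}: {exc}") from exc
    required = {"subject_id", "period", "timestamp", "counts"}
    if missing := required - set(df.columns):
        raise ValidationError(f"counts CSV missing columns: {sorted(missing)}")
    if df.empty:
        return []
    if df["counts"].isna().any() or df["timestamp"].isna().any():
        line = int(df.index[df["counts"].isna() | df["timestamp"].isna()][0]) + 2
        raise ValidationError(f"counts CSV: missing value at line {line}")
    neg = df.index[pd.to_numeric(df["counts"]) < 0]
    if len(neg):
        raise ValidationError(f"counts CSV: negative counts at line {int(neg[0]) + 2}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"counts CSV: bad timestamp: {exc}") from exc

    streams = []
    for (sid, period), grp in df.groupby(["subject_id", "period"], sort=False):
        if grp["timestamp"].duplicated().any():
            dup = grp.loc[grp["timestamp"].duplicated(), "timestamp"].iloc[0]
            raise ValidationError(
                f"duplicate timestamp {dup.isoformat()} for {sid}/{period}"
            )
        streams.append(
            CountStream(
                subject_id=str(sid),
                period=str(period),
                timestamps=pd.DatetimeIndex(grp["timestamp"]),
                counts=grp["counts"].to_numpy(dtype=np.int64),
            )
        )
    return streams


def detect_nonwear(
    stream: CountStream,
    min_run_minutes: int = DEFAULT_NONWEAR_RUN_MINUTES,
) -> np.ndarray:
    """Flag wear epochs: True = worn, False = non-wear.

    Every maximal run of consecutive zero-count epochs of length
    ``min_run_minutes`` or more is non-wear, including runs touching the
    stream boundaries; zeros in shorter runs count as wear.
    """
    if min_run_minutes < 1:
        raise ValueError(f"min_run_minutes must be >= 1, got {min_run_minutes}")
    zero = stream.counts == 0
    wear = np.ones(len(zero), dtype=bool)
    if not zero.any():
        return wear
    # run-length encode the zero mask
    boundaries = np.flatnonzero(np.diff(zero.astype(np.int8)) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(zero)]))
    for s, e in zip(starts, ends):
        if zero[s] and e - s >= min_run_minutes:
            wear[s:e] = False
    return wear


def summarize_days(
    stream: CountStream,
    wear_mask: np.ndarray,
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
) -> list[WearDay]:
    """Aggregate a masked stream into per-calendar-date wear days."""
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if len(wear_mask) != len(stream):
        raise ValueError("wear mask length does not match stream")
    frame = pd.DataFrame(
        {
            "date": stream.timestamps.date,
            "wear": wear_mask,
            "counts": np.where(wear_mask, stream.counts, 0),
        }
    )
    days = []
    for day, grp in frame.groupby("date", sort=True):
        wear_minutes = int(grp["wear"].sum())
        total_counts = int(grp["counts"].sum())
        cpm = total_counts / wear_minutes if wear_minutes > 0 else float("nan")
        days.append(
            WearDay(
                date=day,
                is_weekend=day.weekday() >= 5,
                wear_minutes=wear_minutes,
                total_counts=total_counts,
                cpm=cpm,
                valid=wear_minutes >= min_wear_minutes,
            )
        )
    return days


def summarize_activity(
    days: Sequence[WearDay],
    subject_id: str = "",
    period: str = "",
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    min_valid_weekdays: int = DEFAULT_MIN_VALID_WEEKDAYS,
    min_valid_weekend_days: int = DEFAULT_MIN_VALID_WEEKEND_DAYS,
    cpm_method: str = "per_day",
) -> ActivitySummary:
    """Reduce wear days to a recording summary.

    ``cpm_method`` selects how mean cpm is formed over the valid days:
    ``"per_day"`` (default) averages the daily cpm values so each day
    carries equal weight; ``"pooled"`` divides pooled counts by pooled
    wear minutes.
    """
    if cpm_method not in ("per_day", "pooled"):
        raise ValueError(f"unknown cpm_method {cpm_method!r}")
    valid = [d for d in days if d.valid]
    n_weekdays = sum(not d.is_weekend for d in valid)
    n_weekend = sum(d.is_weekend for d in valid)
    if valid:
        if cpm_method == "per_day":
            mean_cpm = float(np.mean([d.cpm for d in valid]))
        else:
            mean_cpm = sum(d.total_counts for d in valid) / sum(
                d.wear_minutes for d in valid
            )
    else:
        mean_cpm = float("nan")
    meets = (
        len(valid) >= min_valid_days
        and n_weekdays >= min_valid_weekdays
        and n_weekend >= min_valid_weekend_days
    )
    return ActivitySummary(
        subject_id=subject_id,
        period=period,
        n_valid_days=len(valid),
        n_valid_weekdays=n_weekdays,
        n_valid_weekend_days=n_weekend,
        mean_cpm=mean_cpm,
        meets_criteria=meets,
    )


def process_stream(
    stream: CountStream,
    min_run_minutes: int = DEFAULT_NONWEAR_RUN_MINUTES,
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
    **summary_kwargs,
) -> ActivitySummary:
    """Convenience chain: non-wear detection, day accounting, summary."""
    mask = detect_nonwear(stream, min_run_minutes)
    days = summarize_days(stream, mask, min_wear_minutes)
    return summarize_activity(
        days, subject_id=stream.subject_id, period=stream.period,
        **summary_kwargs,
    )


def days_frame(days: Iterable[WearDay]) -> pd.DataFrame:
    """Tabulate wear days for export."""
    return pd.DataFrame(
        [
            {
                "date": d.date.isoformat(),
                "is_weekend": int(d.is_weekend),
                "wear_minutes": d.wear_minutes,
                "total_counts": d.total_counts,
                "cpm": d.cpm,
                "valid": int(d.valid),
            }
            for d in days
        ]
    )
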