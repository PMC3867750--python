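"""Synthetic two-period validation study with known ground truth.

Emulates a school-meal pilot cohort: ~81 children aged 8-11 recording
their diet and wearing a hip accelerometer for two seven-day periods
(baseline and intervention). Every quantity the downstream pipeline
estimates is known by construction:

* anthropometrics are drawn from the study population's distributions
  (weight is derived from BMI and height so the BMI covariate is exact);
* minute-epoch count streams contain overnight sleep zeros (22:00-06:30),
  occasional >= 20-min non-wear gaps, and waking counts centred on a
  per-subject activity level;
* reported intake is generated around a per-subject-period true EI:TEE
  ratio, additive on the percentage scale:

      r(%) = 100 + b_ill * (1 - ill) + b_boy * boy
                 + b_bmi * (BMI - bmi_mean) + u_subject + eps

  with the subject intercept u shared across periods, so illness lowers
  reported intake, boys sit lower than girls, and higher BMI predicts
  under-reporting, as the field consistently observes.

All randomness derives from a single integer seed; the same configuration
always produces byte-identical studies.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .accelerometry import CountStream
from .energy import BmrCoefficientTable, EnergyComponents, Subject, tee_from_cpm
from .errors import ConfigError
from .intake import DietDay

PERIOD_STARTS = {
    # both are Mondays, mirroring January/February-March field work
    "baseline": date(2011, 1, 10),
    "intervention": date(2011, 2, 21),
}

SLEEP_END_MINUTE = 6 * 60 + 30     # 06:30
SLEEP_START_MINUTE = 22 * 60       # 22:00
MINUTES_PER_DAY = 1440
STUDY_DAYS = 7


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, defaulting to the study conditions.

    Cohort distribution defaults follow the pilot sample (n=81, 58% girls,
    age 10.3 +/- 0.6 y, BMI 17.0 +/- 2.4, height 144.0 +/- 7.2 cm,
    parental education 4/54/9/33%); reporting-bias effects default to the
    estimated covariate effects on EI:TEE(%) (+10.73 not-ill, -9.96 boys,
    -3.65 per BMI unit); illness prevalence defaults to 27/81 baseline and
    14/78 intervention.
    """

    n_subjects: int = 81
    pct_girls: float = 0.58
    age_mean: float = 10.3
    age_sd: float = 0.6
    bmi_mean: float = 17.0
    bmi_sd: float = 2.4
    height_mean: float = 144.0
    height_sd: float = 7.2
    education_probs: Sequence[float] = (0.04, 0.54, 0.09, 0.33)
    cpm_mean: float = 500.0
    cpm_sd: float = 150.0
    illness_prob_baseline: float = 0.33
    illness_prob_intervention: float = 0.18
    beta_illness_pct: float = 10.73
    beta_boy_pct: float = -9.96
    beta_bmi_pct: float = -3.65
    ratio_subject_sd_pct: float = 15.0
    ratio_resid_sd_pct: float = 17.0
    seed: int = 0
    # count-stream texture
    cpm_within_sd: float = 250.0        # minute-level SD of waking counts
    zero_minute_prob: float = 0.08      # sedentary zero minutes within wear
    nonwear_gaps_per_day: float = 0.7   # Poisson mean, capped at 2/day
    gap_min_minutes: int = 20
    gap_max_minutes: int = 60
    # diet-record texture
    day_cv: float = 0.2                 # day-to-day spread of intake
    incomplete_day_prob: float = 0.01
    dropout_prob_intervention: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "pct_girls", "illness_prob_baseline", "illness_prob_intervention",
            "zero_minute_prob", "incomplete_day_prob",
            "dropout_prob_intervention",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        probs = np.asarray(self.education_probs, dtype=float)
        if len(probs) != 4 or (probs < 0).any() or (probs > 1).any():
            raise ConfigError("education_probs must be 4 proportions in [0,1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"education_probs must sum to 1, got {probs.sum()!r}"
            )
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in (
            "age_sd", "bmi_sd", "height_sd", "cpm_sd", "cpm_within_sd",
            "ratio_subject_sd_pct", "ratio_resid_sd_pct", "day_cv",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 1 <= self.gap_min_minutes <= self.gap_max_minutes:
            raise ConfigError("gap_min_minutes must be in [1, gap_max_minutes]")


@dataclass
class StudyDataset:
    """A full synthetic study plus its ground truth.

    ``truth`` maps (subject_id, period) to the true EI:TEE ratio (%), the
    true TEE (MJ/day) and the drawn per-subject activity level.
    """

    subjects: list[Subject]
    count_streams: dict
    diet_days: dict
    truth: dict


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic generator for one named random stream."""
    tag = zlib.crc32("|".join(str(k) for k in key).encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def generate_cohort(config: SimulationConfig) -> list[Subject]:
    """Draw the study sample. Weight is BMI * height_m^2, so the BMI
    covariate is controlled exactly."""
    rng = _rng(config.seed, "cohort")
    n = config.n_subjects
    girls = rng.random(n) < config.pct_girls
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 8.0, 11.9)
    heights = np.clip(
        rng.normal(config.height_mean, config.height_sd, n), 110.0, 180.0
    )
    bmis = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 12.0, 32.0)
    education = rng.choice(
        [1, 2, 3, 4], size=n, p=np.asarray(config.education_probs, dtype=float)
    )
    return [
        Subject(
            subject_id=f"S{i + 1:03d}",
            sex="F" if girls[i] else "M",
            age=float(ages[i]),
            weight=float(bmis[i] * (heights[i] / 100.0) ** 2),
            height=float(heights[i]),
            education=int(education[i]),
        )
        for i in range(n)
    ]


def target_cpm(subject: Subject, config: SimulationConfig) -> float:
    """The subject's latent waking activity level (counts/min), shared by
    both periods."""
    rng = _rng(config.seed, "cpm", subject.subject_id)
    return float(
        max(50.0, rng.normal(config.cpm_mean, config.cpm_sd))
    )


def true_energy(
    subject: Subject,
    config: SimulationConfig,
    period: str,
    table: BmrCoefficientTable | None = None,
) -> EnergyComponents:
    """Ground-truth energy components implied by the latent activity level."""
    return tee_from_cpm(subject, target_cpm(subject, config), table, period)


def _illness(subject: Subject, period: str, config: SimulationConfig) -> bool:
    prob = (
        config.illness_prob_baseline
        if period == "baseline"
        else config.illness_prob_intervention
    )
    rng = _rng(config.seed, "ill", subject.subject_id, period)
    return bool(rng.random() < prob)


def true_ratio_pct(subject: Subject, period: str, config: SimulationConfig) -> float:
    """The subject-period's true EI:TEE on the percentage scale."""
    ill = _illness(subject, period, config)
    u = float(
        _rng(config.seed, "u", subject.subject_id).normal(
            0.0, config.ratio_subject_sd_pct
        )
    )
    eps = float(
        _rng(config.seed, "eps", subject.subject_id, period).normal(
            0.0, config.ratio_resid_sd_pct
        )
    )
    r = (
        100.0
        + config.beta_illness_pct * (0 if ill else 1)
        + config.beta_boy_pct * (1 if subject.sex == "M" else 0)
        + config.beta_bmi_pct * (subject.bmi - config.bmi_mean)
        + u
        + eps
    )
    return max(r, 1.0)


def simulate_counts(
    subject: Subject, period: str, config: SimulationConfig
) -> CountStream:
    """Seven calendar days of minute-epoch counts for one subject-period.

    Nights (22:00-06:30) are zero; waking minutes carry counts centred on
    the subject's latent cpm, with occasional zero (sedentary) minutes and
    zero to two inserted non-wear gaps of 20-60 min per day. With the
    noise knobs at zero the waking counts are a constant equal to the
    rounded latent cpm.
    """
    rng = _rng(config.seed, "counts", subject.subject_id, period)
    cpm = target_cpm(subject, config)
    start = PERIOD_STARTS[period]
    n_epochs = STUDY_DAYS * MINUTES_PER_DAY
    minute_of_day = np.tile(np.arange(MINUTES_PER_DAY), STUDY_DAYS)
    asleep = (minute_of_day < SLEEP_END_MINUTE) | (minute_of_day >= SLEEP_START_MINUTE)

    noiseless = config.cpm_within_sd == 0 and config.zero_minute_prob == 0
    if noiseless:
        counts = np.full(n_epochs, int(round(cpm)), dtype=np.int64)
    else:
        p0 = config.zero_minute_prob
        mu_nz = cpm / (1.0 - p0) if p0 < 1 else cpm
        sd = max(config.cpm_within_sd, 1e-9)
        shape = (mu_nz / sd) ** 2
        scale = sd ** 2 / mu_nz
        counts = np.rint(rng.gamma(shape, scale, n_epochs)).astype(np.int64)
        counts = np.maximum(counts, 1)
        counts[rng.random(n_epochs) < p0] = 0
    counts[asleep] = 0

    # inserted non-wear gaps within waking hours
    for day in range(STUDY_DAYS):
        n_gaps = min(int(rng.poisson(config.nonwear_gaps_per_day)), 2)
        for _ in range(n_gaps):
            length = int(
                rng.integers(config.gap_min_minutes, config.gap_max_minutes + 1)
            )
            lo = day * MINUTES_PER_DAY + SLEEP_END_MINUTE
            hi = day * MINUTES_PER_DAY + SLEEP_START_MINUTE - length
            s = int(rng.integers(lo, hi + 1))
            counts[s:s + length] = 0

    timestamps = pd.date_range(
        pd.Timestamp(start), periods=n_epochs, freq="min"
    )
    return CountStream(
        subject_id=subject.subject_id,
        period=period,
        timestamps=timestamps,
        counts=counts,
    )


def simulate_intake(
    subject: Subject,
    true_tee: float,
    period: str,
    config: SimulationConfig,
) -> list[DietDay]:
    """Seven diet days whose mean energy is exactly (r/100) * true TEE.

    Day-to-day spread is multiplicative with coefficient of variation
    ``day_cv`` and is renormalized so the 7-day mean hits the target
    exactly. On ill subject-periods at least one day carries the illness
    flag.
    """
    if true_tee <= 0:
        raise ValueError(f"true_tee must be positive, got {true_tee}")
    rng = _rng(config.seed, "diet", subject.subject_id, period)
    r = true_ratio_pct(subject, period, config)
    ill = _illness(subject, period, config)
    mean_mj = (r / 100.0) * true_tee

    weights = np.clip(rng.normal(1.0, config.day_cv, STUDY_DAYS), 0.1, None)
    energies = mean_mj * weights / weights.mean() * 1000.0  # kJ
    complete = rng.random(STUDY_DAYS) >= config.incomplete_day_prob
    ill_days = np.zeros(STUDY_DAYS, dtype=bool)
    if ill:
        ill_days = rng.random(STUDY_DAYS) < 0.3
        if not ill_days.any():
            ill_days[rng.integers(0, STUDY_DAYS)] = True

    start = PERIOD_STARTS[period]
    return [
        DietDay(
            subject_id=subject.subject_id,
            period=period,
            date=start + timedelta(days=i),
            energy_kj=float(energies[i]),
            complete=bool(complete[i]),
            illness=bool(ill_days[i]),
            unusual=bool(ill_days[i]),
        )
        for i in range(STUDY_DAYS)
    ]


def generate_study(
    config: SimulationConfig,
    include_counts: bool = True,
    table: BmrCoefficientTable | None = None,
) -> StudyDataset:
    """Full study: cohort, count streams, diet records and ground truth.

    ``include_counts=False`` skips the (large) count streams for analyses
    that only need intake and true expenditure.
    """
    table = table or BmrCoefficientTable.henry()
    subjects = generate_cohort(config)
    streams: dict = {}
    diet: dict = {}
    truth: dict = {}
    for subject in subjects:
        dropped = (
            config.dropout_prob_intervention > 0
            and _rng(config.seed, "dropout", subject.subject_id).random()
            < config.dropout_prob_intervention
        )
        for period in ("baseline", "intervention"):
            if period == "intervention" and dropped:
                continue
            components = true_energy(subject, config, period, table)
            if include_counts:
                streams[(subject.subject_id, period)] = simulate_counts(
                    subject, period, config
                )
            diet[(subject.subject_id, period)] = simulate_intake(
                subject, components.tee, period, config
            )
            truth[(subject.subject_id, period)] = {
                "true_ratio_pct": true_ratio_pct(subject, period, config),
                "true_tee": components.tee,
                "target_cpm": target_cpm(subject, config),
                "ill": _illness(subject, period, config),
            }
    return StudyDataset(
        subjects=subjects, count_streams=streams, diet_days=diet, truth=truth
    )


def write_study(dataset: StudyDataset, directory) -> dict:
    """Emit subjects/counts/diet CSVs and a truth JSON; the CSVs round-trip
    through the package's parsers bit-exactly. Returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": directory / "subjects.csv",
        "counts": directory / "counts.csv",
        "diet": directory / "diet.csv",
        "truth": directory / "truth.json",
    }

    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "sex": s.sex,
                "age_years": repr(s.age),
                "weight_kg": repr(s.weight),
                "height_cm": repr(s.height),
                "education": s.education,
            }
            for s in dataset.subjects
        ]
    ).to_csv(paths["subjects"], index=False)

    counts_frames = [
        pd.DataFrame(
            {
                "subject_id": stream.subject_id,
                "period": stream.period,
                "timestamp": stream.timestamps.strftime("%Y-%m-%dT%H:%M"),
                "counts": stream.counts,
            }
        )
        for stream in dataset.count_streams.values()
    ]
    if counts_frames:
        pd.concat(counts_frames).to_csv(paths["counts"], index=False)
    else:
        pd.DataFrame(
            columns=["subject_id", "period", "timestamp", "counts"]
        ).to_csv(paths["counts"], index=False)

    diet_rows = [
        {
            "subject_id": d.subject_id,
            "period": d.period,
            "date": d.date.isoformat(),
            "energy_kj": repr(d.energy_kj),
            "complete": int(d.complete),
            "illness": int(d.illness),
            "unusual": int(d.unusual),
        }
        for days in dataset.diet_days.values()
        for d in days
    ]
    pd.DataFrame(diet_rows).to_csv(paths["diet"], index=False)

    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                f"{sid}|{period}": info
                for (sid, period), info in dataset.truth.items()
            },
            fh,
            indent=1,
        )
    return paths


def read_subjects(path) -> list[Subject]:
    """Read a subjects CSV back into Subject records."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    return [
        Subject(
            subject_id=str(row.subject_id),
            sex=str(row.sex),
            age=float(row.age_years),
            weight=float(row.weight_kg),
            height=float(row.height_cm),
            education=int(row.education),
        )
        for row in df.itertuples()
    ]
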