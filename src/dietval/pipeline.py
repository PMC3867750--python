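"""End-to-end study runner: raw (or simulated) inputs to the report bundle.

The stages mirror the validation study design: accelerometer processing
and intake summarization run independently per subject-period; a
subject-period enters the evaluation only if it passes BOTH the wear-time
criteria and the diet-recording criteria; the joined records feed
misreporter classification, agreement statistics and the mixed model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accelerometry, agreement, intake, misreporting, modeling
from .energy import BmrCoefficientTable, tee_from_cpm
from .errors import ConfigError, DietvalError, FitError
from .misreporting import EvaluationRecord, WeightStatusCutoffs, records_frame
from .synthetic import (
    SimulationConfig,
    StudyDataset,
    generate_study,
    read_subjects,
    write_study,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Paths, thresholds and toggles for one full study run."""

    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    counts_path: str | None = None
    diet_path: str | None = None
    subjects_path: str | None = None
    bmr_table_path: str | None = None
    weight_cutoff_path: str | None = None
    nonwear_run_minutes: int = accelerometry.DEFAULT_NONWEAR_RUN_MINUTES
    min_wear_minutes: int = accelerometry.DEFAULT_MIN_WEAR_MINUTES
    min_valid_days: int = accelerometry.DEFAULT_MIN_VALID_DAYS
    min_valid_weekdays: int = accelerometry.DEFAULT_MIN_VALID_WEEKDAYS
    min_valid_weekend_days: int = accelerometry.DEFAULT_MIN_VALID_WEEKEND_DAYS
    min_diet_weekdays: int = intake.DEFAULT_MIN_WEEKDAYS
    min_diet_weekend_days: int = intake.DEFAULT_MIN_WEEKEND_DAYS
    ratio_lower: float = misreporting.DEFAULT_LOWER_CUTOFF
    ratio_upper: float = misreporting.DEFAULT_UPPER_CUTOFF
    loa_multiplier: float = agreement.DEFAULT_LOA_MULTIPLIER
    cpm_method: str = "per_day"
    out_dir: str = "study_out"
    seed: int | None = None
    log_level: str = "INFO"
    write_inputs: bool = True

    def __post_init__(self) -> None:
        for name in (
            "nonwear_run_minutes", "min_wear_minutes", "min_valid_days",
            "min_valid_weekdays", "min_valid_weekend_days",
            "min_diet_weekdays", "min_diet_weekend_days", "loa_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.ratio_lower < self.ratio_upper:
            raise ConfigError(
                f"reporter cut-offs must satisfy 0 <= lower < upper, got "
                f"{self.ratio_lower} / {self.ratio_upper}"
            )
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))
        if not self.simulate:
            for name in ("counts_path", "diet_path", "subjects_path"):
                if getattr(self, name) is None:
                    raise ConfigError(f"{name} required when simulate is false")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        try:
            return cls(sim=sim, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad study config: {exc}") from exc


def _setup_log(out_dir: Path, level: str) -> logging.Logger:
    log = logging.getLogger("dietval.run")
    log.setLevel(level.upper())
    log.handlers.clear()
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.propagate = False
    return log


def _stage(name: str, subject_period, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except DietvalError:
        raise
    except Exception as exc:
        raise DietvalError(
            f"stage {name!r} failed for {subject_period}: {exc}"
        ) from exc


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the summary dictionary that is also written to summary.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _setup_log(out, config.log_level)
    from importlib.metadata import version as _pkg_version
    try:
        pkg_version = _pkg_version("dietval")
    except Exception:
        pkg_version = "unknown"
    log.info("dietval version %s", pkg_version)
    log.info("thresholds: %s", {
        k: getattr(config, k) for k in (
            "nonwear_run_minutes", "min_wear_minutes", "min_valid_days",
            "min_valid_weekdays", "min_valid_weekend_days",
            "min_diet_weekdays", "min_diet_weekend_days",
            "ratio_lower", "ratio_upper", "loa_multiplier", "cpm_method",
        )
    })

    bmr_table = (
        BmrCoefficientTable.from_yaml(config.bmr_table_path)
        if config.bmr_table_path
        else BmrCoefficientTable.henry()
    )
    cutoffs = (
        WeightStatusCutoffs.from_yaml(config.weight_cutoff_path)
        if config.weight_cutoff_path
        else WeightStatusCutoffs.iotf()
    )

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        log.info("simulating study with seed %d", config.sim.seed)
        dataset = generate_study(config.sim, table=bmr_table)
        subjects = dataset.subjects
        streams = list(dataset.count_streams.values())
        diet_by_sp = dataset.diet_days
        if config.write_inputs:
            inputs_dir = out / "inputs"
            small = StudyDataset(
                subjects=dataset.subjects, count_streams={},
                diet_days=dataset.diet_days, truth=dataset.truth,
            )
            write_study(small, inputs_dir)   # counts omitted: bulky
    else:
        subjects = read_subjects(config.subjects_path)
        streams = accelerometry.parse_counts(config.counts_path)
        diet_days = intake.parse_diet(config.diet_path)
        diet_by_sp = {}
        for d in diet_days:
            diet_by_sp.setdefault((d.subject_id, d.period), []).append(d)
    subject_by_id = {s.subject_id: s for s in subjects}

    # ---- accelerometry ----------------------------------------------------
    activity = {}
    for stream in streams:
        sp = (stream.subject_id, stream.period)
        activity[sp] = _stage(
            "accelerometry", sp, accelerometry.process_stream, stream,
            min_run_minutes=config.nonwear_run_minutes,
            min_wear_minutes=config.min_wear_minutes,
            min_valid_days=config.min_valid_days,
            min_valid_weekdays=config.min_valid_weekdays,
            min_valid_weekend_days=config.min_valid_weekend_days,
            cpm_method=config.cpm_method,
        )
    pd.DataFrame([dataclasses.asdict(a) for a in activity.values()]).to_csv(
        out / "activity_summary.csv", index=False
    )

    # ---- intake -----------------------------------------------------------
    intakes = {}
    for sp, days in diet_by_sp.items():
        intakes[sp] = _stage(
            "intake", sp, intake.summarize_intake, days,
            min_weekdays=config.min_diet_weekdays,
            min_weekend_days=config.min_diet_weekend_days,
        )
    pd.DataFrame([dataclasses.asdict(i) for i in intakes.values()]).to_csv(
        out / "intake_summary.csv", index=False
    )

    # ---- join & classify --------------------------------------------------
    records = []
    energy_rows = []
    for sp in sorted(set(activity) | set(intakes)):
        accel_ok = sp in activity and activity[sp].meets_criteria
        diet_ok = sp in intakes and intakes[sp].meets_criteria
        if not (accel_ok and diet_ok):
            reason = []
            if not accel_ok:
                reason.append("accelerometer")
            if not diet_ok:
                reason.append("diet")
            log.info("excluded %s: invalid %s", sp, " and ".join(reason))
            continue
        subject = subject_by_id[sp[0]]
        components = _stage(
            "energy", sp, tee_from_cpm, subject, activity[sp].mean_cpm,
            bmr_table, sp[1],
        )
        energy_rows.append(dataclasses.asdict(components))
        ratio = intakes[sp].mean_ei / components.tee
        records.append(
            EvaluationRecord(
                subject_id=sp[0],
                period=sp[1],
                mean_ei=intakes[sp].mean_ei,
                tee=components.tee,
                bmr=components.bmr,
                ratio=ratio,
                reporter_class=misreporting.classify_reporter(
                    ratio, config.ratio_lower, config.ratio_upper
                ),
                sex=subject.sex,
                age=subject.age,
                bmi=subject.bmi,
                education=subject.education,
                illness_affected=intakes[sp].illness_affected,
                weight_status=misreporting.classify_weight_status(
                    subject.bmi, subject.age, subject.sex, cutoffs
                ),
            )
        )
    if not records:
        raise DietvalError("no evaluable subject-periods")
    pd.DataFrame(energy_rows).to_csv(out / "energy_components.csv", index=False)
    rec_df = records_frame(records)
    rec_df.to_csv(out / "evaluation_records.csv", index=False)
    log.info("evaluable subject-periods: %d", len(records))

    # ---- misreporting (reporter-group machinery) --------------------------
    reporter_table, chi2, chi2_p = misreporting.tabulate_reporters(records)
    reporter_table.to_csv(out / "reporter_counts.csv")
    group_tables = {}
    for variable in ("sex", "age", "illness_affected", "bmi",
                     "weight_status", "bmr", "tee", "mean_ei", "ratio"):
        try:
            group_tables[variable] = misreporting.compare_groups(records, variable)
        except DietvalError as exc:
            log.warning("group comparison for %s skipped: %s", variable, exc)
    pd.concat(group_tables, names=["variable"]).to_csv(
        out / "reporter_groups.csv"
    )

    # ---- agreement --------------------------------------------------------
    agree_rows = []
    for label in ("baseline", "intervention", "pooled"):
        sub = rec_df if label == "pooled" else rec_df[rec_df.period == label]
        if len(sub) < 2:
            continue
        res = agreement.paired_t(sub.mean_ei, sub.tee)
        agree_rows.append(
            {
                "period": label,
                "n": res.n,
                "ei_mean": float(sub.mean_ei.mean()),
                "ei_sd": float(sub.mean_ei.std(ddof=1)),
                "tee_mean": float(sub.tee.mean()),
                "tee_sd": float(sub.tee.std(ddof=1)),
                "mean_diff": res.mean_diff,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "p": res.p,
            }
        )
    pd.DataFrame(agree_rows).to_csv(out / "agreement_means.csv", index=False)

    r_pooled, r_p = agreement.pearson_r(rec_df.mean_ei, rec_df.tee)
    cross = agreement.quartile_crossclass(rec_df.mean_ei, rec_df.tee)

    # Bland-Altman over all evaluable observations, grouped by subject
    diffs = [
        (grp.mean_ei - grp.tee).to_numpy()
        for _, grp in rec_df.groupby("subject_id")
    ]
    ba = agreement.bland_altman_repeated(diffs, config.loa_multiplier)
    pd.DataFrame(
        {
            "subject_id": rec_df.subject_id,
            "period": rec_df.period,
            "mean_ei_tee": (rec_df.mean_ei + rec_df.tee) / 2,
            "diff_ei_tee": rec_df.mean_ei - rec_df.tee,
        }
    ).to_csv(out / "bland_altman_points.csv", index=False)

    # repeatability of EI over subjects evaluable in both periods
    wide = rec_df.pivot(index="subject_id", columns="period", values="mean_ei")
    complete = wide.dropna()
    icc = (
        agreement.icc_repeatability(
            complete["baseline"], complete["intervention"]
        )
        if {"baseline", "intervention"} <= set(wide.columns) and len(complete) >= 3
        else None
    )

    # ---- mixed model ------------------------------------------------------
    spec = modeling.MixedModelSpec()
    try:
        model_full = modeling.fit_mixed(records, spec)
        model_final = modeling.reduce_model(records, spec)
        model_full.terms.to_csv(out / "model_full.csv")
        model_final.terms.to_csv(out / "model_final.csv")
    except FitError as exc:
        # tiny or degenerate studies: report everything else without a model
        log.warning("mixed model skipped: %s", exc)
        model_full = model_final = None

    summary = {
        "n_subjects": len(subjects),
        "n_evaluable": len(records),
        "reporter_counts": {
            cls: int(reporter_table.loc[cls].sum())
            for cls in reporter_table.index
        },
        "reporter_chi2": {"chi2": chi2, "p": chi2_p},
        "agreement_means": agree_rows,
        "pearson": {"r": r_pooled, "p": r_p},
        "crossclass": {
            "pct_same": cross.pct_same,
            "pct_same_or_adjacent": cross.pct_same_or_adjacent,
            "pct_misclassified": cross.pct_misclassified,
            "pct_gross": cross.pct_gross,
            "kappa": cross.kappa,
            "kappa_p": cross.kappa_p,
        },
        "bland_altman": dataclasses.asdict(ba),
        "icc_ei": dataclasses.asdict(icc) if icc else None,
        "model_final": (
            {
                term: {
                    "estimate": float(model_final.terms.loc[term, "estimate"]),
                    "se": float(model_final.terms.loc[term, "se"]),
                    "ci_lower": float(model_final.terms.loc[term, "ci_lower"]),
                    "ci_upper": float(model_final.terms.loc[term, "ci_upper"]),
                    "p": float(model_final.terms.loc[term, "p"]),
                }
                for term in model_final.terms.index
            }
            if model_final is not None
            else None
        ),
        "model_dropped": model_final.dropped if model_final is not None else None,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    log.info("report bundle written to %s", out)
    return summary
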