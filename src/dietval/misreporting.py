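"""Misreporter classification and reporter-group comparisons.

Reported intake is judged against expenditure through the ratio EI:TEE.
Under stable weight the ratio should be near 1; subject-periods with
EI:TEE < 78% are under-reporters, > 122% over-reporters, and anything in
the closed 78-122% band an acceptable reporter (fixed Black-style cut-offs,
configurable). Each subject contributes one record per measurement period.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from importlib.resources import files
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError, ValidationError

DEFAULT_LOWER_CUTOFF = 0.78
DEFAULT_UPPER_CUTOFF = 1.22

REPORTER_CLASSES = ("under", "acceptable", "over")
WEIGHT_STATUSES = ("normal", "overweight", "obese")


@dataclass(frozen=True)
class EvaluationRecord:
    """One subject-period joining intake, expenditure and covariates."""

    subject_id: str
    period: str
    mean_ei: float       # MJ/day
    tee: float           # MJ/day
    bmr: float           # MJ/day
    ratio: float         # EI:TEE, dimensionless
    reporter_class: str
    sex: str
    age: float
    bmi: float
    education: int
    illness_affected: bool
    weight_status: str = "normal"

    def __post_init__(self) -> None:
        if self.tee <= 0:
            raise ValueError(f"tee must be positive, got {self.tee}")
        if not math.isclose(self.ratio, self.mean_ei / self.tee,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("ratio must equal mean_ei / tee")
        if self.reporter_class not in REPORTER_CLASSES:
            raise ValueError(f"unknown reporter class {self.reporter_class!r}")


def records_frame(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Tabulate evaluation records (one row per subject-period)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "period": r.period,
                "mean_ei": r.mean_ei,
                "tee": r.tee,
                "bmr": r.bmr,
                "ratio": r.ratio,
                "reporter_class": r.reporter_class,
                "sex": r.sex,
                "age": r.age,
                "bmi": r.bmi,
                "education": r.education,
                "illness_affected": int(r.illness_affected),
                "weight_status": r.weight_status,
            }
            for r in records
        ]
    )


def classify_reporter(
    ratio: float,
    lower: float = DEFAULT_LOWER_CUTOFF,
    upper: float = DEFAULT_UPPER_CUTOFF,
) -> str:
    """Classify one EI:TEE ratio; the cut-offs themselves are acceptable."""
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    if not lower < upper:
        raise ConfigError(f"lower cut-off {lower} must be below upper {upper}")
    if ratio < lower:
        return "under"
    if ratio > upper:
        return "over"
    return "acceptable"


def tabulate_reporters(records: Sequence[EvaluationRecord]):
    """Reporter-class counts per period with a chi-squared independence test.

    Returns ``(table, chi2, p)`` where ``table`` is the class-by-period
    count DataFrame. The chi-squared statistic is computed on the
    contingency table without continuity correction.
    """
    if not records:
        raise ValidationError("no records to tabulate")
    df = records_frame(records)
    table = (
        df.groupby(["reporter_class", "period"]).size().unstack(fill_value=0)
    )
    table = table.reindex(
        [c for c in REPORTER_CLASSES if c in table.index]
    )
    counts = table.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return table, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return table, float(chi2), float(p)


def _pairwise_pvalues(groups: dict, categorical: bool) -> dict:
    pvals = {}
    for (a, ga), (b, gb) in itertools.combinations(groups.items(), 2):
        if categorical:
            levels = sorted(set(ga) | set(gb))
            counts = np.array(
                [[(np.asarray(g) == lv).sum() for lv in levels] for g in (ga, gb)]
            )
            counts = counts[:, counts.sum(axis=0) > 0]
            if counts.shape[1] < 2:
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(counts, correction=False)
        else:
            _, p = stats.ttest_ind(ga, gb, equal_var=False)
        pvals[(a, b)] = float(p)
    return pvals


def _letter_display(class_names: list[str], nonsig_pairs: set) -> dict:
    """Compact letter display: classes share a letter iff their pair is in
    ``nonsig_pairs`` (not significantly different)."""
    # collect maximal cliques of the "not different" graph (k <= 3 in use,
    # but written generically)
    cliques: list[set] = []
    for size in range(len(class_names), 0, -1):
        for combo in itertools.combinations(class_names, size):
            if all(
                (a, b) in nonsig_pairs or (b, a) in nonsig_pairs or a == b
                for a, b in itertools.combinations(combo, 2)
            ):
                cset = set(combo)
                if not any(cset <= big for big in cliques):
                    cliques.append(cset)
    letters = {c: "" for c in class_names}
    for letter, clique in zip("abcdefgh", cliques):
        for c in class_names:
            if c in clique:
                letters[c] += letter
    return letters


def compare_groups(
    records: Sequence[EvaluationRecord],
    variable: str,
    categorical: bool | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
):
    """Compare a covariate across reporter classes with pairwise tests.

    Continuous variables use unequal-variance two-sample t-tests on all
    class pairs, categorical ones pairwise chi-squared. Returns a DataFrame
    with one row per reporter class: n, mean (or proportions), sd, and a
    significance letter; classes share a letter iff they are not
    significantly different at ``alpha`` (unadjusted by default).
    """
    df = records_frame(records)
    if variable not in df.columns:
        raise ValidationError(f"unknown variable {variable!r}")
    if categorical is None:
        categorical = df[variable].dtype == object or variable in (
            "sex", "weight_status", "education", "illness_affected",
        )
    present = [c for c in REPORTER_CLASSES if (df.reporter_class == c).any()]
    groups = {c: df.loc[df.reporter_class == c, variable].to_numpy() for c in present}

    rows = []
    suppress = any(len(g) < 2 for g in groups.values())
    if suppress:
        warnings.warn(
            f"compare_groups({variable!r}): a reporter class has <2 members; "
            "significance letters suppressed",
            stacklevel=2,
        )
        letters = {c: "" for c in present}
    else:
        pvals = _pairwise_pvalues(groups, categorical)
        threshold = alpha / len(pvals) if bonferroni and pvals else alpha
        nonsig = {pair for pair, p in pvals.items() if p >= threshold}
        letters = _letter_display(present, nonsig)
    for c in present:
        g = groups[c]
        if categorical:
            levels, cnts = np.unique(g, return_counts=True)
            summary = {
                f"pct_{lv}": 100.0 * n / len(g) for lv, n in zip(levels, cnts)
            }
            rows.append({"class": c, "n": len(g), **summary, "letters": letters[c]})
        else:
            rows.append(
                {
                    "class": c,
                    "n": len(g),
                    "mean": float(np.mean(g)),
                    "sd": float(np.std(g, ddof=1)) if len(g) > 1 else float("nan"),
                    "letters": letters[c],
                }
            )
    return pd.DataFrame(rows).set_index("class")


@dataclass
class WeightStatusCutoffs:
    """Age- and sex-specific child BMI thresholds for overweight and obesity.

    ``male``/``female`` are DataFrames with columns age, overweight, obese
    at tabulated (half-year) ages; lookups interpolate linearly between
    tabulated ages and clamp outside the tabulated range.
    """

    male: pd.DataFrame
    female: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        for name in ("male", "female"):
            tab = getattr(self, name).sort_values("age").reset_index(drop=True)
            if (tab["obese"] < tab["overweight"]).any():
                raise ConfigError(f"{name}: obese threshold below overweight")
            if not (tab["overweight"].is_monotonic_increasing
                    and tab["obese"].is_monotonic_increasing):
                raise ConfigError(f"{name}: thresholds must increase with age")
            setattr(self, name, tab)

    def thresholds(self, age: float, sex: str) -> tuple[float, float]:
        tab = self.male if sex == "M" else self.female
        ow = float(np.interp(age, tab["age"], tab["overweight"]))
        ob = float(np.interp(age, tab["age"], tab["obese"]))
        return ow, ob

    @classmethod
    def from_yaml(cls, path) -> "WeightStatusCutoffs":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "WeightStatusCutoffs":
        try:
            return cls(
                male=pd.DataFrame(raw["male"]),
                female=pd.DataFrame(raw["female"]),
                source=raw.get("source", ""),
            )
        except KeyError as exc:
            raise ConfigError(f"malformed BMI cut-off table: {exc}") from exc

    @classmethod
    def iotf(cls) -> "WeightStatusCutoffs":
        """The bundled international (IOTF) child BMI cut-off table."""
        raw = yaml.safe_load(
            files("dietval.data").joinpath("iotf_bmi_cutoffs.yaml").read_text()
        )
        return cls._from_mapping(raw)


def classify_weight_status(
    bmi: float,
    age: float,
    sex: str,
    cutoffs: WeightStatusCutoffs | None = None,
) -> str:
    """Normal / overweight / obese by interpolated BMI thresholds.

    A BMI exactly on a threshold falls in the heavier category.
    """
    if cutoffs is None:
        cutoffs = WeightStatusCutoffs.iotf()
    ow, ob = cutoffs.thresholds(age, sex)
    if bmi >= ob:
        return "obese"
    if bmi >= ow:
        return "overweight"
    return "normal"
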