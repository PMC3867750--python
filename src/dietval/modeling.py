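"""Random-intercept linear mixed models for EI:TEE (%).

The response is the intake:expenditure ratio on the percentage scale.
Fixed effects are sex (boys vs girls), parental education (dichotomized:
mainly practical vs mainly theoretical), BMI, age, illness affecting eating
(not ill vs ill on >= 1 day) and measurement period, plus their two-way
interactions; a random intercept per subject absorbs the repeated-measures
dependence across the two periods. Estimation is REML through statsmodels'
MixedLM; design-matrix assembly, backward elimination and inference are
owned here.

Inference uses t statistics on the residual degrees of freedom
(n_obs - rank(X)); with two observations per subject and the modest
cluster counts this package targets, the t quantile is within a percent
of a Satterthwaite-style quantile, and the simpler rule keeps inference
reproducible across estimation backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .errors import FitError
from .misreporting import records_frame

#: Canonical single-df model terms and the record columns they derive from.
MAIN_EFFECTS = ("not_ill", "boy", "bmi", "age", "edu_high", "period")


@dataclass
class MixedModelSpec:
    """Which fixed effects (and two-way interactions) enter the model."""

    fixed: Sequence[str] = MAIN_EFFECTS
    interactions: bool | Sequence[str] = True
    response_scale: float = 100.0   # ratio -> percent

    def terms(self) -> list[str]:
        terms = list(self.fixed)
        if self.interactions is True:
            terms += [
                f"{a}:{b}"
                for i, a in enumerate(self.fixed)
                for b in list(self.fixed)[i + 1:]
            ]
        elif self.interactions:
            terms += list(self.interactions)
        return terms


@dataclass
class MixedModelResult:
    """Fixed-effect table plus variance components for one fit."""

    terms: pd.DataFrame          # index term; estimate, se, ci_lower, ci_upper, p
    var_subject: float
    var_resid: float
    n_obs: int
    n_subjects: int
    method: str = "reml"         # "reml" | "ols" (degenerate designs)
    dropped: list = field(default_factory=list)


def _design_frame(records) -> pd.DataFrame:
    """Derive model covariates from evaluation records."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"].astype(str),
            "ratio": df["ratio"].astype(float),
            "not_ill": 1 - df["illness_affected"].astype(int),
            "boy": (df["sex"] == "M").astype(int),
            "bmi": df["bmi"].astype(float),
            "age": df["age"].astype(float),
            "edu_high": (df["education"].astype(int) >= 3).astype(int),
            "period": (df["period"] == "intervention").astype(int),
        }
    )
    return out


def _design_matrix(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for term in terms:
        parts = term.split(":")
        col = np.ones(len(df))
        for part in parts:
            if part not in df.columns:
                raise FitError(f"unknown model term {part!r}")
            col = col * df[part].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def _check_design(X: np.ndarray, terms: list[str]) -> None:
    for j, term in enumerate(terms, start=1):
        if np.ptp(X[:, j]) == 0:
            raise FitError(f"constant covariate: term {term!r} has no variation")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first term whose removal restores full column rank
        for j, term in enumerate(terms, start=1):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                raise FitError(f"singular design: term {term!r} is collinear")
        raise FitError("singular design matrix")


def fit_mixed(records, spec: MixedModelSpec | None = None) -> MixedModelResult:
    """REML random-intercept fit of EI:TEE(%) on the spec's fixed effects.

    Degenerate inputs degrade gracefully: with one observation per subject
    the random intercept is inestimable and the fixed effects are the OLS
    estimates (``method == "ols"``); a perfectly deterministic response is
    also fit by OLS to avoid a zero-variance boundary.
    """
    spec = spec or MixedModelSpec()
    df = _design_frame(records)
    terms = spec.terms()
    y = df["ratio"].to_numpy() * spec.response_scale
    X = _design_matrix(df, terms)
    n_obs = len(y)
    groups = df["subject_id"].to_numpy()
    n_subjects = len(np.unique(groups))
    if n_obs < 2 or n_subjects < 2:
        raise FitError("need at least two observations from two subjects")
    _check_design(X, terms)
    rank = X.shape[1]
    df_resid = max(n_obs - rank, 1)

    singleton = n_subjects == n_obs
    ols = sm.OLS(y, X).fit()
    perfect = ols.ssr <= max(1e-10 * float(y @ y), 1e-12)

    if singleton or perfect:
        if singleton:
            warnings.warn(
                "one observation per subject: random intercept inestimable, "
                "reporting OLS fixed effects",
                stacklevel=2,
            )
        est, se = ols.params, ols.bse
        var_subj, var_resid = 0.0, float(ols.scale)
        method = "ols"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"mixed model failed: {exc}") from exc
        est = np.asarray(fit.fe_params)
        se = np.asarray(fit.bse_fe)
        var_subj = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
        method = "reml"

    tcrit = stats.t.ppf(0.975, df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, est / se, np.inf * np.sign(est))
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    table = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_lower": est - tcrit * se,
            "ci_upper": est + tcrit * se,
            "p": pvals,
        },
        index=["intercept"] + terms,
    )
    return MixedModelResult(
        terms=table,
        var_subject=var_subj,
        var_resid=var_resid,
        n_obs=n_obs,
        n_subjects=n_subjects,
        method=method,
    )


def _parents(term: str) -> set[str]:
    return set(term.split(":")) if ":" in term else set()


def reduce_model(
    records,
    spec: MixedModelSpec | None = None,
    alpha: float = 0.05,
) -> MixedModelResult:
    """Backward elimination to a final model.

    Starting from the full spec, repeatedly drop the least significant
    interaction with p > alpha (refitting after each drop), then the least
    significant main effect not involved in a retained interaction; the
    model hierarchy is never violated. The returned result records the
    elimination path in ``dropped``.
    """
    spec = spec or MixedModelSpec()
    terms = spec.terms()
    dropped: list[str] = []
    while True:
        current = MixedModelSpec(
            fixed=[t for t in terms if ":" not in t],
            interactions=[t for t in terms if ":" in t],
            response_scale=spec.response_scale,
        )
        result = fit_mixed(records, current)
        pvals = result.terms["p"]
        interactions = [t for t in terms if ":" in t]
        weak = [(t, pvals[t]) for t in interactions if pvals[t] > alpha]
        if not weak:
            protected = (
                set().union(*(_parents(t) for t in interactions))
                if interactions
                else set()
            )
            mains = [t for t in terms if ":" not in t and t not in protected]
            weak = [(t, pvals[t]) for t in mains if pvals[t] > alpha]
        if not weak:
            result.dropped = dropped
            return result
        victim = max(weak, key=lambda tp: tp[1])[0]
        terms.remove(victim)
        dropped.append(victim)
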