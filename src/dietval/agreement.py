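"""Agreement between reported intake and expenditure.

Group-level agreement is a paired t-test on EI - TEE. Individual-level
agreement uses a Bland-Altman analysis adapted to repeated measurements
(each subject can contribute both study periods), quartile
cross-classification with Cohen's kappa, and Pearson correlation.
Repeatability of intake between periods is an intraclass correlation.

The repeated-measures Bland-Altman separates the variance of the
differences into between- and within-subject components with one-way
ANOVA mean squares and reports limits of agreement at
mean +/- 2 * corrected SD, where corrected SD = sqrt(sigma2_between +
sigma2_within).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_LOA_MULTIPLIER = 2.0


@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    ci_lower: float
    ci_upper: float
    t: float
    p: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Repeated-measures Bland-Altman summary (all energies MJ/day)."""

    mean_diff: float
    sd_within: float
    sd_between: float
    sd_corrected: float
    loa_lower: float
    loa_upper: float
    n_subjects: int
    n_observations: int
    classic_fallback: bool = False


@dataclass(frozen=True)
class CrossClassification:
    """Quartile cross-classification of EI against TEE."""

    table: np.ndarray            # 4x4 counts, rows EI quartile, cols TEE quartile
    pct_same: float
    pct_same_or_adjacent: float
    pct_misclassified: float     # |delta quartile| == 2
    pct_gross: float             # |delta quartile| == 3
    kappa: float
    kappa_p: float
    n: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    n: int


def paired_t(ei: Sequence[float], tee: Sequence[float],
             confidence: float = 0.95) -> PairedTResult:
    """Paired t-test of EI against TEE over matched subject-periods."""
    ei = np.asarray(ei, dtype=float)
    tee = np.asarray(tee, dtype=float)
    if ei.shape != tee.shape:
        raise ValueError("ei and tee must have equal length")
    n = len(ei)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = ei - tee
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        warnings.warn("zero variance of paired differences", stacklevel=2)
        if mean == 0:
            return PairedTResult(0.0, 0.0, 0.0, 0.0, 1.0, n)
        return PairedTResult(mean, mean, mean, math.copysign(math.inf, mean), 0.0, n)
    t, p = stats.ttest_rel(ei, tee)
    half = stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / math.sqrt(n)
    return PairedTResult(mean, mean - half, mean + half, float(t), float(p), n)


def bland_altman_repeated(
    diffs: Sequence[Sequence[float]],
    multiplier: float = DEFAULT_LOA_MULTIPLIER,
) -> BlandAltmanResult:
    """Limits of agreement from per-subject lists of EI - TEE differences.

    With replicated subjects the SD of a single difference is rebuilt from
    one-way ANOVA components: MSW pooled within subjects, MSB between
    subjects, average replication count m0, sigma2_between =
    max(0, (MSB - MSW) / m0), corrected SD = sqrt(sigma2_between + MSW).
    When every subject contributes a single difference this collapses to
    the classic Bland-Altman sample SD (flagged via ``classic_fallback``).
    """
    groups = [np.asarray(g, dtype=float) for g in diffs]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every subject needs at least one difference")
    n = len(groups)
    if n < 2:
        raise ValueError("need at least two subjects")
    all_d = np.concatenate(groups)
    m = np.array([len(g) for g in groups])
    mean = float(np.mean(all_d))
    n_obs = int(m.sum())

    if (m == 1).all():
        sd = float(np.std(all_d, ddof=1))
        return BlandAltmanResult(
            mean_diff=mean, sd_within=0.0, sd_between=sd, sd_corrected=sd,
            loa_lower=mean - multiplier * sd, loa_upper=mean + multiplier * sd,
            n_subjects=n, n_observations=n_obs, classic_fallback=True,
        )

    means = np.array([g.mean() for g in groups])
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    msw = ssw / (m - 1).sum()
    msb = float((m * (means - mean) ** 2).sum()) / (n - 1)
    m0 = (m.sum() - (m ** 2).sum() / m.sum()) / (n - 1)
    var_b = max(0.0, (msb - msw) / m0)
    sd_corr = math.sqrt(var_b + msw)
    return BlandAltmanResult(
        mean_diff=mean,
        sd_within=math.sqrt(msw),
        sd_between=math.sqrt(var_b),
        sd_corrected=sd_corr,
        loa_lower=mean - multiplier * sd_corr,
        loa_upper=mean + multiplier * sd_corr,
        n_subjects=n,
        n_observations=n_obs,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equally sized arrays with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _quartiles(values: np.ndarray) -> np.ndarray:
    """Quartile labels 1-4 from average ranks cut at n/4, n/2, 3n/4
    (upper-inclusive), so ties resolve deterministically."""
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    return (
        1
        + (ranks > n / 4).astype(int)
        + (ranks > n / 2).astype(int)
        + (ranks > 3 * n / 4).astype(int)
    )


def cohens_kappa(table: np.ndarray) -> tuple[float, float]:
    """Unweighted Cohen's kappa for a square agreement table, with the
    asymptotic two-sided p-value against kappa = 0."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("empty table")
    p_obs = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_exp = float(row @ col)
    if p_exp == 1.0:
        return 1.0 if p_obs == 1.0 else 0.0, 1.0
    kappa = (p_obs - p_exp) / (1 - p_exp)
    # large-sample SE under the null (Fleiss, Cohen & Everitt)
    se0_num = p_exp + p_exp ** 2 - float((row * col * (row + col)).sum())
    if se0_num <= 0:
        return float(kappa), 1.0
    se0 = math.sqrt(se0_num) / ((1 - p_exp) * math.sqrt(n))
    z = kappa / se0
    p = 2 * (1 - stats.norm.cdf(abs(z)))
    return float(kappa), float(p)


def quartile_crossclass(ei: Sequence[float], tee: Sequence[float]) -> CrossClassification:
    """Cross-classify observations by their EI and TEE quartiles.

    Quartiles are formed separately for EI and TEE over the supplied
    observations; agreement is summarized as the share classified into the
    same, same-or-adjacent, two-apart (misclassified) and opposite
    (grossly misclassified) quartiles, plus unweighted Cohen's kappa.
    """
    ei = np.asarray(ei, dtype=float)
    tee = np.asarray(tee, dtype=float)
    if ei.shape != tee.shape:
        raise ValueError("ei and tee must have equal length")
    n = len(ei)
    if n < 8:
        raise ValueError("need at least 8 observations for quartiles")
    q_ei = _quartiles(ei)
    q_tee = _quartiles(tee)
    table = np.zeros((4, 4), dtype=int)
    np.add.at(table, (q_ei - 1, q_tee - 1), 1)
    delta = np.abs(q_ei - q_tee)
    kappa, kappa_p = cohens_kappa(table)
    return CrossClassification(
        table=table,
        pct_same=100.0 * float((delta == 0).mean()),
        pct_same_or_adjacent=100.0 * float((delta <= 1).mean()),
        pct_misclassified=100.0 * float((delta == 2).mean()),
        pct_gross=100.0 * float((delta == 3).mean()),
        kappa=kappa,
        kappa_p=kappa_p,
        n=n,
    )


def icc_repeatability(
    period1: Sequence[float],
    period2: Sequence[float],
    confidence: float = 0.95,
) -> IccResult:
    """Test-retest ICC between the two periods, paired by subject.

    Two-way mixed-effects, absolute-agreement, single-measure ICC (A,1 in
    the McGraw & Wong taxonomy) from the two-way ANOVA mean squares, with
    the standard F-based confidence interval.
    """
    y1 = np.asarray(period1, dtype=float)
    y2 = np.asarray(period2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("periods must be paired by subject")
    n = len(y1)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    k = 2
    data = np.column_stack([y1, y2])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    sse = float(
        ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    )
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return IccResult(1.0, 1.0, 1.0, n)
    icc = (msr - mse) / denom

    alpha = 1 - confidence
    if mse == 0 and msc == mse:
        return IccResult(float(icc), float(icc), float(icc), n)
    # McGraw & Wong (1996) interval for ICC(A,1)
    a = k * icc / (n * (1 - icc)) if icc < 1 else math.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else math.inf
    if math.isinf(a):
        return IccResult(float(icc), float(icc), float(icc), n)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n * (msr - f_l * mse)
        / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_u * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    )
    return IccResult(float(icc), float(lower), float(upper), n)
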