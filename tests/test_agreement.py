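import math

import numpy as np
import pytest

from dietval import (
    bland_altman_repeated,
    cohens_kappa,
    icc_repeatability,
    paired_t,
    pearson_r,
    quartile_crossclass,
)


def ba_oracle(groups, multiplier=2.0):
    """Independent variance-component computation, written loop-by-loop
    from the one-way ANOVA definitions."""
    means = [sum(g) / len(g) for g in groups]
    all_d = [d for g in groups for d in g]
    grand = sum(all_d) / len(all_d)
    n = len(groups)
    m = [len(g) for g in groups]
    ssw = sum((d - mu) ** 2 for g, mu in zip(groups, means) for d in g)
    msw = ssw / sum(mi - 1 for mi in m)
    msb = sum(mi * (mu - grand) ** 2 for mi, mu in zip(m, means)) / (n - 1)
    m0 = (sum(m) - sum(mi ** 2 for mi in m) / sum(m)) / (n - 1)
    var_b = max(0.0, (msb - msw) / m0)
    sd = math.sqrt(var_b + msw)
    return grand, sd, grand - multiplier * sd, grand + multiplier * sd


class TestPairedT:
    def test_identical_series_zero_difference(self):
        res = paired_t([7.0, 8.0, 6.5], [7.0, 8.0, 6.5])
        assert res.mean_diff == 0 and res.p == 1.0

    def test_symmetric_differences_give_t_zero(self):
        res = paired_t([6.0, 7.0, 8.0], [7.0, 7.0, 7.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        ei = rng.normal(7.2, 1.7, 40)
        tee = rng.normal(7.2, 1.0, 40)
        res = paired_t(ei, tee)
        d = ei - tee
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.t == pytest.approx(t_oracle, rel=1e-12)
        assert res.mean_diff == pytest.approx(d.mean())

    def test_constant_nonzero_difference_degenerates(self):
        with pytest.warns(UserWarning):
            res = paired_t([8.0, 9.0], [7.0, 8.0])
        assert res.mean_diff == 1.0 and res.p == 0.0


class TestBlandAltmanRepeated:
    def test_all_zero_differences(self):
        res = bland_altman_repeated([[0.0, 0.0], [0.0, 0.0]])
        assert res.mean_diff == 0 and res.loa_lower == 0 and res.loa_upper == 0

    def test_singletons_fall_back_to_classic(self):
        res = bland_altman_repeated([[-1.0], [0.0], [1.0]])
        assert res.classic_fallback
        assert res.sd_corrected == pytest.approx(1.0)
        assert (res.loa_lower, res.loa_upper) == pytest.approx((-2.0, 2.0))

    def test_hand_built_instance_matches_anova_oracle(self):
        groups = [[0.1, 0.4], [-0.5, -0.2], [0.9, 0.3]]
        res = bland_altman_repeated(groups)
        mean, sd, lo, hi = ba_oracle(groups)
        assert res.mean_diff == pytest.approx(mean)
        assert res.sd_corrected == pytest.approx(sd)
        assert (res.loa_lower, res.loa_upper) == pytest.approx((lo, hi))

    def test_location_equivariance(self, rng):
        groups = [list(rng.normal(0, 1, 2)) for _ in range(20)]
        shifted = [[d + 5.0 for d in g] for g in groups]
        a = bland_altman_repeated(groups)
        b = bland_altman_repeated(shifted)
        assert b.mean_diff == pytest.approx(a.mean_diff + 5.0)
        assert b.sd_corrected == pytest.approx(a.sd_corrected)
        assert b.loa_lower == pytest.approx(a.loa_lower + 5.0)

    def test_recovers_known_variance_components(self, rng):
        # sigma_b = 1.5, sigma_w = 0.8 at 500 subjects x 2 observations
        u = rng.normal(0, 1.5, 500)
        groups = [list(u[i] + rng.normal(0, 0.8, 2)) for i in range(500)]
        res = bland_altman_repeated(groups)
        assert res.sd_corrected == pytest.approx(
            math.sqrt(1.5 ** 2 + 0.8 ** 2), rel=0.05
        )

    def test_empty_subject_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_repeated([[1.0], []])


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(0, 1, 60)
        y = 0.3 * x + rng.normal(0, 1, 60)
        r, _ = pearson_r(x, y)
        oracle = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(oracle, rel=1e-12)


class TestQuartileCrossclass:
    def test_identical_ranks(self, rng):
        x = rng.normal(0, 1, 40)
        res = quartile_crossclass(x, 2 * x + 3)
        assert res.pct_same == 100.0
        assert res.kappa == pytest.approx(1.0)

    def test_chance_agreement_table_gives_zero_kappa(self):
        kappa, _ = cohens_kappa(np.full((4, 4), 5))
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_matches_brute_force(self, rng):
        ei = rng.normal(7, 1.7, 16)
        tee = rng.normal(7, 1.0, 16)
        res = quartile_crossclass(ei, tee)
        table = res.table.astype(float)
        n = table.sum()
        p_o = np.trace(table) / n
        p_e = float(table.sum(1) @ table.sum(0)) / n ** 2
        assert res.kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_percentages_partition(self, rng):
        ei = rng.normal(7, 1.7, 57)
        tee = rng.normal(7, 1.0, 57)
        res = quartile_crossclass(ei, tee)
        total = (
            res.pct_same_or_adjacent + res.pct_misclassified + res.pct_gross
        )
        assert total == pytest.approx(100.0)

    def test_invariant_under_monotone_transform(self, rng):
        ei = rng.normal(7, 1.7, 50)
        tee = rng.normal(7, 1.0, 50)
        a = quartile_crossclass(ei, tee)
        b = quartile_crossclass(np.exp(ei / 3), tee ** 3)
        assert a.pct_same == b.pct_same
        assert a.kappa == pytest.approx(b.kappa)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            quartile_crossclass([1, 2, 3], [1, 2, 3])


class TestIcc:
    def test_identical_periods(self, rng):
        x = rng.normal(7, 1.5, 30)
        res = icc_repeatability(x, x)
        assert res.icc == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        res = icc_repeatability(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
        assert abs(res.icc) < 0.1

    def test_matches_mean_squares_oracle(self):
        y1 = np.array([7.0, 6.2, 8.1, 5.5, 7.7])
        y2 = np.array([7.4, 6.0, 7.9, 6.1, 7.2])
        res = icc_repeatability(y1, y2)
        # explicit two-way decomposition
        data = np.column_stack([y1, y2])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            (data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2
        ).sum() / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.icc == pytest.approx(oracle, rel=1e-12)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        y1 = rng.normal(7, 1.5, 25)
        y2 = 0.7 * y1 + rng.normal(2, 1.0, 25)
        res = icc_repeatability(y1, y2)
        df = pd.DataFrame(
            {
                "subject": list(range(25)) * 2,
                "rater": ["p1"] * 25 + ["p2"] * 25,
                "score": np.concatenate([y1, y2]),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        row = ref[ref["Type"].str.contains("A,1|ICC2", regex=True)].iloc[0]
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-6)
        assert res.ci_lower == pytest.approx(row["CI95"][0], abs=0.02)
        assert res.ci_upper == pytest.approx(row["CI95"][1], abs=0.02)

    def test_ci_brackets_estimate(self, rng):
        y1 = rng.normal(7, 1.5, 40)
        y2 = y1 + rng.normal(0, 1.0, 40)
        res = icc_repeatability(y1, y2)
        assert res.ci_lower <= res.icc <= res.ci_upper
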