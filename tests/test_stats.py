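"""Reproducibility statistics: CV, ICC, Bland-Altman, t-test, Pearson."""

import numpy as np
import pandas as pd
import pytest

from renasl.phantom import CohortSpec, make_cohort
from renasl.stats import (
    bland_altman,
    icc,
    paired_t,
    pearson,
    reproducibility_report,
    within_subject_cv,
)


def _table_from_matrix(x):
    rows = []
    for s, vals in enumerate(x):
        for r, v in enumerate(vals):
            rows.append((s + 1, 1, r + 1, float(v)))
    return pd.DataFrame(rows, columns=["subject", "session", "repetition", "value"])


FIXED_MATRIX = np.array(
    [
        [300.0, 305.0, 310.0],
        [280.0, 282.0, 284.0],
        [320.0, 318.0, 322.0],
        [290.0, 295.0, 300.0],
    ]
)


def _icc_anova_oracle(x, model):
    """Independent mean-squares computation with explicit loops."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum((row.mean() - grand) ** 2 for row in x) * k / (n - 1)
    msc = sum((x[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    if model == "single":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (msc - mse) / n)


class TestWithinSubjectCV:
    def test_identical_repetitions_give_zero(self):
        cv_mean, cv_sd = within_subject_cv(_table_from_matrix([[5.0, 5.0, 5.0]] * 3))
        assert cv_mean == 0.0 and cv_sd == 0.0

    def test_hand_example_single_subject(self):
        cv_mean, _ = within_subject_cv(_table_from_matrix([[290.0, 300.0, 310.0]]))
        assert cv_mean == pytest.approx(100.0 * 10.0 / 300.0, abs=1e-12)

    def test_mean_and_sd_across_subjects(self):
        # subjects with CVs exactly 2% and 4%
        t = _table_from_matrix([[100 - 2, 100 + 2], [100 - 4, 100 + 4]])
        cv = 100.0 * np.std([98, 102], ddof=1) / 100.0  # 2.828...
        cv_mean, cv_sd = within_subject_cv(t)
        assert cv_mean == pytest.approx(1.5 * cv, rel=1e-12)
        assert cv_sd == pytest.approx(np.std([cv, 2 * cv], ddof=1), rel=1e-12)

    def test_scale_invariance(self):
        t = _table_from_matrix(FIXED_MATRIX)
        t2 = t.assign(value=t["value"] * 7.3)
        assert within_subject_cv(t) == pytest.approx(within_subject_cv(t2), rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            within_subject_cv(_table_from_matrix([[-1.0, 1.0]]))


class TestICC:
    def test_perfect_agreement(self):
        t = _table_from_matrix([[300.0] * 3, [280.0] * 3, [320.0] * 3])
        assert icc(t, "single") == pytest.approx(1.0)
        assert icc(t, "average") == pytest.approx(1.0)

    @pytest.mark.parametrize("model", ["single", "average"])
    def test_fixed_matrix_matches_anova_oracle(self, model):
        t = _table_from_matrix(FIXED_MATRIX)
        assert icc(t, model) == pytest.approx(_icc_anova_oracle(FIXED_MATRIX, model), abs=1e-10)

    @pytest.mark.parametrize("model", ["single", "average"])
    def test_matches_pingouin(self, model):
        pingouin = pytest.importorskip("pingouin")
        t = _table_from_matrix(FIXED_MATRIX)
        res = pingouin.intraclass_corr(
            data=t.assign(rater=t.groupby("subject").cumcount()),
            targets="subject",
            raters="rater",
            ratings="value",
        ).set_index("Type")
        key = "ICC(A,1)" if model == "single" else "ICC(A,k)"
        assert icc(t, model) == pytest.approx(res.loc[key, "ICC"], abs=1e-10)

    def test_spearman_brown_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(300, 25, size=(10, 1))[:, [0] * 6] + rng.normal(0, 10, (10, 6))
            t = _table_from_matrix(x)
            rho = icc(t, "single")
            k = 6
            assert icc(t, "average") == pytest.approx(k * rho / (1 + (k - 1) * rho), abs=1e-12)

    def test_simulated_cohort_matches_closed_form(self):
        """Average-measures ICC approaches 6 rho / (1 + 5 rho)."""
        sb, sw = 25.0, 10.5
        rho = sb**2 / (sb**2 + sw**2)
        expected = 6 * rho / (1 + 5 * rho)
        vals = [
            icc(
                make_cohort(
                    CohortSpec(
                        n_subjects=40, between_subject_sd=sb, within_subject_sd=sw, seed=s
                    )
                ),
                "average",
            )
            for s in range(20)
        ]
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc(_table_from_matrix([[1.0, 1.0], [1.0, 1.0]]), "single")

    def test_unbalanced_rejected_with_subject_named(self):
        t = _table_from_matrix(FIXED_MATRIX).drop(index=0)
        with pytest.raises(ValueError, match="subject 1"):
            icc(t, "single")


class TestBlandAltman:
    def test_identical_arrays(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_constant_difference(self):
        bias, lo, hi = bland_altman([5.0, 7.0], [10.0, 12.0])
        assert bias == lo == hi == -5.0

    def test_hand_example(self):
        bias, lo, hi = bland_altman([10.0, 12.0, 14.0], [10.0, 10.0, 10.0])
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(2.0 - 1.96 * 2.0)
        assert hi == pytest.approx(2.0 + 1.96 * 2.0)

    def test_limits_cover_95_percent(self):
        rng = np.random.default_rng(4)
        a = rng.normal(300, 20, 10_000)
        b = a + rng.normal(1, 5, 10_000)
        bias, lo, hi = bland_altman(a, b)
        coverage = np.mean((a - b >= lo) & (a - b <= hi))
        assert coverage == pytest.approx(0.95, abs=0.02)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestTAndPearson:
    def test_identical_inputs_degenerate_t(self):
        assert np.isnan(paired_t(np.arange(5.0), np.arange(5.0)))

    def test_perfect_linearity(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, r2 = pearson(a, 2 * a + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_five_point_textbook_example(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, r2 = pearson(a, b)
        # hand computation: cov = 2.0, sd_a = sd_b = sqrt(2.5)
        assert r == pytest.approx(2.0 / 2.5, abs=1e-12)
        assert r2 == pytest.approx(r * r, abs=1e-15)
        p = paired_t(a, b)  # differences average to zero here: t = 0, p = 1
        assert p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestReproducibilityReport:
    def test_perfect_reproducibility(self):
        rng = np.random.default_rng(5)
        truths = rng.normal(300, 25, 8)
        rows = [
            (s + 1, sess, rep, truths[s])
            for s in range(8)
            for sess in (1, 2)
            for rep in (1, 2, 3)
        ]
        t = pd.DataFrame(rows, columns=["subject", "session", "repetition", "value"])
        res = reproducibility_report(t)
        assert res.icc == pytest.approx(1.0)
        assert res.cv_mean == pytest.approx(0.0)
        assert res.bias == pytest.approx(0.0)
        assert np.isnan(res.t_p)
        assert res.pearson_r == pytest.approx(1.0)

    def test_default_cohort_report_is_consistent(self):
        table = make_cohort(CohortSpec(seed=8))
        res = reproducibility_report(table)
        assert res.loa_low <= res.bias <= res.loa_high
        assert res.r_squared == pytest.approx(res.pearson_r**2, abs=1e-12)
        assert 0.8 < res.icc <= 1.0
        assert set(res.per_session) == {1, 2}
        k, rho = 6, res.icc_single
        assert res.icc == pytest.approx(k * rho / (1 + (k - 1) * rho), abs=1e-12)
        assert "ICC" in res.summary()

    def test_unbalanced_design_names_subject(self):
        table = make_cohort(CohortSpec(seed=8)).drop(index=0)
        with pytest.raises(ValueError, match="subject 1"):
            reproducibility_report(table)

    def test_missing_session_rejected(self):
        table = make_cohort(CohortSpec(seed=8))
        with pytest.raises(ValueError, match="session"):
            reproducibility_report(table[table["session"] == 1])
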