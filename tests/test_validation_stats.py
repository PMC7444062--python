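"""Statistics layer vs independent brute-force oracles and pingouin."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from apa.respondent_sim import CohortSpec, simulate_cohort
from apa.validation_stats import (
    icc_absolute_agreement,
    independent_t,
    partial_correlation,
    pearson,
    render_report,
    run_validation_report,
)


def brute_pearson(x, y):
    """Direct covariance-formula implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = np.sum((x - mx) * (y - my))
    den = np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    return num / den


def brute_partial(x, y, c):
    """Residualize via explicitly solved normal equations, then correlate."""
    X = np.column_stack([np.ones(len(c)), c])
    bx = np.linalg.solve(X.T @ X, X.T @ x)
    by = np.linalg.solve(X.T @ X, X.T @ y)
    return brute_pearson(x - X @ bx, y - X @ by)


def brute_icc_a1(m):
    """ICC(A,1) from an explicit double-loop ANOVA decomposition."""
    n, k = m.shape
    grand = m.mean()
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum(
        (m[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_t(a, b):
    """Textbook pooled-variance t statistic."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestPearson:
    def test_identity(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson(x, x).r == pytest.approx(1.0)

    def test_exact_linearity(self):
        res = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 5))
            assert pearson(x, y).r == pytest.approx(brute_pearson(x, y), abs=1e-12)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, np.nan, 3.0, 8.0, 10.0]
        assert pearson(x, y).n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestPartialCorrelation:
    def test_empty_covariates_reduce_to_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 30))
        plain = pearson(x, y)
        part = partial_correlation(x, y, pd.DataFrame(index=range(30)))
        assert part.r == pytest.approx(plain.r)
        assert part.p == pytest.approx(plain.p)

    def test_y_equals_covariate_is_degenerate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="zero-variance"):
            partial_correlation(x, c, pd.DataFrame({"c": c}))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = rng.normal(size=(8, 1))
            x = 0.5 * c[:, 0] + rng.normal(size=8)
            y = -0.3 * c[:, 0] + rng.normal(size=8)
            res = partial_correlation(x, y, pd.DataFrame({"c": c[:, 0]}))
            assert res.r == pytest.approx(brute_partial(x, y, c), abs=1e-10)
            assert res.df == 8 - 2 - 1

    def test_matches_pingouin(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("xyab"))
        res = partial_correlation(df.x, df.y, df[["a", "b"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-9)

    def test_collinear_design_named(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=20)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_correlation(rng.normal(size=20), rng.normal(size=20), cov)

    def test_independent_covariates_leave_r_unchanged(self):
        rng = np.random.default_rng(6)
        n = 4000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        cov = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        assert partial_correlation(x, y, cov).r == pytest.approx(
            pearson(x, y).r, abs=0.01
        )


class TestIcc:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 2.0, 5.0, 9.0, 12.0, 3.0])
        res = icc_absolute_agreement(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0)

    def test_offset_penalized(self):
        col = np.array([1.0, 2.0, 5.0, 9.0, 12.0, 3.0])
        res = icc_absolute_agreement(np.column_stack([col, col + 20.0]))
        assert res.icc < 1.0  # absolute agreement penalizes systematic shift

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = rng.normal(size=(10, 2))
            res = icc_absolute_agreement(m)
            assert res.icc == pytest.approx(brute_icc_a1(m), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=12)
        m = np.column_stack([base + rng.normal(0, 0.5, 12) for _ in range(3)])
        res = icc_absolute_agreement(m)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subject", "rater", "score")
        row = ref[ref.Type.astype(str).str.contains(r"ICC2|A,1")].iloc[0]
        assert res.icc == pytest.approx(float(row.ICC), abs=1e-9)
        lo, hi = row["CI95"] if "CI95" in ref.columns else row["CI95%"]
        assert res.ci_low == pytest.approx(lo, abs=0.006)  # pingouin rounds CIs
        assert res.ci_high == pytest.approx(hi, abs=0.006)

    def test_subject_reordering_invariant(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(15, 2))
        perm = rng.permutation(15)
        assert icc_absolute_agreement(m).icc == pytest.approx(
            icc_absolute_agreement(m[perm]).icc
        )

    def test_shared_affine_invariance(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(15, 2))
        assert icc_absolute_agreement(3.0 * m + 7.0).icc == pytest.approx(
            icc_absolute_agreement(m).icc, abs=1e-10
        )

    def test_constant_matrix_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_absolute_agreement(np.full((6, 2), 5.0))

    def test_listwise_deletion(self):
        rng = np.random.default_rng(11)
        m = rng.normal(size=(10, 2))
        m[0, 1] = np.nan
        assert icc_absolute_agreement(m).n == 9


class TestIndependentT:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = independent_t(g, g)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b = rng.normal(size=(2, 4))
            res = independent_t(a, b)
            assert res.t == pytest.approx(brute_t(a, b), abs=1e-12)
            assert res.df == 6

    def test_group_difference_direction(self):
        # groups constructed at the reported race-contrast means (28.7 vs 5.3)
        rng = np.random.default_rng(13)
        minority = 28.7 + 46.0 * rng.standard_normal(35)
        white = 5.3 + 46.0 * rng.standard_normal(25)
        minority += 28.7 - minority.mean()
        white += 5.3 - white.mean()
        res = independent_t(minority, white)
        assert res.t > 0

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            independent_t([2.0, 2.0], [2.0, 2.0])


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(n=60, seed=21))


class TestValidationReport:
    def test_grid_complete(self, cohort):
        rep = run_validation_report(cohort)
        for m in ("freeplay_sed_pct", "daily_sed_min", "daily_mvpa_min",
                  "vo2peak_ffm", "bmi_z", "pct_body_fat", "fmi"):
            assert "raw" in rep["correlations"][m]
            assert "adjusted" in rep["correlations"][m]
        assert "retest_icc" in rep
        assert set(rep["accelerometry_by_sex"]) == {"girls", "boys"}
        assert rep["n"] == 60

    def test_all_positive_bias_fraction(self, cohort):
        shifted = cohort.copy()
        shifted["bias"] = np.abs(shifted["bias"]) + 1.0
        rep = run_validation_report(shifted)
        assert rep["sedentary_preference_pct"] == 100.0

    def test_adjusted_r_near_generator_target(self):
        # Monte-Carlo check against the generator's %body-fat target
        vals = []
        for i in range(200):
            table = simulate_cohort(CohortSpec(n=60, seed=40_000 + i))
            rep = run_validation_report(table)
            vals.append(rep["correlations"]["pct_body_fat"]["adjusted"]["r"])
        assert np.mean(vals) == pytest.approx(0.43, abs=0.05)

    def test_column_errors_do_not_abort(self, cohort):
        broken = cohort.copy()
        broken["fmi"] = 1.0  # zero variance
        rep = run_validation_report(broken)
        assert "error" in rep["correlations"]["fmi"]["raw"]
        assert "raw" in rep["correlations"]["pct_body_fat"]

    def test_missing_column_reported(self, cohort):
        rep = run_validation_report(cohort.drop(columns=["fmi"]))
        assert "error" in rep["correlations"]["fmi"]

    def test_report_renders_and_serializes(self, cohort):
        import json

        rep = run_validation_report(cohort)
        text = render_report(rep)
        assert "Test-retest ICC" in text and "pct_body_fat" in text
        json.dumps(rep)  # JSON-serializable

    def test_p_and_r_ranges(self, cohort):
        rep = run_validation_report(cohort)
        for cell in rep["correlations"].values():
            for kind in ("raw", "adjusted"):
                if kind in cell and "error" not in cell[kind]:
                    assert -1.0 <= cell[kind]["r"] <= 1.0
                    assert 0.0 <= cell[kind]["p"] <= 1.0
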