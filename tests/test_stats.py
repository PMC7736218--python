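"""Statistics: every estimator against an independently coded oracle."""

import numpy as np
import pytest
from scipy import stats as st

from betastop.stats import (bonferroni, effect_size_label, jzs_bf10,
                            one_sample_t, one_way_rm_anova, paired_t, pearson,
                            rmcorr, two_sample_t)


def rmcorr_oracle(x, y, subject):
    """Brute-force ANCOVA by explicit design-matrix least squares."""
    subjects = sorted(set(subject))
    n, k = len(x), len(subjects)
    X = np.zeros((n, k + 1))
    for j, s in enumerate(subjects):
        X[np.asarray(subject) == s, j] = 1.0
    X[:, k] = x
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_err = float(resid @ resid)
    X0 = X[:, :k]
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    ss_err0 = float((y - X0 @ beta0) @ (y - X0 @ beta0))
    ss_measure = ss_err0 - ss_err
    r = np.sign(beta[k]) * np.sqrt(ss_measure / (ss_measure + ss_err))
    return float(r), float(beta[k]), n - k - 1


class TestRmcorr:
    def test_parallel_unit_slope_lines(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = x + np.array([0, 0, 0, 5, 5, 5], dtype=float)
        sub = np.array([0, 0, 0, 1, 1, 1])
        res = rmcorr(x, y, sub)
        assert res.r_m == pytest.approx(1.0)
        assert res.common_slope == pytest.approx(1.0)

    def test_negative_slope(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = -x + np.array([3, 3, 3, 9, 9, 9], dtype=float)
        res = rmcorr(x, y, np.array([0, 0, 0, 1, 1, 1]))
        assert res.r_m == pytest.approx(-1.0)

    def test_matches_design_matrix_oracle_exactly(self, rng):
        """Fixed 3-subject, 4-points-each dataset vs brute-force lstsq."""
        sub = np.repeat([0, 1, 2], 4)
        x = rng.normal(size=12) + sub * 1.5
        y = 0.7 * x + rng.normal(size=12) + sub * 3.0
        res = rmcorr(x, y, sub)
        r_o, slope_o, df_o = rmcorr_oracle(x, y, sub)
        assert res.r_m == pytest.approx(r_o, abs=1e-10)
        assert res.common_slope == pytest.approx(slope_o, abs=1e-10)
        assert res.df == df_o

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        sub = np.repeat(np.arange(5), 8)
        x = rng.normal(size=40) + sub * 2.0
        y = 0.5 * x + rng.normal(size=40)
        res = rmcorr(x, y, sub)
        out = pg.rm_corr(pd.DataFrame({"x": x, "y": y, "s": sub}),
                         "x", "y", "s")
        assert res.r_m == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(out["pval"].iloc[0]),
                                            abs=1e-9)
        assert res.df == int(out["dof"].iloc[0])

    def test_constant_x_everywhere_errors(self):
        with pytest.raises(ValueError):
            rmcorr(np.ones(6), np.arange(6.0), np.repeat([0, 1], 3))

    def test_recovers_known_within_subject_coupling(self):
        """Latent shared jitter induces a predictable r_m.

        y = x + e with var(x) = 9, var(e) = 16 gives an expected common
        correlation of 3/5 (derived from the variance ratio).
        """
        rng = np.random.default_rng(42)
        sub = np.repeat(np.arange(10), 200)
        x = rng.normal(0.0, 3.0, size=2000) + 10.0 * sub
        y = x + rng.normal(0.0, 4.0, size=2000) - 5.0 * sub
        res = rmcorr(x, y, sub)
        assert res.r_m == pytest.approx(0.6, abs=0.1)


class TestTTests:
    def test_identical_vectors_null_result(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.effect_size == 0.0

    def test_constant_nonzero_diffs_error(self):
        with pytest.raises(ValueError):
            paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = paired_t(x, y)
        d = x - y
        t_o = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert res.statistic == pytest.approx(t_o, abs=1e-12)
        t_sp, p_sp = st.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t_sp, abs=1e-12)
        assert res.p_value == pytest.approx(p_sp, abs=1e-12)

    def test_one_sample_vs_scipy(self, rng):
        x = rng.normal(1.0, 2.0, size=15)
        res = one_sample_t(x, mu0=0.5)
        t_sp, p_sp = st.ttest_1samp(x, 0.5)
        assert res.statistic == pytest.approx(t_sp, abs=1e-12)
        assert res.p_value == pytest.approx(p_sp, abs=1e-12)

    def test_two_sample_vs_scipy(self, rng):
        x, y = rng.normal(size=12), rng.normal(0.8, 1.0, size=9)
        res = two_sample_t(x, y)
        t_sp, p_sp = st.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t_sp, abs=1e-12)
        assert res.p_value == pytest.approx(p_sp, abs=1e-12)


def bf10_trapezoid_oracle(t, n, r=np.sqrt(2) / 2, grid=200_001, span=60.0):
    """Fine-grid trapezoid integration of the Cauchy-prior marginal."""
    nu = n - 1
    delta = np.linspace(-span, span, grid)
    prior = st.cauchy.pdf(delta, scale=r)
    like = st.nct.pdf(t, nu, delta * np.sqrt(n))
    m1 = np.trapezoid(like * prior, delta)
    return m1 / st.t.pdf(t, nu)


class TestJzsBf10:
    @pytest.mark.parametrize("t,n", [(3.0, 20), (0.0, 20), (2.2, 15),
                                     (-1.5, 30), (5.0, 12)])
    def test_matches_quadrature_oracle(self, t, n):
        assert jzs_bf10(t, n) == pytest.approx(
            bf10_trapezoid_oracle(t, n), rel=1e-5)

    def test_matches_pingouin(self):
        import pingouin as pg
        for t, n in [(3.0, 20), (2.2, 15), (0.0, 20)]:
            assert jzs_bf10(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-3)

    def test_scale_zero_gives_unity(self):
        assert jzs_bf10(2.5, 20, cauchy_scale=0.0) == 1.0

    def test_t_zero_favors_null(self):
        assert jzs_bf10(0.0, 20) < 1.0

    def test_monotone_in_abs_t(self):
        vals = [jzs_bf10(t, 20) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


def rm_anova_oracle(v):
    """Hand-computed sums of squares for a subject x level table."""
    n, k = v.shape
    grand = v.mean()
    ss_level = n * sum((v[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((v[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = ((v - grand) ** 2).sum()
    ss_err = ss_tot - ss_level - ss_subj
    f = (ss_level / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    eta = ss_level / (ss_level + ss_err)
    return f, eta


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        v = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = one_way_rm_anova(v)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_df_for_18_subjects_3_levels(self, rng):
        res = one_way_rm_anova(rng.normal(size=(18, 3)))
        assert res.df == (2, 34)

    def test_matches_hand_oracle(self, rng):
        v = rng.normal(size=(4, 3)) + np.array([0.0, 0.5, 1.0])
        res = one_way_rm_anova(v)
        f_o, eta_o = rm_anova_oracle(v)
        assert res.statistic == pytest.approx(f_o, abs=1e-10)
        assert res.effect_size == pytest.approx(eta_o, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        v = rng.normal(size=(12, 4)) + np.arange(4) * 0.3
        res = one_way_rm_anova(v)
        long = pd.DataFrame({
            "y": v.ravel(),
            "s": np.repeat(np.arange(12), 4),
            "l": np.tile(np.arange(4), 12),
        })
        out = pg.rm_anova(long, dv="y", within="l", subject="s",
                          detailed=True, effsize="np2").iloc[0]
        assert res.statistic == pytest.approx(float(out["F"]), abs=1e-8)
        assert res.p_value == pytest.approx(float(out["p_unc"]), abs=1e-8)
        assert res.effect_size == pytest.approx(float(out["np2"]), abs=1e-8)

    def test_missing_cells_rejected(self):
        v = np.ones((4, 3))
        v[1, 2] = np.nan
        with pytest.raises(ValueError):
            one_way_rm_anova(v)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(6.0)
        assert pearson(x, 2 * x).statistic == pytest.approx(1.0)

    def test_orthogonal_after_centering(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson(x, y).statistic == pytest.approx(0.0)

    def test_matches_scipy_on_fixed_set(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        res = pearson(x, y)
        r_sp, p_sp = st.pearsonr(x, y)
        assert res.statistic == pytest.approx(r_sp, abs=1e-12)
        assert res.p_value == pytest.approx(p_sp, abs=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


class TestBonferroni:
    def test_simple_multiplication(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)

    def test_clamped_at_one(self):
        assert bonferroni(0.5, 3) == 1.0

    def test_zero_stays_zero(self):
        assert bonferroni(0.0, 10) == 0.0

    def test_vector_and_validation(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.02], 4), [0.04, 0.08])
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


def test_effect_size_labels():
    assert effect_size_label(0.3, "d") == "small"
    assert effect_size_label(0.9, "d") == "large"
    assert effect_size_label(5.0, "bf10") == "medium"
    assert effect_size_label(0.08, "eta_p2") == "medium"
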