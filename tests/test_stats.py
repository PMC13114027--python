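"""Correlation, partial correlation, t-tests, and Bonferroni control."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from cochmap import (
    TestFamily,
    bonferroni,
    partial_correlation,
    pearson,
    two_sample_t,
)
from cochmap.stats import apply_bonferroni, p_value_from_r


def t_pvalue_by_quadrature(t_stat: float, df: int) -> float:
    """Independent oracle: numeric integration of the t density."""
    tail, _ = quad(lambda u: sps.t.pdf(u, df), abs(t_stat), np.inf)
    return 2.0 * tail


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.df == 8

    def test_hand_table_against_sum_of_products_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 11.0])
        y = np.array([3.0, 1.0, 5.0, 9.0, 8.0, 13.0])
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        res = pearson(x, y)
        assert res.r == pytest.approx(oracle, abs=1e-12)
        sp_r, sp_p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(sp_r, abs=1e-12)
        assert res.p == pytest.approx(sp_p, abs=1e-12)

    def test_independent_samples_yield_small_r(self, rng):
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        assert abs(pearson(x, y).r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(10), np.arange(10.0))


class TestPartialCorrelation:
    def test_headline_transform(self):
        """r = -0.52 with n = 35 and two covariates gives p = 0.002."""
        p = p_value_from_r(-0.52, n=35, k=2)
        assert round(p, 3) == 0.002
        t = -0.52 * np.sqrt(31 / (1 - 0.52**2))
        assert p == pytest.approx(t_pvalue_by_quadrature(t, 31), abs=1e-8)

    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        a = partial_correlation(x, y)
        b = pearson(x, y)
        assert a.r == pytest.approx(b.r, abs=1e-14)
        assert a.df == b.df

    def test_confounder_removal(self, rng):
        """x and y driven only by a shared covariate: marginal correlation is
        large, partial correlation is near zero."""
        z = rng.standard_normal(500)
        x = z + 0.3 * rng.standard_normal(500)
        y = 2 * z + 0.3 * rng.standard_normal(500)
        assert pearson(x, y).r > 0.8
        assert abs(partial_correlation(x, y, z).r) < 0.1

    def test_matches_independent_reference(self, rng):
        """Residualization agrees with pingouin's inverse-covariance route."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 35
        z = rng.standard_normal((n, 2))
        x = z @ [0.5, -0.3] + rng.standard_normal(n)
        y = z @ [-0.2, 0.4] - 0.6 * x + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)
        assert res.df == n - 4

    def test_affine_transform_of_covariates_is_invariant(self, rng):
        n = 60
        z = rng.standard_normal((n, 2))
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        base = partial_correlation(x, y, z)
        shifted = partial_correlation(x, y, z * [2.5, -7.0] + [100.0, -3.0])
        assert shifted.r == pytest.approx(base.r, abs=1e-10)

    def test_collinear_covariate_named(self, rng):
        n = 30
        z0 = rng.standard_normal(n)
        Z = np.column_stack([z0, 3 * z0])
        with pytest.raises(ValueError, match="column 1"):
            partial_correlation(rng.standard_normal(n), rng.standard_normal(n), Z)

    def test_insufficient_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= k"):
            partial_correlation(
                rng.standard_normal(5), rng.standard_normal(5), rng.standard_normal((5, 2))
            )


class TestTwoSampleT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(a, a)
        assert res.t_stat == pytest.approx(0.0, abs=1e-14)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_three_vs_three(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 6.0, 8.0])
        sp = np.sqrt(((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4)
        oracle_t = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 3))
        res = two_sample_t(a, b)
        assert res.t_stat == pytest.approx(oracle_t, abs=1e-12)
        assert res.df == 4

    def test_sex_difference_in_duct_length_is_detectable(self, rng):
        """At the cohort's sex-conditional CDL distributions the t-test finds
        the ~1 mm difference in most replicates."""
        hits = 0
        for _ in range(100):
            male = rng.normal(34.6, 0.9, 15)
            female = rng.normal(33.6, 1.5, 29)
            hits += two_sample_t(male, female).p < 0.05
        assert hits > 50

    def test_welch_flag(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 40)
        assert two_sample_t(a, b, welch=True).df != two_sample_t(a, b).df

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestBonferroni:
    def test_study_family_threshold(self):
        """alpha = 0.05 over the 4 x 3 outcome grid gives 0.0042 at 4 dp."""
        fam = TestFamily(alpha=0.05, m=12)
        assert bonferroni(fam) == pytest.approx(0.05 / 12, rel=1e-15)
        assert round(bonferroni(fam), 4) == 0.0042

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_simple_families(self, alpha, m, expected):
        assert bonferroni(TestFamily(alpha=alpha, m=m)) == pytest.approx(expected)

    def test_flags_set_on_results(self, rng):
        x = np.arange(20.0)
        strong = pearson(x, x + rng.normal(0, 0.5, 20))
        weak = pearson(rng.standard_normal(20), rng.standard_normal(20))
        fam = TestFamily(alpha=0.05, m=12)
        flagged = apply_bonferroni([strong, weak], fam)
        assert flagged[0].significant_bonferroni is True
        assert flagged[1].significant_bonferroni is False

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            TestFamily(alpha=0.0, m=12)
        with pytest.raises(ValueError):
            TestFamily(alpha=0.05, m=0)


def test_t_transform_matches_quadrature_over_a_grid():
    """p-values from the closed-form t transform agree with numeric
    integration of the t density to 1e-8."""
    for r in (-0.9, -0.52, -0.1, 0.3, 0.75):
        for n, k in ((35, 2), (27, 2), (15, 0)):
            df = n - 2 - k
            t = r * np.sqrt(df / (1 - r * r))
            assert p_value_from_r(r, n, k) == pytest.approx(
                t_pvalue_by_quadrature(t, df), abs=1e-8
            )
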