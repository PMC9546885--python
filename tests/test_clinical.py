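"""Clinical covariate statistics: permutation correlations, ANCOVA-style
overall F, summary-statistic Welch t and chi-square tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegaec.clinical import (
    chisq_independence,
    clinical_correlations,
    linear_model_f,
    perm_pearson,
    welch_t_summary,
)


class TestPermPearson:
    def test_perfect_correlation_minimal_p(self, rng):
        x = rng.standard_normal(20)
        r, p = perm_pearson(x, x, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_null_calibration(self, rng):
        n_rep = 400
        ps = np.empty(n_rep)
        for i in range(n_rep):
            x = rng.uniform(size=20)
            y = rng.uniform(size=20)
            _, ps[i] = perm_pearson(x, y, n_perm=199, seed=i)
        rate = np.mean(ps <= 0.05)
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se

    def test_p_uniform_under_null(self, rng):
        """Empirical distribution of permutation p-values is uniform."""
        import scipy.stats

        ps = []
        for i in range(300):
            x = rng.standard_normal(16)
            y = rng.standard_normal(16)
            ps.append(perm_pearson(x, y, n_perm=2000, seed=1000 + i)[1])
        d, p_ks = scipy.stats.kstest(ps, "uniform")
        assert p_ks > 0.001

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            perm_pearson(np.ones(10), rng.standard_normal(10))

    def test_planted_negative_association_recovered(self):
        """Cohorts planted with a strong negative episodes-AEC link yield a
        negative, significant permutation correlation in most replicates."""
        from eegaec.simulate import (
            TARGET_BAND,
            TARGET_PAIR,
            SimulationConfig,
            simulate_cohort,
        )

        hits, rs = 0, []
        n_rep = 5
        for s in range(n_rep):
            cfg = SimulationConfig(
                n_per_group=20, fs=256, duration=60, n_sensors=8, seed=300 + s
            )
            coh = simulate_cohort(cfg)
            pi = coh.pair_labels.index(tuple(sorted(TARGET_PAIR)))
            bi = coh.band_labels.index(TARGET_BAND)
            pat = coh.labels == 1
            r, p = perm_pearson(
                coh.true_aec[pat, pi, bi],
                coh.covariates.episodes[pat].to_numpy(float),
                n_perm=2000,
                seed=s,
            )
            rs.append(r)
            hits += (r < 0) and (p <= 0.05)
        assert hits >= 4  # >= 80% of replicates
        assert abs(np.mean(rs) - (-0.71)) < 0.15


def test_clinical_correlations_fdr_family(rng):
    n = 20
    aec_vals = rng.uniform(0, 0.4, n)
    cov = pd.DataFrame(
        {
            "episodes": 10 - 20 * aec_vals + rng.normal(0, 0.5, n),
            "onset_age": rng.uniform(18, 50, n),
            "episode_weeks": rng.uniform(2, 60, n),
        }
    )
    out = clinical_correlations(
        aec_vals, cov, ["onset_age", "episodes", "episode_weeks"], n_perm=999, seed=2
    )
    assert list(out.covariate) == ["onset_age", "episodes", "episode_weeks"]
    strong = out[out.covariate == "episodes"].iloc[0]
    assert strong.r < -0.9 and strong.fdr_reject


class TestLinearModelF:
    def test_perfect_fit_flags_overflow(self, rng):
        x = pd.DataFrame({"a": rng.standard_normal(12)})
        res = linear_model_f(2.0 * x["a"].to_numpy() + 1.0, x)
        assert res.overflow and np.isinf(res.f)

    def test_df_bookkeeping_five_predictors_n18(self, rng):
        """n=18 with 5 predictor columns leaves 12 denominator df."""
        x = pd.DataFrame(
            {
                "aec": rng.standard_normal(18),
                "age": rng.uniform(20, 60, 18),
                "sex": rng.choice(["F", "M"], 18),
                "education": rng.choice([1, 2, 3], 18).astype(float),
                "severity": rng.uniform(10, 60, 18),
            }
        )
        res = linear_model_f(rng.standard_normal(18), x)
        assert (res.df1, res.df2) == (5, 12)

    def test_matches_projection_matrix_oracle(self, rng):
        x = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        y = rng.standard_normal(30)
        res = linear_model_f(y, x)
        # independent computation via hat matrix
        mat = np.column_stack([np.ones(30), x.to_numpy()])
        h = mat @ np.linalg.inv(mat.T @ mat) @ mat.T
        yc = y - y.mean()
        r2 = (yc @ (h @ y - y.mean())) / (yc @ yc)
        f = (r2 / 4) / ((1 - r2) / 25)
        assert res.f == pytest.approx(f, rel=1e-8)
        assert res.r_squared == pytest.approx(r2, rel=1e-8)

    def test_rank_deficiency_names_column(self, rng):
        a = rng.standard_normal(15)
        x = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="'a'|'b'"):
            linear_model_f(rng.standard_normal(15), x)


class TestWelchFromSummary:
    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,t2dp,df1dp",
        [
            (41.25, 14.6, 20, 36.6, 13.1, 20, 1.06, 37.5),  # age row
            (1.45, 3.71, 20, 33.45, 11.41, 18, -11.37, 20.2),  # BDI-II row
            (0.2, 0.52, 20, 27.56, 5.31, 18, -21.78, 17.3),  # HAM-D row
        ],
    )
    def test_cohort_table_rows(self, m1, s1, n1, m2, s2, n2, t2dp, df1dp):
        # inputs are printed to 2 decimals, so t can land one ulp off at
        # 2 dp (HAM-D: -21.77 vs -21.78); df reproduces to 1 dp throughout
        t, df = welch_t_summary(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(t2dp, abs=0.015)
        assert round(df, 1) == pytest.approx(df1dp, abs=0.11)

    def test_equal_means_zero_t(self):
        t, _ = welch_t_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0

    @given(
        st.floats(-50, 50),
        st.floats(0.1, 20),
        st.integers(2, 50),
        st.floats(-50, 50),
        st.floats(0.1, 20),
        st.integers(2, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_in_groups(self, m1, s1, n1, m2, s2, n2):
        t1, df1 = welch_t_summary(m1, s1, n1, m2, s2, n2)
        t2, df2 = welch_t_summary(m2, s2, n2, m1, s1, n1)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert df1 == pytest.approx(df2)

    def test_matches_scipy_from_stats(self):
        import scipy.stats

        t, _ = welch_t_summary(3.0, 1.2, 15, 2.1, 2.4, 12)
        ref = scipy.stats.ttest_ind_from_stats(
            3.0, 1.2, 15, 2.1, 2.4, 12, equal_var=False
        )
        assert t == pytest.approx(ref.statistic)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_t_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestChiSquare:
    def test_sex_table_with_yates(self):
        chi2, df = chisq_independence(np.array([[15, 13], [5, 7]]), yates=True)
        assert round(chi2, 2) == 0.12
        assert df == 1

    def test_education_table_plain(self):
        chi2, df = chisq_independence(
            np.array([[4, 8], [9, 9], [7, 3]]), yates=False
        )
        assert round(chi2, 2) == 2.93
        assert df == 2

    def test_proportional_rows_give_zero(self):
        chi2, _ = chisq_independence(np.array([[10, 20], [5, 10]]), yates=False)
        assert chi2 == pytest.approx(0.0)

    def test_yates_never_exceeds_pearson_on_2x2(self, rng):
        for _ in range(50):
            tab = rng.integers(1, 40, size=(2, 2))
            cy, _ = chisq_independence(tab, yates=True)
            cp, _ = chisq_independence(tab, yates=False)
            assert cy <= cp + 1e-12

    def test_invariant_to_permutation(self, rng):
        tab = rng.integers(1, 30, size=(3, 2))
        c1, _ = chisq_independence(tab, yates=False)
        c2, _ = chisq_independence(tab[::-1, ::-1], yates=False)
        assert c1 == pytest.approx(c2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chisq_independence(np.array([[0, 0], [3, 4]]))
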