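import numpy as np
import pandas as pd
import pytest

from gazemark.psychometrics import (
    cohens_d_from_summary,
    construct_validity_table,
    discrimination_table,
    group_discrimination,
    icc_stability,
    one_sample_construct_test,
    one_sample_from_summary,
    partial_spearman_rho,
    pooled_cohens_d,
    spearman_matrix,
    spearman_rho,
    subgroup_analyses,
)


class TestOneSample:
    @pytest.mark.parametrize(
        "n,mean,sd,mu0,t_ref,d_ref",
        [
            (119, 27.6, 8.5, 3.2, 31.3, 2.87),
            (119, 30.4, 9.6, 8.3, 25.0, 2.30),
            (119, 34.9, 8.0, 3.9, 42.1, 3.88),
            (119, 54.8, 6.1, 50.0, 8.5, 0.79),
        ],
    )
    def test_ref_construct_statistics(self, n, mean, sd, mu0, t_ref, d_ref):
        r = one_sample_from_summary(n, mean, sd, mu0)
        assert r.t == pytest.approx(t_ref, abs=0.2)
        assert r.d == pytest.approx(d_ref, abs=0.01)
        assert r.df == n - 1
        assert r.p < 0.001

    def test_ref_constriction_one_sided(self):
        r = one_sample_from_summary(117, 0.505, 0.074, 0.0, alternative="greater")
        assert r.t == pytest.approx(73.9, abs=0.2)
        assert r.d == pytest.approx(6.83, abs=0.01)
        assert r.df == 116

    def test_mean_equal_mu0(self):
        r = one_sample_from_summary(30, 5.0, 2.0, 5.0)
        assert r.t == 0.0 and r.d == 0.0
        assert r.p == pytest.approx(1.0)

    def test_raw_values_match_summary_path(self, rng):
        x = rng.normal(10, 3, 40)
        r1 = one_sample_construct_test(x, 8.0)
        r2 = one_sample_from_summary(40, x.mean(), x.std(ddof=1), 8.0)
        assert r1.t == pytest.approx(r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_sd_flagged(self):
        with pytest.warns(UserWarning):
            r = one_sample_from_summary(10, 5.0, 0.0, 3.0)
        assert np.isinf(r.t)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            one_sample_construct_test([1.0], 0.0)


class TestCohensD:
    def test_identical_distributions_zero(self, rng):
        x = rng.normal(0, 1, 50)
        assert pooled_cohens_d(x, x.copy()) == 0.0

    def test_ref_group_discrimination_value(self):
        d = cohens_d_from_summary(24.4, 8.5, 272, 30.9, 7.6, 119)
        assert abs(d) == pytest.approx(0.788, abs=0.01)

    def test_location_scale_property(self, rng):
        x = rng.normal(3, 2, 60)
        y = rng.normal(3, 2, 80)
        d0 = pooled_cohens_d(x, y)
        n1, n2 = len(x), len(y)
        sp = np.sqrt(
            ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        )
        d1 = pooled_cohens_d(x + sp, y)
        assert d1 - d0 == pytest.approx(1.0, abs=1e-9)


def icc_oracle(data):
    """Brute-force two-way ANOVA decomposition (independent path)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    row_m = data.mean(axis=1, keepdims=True)
    col_m = data.mean(axis=0, keepdims=True)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    mse = ((data - row_m - col_m + grand) ** 2).sum() / ((n - 1) * (k - 1))
    icc_c = (msr - mse) / (msr + (k - 1) * mse)
    icc_a = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return icc_c, icc_a


class TestIcc:
    def test_perfect_agreement(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = icc_stability(x, x)
        assert r.icc_consistency == pytest.approx(1.0)
        assert r.icc_absolute == pytest.approx(1.0)

    def test_hand_matrix_against_oracle(self):
        data = np.array([(1, 2), (3, 3), (5, 4), (7, 8), (9, 9)], dtype=float)
        r = icc_stability(data[:, 0], data[:, 1])
        icc_c, icc_a = icc_oracle(data)
        assert r.icc_consistency == pytest.approx(icc_c, rel=1e-12)
        assert r.icc_absolute == pytest.approx(icc_a, rel=1e-12)
        assert r.n == 5 and r.df == 4

    def test_hand_matrix_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        data = np.array([(1, 2), (3, 3), (5, 4), (7, 8), (9, 9)], dtype=float)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(5), 2),
                "rater": np.tile(["a", "b"], 5),
                "score": data.ravel(),
            }
        )
        pg = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        r = icc_stability(data[:, 0], data[:, 1])
        assert r.icc_consistency == pytest.approx(pg.loc["ICC(C,1)", "ICC"], abs=1e-6)
        assert r.icc_absolute == pytest.approx(pg.loc["ICC(A,1)", "ICC"], abs=1e-6)

    def test_missing_pairs_dropped(self):
        a = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        b = [1.1, 2.1, 3.0, np.nan, 5.2, 6.1]
        r = icc_stability(a, b)
        assert r.n == 4

    def test_zero_between_subject_variance_reported_asis(self, rng):
        a = np.zeros(10)
        b = rng.normal(0, 1, 10)
        r = icc_stability(a, b)
        assert r.icc_consistency <= 0 or np.isnan(r.icc_consistency)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            icc_stability([1.0, 2.0], [1.0, 2.0])

    def test_bands(self):
        data = np.array([(1, 2), (3, 3), (5, 4), (7, 8), (9, 9)], dtype=float)
        r = icc_stability(data[:, 0], data[:, 1])
        assert r.band() in {"low", "moderate", "high"}


class TestHc3:
    def test_covariance_matches_explicit_formula(self, rng):
        # 10x3 fixture: intercept + group indicator + one covariate
        n = 10
        group = np.array(["ASD"] * 5 + ["TD"] * 5)
        cov = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n) + (group == "TD") * 0.5 + 0.3 * cov
        res = group_discrimination(y, group, pd.DataFrame({"c": cov}))
        x = np.column_stack([np.ones(n), (group == "TD").astype(float), cov])
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y
        e = y - x @ beta
        h = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
        meat = x.T @ np.diag(e**2 / (1 - h) ** 2) @ x
        v = xtx_inv @ meat @ xtx_inv
        np.testing.assert_allclose(res.cov_hc3, v, rtol=1e-10)
        np.testing.assert_allclose(res.params, beta, rtol=1e-10)

    def test_homoskedastic_large_n_close_to_classical(self, rng):
        import statsmodels.api as sm

        n = 4000
        group = np.array(["ASD"] * (n // 2) + ["TD"] * (n // 2))
        y = rng.normal(0, 1, n) + (group == "TD") * 0.1
        res = group_discrimination(y, group)
        x = np.column_stack([np.ones(n), (group == "TD").astype(float)])
        classical = sm.OLS(y, x).fit()
        f_classical = classical.tvalues[1] ** 2
        assert res.f == pytest.approx(f_classical, rel=0.02)

    def test_rank_deficiency_names_columns(self, rng):
        n = 20
        group = np.array(["ASD"] * 10 + ["TD"] * 10)
        cov = (group == "TD").astype(float)  # aliased with the group term
        with pytest.raises(ValueError, match="aliased"):
            group_discrimination(rng.normal(0, 1, n), group, pd.DataFrame({"dup": cov}))

    def test_site_coded_as_indicators(self, rng):
        n = 60
        group = np.array(["ASD", "TD"] * 30)
        site = np.array(["S1", "S2", "S3"] * 20)
        y = rng.normal(0, 1, n)
        res = group_discrimination(y, group, pd.DataFrame({"site": site}))
        assert any("site[" in c for c in res.exog_names)
        # alphabetical reference level: first site absorbed by the intercept
        assert not any("site[S1]" in c for c in res.exog_names)

    def test_effect_size_outputs(self, rng):
        n = 200
        group = np.array(["ASD"] * 120 + ["TD"] * 80)
        y = np.concatenate([rng.normal(0, 1.5, 120), rng.normal(1, 0.8, 80)])
        res = group_discrimination(y, group)
        assert res.d == pytest.approx(pooled_cohens_d(y[:120], y[120:]))
        assert 0 <= res.eta_p2 <= 1
        assert res.p < 0.01


class TestSpearman:
    def test_ref_toy_pair(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        rho, p, n = spearman_rho(x, y)
        # classical rank formula: 1 - 6*sum(d^2)/(n(n^2-1))
        assert rho == pytest.approx(1 - 6 * 6 / (6 * 35), rel=1e-12)
        assert rho == pytest.approx(0.8286, abs=1e-4)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 60)
        y = x**3 + rng.normal(0, 0.1, 60)
        r1, _, _ = spearman_rho(x, y)
        r2, _, _ = spearman_rho(np.exp(x), y)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_strictly_monotone_is_one(self):
        x = np.arange(20.0)
        rho, _, _ = spearman_rho(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        rho, p, _ = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_column_reported_missing(self):
        rho, p, n = spearman_rho([1.0] * 10, list(range(10)))
        assert np.isnan(rho)

    def test_partial_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 80
        z = rng.normal(0, 1, n)
        x = z + rng.normal(0, 1, n)
        y = 0.5 * z + rng.normal(0, 1, n)
        rho, p, _ = partial_spearman_rho(x, y, pd.DataFrame({"z": z}))
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman",
        )
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_matrix_shape_and_missing_policy(self, rng):
        n = 40
        tab = pd.DataFrame(
            {
                "a": rng.normal(0, 1, n),
                "b": rng.normal(0, 1, n),
                "c": rng.normal(0, 1, n),
            }
        )
        tab.loc[:5, "b"] = np.nan
        out = spearman_matrix(tab, ["a"], ["b", "c"])
        assert len(out) == 2
        assert out.loc[out["clinical"] == "b", "n"].iloc[0] == n - 6


class TestSubgroups:
    def _table(self, ages):
        rows = []
        rng = np.random.default_rng(0)
        for i, age in enumerate(ages):
            base = rng.normal(25, 5)
            for tp in (1, 2):
                rows.append(
                    {
                        "participant_id": f"P{i:03d}",
                        "group": "ASD",
                        "timepoint": tp,
                        "age_years": age,
                        "iq": 100.0,
                        "omi": base + rng.normal(0, 1),
                    }
                )
        return pd.DataFrame(rows)

    def test_age_boundary_split(self):
        ages = [8.4] * 4 + [8.5] * 4
        out = subgroup_analyses(self._table(ages), variables=["omi"])
        young = out[out["subgroup"] == "age<8.5"]
        old = out[out["subgroup"] == "age>=8.5"]
        assert young["n"].iloc[0] == 4
        assert old["n"].iloc[0] == 4

    def test_empty_cell_warns_and_omits(self):
        ages = [9.0] * 6  # everyone above the split
        with pytest.warns(UserWarning):
            out = subgroup_analyses(self._table(ages), variables=["omi"])
        assert "age<8.5" not in set(out["subgroup"])


class TestTables:
    def test_construct_table_on_micro_cohort(self, micro_bundle):
        tab = construct_validity_table(micro_bundle.biomarker_table)
        assert set(tab["variable"]) <= {
            "am_pct_face", "si_pct_face", "ss_pct_face", "bm_pct_bio",
            "plr_constriction",
        }
        gaze_rows = tab[tab["variable"] == "am_pct_face"]
        if not gaze_rows.empty:
            assert gaze_rows["t"].iloc[0] > 0

    def test_discrimination_table_runs(self, micro_bundle):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = discrimination_table(
                micro_bundle.biomarker_table, variables=["omi"], covariates=[]
            )
        assert (tab["adjusted"] == False).any()  # noqa: E712
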