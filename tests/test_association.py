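import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from coreis.association import (
    assemble_core_is,
    associate_study,
    bh_fdr,
    directional_consistency,
    fit_bivariate_model,
    stouffer_combine,
    stouffer_rows,
    univariate_r,
)
from tests._oracles import (
    bh_bruteforce,
    sequential_anova_bruteforce,
    stouffer_bruteforce,
)


class TestBivariateModel:
    def test_perfect_fit_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        is_log = rng.normal(size=12)
        cov = rng.normal(size=12)
        fit = fit_bivariate_model(2 * is_log, is_log, cov)
        assert fit.degenerate
        assert fit.p_is == 0.0

    def test_constant_expression_degenerate(self):
        fit = fit_bivariate_model(np.ones(10), np.arange(10.0), np.arange(10.0) ** 2)
        assert fit.degenerate and fit.p_is == 1.0

    def test_orthogonal_covariate_makes_order_irrelevant(self):
        rng = np.random.default_rng(1)
        is_log = rng.normal(size=20)
        cov = rng.normal(size=20)
        # center, then orthogonalize: with zero sample correlation the
        # sequential SS of the IS term is identical under both orders
        is_log -= is_log.mean()
        cov -= cov.mean()
        cov = cov - (cov @ is_log) / (is_log @ is_log) * is_log
        y = 0.5 * is_log + rng.normal(size=20)
        a = fit_bivariate_model(y, is_log, cov, "is_first")
        b = fit_bivariate_model(y, is_log, cov, "cov_first")
        assert a.p_is == pytest.approx(b.p_is, abs=1e-8)

    def test_matches_normal_equations_bruteforce(self):
        # 200 seeded draws across a range of sample sizes
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(8, 40))
            is_log = rng.normal(size=n)
            cov = 0.4 * is_log + rng.normal(size=n)
            y = 0.3 * is_log + 0.1 * cov + rng.normal(size=n)
            fit = fit_bivariate_model(y, is_log, cov)
            p_expected = sequential_anova_bruteforce(y, is_log, cov)
            assert fit.p_is == pytest.approx(p_expected[0], abs=1e-10)
            assert fit.p_covariate == pytest.approx(p_expected[1], abs=1e-10)
            assert fit.p_interaction == pytest.approx(p_expected[2], abs=1e-10)

    def test_matches_statsmodels_type_one_anova(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(7)
        n = 30
        x1 = rng.normal(size=n)
        x2 = 0.5 * x1 + rng.normal(size=n)
        y = 0.3 * x1 + 0.2 * x2 + rng.normal(size=n)
        tab = sm.stats.anova_lm(
            ols("y ~ a*b", pd.DataFrame({"y": y, "a": x1, "b": x2})).fit(), typ=1
        )
        fit = fit_bivariate_model(y, x1, x2)
        assert fit.p_is == pytest.approx(tab.loc["a", "PR(>F)"], abs=1e-12)
        assert fit.p_covariate == pytest.approx(tab.loc["b", "PR(>F)"], abs=1e-12)
        assert fit.p_interaction == pytest.approx(tab.loc["a:b", "PR(>F)"], abs=1e-12)

    def test_collinear_covariate_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_bivariate_model(x, x, x * 2 + 1e-9)


class TestUnivariateR:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert univariate_r(x, x) == pytest.approx(1.0)
        assert univariate_r(-x + 3, x) == pytest.approx(-1.0)

    def test_hand_computation(self):
        assert univariate_r(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0])) == pytest.approx(
            0.9820, abs=1e-4
        )

    def test_zero_variance_undefined(self):
        assert np.isnan(univariate_r(np.ones(5), np.arange(5.0)))


class TestStouffer:
    def test_single_study_identity(self):
        _, p = stouffer_combine([0.2])
        assert p == pytest.approx(0.2, abs=1e-12)

    def test_two_identical_pvalues(self):
        Z, p = stouffer_combine([0.05, 0.05])
        # closed form: Z = 2 z_{0.05} / sqrt(2) = 2.32617, p = 0.0100 (4 dp)
        assert Z == pytest.approx(2.326174, abs=1e-5)
        assert p == pytest.approx(0.0100, abs=1e-4)

    def test_null_pvalues_stay_null(self):
        Z, p = stouffer_combine([0.5] * 4)
        assert Z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_formula_and_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ps = rng.uniform(0.001, 0.999, size=rng.integers(2, 7))
            Z, p = stouffer_combine(ps)
            Z2, p2 = stouffer_bruteforce(ps)
            assert Z == pytest.approx(Z2, abs=1e-10)
            assert p == pytest.approx(p2, abs=1e-10)
            res = stats.combine_pvalues(ps, method="stouffer")
            assert Z == pytest.approx(res.statistic, abs=1e-10)

    def test_extreme_pvalues_clamped(self):
        Z, p = stouffer_combine([0.0, 1.0])
        assert np.isfinite(Z) and 0.0 <= p <= 1.0

    @given(st.floats(min_value=0.01, max_value=0.49), st.integers(min_value=1, max_value=10))
    def test_more_agreeing_studies_more_significant(self, p_each, k):
        _, pk = stouffer_combine([p_each] * k)
        _, pk1 = stouffer_combine([p_each] * (k + 1))
        assert pk1 < pk

    def test_rowwise_matches_scalar(self):
        rng = np.random.default_rng(3)
        P = pd.DataFrame(rng.uniform(0.001, 0.999, size=(10, 4)))
        rows = stouffer_rows(P)
        for g in P.index:
            Z, p = stouffer_combine(P.loc[g])
            assert rows.loc[g, "z"] == pytest.approx(Z, abs=1e-12)
            assert rows.loc[g, "p_meta"] == pytest.approx(p, abs=1e-12)


class TestBH:
    def test_single_pvalue_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_array_equal(bh_fdr(p), bh_bruteforce(p))

    def test_matches_statsmodels_correction(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestDirectionalConsistency:
    def test_all_positive(self):
        ok, d = directional_consistency(
            {"a": 0.21, "b": 0.33, "c": 0.12, "d": 0.08}, ["a", "b", "c", "d"]
        )
        assert ok and d == 1

    def test_one_flip_breaks_consistency(self):
        ok, d = directional_consistency(
            {"a": 0.2, "b": 0.3, "c": -0.1, "d": 0.2}, ["a", "b", "c", "d"]
        )
        assert not ok and d == 0

    def test_zero_r_is_inconsistent(self):
        ok, _ = directional_consistency(
            {"a": 0.0, "b": 0.3, "c": 0.1, "d": 0.2}, ["a", "b", "c", "d"]
        )
        assert not ok

    def test_missing_study_raises(self):
        with pytest.raises(KeyError):
            directional_consistency({"a": 0.1}, ["a", "b"])


def _study_frame(genes, p, r, n=100):
    return pd.DataFrame(
        {
            "r_is": r,
            "p_is_first": p,
            "p_is_adjusted": p,
            "p_interaction": 0.5,
            "n": n,
        },
        index=genes,
    )


class TestAssembleCoreIS:
    def test_sign_flip_in_required_study_blocks_selection(self):
        genes = ["g1", "g2"]
        studies = {}
        for i, sid in enumerate(["s1", "s2", "s3", "s4"]):
            r = [0.5, 0.5 if sid != "s3" else -0.5]
            studies[sid] = _study_frame(genes, [1e-6, 1e-6], r, n=100 + i)
        out = assemble_core_is(studies, None, required_studies=list(studies))
        assert bool(out.loc["g1", "core_is"])
        assert not bool(out.loc["g2", "core_is"])
        assert out.loc["g1", "direction"] == 1

    def test_required_studies_default_to_largest(self):
        genes = ["g1"]
        studies = {
            sid: _study_frame(genes, [0.5], [0.1], n=n)
            for sid, n in [("a", 50), ("b", 150), ("c", 100), ("d", 120), ("e", 80)]
        }
        out = assemble_core_is(studies, None)
        assert out.attrs["required_studies"] == ["b", "d", "c", "e"]

    def test_both_models_required_semantics(self):
        genes = ["g1"]
        age = {s: _study_frame(genes, [1e-8], [0.4]) for s in ["a", "b", "c", "d"]}
        bmi_ns = {s: _study_frame(genes, [0.8], [0.4]) for s in ["a", "b", "c", "d"]}
        both = assemble_core_is(age, bmi_ns, required_studies=["a", "b", "c", "d"])
        either = assemble_core_is(
            age, bmi_ns, required_studies=["a", "b", "c", "d"], both_models_required=False
        )
        assert not bool(both.loc["g1", "core_is"])
        assert bool(either.loc["g1", "core_is"])

    def test_threshold_validation(self):
        age = {s: _study_frame(["g"], [0.5], [0.1]) for s in ["a", "b"]}
        with pytest.raises(ValueError):
            assemble_core_is(age, None, fdr_threshold=1.5, required_studies=["a", "b"])

    def test_agrees_with_naive_reimplementation(self):
        # whole-module oracle: 200 genes x 4 studies, direct formulas
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(200)]
        studies = {}
        for sid in ["s1", "s2", "s3", "s4"]:
            p = rng.uniform(1e-6, 1, size=200)
            r = rng.normal(0, 0.3, size=200)
            studies[sid] = _study_frame(genes, p, r, n=int(rng.integers(60, 200)))
        out = assemble_core_is(studies, None, required_studies=list(studies))

        P = np.column_stack([studies[s]["p_is_first"] for s in studies])
        z = stats.norm.ppf(1 - P)
        Z = z.sum(axis=1) / np.sqrt(4)
        p_meta = 1 - stats.norm.cdf(Z)
        q = bh_bruteforce(p_meta)
        R = np.column_stack([studies[s]["r_is"] for s in studies])
        consistent = (np.sign(R) == np.sign(R[:, [0]])).all(axis=1) & (R != 0).all(axis=1)
        expected_core = (q < 0.10) & consistent
        np.testing.assert_allclose(out["z_age"], Z, atol=1e-8)
        np.testing.assert_allclose(out["p_meta_age"], p_meta, atol=1e-8)
        np.testing.assert_allclose(out["q_age"], q, atol=1e-8)
        np.testing.assert_array_equal(out["core_is"], expected_core)

    def test_planted_signal_recovered_with_direction(self, six_cohorts):
        cohorts, truth = six_cohorts
        age = {c.study_id: associate_study(c.expression, c.phenotypes, "age") for c in cohorts}
        bmi = {c.study_id: associate_study(c.expression, c.phenotypes, "bmi") for c in cohorts}
        out = assemble_core_is(age, bmi)
        planted = truth.index[truth["is_planted"]]
        recovered = out.loc[planted, "core_is"]
        assert recovered.mean() > 0.9
        rec = planted[recovered]
        assert (
            out.loc[rec, "direction"] == truth.loc[rec, "true_direction"]
        ).mean() > 0.95


class TestAssociateStudy:
    def test_invalid_subjects_dropped(self, six_cohorts):
        cohorts, _ = six_cohorts
        c = cohorts[0]
        res = associate_study(c.expression, c.phenotypes, "age")
        assert res["n"].iloc[0] == int(c.phenotypes["is_log"].notna().sum())

    def test_single_gene_path_agrees_with_vectorized(self, six_cohorts):
        cohorts, _ = six_cohorts
        c = cohorts[0]
        res = associate_study(c.expression, c.phenotypes, "bmi")
        pheno = c.phenotypes[c.phenotypes["is_log"].notna()]
        g = c.expression.index[5]
        y = c.expression.loc[g, pheno.index].to_numpy()
        fit = fit_bivariate_model(y, pheno["is_log"].to_numpy(), pheno["bmi"].to_numpy())
        assert res.loc[g, "p_is_first"] == pytest.approx(fit.p_is, abs=1e-12)
        assert res.loc[g, "r_is"] == pytest.approx(
            univariate_r(y, pheno["is_log"].to_numpy()), abs=1e-12
        )
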