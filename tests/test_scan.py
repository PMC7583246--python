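"""Association scans, multiple testing, and inflation diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ldridge as lr
from ldridge.errors import (
    CollinearityError,
    DegenerateDesignError,
    ValidationError,
)
from ldridge.scan import CHI2_1_MEDIAN, _irls_logistic, wald_chi2
from ldridge.simulate import independent_genotypes


def _toy_cohort(G, y_binary=None, ggt=None, rng=None):
    n, m = G.shape
    rng = rng or np.random.default_rng(0)
    variants = pd.DataFrame(
        dict(variant_id=[f"v{j}" for j in range(m)], chrom="1",
             pos=np.arange(1, m + 1), ref="A", alt="C", gene="g",
             func_class="missense")
    )
    pheno = pd.DataFrame(
        dict(sample_id=[f"S{i}" for i in range(n)],
             drink=y_binary if y_binary is not None else rng.integers(0, 2, n),
             ggt=ggt if ggt is not None else np.exp(rng.normal(3, 0.5, n)),
             age=rng.normal(49, 11, n), sex=rng.integers(0, 2, n))
    )
    return lr.Cohort(G, variants, pheno)


class TestComputePcs:
    def test_rank_one_structure(self, rng):
        g = rng.binomial(2, 0.4, 200).astype(float)
        G = np.column_stack([g, g])  # perfectly correlated pair
        scores = lr.compute_pcs(G, 1)
        z = (G - G.mean(0)) / G.std(0)
        total = np.var(z, axis=0).sum()
        assert np.var(scores[:, 0]) == pytest.approx(total, rel=1e-9)

    def test_matches_dense_eigendecomposition(self, rng):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 30), size=(100, 30)).astype(float)
        scores = lr.compute_pcs(G, 5)
        Z = (G - G.mean(0)) / G.std(0)
        w, v = np.linalg.eigh(Z.T @ Z)
        order = np.argsort(w)[::-1][:5]
        for j, col in enumerate(order):
            vec = v[:, col]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            assert np.allclose(scores[:, j], Z @ vec, atol=1e-8)

    def test_monomorphic_column_named(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 3)).astype(float)
        G[:, 1] = 2
        with pytest.raises(DegenerateDesignError, match="snpB"):
            lr.compute_pcs(G, 2, variant_ids=["snpA", "snpB", "snpC"])

    def test_no_case_control_separation_on_homogeneous_cohort(self):
        rng = np.random.default_rng(42)
        n = 2000
        G = independent_genotypes(n, 300, rng)
        y = rng.binomial(1, 0.106, n)
        scores = lr.compute_pcs(G, 10)
        for j in range(10):
            r = np.corrcoef(scores[:, j], y)[0, 1]
            assert abs(r) < 0.08  # ~3.5/sqrt(n) point-biserial null band


class TestLogisticScan:
    def test_matches_statsmodels_logit(self, rng):
        for _ in range(10):
            n = 400
            X = np.column_stack(
                [np.ones(n), rng.binomial(2, 0.3, n), rng.normal(size=(n, 2))]
            )
            eta = X @ np.array([-1.0, 0.4, 0.2, -0.3])
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            beta, se, conv, sep = _irls_logistic(X, y)
            assert conv and not sep
            ref = sm.Logit(y, X).fit(disp=0)
            assert np.allclose(beta, ref.params, atol=1e-8)
            assert np.allclose(se, ref.bse, atol=1e-8)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, m = 2000, 1000
        G = independent_genotypes(n, m, rng)
        y = rng.binomial(1, 0.2, n).astype(np.int8)
        cohort = _toy_cohort(G, y_binary=y, rng=rng)
        C = np.column_stack([cohort.phenotypes["age"], cohort.phenotypes["sex"]])
        table = lr.logistic_scan(cohort, C)
        rate = (table["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_wald_ci_coverage(self):
        rng = np.random.default_rng(12)
        n, beta_true = 2500, 0.9
        hits = 0
        reps = 200
        for _ in range(reps):
            g = rng.binomial(2, 0.29, n).astype(float)
            eta = -2.5 + beta_true * g
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            X = np.column_stack([np.ones(n), g])
            b, se, conv, sep = _irls_logistic(X, y)
            if abs(b[1] - beta_true) < 1.96 * se[1]:
                hits += 1
        assert hits / reps >= 0.93

    def test_constant_genotype_column_is_an_error(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 2)).astype(np.int8)
        G[:, 1] = 1
        cohort = _toy_cohort(G, rng=rng)
        C = np.column_stack([cohort.phenotypes["age"]])
        with pytest.raises(DegenerateDesignError, match="v1"):
            lr.logistic_scan(cohort, C)

    def test_requires_binary_outcome(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 2)).astype(np.int8)
        cohort = _toy_cohort(G, y_binary=np.ones(50, dtype=np.int8), rng=rng)
        with pytest.raises(ValidationError):
            lr.logistic_scan(cohort, np.column_stack([cohort.phenotypes["age"]]))


class TestLinearScan:
    def test_matches_normal_equations_oracle(self, rng):
        n, m = 300, 5
        G = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        ggt = np.exp(rng.normal(3, 0.6, n))
        cohort = _toy_cohort(G, ggt=ggt, rng=rng)
        C = np.column_stack([cohort.phenotypes["age"], cohort.phenotypes["sex"]])
        table = lr.linear_scan(cohort, C)
        y = np.log(ggt)
        for j in range(m):
            X = np.column_stack([np.ones(n), G[:, j], C])
            bhat = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ bhat
            cov = resid @ resid / (n - X.shape[1]) * np.linalg.inv(X.T @ X)
            assert table["beta"].iloc[j] == pytest.approx(bhat[1], abs=1e-8)
            assert table["se"].iloc[j] == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-8)

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        n, m = 1500, 1000
        G = independent_genotypes(n, m, rng)
        ggt = np.exp(rng.normal(3, 0.8, n))
        cohort = _toy_cohort(G, ggt=ggt, rng=rng)
        C = np.column_stack([cohort.phenotypes["age"]])
        table = lr.linear_scan(cohort, C)
        rate = (table["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_nonfinite_trait_rejected(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 2)).astype(np.int8)
        ggt = np.exp(rng.normal(3, 0.5, 50))
        cohort = _toy_cohort(G, ggt=ggt, rng=rng)
        cohort.phenotypes.loc[0, "ggt"] = np.inf
        with pytest.raises(ValidationError):
            lr.linear_scan(cohort, np.column_stack([cohort.phenotypes["age"]]))


class TestBhFdr:
    def test_step_up_worked_example(self):
        q = lr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert lr.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_definition(self, rng):
        p = rng.random(100)
        q = lr.bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            expected[idx] = min(
                p[j] * m / (np.searchsorted(p[order], p[j], side="right"))
                for j in order[rank - 1:]
            )
        expected = np.minimum(expected, 1.0)
        assert np.allclose(q, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            lr.bh_fdr([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
        st.integers(0, 29),
        st.floats(0.0, 0.3),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_p(self, ps, idx, bump):
        ps = np.array(ps)
        idx = idx % len(ps)
        q0 = lr.bh_fdr(ps)
        ps2 = ps.copy()
        ps2[idx] = min(1.0, ps2[idx] + bump)
        q1 = lr.bh_fdr(ps2)
        assert np.all(q1 >= q0 - 1e-12)


class TestGenomicLambda:
    def test_definition_and_scale(self):
        chi = np.full(100, CHI2_1_MEDIAN)
        assert lr.genomic_lambda(chi2=chi) == pytest.approx(1.0)
        assert lr.genomic_lambda(chi2=2 * chi) == pytest.approx(2.0)

    def test_null_chi2_draws(self, rng):
        chi = rng.chisquare(1, 10_000)
        assert lr.genomic_lambda(chi2=chi) == pytest.approx(1.0, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            lr.genomic_lambda(chi2=np.array([]))


class TestLdScores:
    def test_duplicated_pair_scores_two(self, rng):
        g = rng.binomial(2, 0.4, 500).astype(float)
        G = np.column_stack([g, g])
        ell = lr.ld_scores(G, window=5)
        assert np.allclose(ell, 2.0)

    def test_independence_limit(self):
        rng = np.random.default_rng(21)
        G = independent_genotypes(5000, 150, rng)
        ell = lr.ld_scores(G, window=50)
        assert abs(ell.mean() - 1.0) < 0.05

    def test_matches_quadratic_oracle(self, rng):
        n, m, w = 200, 12, 3
        G = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
        ell = lr.ld_scores(G, window=w)
        Z = (G - G.mean(0)) / G.std(0)
        R2 = (Z.T @ Z / n) ** 2
        R2a = R2 - (1 - R2) / (n - 2)
        expected = np.ones(m)
        for j in range(m):
            for k in range(m):
                if k != j and abs(k - j) <= w:
                    expected[j] += R2a[j, k]
        assert np.allclose(ell, expected, atol=1e-12)

    def test_monomorphic_rejected(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 3)).astype(float)
        G[:, 0] = 0
        with pytest.raises(DegenerateDesignError):
            lr.ld_scores(G)


class TestLdscIntercept:
    def test_planted_linear_model(self, rng):
        ell = rng.uniform(1, 8, 4000)
        chi2 = 1.0 + 2.0 * ell + rng.normal(0, 0.5, 4000)
        icpt, slope, _, _ = lr.ldsc_intercept(chi2, ell)
        assert icpt == pytest.approx(1.0, abs=0.05)
        assert slope == pytest.approx(2.0, abs=0.02)

    def test_matches_closed_form_simple_regression(self, rng):
        ell = rng.uniform(1, 5, 50)
        chi2 = rng.chisquare(1, 50)
        icpt, slope, icpt_se, slope_se = lr.ldsc_intercept(chi2, ell)
        res = stats.linregress(ell, chi2)
        assert icpt == pytest.approx(res.intercept, abs=1e-10)
        assert slope == pytest.approx(res.slope, abs=1e-10)
        assert slope_se == pytest.approx(res.stderr, abs=1e-10)
        assert icpt_se == pytest.approx(res.intercept_stderr, abs=1e-10)

    def test_constant_scores_rejected(self):
        with pytest.raises(CollinearityError):
            lr.ldsc_intercept(np.ones(20), np.ones(20))


class TestQqPoints:
    def test_single_half_p(self):
        e, o = lr.qq_points([0.5])
        assert e[0] == pytest.approx(0.30103, abs=1e-5)
        assert o[0] == pytest.approx(0.30103, abs=1e-5)

    def test_uniform_p_on_diagonal(self, rng):
        e, o = lr.qq_points(rng.random(5000))
        assert np.all(np.diff(e) > 0)
        assert abs((o - e).mean()) < 0.05

    def test_zero_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            e, o = lr.qq_points([0.0, 0.5])
        assert np.isfinite(o).all()


def test_scan_estimates_agree_with_maximization_oracles(rng):
    """Logistic and linear per-variant estimates equal the exact-likelihood
    optimum (statsmodels Newton) and normal equations on random small designs."""
    for rep in range(10):
        n = 200
        G = rng.binomial(2, rng.uniform(0.2, 0.5, 3), size=(n, 3)).astype(np.int8)
        eta = -1.0 + 0.5 * G[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        ggt = np.exp(rng.normal(3, 0.5, n) + 0.1 * G[:, 1])
        cohort = _toy_cohort(G, y_binary=y, ggt=ggt, rng=rng)
        C = np.column_stack([cohort.phenotypes["age"], cohort.phenotypes["sex"]])
        log_table = lr.logistic_scan(cohort, C)
        lin_table = lr.linear_scan(cohort, C)
        for j in range(3):
            X = np.column_stack([np.ones(n), G[:, j], C])
            ref = sm.Logit(y, X).fit(disp=0, method="newton")
            assert log_table["beta"].iloc[j] == pytest.approx(ref.params[1], abs=1e-6)
            lin = sm.OLS(np.log(ggt), X).fit()
            assert lin_table["beta"].iloc[j] == pytest.approx(lin.params[1], abs=1e-8)


def test_lr_pvalues_match_statsmodels_likelihood_ratio(rng):
    """Optional likelihood-ratio p-values agree with an explicit LR test
    built from statsmodels log-likelihoods."""
    n = 400
    G = rng.binomial(2, rng.uniform(0.2, 0.5, 3), size=(n, 3)).astype(np.int8)
    eta = -1.0 + 0.6 * G[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
    cohort = _toy_cohort(G, y_binary=y, rng=rng)
    C = np.column_stack([cohort.phenotypes["age"], cohort.phenotypes["sex"]])
    table = lr.logistic_scan(cohort, C, p_method="lr")
    null_X = np.column_stack([np.ones(n), C])
    ll0 = sm.Logit(y, null_X).fit(disp=0).llf
    for j in range(3):
        X = np.column_stack([np.ones(n), G[:, j], C])
        ll1 = sm.Logit(y, X).fit(disp=0).llf
        p_ref = stats.chi2.sf(2 * (ll1 - ll0), df=1)
        assert table["p"].iloc[j] == pytest.approx(p_ref, rel=1e-6)
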