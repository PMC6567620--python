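"""Spearman-t, residualization, LASSO soft-threshold/KKT oracles, stratified correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import hadamard

import bloomline as bl
from bloomline.association import fit_lasso, lasso_for_metabolite
from bloomline.simulate import generate_design


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = bl.spearman_with_t(x, np.exp(x))
        assert rho == 1.0 and p == 0.0

    def test_perfect_reverse(self):
        x = np.arange(8.0)
        rho, _ = bl.spearman_with_t(x, -(x**3))
        assert rho == -1.0

    def test_matches_scipy_rho(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = bl.spearman_with_t(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = [bl.spearman_with_t(rng.normal(size=10), rng.normal(size=10))[1] for _ in range(300)]
        assert 0.45 < np.mean(ps) < 0.55
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.10

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = bl.spearman_with_t(np.ones(5), np.arange(5.0))
        assert np.isnan(rho)


class TestResidualize:
    @pytest.fixture(scope="class")
    def meta(self):
        return generate_design(4, seed=1)

    def test_design_column_residuals_zero(self, meta):
        y = (meta.treatment.astype(str) == "ACA").to_numpy(float)
        np.testing.assert_allclose(bl.residualize(y, meta), 0.0, atol=1e-10)

    def test_orthogonal_response_unchanged(self, meta):
        rng = np.random.default_rng(2)
        y = rng.normal(size=len(meta))
        r = bl.residualize(y, meta)
        rr = bl.residualize(r, meta)
        np.testing.assert_allclose(rr, r, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, meta):
        rng = np.random.default_rng(3)
        r = bl.residualize(rng.normal(size=len(meta)), meta)
        assert abs(r.mean()) < 1e-10
        for col in ("treatment", "sex", "site"):
            for level in meta[col].unique():
                ind = (meta[col] == level).to_numpy(float)
                assert abs(r @ ind) < 1e-8


class TestLasso:
    def test_soft_threshold_oracle_orthonormal_design(self):
        # columns of a Hadamard matrix are mean-zero, unit-SD, mutually orthogonal:
        # the LASSO solution is the soft-threshold of the per-column OLS coefficients
        H = hadamard(8).astype(float)
        X = H[:, 1:5]
        rng = np.random.default_rng(4)
        y = X @ np.array([2.0, -1.0, 0.3, 0.0]) + rng.normal(0, 0.1, 8)
        b_ols = X.T @ y / 8
        for alpha in (0.05, 0.5, 1.5):
            beta = fit_lasso(X, y, alpha)
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - alpha, 0.0)
            np.testing.assert_allclose(beta, expected, atol=1e-6)

    def test_huge_penalty_all_zero(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        y = rng.normal(size=30)
        res = bl.lasso_cv(X, y, n_folds=5, seed=0, n_alphas=10)
        beta = fit_lasso((X - X.mean()) / X.std(ddof=0), y, alpha=1e6)
        np.testing.assert_allclose(beta, 0.0)
        assert res.alphas[0] >= res.alpha  # grid starts at lambda_max

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(6)
        n, p = 60, 12
        X = rng.normal(size=(n, p))
        Xs = (X - X.mean(0)) / X.std(0)
        y = Xs[:, 0] * 1.5 - Xs[:, 3] + rng.normal(0, 0.5, n)
        alpha = 0.1
        beta = fit_lasso(Xs, y, alpha)
        resid = y - y.mean() - Xs @ beta + (Xs @ beta).mean()
        grad = Xs.T @ resid / n
        active = beta != 0
        np.testing.assert_allclose(np.abs(grad[active]), alpha, atol=1e-4)
        assert (np.abs(grad[~active]) <= alpha + 1e-4).all()

    def test_seeded_folds_reproduce(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(40, 8)))
        y = X[0] - X[3] + rng.normal(0, 0.3, 40)
        r1 = bl.lasso_cv(X, y, seed=3, n_alphas=20)
        r2 = bl.lasso_cv(X, y, seed=3, n_alphas=20)
        assert r1.alpha == r2.alpha
        pd.testing.assert_series_equal(r1.coefficients, r2.coefficients)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        X["c"] = 1.0
        y = X["a"].to_numpy() + rng.normal(0, 0.2, 30)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = bl.lasso_cv(X, y, n_folds=5, seed=0, n_alphas=15)
        assert "c" not in res.coefficients.index

    def test_validation_gate_type_I_error(self):
        # y independent of X: the holdout Spearman gate validates at <= ~5%
        rng = np.random.default_rng(9)
        n, p = 40, 15
        validated = 0
        reps = 200
        for r in range(reps):
            X = pd.DataFrame(rng.normal(size=(n, p)))
            y = rng.normal(size=n)
            res = bl.lasso_cv(X, y, n_folds=5, seed=r, n_alphas=12)
            validated += res.validated
        rate = validated / reps
        assert rate <= 0.10  # 5% nominal + binomial tolerance at 200 replicates


class TestPipelineRecovery:
    def test_planted_propionate_support_recovered(self, planted_cohort, planted_spike_equiv):
        c = planted_cohort
        res = lasso_for_metabolite(
            planted_spike_equiv.values, c.counts, c.metabolites, c.metadata, "propionate", seed=0
        )
        support = set(res.coefficients[res.coefficients != 0].index)
        assert {"OTU-1", "OTU-4", "OTU-5"} <= support
        assert res.oob_r2 > 0

    def test_family_correlations_recover_planted_couplings(
        self, planted_cohort, planted_spike_equiv
    ):
        c = planted_cohort
        fam = bl.aggregate_family(planted_spike_equiv, c.taxonomy)
        tbl = bl.family_metabolite_correlations(
            fam.values, c.metabolites, c.metadata, metabolites=["propionate", "lactate"]
        )
        for stratum in ("control", "ACA"):
            row = tbl[(tbl.family == "Muribaculaceae") & (tbl.metabolite == "propionate")
                      & (tbl.stratum == stratum)].iloc[0]
            assert row.rho > 0.2 and row.p < 0.05
            lac = tbl[(tbl.family == "Lactobacillaceae") & (tbl.metabolite == "lactate")
                      & (tbl.stratum == stratum)].iloc[0]
            assert lac.rho > 0.3

    def test_site_confounded_correlation_vanishes_within_strata(self):
        # a correlation induced purely by site offsets disappears stratified by site
        rng = np.random.default_rng(10)
        site = np.repeat(["A", "B", "C"], 30)
        offsets = {"A": 0.0, "B": 2.0, "C": 4.0}
        fam_ab = np.array([offsets[s] for s in site]) + rng.normal(0, 0.3, 90)
        met = np.array([offsets[s] for s in site]) + rng.normal(0, 0.3, 90)
        idx = [f"s{i}" for i in range(90)]
        fam = pd.DataFrame({"F": fam_ab}, index=idx)
        panel = pd.DataFrame({"m": met}, index=idx)
        meta = pd.DataFrame({"site": site}, index=idx)
        pooled, _ = bl.spearman_with_t(fam_ab, met)
        assert pooled > 0.8
        tbl = bl.family_metabolite_correlations(fam, panel, meta, strata_cols=("site",))
        assert (tbl.rho.abs() < 0.3).all()
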