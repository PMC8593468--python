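"""LASSO selection and relaxed refit: design bookkeeping, closed-form
and sklearn cross-checks, KKT conditions, and the mixed-model t-test."""

import numpy as np
import pandas as pd
import pytest

from cnvherit.assoc import (
    AssocResult,
    DesignMatrix,
    _cd_solve,
    build_design,
    fit_lasso,
    kkt_violation,
    lambda_max,
    relaxed_refit,
    single_marker_mlm,
    variance_explained,
)
from cnvherit.cnv import CnvLocus
from cnvherit.qc import SnpPanel


def _design(x, y, penalty=None):
    x = np.asarray(x, float)
    p = x.shape[1]
    penalty = np.ones(p) if penalty is None else np.asarray(penalty, float)
    return DesignMatrix(
        x=x, y=np.asarray(y, float),
        col_names=[f"m{j}" for j in range(p)],
        col_types=["snp" if penalty[j] else "pc" for j in range(p)],
        penalty_mask=penalty,
        col_scale=np.ones(p), col_center=np.zeros(p),
        marker_freq={f"m{j}": 0.3 for j in range(p)},
    )


def _standardize(x):
    return (x - x.mean(axis=0)) / x.std(axis=0)


class TestBuildDesign:
    def _inputs(self, weights):
        snp_map = pd.DataFrame(
            {"snp_id": ["s0", "s1", "s2"], "chrom": 1, "pos_bp": [100, 200, 300],
             "index": range(3)}
        )
        geno = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 1]], float)
        panel = SnpPanel(np.array([f"a{i}" for i in range(4)], object), geno, snp_map)
        loci = [CnvLocus("c0", 1, 0, 2, 100, 300, classes={"a0": 1, "a2": 1})]
        traits = pd.DataFrame(
            {"animal_id": panel.animal_ids, "debv": [1.0, -0.5, 0.2, 0.4],
             "weight": weights}
        )
        return panel, loci, traits

    def test_unit_weights_leave_debv_untouched(self):
        panel, loci, traits = self._inputs([1.0] * 4)
        d = build_design(panel, loci, None, None, traits, k_pcs=0)
        np.testing.assert_allclose(d.y, traits["debv"])

    def test_column_count_and_mask(self):
        panel, loci, traits = self._inputs([1.0, 2.0, 0.5, 1.0])
        pcs = np.random.default_rng(0).standard_normal((4, 3))
        d = build_design(panel, loci, pcs, pcs, traits, k_pcs=2)
        # intercept + 2 PC blocks of 2 + 3 SNPs + 1 CNV column
        assert d.x.shape[1] == 1 + 4 + 3 + 1
        assert d.penalty_mask.sum() == 4
        assert d.penalty_mask[d.col_types.index("intercept")] == 0

    def test_marker_columns_standardized(self):
        panel, loci, traits = self._inputs([1.0, 2.0, 0.5, 1.0])
        d = build_design(panel, loci, None, None, traits, k_pcs=0)
        marker = d.penalty_mask == 1
        np.testing.assert_allclose(d.x[:, marker].mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(d.x[:, marker].std(axis=0), 1, atol=1e-12)


class TestLasso:
    def test_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(0)
        x = _standardize(rng.standard_normal((80, 12)))
        y = rng.standard_normal(80)
        d = _design(x, y)
        lmax = lambda_max(d)
        fit = fit_lasso(d, lambda_grid=np.array([lmax * 1.0001]), cv_folds=4)
        assert fit.selected == []
        assert np.all(fit.beta == 0.0)

    def test_single_predictor_soft_threshold(self):
        rng = np.random.default_rng(1)
        n = 150
        x = _standardize(rng.standard_normal((n, 1)))
        y = 0.7 * x[:, 0] + rng.standard_normal(n)
        b = float(x[:, 0] @ y / n)
        for lam in (0.05, 0.2, abs(b) + 0.1):
            beta = _cd_solve(x, y, np.array([1.0]), lam)
            expected = np.sign(b) * max(abs(b) - lam, 0.0)
            assert beta[0] == pytest.approx(expected, abs=1e-8)

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(2)
        x = _standardize(rng.standard_normal((100, 30)))
        y = x[:, :3] @ [1.0, -0.5, 0.8] + rng.standard_normal(100)
        d = _design(x, y)
        fit = fit_lasso(d, cv_folds=5, seed=0)
        assert kkt_violation(d.x, d.y, fit.beta, d.penalty_mask, fit.lam) <= 1e-6

    def test_matches_sklearn_on_fully_penalized_design(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(3)
        n, p = 120, 15
        x = _standardize(rng.standard_normal((n, p)))
        y = x[:, :2] @ [1.0, -1.0] + rng.standard_normal(n)
        lam = 0.1
        mine = _cd_solve(x, y, np.ones(p), lam, tol=1e-12)
        ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12).fit(x, y).coef_
        np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_unpenalized_columns_stay_unshrunk(self):
        rng = np.random.default_rng(4)
        n = 100
        cov = rng.standard_normal(n)
        y = 2.0 * cov + rng.standard_normal(n)
        x = np.column_stack([cov, _standardize(rng.standard_normal((n, 5)))])
        penalty = np.array([0.0, 1, 1, 1, 1, 1])
        beta = _cd_solve(x, y, penalty, lam=10.0)
        # markers all zeroed at huge lambda, covariate keeps its OLS value
        assert np.all(beta[1:] == 0)
        assert beta[0] == pytest.approx(float(cov @ y / (cov @ cov)), rel=1e-6)

    def test_more_folds_than_animals(self):
        d = _design(np.ones((3, 2)), np.ones(3))
        with pytest.raises(ValueError):
            fit_lasso(d, cv_folds=10)


class TestRelaxedRefit:
    def test_orthonormal_design_debias_exceeds_shrunk(self):
        rng = np.random.default_rng(5)
        n, p = 64, 8
        q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        x = q * np.sqrt(n)  # columns orthonormal under the 1/n inner product
        beta_true = np.array([1.0, -0.8, 0.6, 0, 0, 0, 0, 0])
        y = x @ beta_true + 0.1 * rng.standard_normal(n)
        d = _design(x, y)
        fit = fit_lasso(d, lambda_grid=np.array([0.3]), cv_folds=4)
        res = relaxed_refit(d, fit)
        ols = x.T @ y / n
        for r in res:
            j = int(r.variant_id[1:])
            assert r.effect == pytest.approx(float(ols[j]), abs=1e-6)
            assert abs(r.effect) >= abs(fit.beta[j]) - 1e-10

    def test_empty_selection_empty_results(self):
        d = _design(np.random.default_rng(6).standard_normal((30, 3)),
                    np.zeros(30))
        fit = fit_lasso(d, lambda_grid=np.array([10.0]), cv_folds=3)
        assert relaxed_refit(d, fit) == []

    def test_aliased_columns_dropped(self):
        rng = np.random.default_rng(7)
        n = 60
        base = rng.standard_normal(n)
        x = _standardize(np.column_stack([base, base, rng.standard_normal(n)]))
        y = base + 0.1 * rng.standard_normal(n)
        d = _design(x, y)
        fit = fit_lasso(d, lambda_grid=np.array([0.01]), cv_folds=3)
        res = relaxed_refit(d, fit)
        assert len(res) <= 2  # one of the duplicated columns was aliased out


class TestVarianceExplained:
    def test_substitution_values(self):
        r = AssocResult("v", "cnv", effect=1.0, se=0.1, freq=0.5, lasso_beta=0.5)
        assert variance_explained(r, 1.0) == pytest.approx(0.5)
        r = AssocResult("v", "cnv", effect=2.0, se=0.1, freq=0.1, lasso_beta=0.5)
        assert variance_explained(r, 4.0) == pytest.approx(0.18)
        r = AssocResult("v", "cnv", effect=0.0, se=0.1, freq=0.2, lasso_beta=0.0)
        assert variance_explained(r, 1.0) == 0.0

    def test_domain_errors(self):
        r = AssocResult("v", "cnv", effect=1.0, se=0.1, freq=0.5, lasso_beta=0.5)
        with pytest.raises(ValueError):
            variance_explained(r, 0.0)
        r.freq = 0.0
        with pytest.raises(ValueError):
            variance_explained(r, 1.0)


class TestSingleMarkerMlm:
    def test_identity_limit_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 80
        marker = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * marker + rng.standard_normal(n)
        eff, t, p = single_marker_mlm(
            marker, np.eye(n), y, np.ones(n), sigma_g2=1.0, sigma_e2=1.0
        )
        ols = sm.OLS(y, sm.add_constant(marker)).fit()
        assert t == pytest.approx(ols.tvalues[1], abs=1e-6)
        assert p == pytest.approx(ols.pvalues[1], abs=1e-8)

    def test_null_pvalues_approximately_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(9)
        n, m = 150, 500
        from conftest import make_grm_from_snps

        g = make_grm_from_snps(n, 400, rng)
        from cnvherit.varcomp import draw_polygenic

        y = draw_polygenic(g, 0.3, rng) + rng.standard_normal(n) * np.sqrt(0.7)
        pvals = []
        markers = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        for j in range(m):
            if markers[:, j].std() == 0:
                continue
            _, _, p = single_marker_mlm(markers[:, j], g, y, np.ones(n), 0.3, 0.7)
            pvals.append(p)
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.1

    def test_zero_variance_marker_rejected(self):
        with pytest.raises(ValueError):
            single_marker_mlm(np.ones(50), np.eye(50), np.ones(50), np.ones(50), 1, 1)
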