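import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag
from scipy.stats import multivariate_normal

from covselect import (
    CorrelationStructure,
    LongitudinalDataset,
    MarginalModelSpec,
    fit_heteroscedastic_pair,
    fit_marginal_model,
    information_criteria,
    neg_log_likelihood,
)
from covselect.corrstruct import build_correlation_matrix
from covselect.diagnose import design_matrix
from covselect.fitmm import _ModelData, _Reparam, _profiled
from conftest import MEAN_FORMULA, make_dataset


def dense_ml_loglik(dataset, formula, structure, sigma2, weights=None):
    """Oracle: stacked multivariate-normal log density with an explicit dense
    block-diagonal covariance, beta set to its GLS value."""
    X, _ = design_matrix(dataset, formula)
    y = dataset.data[dataset.outcome].to_numpy()
    occ = dataset.occasions
    T = len(occ)
    R = build_correlation_matrix(structure, occ).values
    d = np.ones(T) if weights is None else np.asarray(weights)
    C = sigma2 * (d[:, None] * R * d[None, :])
    n = dataset.n_subjects
    V = block_diag(*([C] * n))
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    return multivariate_normal(mean=X @ beta, cov=V).logpdf(y), beta


def dense_reml_loglik(dataset, formula, structure, sigma2, weights=None):
    """Oracle: restricted likelihood through explicit error contrasts K with
    X'K = 0 — the log density of K'y under N(0, K'VK)."""
    X, _ = design_matrix(dataset, formula)
    y = dataset.data[dataset.outcome].to_numpy()
    occ = dataset.occasions
    R = build_correlation_matrix(structure, occ).values
    T = len(occ)
    d = np.ones(T) if weights is None else np.asarray(weights)
    C = sigma2 * (d[:, None] * R * d[None, :])
    V = block_diag(*([C] * dataset.n_subjects))
    # orthonormal basis of the null space of X'
    q, _ = np.linalg.qr(X, mode="complete")
    K = q[:, X.shape[1]:]
    W = K.T @ V @ K
    return multivariate_normal(mean=np.zeros(K.shape[1]), cov=W).logpdf(K.T @ y)


class TestNegLogLikelihood:
    def test_independent_equals_ols_deviance(self, ar1_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("independent"),
                                 estimation="ML")
        fit = fit_marginal_model(spec, ar1_dataset)
        X, _ = design_matrix(ar1_dataset, MEAN_FORMULA)
        y = ar1_dataset.data["outcome"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        N = len(y)
        s2 = rss / N
        dev = N * math.log(2 * math.pi * s2) + N
        assert -2 * fit.loglik == pytest.approx(dev, abs=1e-8)

    def test_cs_zero_equals_independent(self, ar1_dataset):
        spec_cs = MarginalModelSpec(MEAN_FORMULA,
                                    CorrelationStructure("cs", (0.3,)),
                                    estimation="ML")
        spec_ind = MarginalModelSpec(MEAN_FORMULA,
                                     CorrelationStructure("independent"),
                                     estimation="ML")
        obj_cs = neg_log_likelihood(spec_cs, ar1_dataset, [0.0])
        obj_ind = neg_log_likelihood(spec_ind, ar1_dataset, [])
        assert obj_cs == pytest.approx(obj_ind, abs=1e-10)

    @pytest.mark.parametrize("structure,theta", [
        (CorrelationStructure("ar", (0.4,)), [0.4]),
        (CorrelationStructure("cs", (0.25,)), [0.25]),
        (CorrelationStructure("ar", (0.5, 0.2)), [0.5, 0.2]),
    ])
    def test_ml_matches_dense_mvn_oracle(self, small_dataset, structure, theta):
        spec = MarginalModelSpec(MEAN_FORMULA, structure, estimation="ML")
        obj = neg_log_likelihood(spec, small_dataset, theta)
        md = _ModelData(spec, small_dataset)
        _, _, _, sigma2 = _profiled(spec, md, np.asarray(theta), np.ones(md.T))
        sigma2 *= md.y_scale**2  # _profiled works on the standardized outcome
        oracle, _ = dense_ml_loglik(small_dataset, MEAN_FORMULA, structure, sigma2)
        assert -obj == pytest.approx(oracle, abs=1e-8)

    def test_reml_matches_error_contrast_oracle(self, small_dataset):
        structure = CorrelationStructure("ar", (0.4,))
        spec = MarginalModelSpec(MEAN_FORMULA, structure, estimation="REML")
        obj = neg_log_likelihood(spec, small_dataset, [0.4])
        md = _ModelData(spec, small_dataset)
        _, _, _, sigma2 = _profiled(spec, md, np.array([0.4]), np.ones(md.T))
        sigma2 *= md.y_scale**2
        oracle = dense_reml_loglik(small_dataset, MEAN_FORMULA, structure, sigma2)
        # conventions differ by a data-only constant: the error-contrast
        # density exceeds the profiled form by 0.5*log|X'X| (Harville)
        X, _ = design_matrix(small_dataset, MEAN_FORMULA)
        const = 0.5 * np.linalg.slogdet(X.T @ X)[1]
        assert -obj == pytest.approx(oracle - const, abs=1e-8)

    def test_hetero_matches_dense_oracle(self, small_dataset):
        structure = CorrelationStructure("cs", (0.2,))
        spec = MarginalModelSpec(MEAN_FORMULA, structure,
                                 heteroscedastic=True, estimation="ML")
        weights = [1.0, 1.3, 0.8, 1.1]
        obj = neg_log_likelihood(spec, small_dataset, [0.2] + weights[1:])
        md = _ModelData(spec, small_dataset)
        _, _, _, sigma2 = _profiled(spec, md, np.array([0.2]),
                                    np.asarray(weights))
        sigma2 *= md.y_scale**2
        oracle, _ = dense_ml_loglik(small_dataset, MEAN_FORMULA, structure,
                                    sigma2, weights=weights)
        assert -obj == pytest.approx(oracle, abs=1e-8)

    def test_penalty_on_invalid_theta(self, small_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("cs", (0.3,)),
                                 estimation="ML")
        val = neg_log_likelihood(spec, small_dataset, [-0.9])  # breaks PD at T=4
        assert np.isfinite(val) and val >= 1e9


class TestFitMarginalModel:
    def test_independent_equals_ols(self, ar1_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("independent"),
                                 estimation="ML")
        fit = fit_marginal_model(spec, ar1_dataset)
        X, _ = design_matrix(ar1_dataset, MEAN_FORMULA)
        y = ar1_dataset.data["outcome"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta.to_numpy(), beta, atol=1e-8)
        assert fit.converged

    def test_ar1_parameter_recovery_seeded(self):
        ds = make_dataset(CorrelationStructure("ar", (0.5,)), n_subjects=100,
                          T=6, sigma2=1.0, seed=77)
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        fit = fit_marginal_model(spec, ds)
        assert fit.converged
        assert fit.theta[0] == pytest.approx(0.5, abs=0.1)
        assert fit.sigma2 == pytest.approx(1.0, abs=0.2)

    def test_unstructured_dominates_ar1_loglik(self, ar1_dataset):
        T = 6
        spec_u = MarginalModelSpec(
            MEAN_FORMULA,
            CorrelationStructure("unstructured", (0.0,) * (T * (T - 1) // 2)),
            estimation="ML")
        spec_a = MarginalModelSpec(MEAN_FORMULA,
                                   CorrelationStructure("ar", (0.0,)),
                                   estimation="ML")
        fu = fit_marginal_model(spec_u, ar1_dataset)
        fa = fit_marginal_model(spec_a, ar1_dataset)
        assert fu.loglik >= fa.loglik - 1e-4

    def test_equivariance_outcome_rescaling(self, ar1_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        fit1 = fit_marginal_model(spec, ar1_dataset)
        df = ar1_dataset.data.copy()
        c = 3.7
        df["outcome"] = df["outcome"] * c
        fit2 = fit_marginal_model(spec, LongitudinalDataset(df))
        assert fit2.sigma2 == pytest.approx(c**2 * fit1.sigma2, rel=1e-6)
        assert np.allclose(fit2.theta, fit1.theta, atol=1e-6)

    def test_reml_ml_beta_agree_at_fixed_theta(self, ar1_dataset):
        theta = np.array([0.45])
        betas = []
        for est in ("ML", "REML"):
            spec = MarginalModelSpec(MEAN_FORMULA,
                                     CorrelationStructure("ar", (0.45,)),
                                     estimation=est)
            md = _ModelData(spec, ar1_dataset)
            _, beta, _, _ = _profiled(spec, md, theta, np.ones(md.T))
            betas.append(beta)
        assert np.allclose(betas[0], betas[1], atol=1e-12)

    def test_car1_matches_ar1_on_integer_grid(self, ar1_dataset):
        fit_a = fit_marginal_model(
            MarginalModelSpec(MEAN_FORMULA, CorrelationStructure("ar", (0.0,)),
                              estimation="REML"), ar1_dataset)
        fit_c = fit_marginal_model(
            MarginalModelSpec(MEAN_FORMULA, CorrelationStructure("car1", (0.5,)),
                              estimation="REML"), ar1_dataset)
        assert fit_c.loglik == pytest.approx(fit_a.loglik, abs=1e-4)
        assert fit_c.theta[0] == pytest.approx(fit_a.theta[0], abs=1e-3)

    def test_continuous_structure_on_irregular_unbalanced_data(self):
        ds_full = make_dataset(CorrelationStructure("exponential", (2.0,)),
                               n_subjects=60, times=(0.0, 0.7, 1.1, 2.5, 4.0),
                               seed=55)
        # drop a couple of rows -> unbalanced
        df = ds_full.data.drop(index=[3, 11]).reset_index(drop=True)
        ds = LongitudinalDataset(df)
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("exponential", (1.0,)),
                                 estimation="REML")
        fit = fit_marginal_model(spec, ds)
        assert fit.converged
        assert fit.theta[0] > 0

    def test_discrete_structure_refuses_unbalanced(self, ar1_dataset):
        ds = LongitudinalDataset(ar1_dataset.data.iloc[:-1].copy())
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        with pytest.raises(ValueError, match="unbalanced"):
            fit_marginal_model(spec, ds)

    def test_ar2_refused_at_t2(self):
        ds = make_dataset(CorrelationStructure("cs", (0.3,)), n_subjects=20, T=2)
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0, 0.0)),
                                 estimation="REML")
        with pytest.raises(ValueError, match="identifiable"):
            fit_marginal_model(spec, ds)

    def test_rank_deficient_design_raises(self, ar1_dataset):
        df = ar1_dataset.data.copy()
        df["age2"] = df["age"] * 2
        spec = MarginalModelSpec("age + age2",
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        with pytest.raises(ValueError, match="rank deficient"):
            fit_marginal_model(spec, LongitudinalDataset(df))

    def test_deterministic(self, ar1_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        f1 = fit_marginal_model(spec, ar1_dataset)
        f2 = fit_marginal_model(spec, ar1_dataset)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.theta, f2.theta)


class TestInformationCriteria:
    def test_direct_formula_evaluation(self):
        aic, bic, aicc = (lambda f: (f.aic, f.bic, f.aicc))(
            _FakeFit(loglik=-100.0, n_params=5, n_eff=100))
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200.0 + 5 * math.log(100))
        assert aicc == pytest.approx(210.0 + 2 * 5 * 6 / 94)

    def test_aicc_exceeds_aic(self, ar1_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        fit = fit_marginal_model(spec, ar1_dataset)
        assert fit.aicc > fit.aic

    def test_recompute_matches_fit(self, ar1_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("cs", (0.0,)),
                                 estimation="ML")
        fit = fit_marginal_model(spec, ar1_dataset)
        aic, bic, aicc = information_criteria(fit)
        assert (aic, bic, aicc) == (fit.aic, fit.bic, fit.aicc)
        assert aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert bic == pytest.approx(-2 * fit.loglik
                                    + fit.n_params * math.log(fit.n_eff))

    def test_aicc_undefined_small_n(self):
        from covselect.fitmm import _ic
        aic, bic, aicc = _ic(-10.0, 5, 6)
        assert math.isnan(aicc)

    def test_k_zero_hypothetical(self):
        from covselect.fitmm import _ic
        aic, _, _ = _ic(-50.0, 0, 100)
        assert aic == 100.0


class _FakeFit:
    """Minimal stand-in exposing the IC formula inputs."""

    def __init__(self, loglik, n_params, n_eff):
        from covselect.fitmm import _ic
        self.loglik = loglik
        self.n_params = n_params
        self.n_eff = n_eff
        self.aic, self.bic, self.aicc = _ic(loglik, n_params, n_eff)


class TestHeteroscedasticPair:
    def test_nesting_inequality(self, cs_dataset):
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("cs", (0.0,)),
                                 estimation="ML")
        homo, het = fit_heteroscedastic_pair(spec, cs_dataset)
        assert het.loglik >= homo.loglik - 1e-6
        assert not homo.heteroscedastic and het.heteroscedastic
        assert homo.structure.kind == het.structure.kind

    def test_null_weights_recovered(self):
        ds = make_dataset(CorrelationStructure("ar", (0.4,)), n_subjects=200,
                          T=5, seed=61)
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        _, het = fit_heteroscedastic_pair(spec, ds)
        assert het.converged
        assert np.all(np.abs(het.variance_weights - 1.0) < 0.15)

    def test_ordered_weights_recovered(self):
        ds = make_dataset(CorrelationStructure("ar", (0.4,)), n_subjects=300,
                          T=3, seed=62, variance_weights=(1.0, 2.0, 3.0))
        spec = MarginalModelSpec(MEAN_FORMULA,
                                 CorrelationStructure("ar", (0.0,)),
                                 estimation="REML")
        _, het = fit_heteroscedastic_pair(spec, ds)
        w = het.variance_weights
        assert w[2] > w[1] > w[0]

    def test_hetero_requires_discrete_occasions(self):
        ds_full = make_dataset(CorrelationStructure("exponential", (2.0,)),
                               n_subjects=30, times=(0.0, 1.0, 2.0), seed=5)
        df = ds_full.data.copy()
        # perturb one subject's time so occasions are no longer shared
        df.loc[1, "time"] = 1.21
        ds = LongitudinalDataset(df)
        spec = MarginalModelSpec(
            MEAN_FORMULA, CorrelationStructure("exponential", (1.0,)),
            heteroscedastic=True, estimation="REML")
        fit = fit_marginal_model(spec, ds)  # every distinct time = an occasion
        assert fit.variance_weights.shape[0] == len(ds.occasions)
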