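"""Fitting driver, standard errors, and model-comparison statistics."""

import numpy as np
import pytest

from melsm import (
    FitResult,
    ModelSpec,
    ParameterSet,
    SimDesign,
    WithinVarSpec,
    fit_ml,
    information_criteria,
    lrt,
    simulate_dataset,
    staged_start,
    wald_linear,
)
from melsm.data import BetweenVarSpec, LocationSpec
from melsm.likelihood import LikelihoodEngine
from melsm.parameters import ParameterPacker
from conftest import make_manifest_truth


@pytest.fixture(scope="module")
def hetero_data():
    spec = ModelSpec()
    truth = make_manifest_truth(phi_a=1.0, tau0=-1.5)
    data, _ = simulate_dataset(
        SimDesign(n_subjects=100, n_occasions=6, truth=truth, spec=spec, seed=21)
    )
    return data, truth, spec


class TestStagedStart:
    def test_stage1_closed_form_intercept_only(self, hetero_data):
        data, _, spec = hetero_data
        start = staged_start(data, spec, refine=False)
        y = data.frame["y"]
        assert start.beta[0] == pytest.approx(y.mean(), abs=1e-10)
        assert start.phi_a > 0  # scale SD starts small positive
        assert np.all(start.rho_upsilon_a == 0)

    def test_variance_covariate_coefficients_start_at_zero(self):
        truth = make_manifest_truth()
        spec = ModelSpec()
        data, _ = simulate_dataset(
            SimDesign(n_subjects=30, n_occasions=4, truth=truth, spec=spec, seed=2)
        )
        frame = data.frame.assign(w=np.repeat(np.arange(30) % 2, 4).astype(float))
        from melsm import DiaryDataset

        cov_spec = ModelSpec(
            location=LocationSpec(x_terms=("1",), w_terms=("w",)),
            between_var=BetweenVarSpec(terms=("w",)),
            within_var=WithinVarSpec(w_terms=("w",)),
        )
        start = staged_start(DiaryDataset(frame), cov_spec, refine=False)
        assert start.alpha[0, 1] == 0.0
        assert start.tau[1] == 0.0

    def test_start_never_beats_fit(self, hetero_data):
        data, _, spec = hetero_data
        start = staged_start(data, spec)
        engine = LikelihoodEngine(data, spec)
        fit = fit_ml(data, spec, start=start, compute_se=False)
        assert engine.loglik(start) <= fit.loglik + 1e-8


class TestFitML:
    def test_refit_from_solution_is_fixed_point(self, hetero_data):
        data, _, spec = hetero_data
        fit = fit_ml(data, spec, compute_se=False)
        refit = fit_ml(data, spec, start=fit.estimates, compute_se=False)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-8)

    def test_matches_reference_lmm_in_no_scale_limit(self, lmm_dataset):
        import statsmodels.formula.api as smf

        data, _, spec = lmm_dataset
        fit = fit_ml(data, spec, compute_se=False)
        ref = smf.mixedlm("y ~ 1", data.frame, groups=data.frame["subject"]).fit(
            reml=False, method="lbfgs"
        )
        est = dict(zip(fit.natural_names, fit.natural_estimates))
        assert est["beta[1]"] == pytest.approx(ref.params["Intercept"], abs=1e-4)
        assert np.exp(est["alpha[1]"]) == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
        assert np.exp(est["tau[1]"]) == pytest.approx(ref.scale, abs=1e-4)
        assert fit.loglik >= ref.llf - 1e-6

    def test_nesting_monotonicity(self, hetero_data):
        data, _, spec = hetero_data
        reduced = fit_ml(
            data, ModelSpec(within_var=WithinVarSpec(random_scale=False)),
            compute_se=False,
        )
        full = fit_ml(data, spec, compute_se=False)
        assert full.loglik >= reduced.loglik - 1e-6
        assert full.n_params == reduced.n_params + 2

    def test_standard_errors_shrink_with_sample_size(self):
        spec = ModelSpec()
        truth = make_manifest_truth(phi_a=1.0)
        ses = {}
        for N in (50, 200):
            data, _ = simulate_dataset(
                SimDesign(n_subjects=N, n_occasions=6, truth=truth, spec=spec, seed=31)
            )
            fit = fit_ml(data, spec)
            ses[N] = dict(zip(fit.natural_names, fit.se))
        ratio = ses[50]["beta[1]"] / ses[200]["beta[1]"]
        assert 1.4 < ratio < 2.9  # ~sqrt(4) = 2

    def test_se_of_scale_parameters_reported_on_natural_scale(self, hetero_data):
        data, _, spec = hetero_data
        fit = fit_ml(data, spec)
        se = dict(zip(fit.natural_names, fit.se))
        assert np.isfinite(se["phi_a"]) and se["phi_a"] > 0
        assert np.isfinite(se["rho_ua[1]"])


class TestManifestParameterRecovery:
    """Replicate fits of the heteroscedastic manifest model recover the truth.

    Quadrature is run at 30 points so that numerical-integration error is
    negligible against the Monte-Carlo error of the replicate means.
    """

    def test_recovery_within_monte_carlo_error(self):
        truth = ParameterSet(
            beta=[3.0], alpha=[[-1.2]], tau=[-2.0], phi_a=1.2, rho_upsilon_a=[-0.4]
        )
        spec = ModelSpec()
        from melsm.inference import _natural_vector

        truth_vec = _natural_vector(truth, spec)
        estimates, start = [], None
        for rep in range(50):
            data, _ = simulate_dataset(
                SimDesign(n_subjects=400, n_occasions=8, truth=truth, spec=spec,
                          seed=3000 + rep)
            )
            fit = fit_ml(data, spec, n_quad=30, compute_se=False, start=start)
            start = fit.estimates
            estimates.append(fit.natural_estimates)
        est = np.asarray(estimates)
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        bias = est.mean(axis=0) - truth_vec
        assert np.all(np.abs(bias) < 3 * mc_se), dict(
            zip(fit.natural_names, zip(bias.round(4), (3 * mc_se).round(4)))
        )


class TestParameterCounting:
    """Free-parameter bookkeeping for the model ladder of the diary analyses."""

    def test_manifest_ladder_counts(self):
        # unconditional homoscedastic / heteroscedastic, then the stressor model
        a1 = ModelSpec(within_var=WithinVarSpec(random_scale=False))
        a2 = ModelSpec()
        a3 = ModelSpec(
            location=LocationSpec(x_terms=("1", "dsc"), w_terms=("dsm",)),
            between_var=BetweenVarSpec(terms=("dsm",)),
            within_var=WithinVarSpec(x_terms=("dsc",), w_terms=("dsm",)),
        )
        assert ParameterPacker(a1).n_params == 3
        assert ParameterPacker(a2).n_params == 5
        assert ParameterPacker(a3).n_params == 10

    def test_latent_invariant_model_counts(self, diary_spec):
        # 13 measurement + beta0 + alpha0 + tau0 + phi_a + rho
        assert ParameterPacker(diary_spec).n_params == 18


class TestModelComparison:
    @pytest.mark.parametrize(
        "dev_r, dev_f, df, stat",
        [(6081, 5537, 2, 544), (33678, 33034, 2, 644)],
    )
    def test_published_lrt_statistics(self, dev_r, dev_f, df, stat):
        got, got_df, p = lrt(dev_r, dev_f, df)
        assert got == stat and got_df == df
        assert p < 0.001

    def test_equal_deviances(self):
        stat, df, p = lrt(100.0, 100.0, 0)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            lrt(99.0, 100.0, 1)

    @pytest.mark.parametrize(
        "dev, k, aic", [(6081, 3, 6087), (5537, 5, 5547), (5245, 10, 5265), (42.0, 0, 42.0)]
    )
    def test_aic_identities(self, dev, k, aic):
        got_aic, _ = information_criteria(dev, k, 435)
        assert got_aic == aic

    def test_bic_uses_log_n(self):
        _, bic = information_criteria(100.0, 3, 50)
        assert bic == pytest.approx(100.0 + 3 * np.log(50))


class TestWald:
    def test_null_contrast(self):
        stat, df, p = wald_linear([1, -1], [2.0, 2.0], np.eye(2))
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_scalar_case(self):
        stat, _, _ = wald_linear([1.0], [2.0], [[4.0]])
        assert stat == 1.0

    def test_matches_direct_quadratic_form(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            k = rng.integers(2, 5)
            A = rng.normal(size=(k, k))
            V = A @ A.T + k * np.eye(k)
            theta = rng.normal(size=k)
            c = rng.normal(size=k)
            stat, _, _ = wald_linear(c, theta, V)
            assert stat == pytest.approx((c @ theta) ** 2 / (c @ V @ c))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            wald_linear([1.0, -1.0], [0.0, 1.0], np.zeros((2, 2)))


class TestFitResultInvariants:
    def test_aic_bic_identity_enforced(self, hetero_data):
        data, _, spec = hetero_data
        fit = fit_ml(data, spec, compute_se=False)
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.n_params)
        assert fit.bic == pytest.approx(fit.deviance + fit.n_params * np.log(fit.n_subjects))
        import dataclasses

        with pytest.raises(ValueError, match="AIC"):
            dataclasses.replace(fit, aic=fit.aic + 1.0)
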