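"""Marginal likelihood: quadrature, reduction correctness, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from melsm import (
    DiaryDataset,
    ModelSpec,
    ParameterSet,
    QuadratureRule,
    WithinVarSpec,
    deviance,
    marginal_loglik,
    marginal_loglik_bruteforce,
    marginal_loglik_manifest,
)
from melsm.measurement import MeasurementParams
from melsm.measurement import MeasurementSpec


class TestQuadratureRule:
    @pytest.mark.parametrize("n", [1, 5, 10, 30])
    def test_weights_sum_to_sqrt_pi_and_nodes_symmetric(self, n):
        rule = QuadratureRule.gauss_hermite(n)
        assert rule.weights.sum() == pytest.approx(np.sqrt(np.pi))
        np.testing.assert_allclose(np.sort(rule.nodes), -np.sort(-rule.nodes)[::-1])

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            QuadratureRule.gauss_hermite(0)


class TestClosedFormLimits:
    def test_single_standard_normal_observation(self):
        data = DiaryDataset(pd.DataFrame({"subject": [1], "occasion": [1], "y": [0.0]}))
        spec = ModelSpec(within_var=WithinVarSpec(random_scale=False))
        params = ParameterSet(beta=[0.0], alpha=[[-30.0]], tau=[0.0])
        ll = marginal_loglik_manifest(params, data, spec)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_no_scale_effect_equals_multivariate_normal(self, lmm_dataset):
        """With phi_a^2 = 0 the marginal is exactly Gaussian: Sigma_i =
        Gamma Phi_u Gamma' + exp(tau0) I, computed here independently."""
        data, truth, spec = lmm_dataset
        ll = marginal_loglik_manifest(truth, data, spec)
        expected = 0.0
        phi2, sig2 = np.exp(truth.alpha[0, 0]), np.exp(truth.tau[0])
        for _, grp in data.subject_frames():
            y = grp["y"].to_numpy()
            n = len(y)
            cov = phi2 * np.ones((n, n)) + sig2 * np.eye(n)
            expected += stats.multivariate_normal.logpdf(
                y, mean=np.full(n, truth.beta[0]), cov=cov
            )
        assert ll == pytest.approx(expected, abs=1e-8)


class TestReductionAgainstBruteForce:
    """The 1-D reduced integral must match the unreduced (upsilon, a) integral."""

    def test_manifest_toy(self, manifest_toy):
        data, truth, spec = manifest_toy
        reduced = marginal_loglik(truth, data, spec, QuadratureRule.gauss_hermite(40))
        brute = marginal_loglik_bruteforce(truth, data, spec, n_points=300)
        assert abs(reduced - brute) < 1e-8

    def test_latent_toy(self, latent_toy):
        data, truth, spec = latent_toy
        reduced = marginal_loglik(truth, data, spec, QuadratureRule.gauss_hermite(40))
        brute = marginal_loglik_bruteforce(truth, data, spec, n_points=300)
        assert abs(reduced - brute) < 1e-8


class TestManifestEmbedding:
    def test_identity_measurement_collapses_to_manifest(self, manifest_toy):
        data, truth, spec = manifest_toy
        T = 3
        mspec = MeasurementSpec.configural(1, T)
        latent_spec = ModelSpec(measurement=mspec)
        frame = data.frame.rename(columns={"y": "item1"})
        latent_data = DiaryDataset(frame, outcome_col=None, item_cols=("item1",))
        meas = MeasurementParams(
            tau=np.zeros((1, T)), lam=np.ones((1, T)), psi=np.zeros((1, T))
        )
        lt = truth.replace(measurement=meas)
        rule = QuadratureRule.gauss_hermite(15)
        ll_manifest = marginal_loglik_manifest(truth, data, spec, rule)
        ll_latent = marginal_loglik(lt, latent_data, latent_spec, rule)
        assert ll_latent == pytest.approx(ll_manifest, abs=1e-10)

    def test_manifest_wrapper_rejects_latent_spec(self, latent_toy):
        data, truth, spec = latent_toy
        with pytest.raises(ValueError, match="measurement"):
            marginal_loglik_manifest(truth, data, spec)


class TestConditionalMoments:
    def test_compound_symmetry_with_independent_scale(self, latent_toy):
        """With rho = 0 and a = 0 the latent block is exchangeable:
        Sigma_{y.a} = Lam (1 phi_u^2 1' + exp(tau0) I) Lam' + diag(psi)."""
        from melsm.likelihood import conditional_moments_latent

        data, truth, spec = latent_toy
        params = truth.replace(rho_upsilon_a=np.zeros(1))
        sid = data.subjects[0]
        cm = conditional_moments_latent(params, data, spec, sid, a=0.0)
        mp = params.measurement
        lam = mp.lam[:, 0]
        phi_u2 = np.exp(params.alpha[0, 0])
        sig2 = np.exp(params.tau[0])
        T = 2
        Lam = np.kron(np.eye(T), lam[:, None])
        expected = Lam @ (phi_u2 * np.ones((T, T)) + sig2 * np.eye(T)) @ Lam.T
        expected += np.diag(np.tile(mp.psi[:, 0], T))
        np.testing.assert_allclose(cm.sigma_y_a, expected, atol=1e-12)
        np.testing.assert_allclose(
            cm.mu_y_a, np.tile(mp.tau[:, 0] + lam * truth.beta[0], T), atol=1e-12
        )

    def test_matches_simulated_conditional_covariance(self, latent_toy):
        """Sigma_{y.a} equals the empirical covariance of y | a draws."""
        from melsm.likelihood import conditional_moments_latent

        data, truth, spec = latent_toy
        a = 0.5
        sid = data.subjects[0]
        cm = conditional_moments_latent(truth, data, spec, sid, a)
        rng = np.random.default_rng(23)
        n = 10**6
        mp = truth.measurement
        su = np.exp(0.5 * truth.alpha[0, 0])
        # draw upsilon | a, then the latent scores, then the items
        mean_u = truth.rho_upsilon_a[0] * su / truth.phi_a * a
        var_u = su**2 * (1 - truth.rho_upsilon_a[0] ** 2)
        ups = rng.normal(mean_u, np.sqrt(var_u), size=n)
        sig = np.sqrt(np.exp(truth.tau[0] + a))
        lam, nu, psi = mp.lam[:, 0], mp.tau[:, 0], mp.psi[:, 0]
        Y = np.empty((n, 4))
        for t in range(2):
            eta = truth.beta[0] + ups + rng.normal(0, sig, size=n)
            Y[:, 2 * t : 2 * t + 2] = (
                nu + lam * eta[:, None]
                + rng.normal(0, np.sqrt(psi), size=(n, 2))
            )
        emp_mean = Y.mean(axis=0)
        emp_cov = np.cov(Y.T)
        np.testing.assert_allclose(cm.mu_y_a, emp_mean, atol=5e-3)
        np.testing.assert_allclose(cm.sigma_y_a, emp_cov, atol=5e-3)

    def test_unknown_subject_rejected(self, latent_toy):
        from melsm.likelihood import conditional_moments_latent

        data, truth, spec = latent_toy
        with pytest.raises(KeyError):
            conditional_moments_latent(truth, data, spec, "no-such-subject", 0.0)


class TestInvariances:
    def test_subject_and_occasion_order_invariance(self, manifest_toy):
        data, truth, spec = manifest_toy
        ll = marginal_loglik(truth, data, spec)
        shuffled = data.frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        ll_shuffled = marginal_loglik(truth, DiaryDataset(shuffled), spec)
        assert ll_shuffled == pytest.approx(ll, abs=1e-10)

    def test_subject_additivity(self, manifest_toy):
        data, truth, spec = manifest_toy
        full = marginal_loglik(truth, data, spec)
        first = data.frame["subject"].iloc[0]
        rest = DiaryDataset(data.frame[data.frame["subject"] != first])
        only = DiaryDataset(data.frame[data.frame["subject"] == first])
        assert full == pytest.approx(
            marginal_loglik(truth, rest, spec) + marginal_loglik(truth, only, spec),
            abs=1e-10,
        )

    def test_quadrature_refinement_stabilizes(self, latent_toy):
        data, truth, spec = latent_toy
        lls = {
            K: marginal_loglik(truth, data, spec, QuadratureRule.gauss_hermite(K))
            for K in (5, 10, 20, 40)
        }
        gaps = [abs(lls[10] - lls[5]), abs(lls[20] - lls[10]), abs(lls[40] - lls[20])]
        assert gaps[0] >= gaps[1] >= gaps[2]

    def test_ten_vs_thirty_points_stable(self, latent_toy):
        data, truth, spec = latent_toy
        l10 = marginal_loglik(truth, data, spec, QuadratureRule.gauss_hermite(10))
        l30 = marginal_loglik(truth, data, spec, QuadratureRule.gauss_hermite(30))
        assert abs(l10 - l30) < 1e-6

    def test_extreme_parameters_stay_finite(self, manifest_toy):
        data, truth, spec = manifest_toy
        far = truth.replace(beta=np.array([50.0]))
        assert np.isfinite(marginal_loglik(far, data, spec))


class TestMissingData:
    def test_missing_occasions_drop_from_manifest_likelihood(self, manifest_toy):
        data, truth, spec = manifest_toy
        frame = data.frame.copy()
        frame.loc[0, "y"] = np.nan
        ll_masked = marginal_loglik(truth, DiaryDataset(frame), spec)
        dropped = DiaryDataset(frame.dropna(subset=["y"]))
        assert ll_masked == pytest.approx(marginal_loglik(truth, dropped, spec), abs=1e-10)

    def test_missing_item_cell_drops_row(self, latent_toy):
        data, truth, spec = latent_toy
        frame = data.frame.copy()
        frame.loc[0, "item2"] = np.nan
        ll = marginal_loglik(truth, DiaryDataset(frame, outcome_col=None,
                                                 item_cols=data.item_cols), spec)
        assert np.isfinite(ll)
        assert ll != pytest.approx(marginal_loglik(truth, data, spec))


class TestDeviance:
    def test_examples(self):
        assert deviance(-2768.5) == 5537.0
        assert deviance(0.0) == 0.0

    def test_additive_over_subjects(self, manifest_toy):
        data, truth, spec = manifest_toy
        from melsm.likelihood import LikelihoodEngine

        per = LikelihoodEngine(data, spec).subject_logliks(truth)
        assert deviance(per.sum()) == pytest.approx(sum(deviance(x) for x in per))
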