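"""Shared fixtures: toy datasets and truth parameterizations.

Toy instances for likelihood-correctness checks use moderate variance
magnitudes (scale-effect SD 0.6) where nonadaptive quadrature is highly
accurate; the parameter-recovery study uses the large-study truth with the
magnitudes reported for daily positive-affect diary data.
"""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from melsm import (
    MeasurementSpec,
    ModelSpec,
    ParameterSet,
    SimDesign,
    WithinVarSpec,
    simulate_dataset,
)
from melsm.measurement import MeasurementParams


def make_manifest_truth(phi_a=0.6, rho=-0.4, alpha0=-1.2, tau0=-1.0, beta0=3.0):
    return ParameterSet(
        beta=[beta0], alpha=[[alpha0]], tau=[tau0],
        phi_a=phi_a, rho_upsilon_a=[rho],
    )


def make_latent_truth(
    M, T, *, phi_a=0.6, rho=-0.4, alpha0=-1.2, tau0=-1.0, beta0=3.0,
    lam=None, nu=None, psi=None,
):
    lam = np.linspace(1.0, 1.3, M) if lam is None else np.asarray(lam, float)
    nu = np.linspace(0.0, -0.5, M) if nu is None else np.asarray(nu, float)
    psi = np.full(M, 0.25) if psi is None else np.asarray(psi, float)
    lam[0], nu[0] = 1.0, 0.0
    meas = MeasurementParams(
        tau=np.tile(nu[:, None], (1, T)),
        lam=np.tile(lam[:, None], (1, T)),
        psi=np.tile(psi[:, None], (1, T)),
    )
    return ParameterSet(
        beta=[beta0], alpha=[[alpha0]], tau=[tau0],
        phi_a=phi_a, rho_upsilon_a=[rho], measurement=meas,
    )


@pytest.fixture(scope="session")
def manifest_spec():
    return ModelSpec()


@pytest.fixture(scope="session")
def manifest_toy(manifest_spec):
    """5 subjects x 3 days, manifest outcome, moderate-variance truth."""
    truth = make_manifest_truth()
    data, _ = simulate_dataset(
        SimDesign(n_subjects=5, n_occasions=3, truth=truth, spec=manifest_spec, seed=101)
    )
    return data, truth, manifest_spec


@pytest.fixture(scope="session")
def latent_toy():
    """3 subjects x 2 days x 2 items, moderate-variance truth."""
    mspec = MeasurementSpec.invariant(2, 2, equal_uniquenesses=True)
    spec = ModelSpec(measurement=mspec)
    truth = make_latent_truth(2, 2)
    data, _ = simulate_dataset(
        SimDesign(n_subjects=3, n_occasions=2, n_items=2, truth=truth, spec=spec, seed=202)
    )
    return data, truth, spec


@pytest.fixture(scope="session")
def diary_truth():
    """Truth at the magnitudes of the published latent diary-study fit:
    trait variance exp(-1.21)=0.30, state intercept -2.69, scale SD 1.40,
    location-scale correlation -0.43, loadings (1, 1.15, 1.13, 1.15, 1.32)."""
    return make_latent_truth(
        5, 8,
        phi_a=1.40, rho=-0.43, alpha0=-1.21, tau0=-2.69, beta0=2.99,
        lam=[1.0, 1.15, 1.13, 1.15, 1.32],
        nu=[0.0, -0.58, -0.61, -0.55, -1.4],
        psi=[0.20, 0.22, 0.35, 0.21, 0.52],
    )


@pytest.fixture(scope="session")
def diary_spec():
    return ModelSpec(measurement=MeasurementSpec.invariant(5, 8, equal_uniquenesses=True))


@pytest.fixture(scope="session")
def lmm_dataset():
    """Random-intercept data (no scale effect) for reference-fitter checks."""
    spec = ModelSpec(within_var=WithinVarSpec(random_scale=False))
    truth = ParameterSet(
        beta=[3.0], alpha=[[-1.2]], tau=[-2.0], phi_a=0.0, rho_upsilon_a=[0.0]
    )
    data, _ = simulate_dataset(
        SimDesign(n_subjects=150, n_occasions=6, truth=truth, spec=spec, seed=303)
    )
    return data, truth, spec
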