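"""Synthetic daily-diary data from a specified model parameterization.

The generator emulates an intensive longitudinal design of the kind used in
daily-diary affect studies: several hundred subjects observed over about a
week, answering a handful of items on a 0-4 scale each day, with a daily
stressor count covariate.  Responses are generated from the exact generative
model that the estimators fit — draw (upsilon_i, a_i) jointly normal, draw
occasion residuals with variance exp{tau'v + a_i}, form the latent score, and
(in latent mode) emit items through the measurement model — so simulated data
support exact parameter-recovery studies.

Stressor counts are drawn from a subject-level gamma-frailty Poisson
truncated to [0, 7], calibrated so that subjects' mean daily counts have mean
about 0.53 and SD about 0.42 across subjects, matching the published summary
statistics of the motivating diary sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DiaryDataset, ModelSpec, build_designs
from .parameters import ParameterSet

__all__ = ["SimDesign", "SimulationTruth", "simulate_dataset", "simulate_stressors"]

# stressor-count calibration targets (sample summaries of the emulated design)
STRESSOR_MEAN = 0.53
STRESSOR_PM_SD = 0.42
STRESSOR_MAX = 7


@dataclass(frozen=True)
class SimDesign:
    """Simulation settings: design dimensions, truth, covariates, missingness."""

    n_subjects: int = 435
    n_occasions: int = 8
    n_items: int = 0  # 0 -> manifest mode
    truth: ParameterSet = None
    spec: ModelSpec = None
    seed: int = 0
    missing_rate: float = 0.0
    stressors: bool = False
    clip_to_scale: bool = False  # optionally clip responses to the 0-4 scale

    def __post_init__(self):
        if self.truth is None or self.spec is None:
            raise ValueError("SimDesign requires truth parameters and a model spec")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_stressors(
    n_subjects: int,
    n_occasions: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Daily stressor counts with person-mean and person-mean-centered columns.

    Subject rates are gamma distributed and daily counts Poisson given the
    rate, truncated to [0, 7].  Columns: subject, occasion, stressors,
    stressors_pm (person mean over observed days), stressors_pmc (centered,
    sums to zero within subject).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var_rate = max(STRESSOR_PM_SD**2 - STRESSOR_MEAN / n_occasions, 1e-3)
    shape = STRESSOR_MEAN**2 / var_rate
    scale = var_rate / STRESSOR_MEAN
    rates = rng.gamma(shape, scale, size=n_subjects)
    counts = rng.poisson(rates[:, None], size=(n_subjects, n_occasions))
    counts = np.minimum(counts, STRESSOR_MAX)
    pm = counts.mean(axis=1)
    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(1, n_subjects + 1), n_occasions),
            "occasion": np.tile(np.arange(1, n_occasions + 1), n_subjects),
            "stressors": counts.ravel(),
            "stressors_pm": np.repeat(pm, n_occasions),
            "stressors_pmc": (counts - pm[:, None]).ravel(),
        }
    )
    return frame


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters plus the realized per-subject random effects."""

    params: ParameterSet
    upsilon: np.ndarray  # (n_subjects, p*)
    a: np.ndarray  # (n_subjects,)


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerating exactly singular (degenerate) covariances."""
    evals, evecs = np.linalg.eigh(M)
    if evals.min() < -1e-10:
        raise ValueError("truth covariance of the random effects is not PSD")
    return evecs * np.sqrt(np.clip(evals, 0, None))


def simulate_dataset(design: SimDesign) -> tuple[DiaryDataset, SimulationTruth]:
    """Generate a diary dataset from the design's truth; deterministic per seed.

    Returns the dataset together with the truth record (parameters and the
    realized subject effects).  In latent mode the item columns are named
    item1..itemM; manifest mode writes a single ``y``.
    """
    rng = np.random.default_rng(design.seed)
    spec, truth = design.spec, design.truth
    N, T = design.n_subjects, design.n_occasions
    latent = design.n_items > 0
    if latent != spec.is_latent:
        raise ValueError("n_items and spec.measurement disagree about latent mode")

    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(1, N + 1), T),
            "occasion": np.tile(np.arange(1, T + 1), N),
        }
    )
    if design.stressors:
        sc = simulate_stressors(N, T, rng)
        for col in ("stressors", "stressors_pm", "stressors_pmc"):
            frame[col] = sc[col].to_numpy()
    item_cols = tuple(f"item{m + 1}" for m in range(design.n_items)) if latent else ()
    for col in item_cols or ("y",):
        frame[col] = 0.0
    skeleton = DiaryDataset(
        frame,
        outcome_col=None if latent else "y",
        item_cols=item_cols,
    )
    designs = build_designs(skeleton, spec)

    p_star = spec.location.p_star
    values = []
    ups_drawn, a_drawn = [], []
    for s in designs:
        n_i = len(s.occasions)
        # joint draw of (upsilon_i, a_i)
        log_var = truth.alpha @ s.B
        sd = np.exp(0.5 * log_var)
        R = np.eye(p_star + 1)
        if p_star > 1:
            iu = np.triu_indices(p_star, 1)
            R[:p_star, :p_star][iu] = truth.rho_upsilon
            R[:p_star, :p_star][(iu[1], iu[0])] = truth.rho_upsilon
        if spec.within_var.random_scale and truth.phi_a > 0:
            R[:p_star, p_star] = R[p_star, :p_star] = truth.rho_upsilon_a
            sds = np.append(sd, truth.phi_a)
        else:
            sds = np.append(sd, 0.0)
        Phi_c = R * np.outer(sds, sds)
        c = _psd_sqrt(Phi_c) @ rng.standard_normal(p_star + 1)
        ups, a = c[:p_star], c[p_star]
        ups_drawn.append(ups)
        a_drawn.append(a)
        sig2 = np.exp(s.V @ truth.tau + a)
        eps = rng.standard_normal(n_i) * np.sqrt(sig2)
        eta = s.Gamma @ truth.beta + s.Z @ ups + eps
        if latent:
            mp = truth.measurement
            occ0 = s.occasions.astype(int) - 1
            lam = mp.lam[:, occ0].T  # (n_i, M)
            tau_m = mp.tau[:, occ0].T
            psi = mp.psi[:, occ0].T
            delta = rng.standard_normal((n_i, design.n_items)) * np.sqrt(psi)
            values.append(tau_m + lam * eta[:, None] + delta)
        else:
            values.append(eta)
    values = np.vstack(values) if latent else np.concatenate(values)
    if design.clip_to_scale:
        values = np.clip(values, 0.0, 4.0)
    if design.missing_rate > 0:
        mask = rng.random(values.shape) < design.missing_rate
        values = np.where(mask, np.nan, values)
    frame = skeleton.frame.copy()
    if latent:
        frame[list(item_cols)] = values
    else:
        frame["y"] = values
    record = SimulationTruth(
        params=truth, upsilon=np.array(ups_drawn), a=np.array(a_drawn)
    )
    return skeleton.with_frame(frame), record
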