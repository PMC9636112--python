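"""Packed parameter vector and transforms to an unconstrained scale.

Optimization runs on an unconstrained vector: variance-model coefficients are
already log-scale, the scale-effect SD enters as log(phi_a), correlations as
atanh(rho), and uniquenesses as log(psi).  This keeps the joint random-effect
covariance positive definite and the uniquenesses positive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import ModelSpec
from .measurement import MeasurementParams, pack_measurement, unpack_measurement

__all__ = ["ParameterSet", "ParameterPacker"]


@dataclass(frozen=True)
class ParameterSet:
    """Natural-scale model parameters.

    beta : fixed location effects, x-terms then w-terms (length p+q)
    alpha : (p*, n_bv) log-linear between-variance coefficients, one row per
        random location effect
    tau : within-variance coefficients (intercept, x-terms, w-terms)
    phi_a : SD of the random scale effect (0 when the model has none)
    rho_upsilon_a : (p*,) correlations between location effects and a_i
    rho_upsilon : strict-upper-triangle correlations among location effects
    measurement : full item parameter tables, or None for manifest models
    """

    beta: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray
    phi_a: float = 0.0
    rho_upsilon_a: np.ndarray = ()
    rho_upsilon: np.ndarray = ()
    measurement: MeasurementParams | None = None

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        object.__setattr__(self, "alpha", np.atleast_2d(np.asarray(self.alpha, float)))
        object.__setattr__(self, "tau", np.atleast_1d(np.asarray(self.tau, float)))
        object.__setattr__(
            self, "rho_upsilon_a", np.atleast_1d(np.asarray(self.rho_upsilon_a, float))
        )
        object.__setattr__(
            self, "rho_upsilon", np.atleast_1d(np.asarray(self.rho_upsilon, float))
        )

    @property
    def p_star(self) -> int:
        return self.alpha.shape[0]

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


class ParameterPacker:
    """Maps a :class:`ParameterSet` to/from the unconstrained optimizer vector."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        loc = spec.location
        self.p_star = loc.p_star
        self.n_beta = loc.p + loc.q
        self.n_alpha = self.p_star * spec.between_var.n_coef
        self.n_tau = spec.within_var.n_coef
        self.random_scale = spec.within_var.random_scale
        self.n_scale = (1 + self.p_star) if self.random_scale else 0
        self.n_rho_u = self.p_star * (self.p_star - 1) // 2
        self.n_meas = spec.measurement.n_free if spec.is_latent else 0
        self.n_params = (
            self.n_beta + self.n_alpha + self.n_tau + self.n_scale
            + self.n_rho_u + self.n_meas
        )

    def pack(self, params: ParameterSet) -> np.ndarray:
        parts = [params.beta, params.alpha.ravel(), params.tau]
        if self.random_scale:
            parts.append([np.log(params.phi_a)])
            parts.append(np.arctanh(params.rho_upsilon_a))
        if self.n_rho_u:
            parts.append(np.arctanh(params.rho_upsilon))
        if self.n_meas:
            mspec = self.spec.measurement
            free = pack_measurement(mspec, params.measurement)
            n_tl = len(mspec.intercept_labels) + len(mspec.loading_labels)
            free = free.copy()
            free[n_tl:] = np.log(free[n_tl:])  # psi block -> log scale
            parts.append(free)
        vec = np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])
        if len(vec) != self.n_params:
            raise ValueError(f"packed {len(vec)} values, expected {self.n_params}")
        return vec

    def unpack(self, vec: np.ndarray) -> ParameterSet:
        vec = np.asarray(vec, float).ravel()
        if len(vec) != self.n_params:
            raise ValueError(f"expected {self.n_params} values, got {len(vec)}")
        i = 0

        def take(n):
            nonlocal i
            out = vec[i : i + n]
            i += n
            return out

        beta = take(self.n_beta)
        alpha = take(self.n_alpha).reshape(self.p_star, -1)
        tau = take(self.n_tau)
        if self.random_scale:
            phi_a = float(np.exp(take(1)[0]))
            rho_ua = np.tanh(take(self.p_star))
        else:
            phi_a, rho_ua = 0.0, np.zeros(self.p_star)
        rho_u = np.tanh(take(self.n_rho_u)) if self.n_rho_u else np.zeros(0)
        meas = None
        if self.n_meas:
            mspec = self.spec.measurement
            free = take(self.n_meas).copy()
            n_tl = len(mspec.intercept_labels) + len(mspec.loading_labels)
            free[n_tl:] = np.exp(free[n_tl:])
            meas = unpack_measurement(free, mspec)
        return ParameterSet(
            beta=beta, alpha=alpha, tau=tau, phi_a=phi_a,
            rho_upsilon_a=rho_ua, rho_upsilon=rho_u, measurement=meas,
        )
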