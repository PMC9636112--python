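"""Log-linear variance maps and the joint random-effects distribution.

Both variance submodels use a log link, so fitted variances are strictly
positive for any finite coefficients: the between-subject (random-effect)
variance is ``exp{alpha'(1, w)}`` and the occasion-level residual variance is
``exp{tau_0 + tau_x'x + tau_w'w + a}``, where ``a`` is the subject's random
scale effect.  The location effects ``upsilon`` and the scale effect ``a`` are
jointly normal; conditioning the former on the latter is what reduces the
marginal likelihood to a one-dimensional integral, so the conditional-normal
algebra lives here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "between_variance",
    "within_variance",
    "typical_subject_within_variance",
    "RandomEffectsJoint",
    "ConditionalREDist",
    "conditional_re_given_a",
    "assemble_phi_c",
]


def between_variance(alpha, w=()) -> float:
    """Variance of a random location effect, ``exp{alpha_0 + alpha_1 w_1 + ...}``."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if len(alpha) != len(w) + 1:
        raise ValueError(
            f"alpha has {len(alpha)} coefficients but w has {len(w)} covariates"
        )
    return float(np.exp(alpha[0] + alpha[1:] @ w))


def within_variance(tau, x=(), w=(), a: float = 0.0) -> float:
    """Occasion-level residual variance ``exp{tau_0 + tau_x'x + tau_w'w + a}``.

    ``exp(tau_0)`` is the residual variance at zero covariates for a subject
    with ``a = 0``.
    """
    tau = np.asarray(tau, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if len(tau) != 1 + len(x) + len(w):
        raise ValueError(
            f"tau has {len(tau)} coefficients but x, w supply {len(x)}+{len(w)}"
        )
    return float(np.exp(tau[0] + tau[1 : 1 + len(x)] @ x + tau[1 + len(x) :] @ w + a))


def typical_subject_within_variance(tau0: float, phi_a_sq: float) -> float:
    """Marginal mean of the log-normal within-subject variance.

    With ``a ~ Normal(0, phi_a^2)`` the residual variance ``exp{tau_0 + a}``
    averages to ``exp{tau_0 + phi_a^2 / 2}`` over subjects — the residual
    state variance of the typical individual.  By Jensen this is never below
    the ``a = 0`` variance ``exp(tau_0)``.
    """
    if phi_a_sq < 0:
        raise ValueError(f"phi_a_sq must be nonnegative, got {phi_a_sq}")
    return float(np.exp(tau0 + 0.5 * phi_a_sq))


@dataclass(frozen=True)
class RandomEffectsJoint:
    """Joint normal law of the stacked effects c_i = (upsilon_i', a_i)'.

    ``mu_c`` has length p*+1 (location means, then 0 for the scale effect);
    ``Phi_upsilon`` is the p* x p* covariance of the location effects,
    ``phi_upsilon_a`` their covariances with a_i, and ``phi_a_sq`` its variance.
    """

    mu_c: np.ndarray
    Phi_upsilon: np.ndarray
    phi_upsilon_a: np.ndarray
    phi_a_sq: float

    def __post_init__(self):
        object.__setattr__(self, "mu_c", np.atleast_1d(np.asarray(self.mu_c, float)))
        object.__setattr__(
            self, "Phi_upsilon", np.atleast_2d(np.asarray(self.Phi_upsilon, float))
        )
        object.__setattr__(
            self, "phi_upsilon_a", np.atleast_1d(np.asarray(self.phi_upsilon_a, float))
        )
        p = self.Phi_upsilon.shape[0]
        if self.Phi_upsilon.shape != (p, p):
            raise ValueError("Phi_upsilon must be square")
        if len(self.phi_upsilon_a) != p:
            raise ValueError("phi_upsilon_a length must match Phi_upsilon")
        if len(self.mu_c) != p + 1:
            raise ValueError("mu_c must have length p*+1")

    @property
    def p_star(self) -> int:
        return self.Phi_upsilon.shape[0]


@dataclass(frozen=True)
class ConditionalREDist:
    """Normal law of upsilon_i given a_i: mean linear in a, covariance constant."""

    mean: np.ndarray
    cov: np.ndarray


def conditional_re_given_a(joint: RandomEffectsJoint, a: float) -> ConditionalREDist:
    """Conditional distribution of the location effects given the scale effect.

    mean = mu_upsilon + (phi_upsilon_a / phi_a^2) * a,
    cov  = Phi_upsilon - phi_upsilon_a phi_upsilon_a' / phi_a^2.

    The covariance does not depend on ``a``; eigenvalues down to -1e-10 are
    tolerated and clipped to zero.
    """
    if joint.phi_a_sq <= 0:
        if np.any(joint.phi_upsilon_a != 0):
            raise ValueError("phi_a_sq = 0 with nonzero phi_upsilon_a is degenerate")
        return ConditionalREDist(joint.mu_c[:-1].copy(), joint.Phi_upsilon.copy())
    shift = joint.phi_upsilon_a / joint.phi_a_sq
    mean = joint.mu_c[:-1] + shift * a
    cov = joint.Phi_upsilon - np.outer(joint.phi_upsilon_a, shift)
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-10:
        raise ValueError(
            f"conditional covariance not PSD (smallest eigenvalue {evals.min():.3e})"
        )
    if evals.min() < 0:
        cov = (evecs * np.clip(evals, 0, None)) @ evecs.T
    return ConditionalREDist(mean, cov)


def assemble_phi_c(joint: RandomEffectsJoint) -> np.ndarray:
    """Assemble the full (p*+1) x (p*+1) covariance of (upsilon_i', a_i)'.

    Raises if the assembly is not positive definite, reporting the smallest
    eigenvalue.
    """
    p = joint.p_star
    phi = np.empty((p + 1, p + 1))
    phi[:p, :p] = joint.Phi_upsilon
    phi[:p, p] = joint.phi_upsilon_a
    phi[p, :p] = joint.phi_upsilon_a
    phi[p, p] = joint.phi_a_sq
    phi = 0.5 * (phi + phi.T)
    smallest = np.linalg.eigvalsh(phi)[0]
    if smallest <= 0:
        raise ValueError(
            f"assembled Phi_c is not positive definite (smallest eigenvalue {smallest:.3e})"
        )
    return phi


def phi_c_from_correlations(
    phi_upsilon_sd: np.ndarray,
    rho_upsilon: np.ndarray,
    phi_a: float,
    rho_upsilon_a: np.ndarray,
    mu_upsilon: np.ndarray | None = None,
) -> RandomEffectsJoint:
    """Build the joint law from SDs and correlations.

    ``phi_upsilon_sd`` are the location-effect SDs, ``rho_upsilon`` the
    correlations among them (row-major strict upper triangle), ``phi_a`` the
    scale-effect SD and ``rho_upsilon_a`` the location-scale correlations,
    each in (-1, 1).
    """
    sd = np.atleast_1d(np.asarray(phi_upsilon_sd, float))
    p = len(sd)
    R = np.eye(p)
    iu = np.triu_indices(p, 1)
    rho_upsilon = np.asarray(rho_upsilon, float).ravel()
    if len(rho_upsilon) != len(iu[0]):
        raise ValueError("rho_upsilon length must be p*(p*-1)/2")
    R[iu] = rho_upsilon
    R[(iu[1], iu[0])] = rho_upsilon
    Phi_u = R * np.outer(sd, sd)
    rho_ua = np.atleast_1d(np.asarray(rho_upsilon_a, float))
    phi_ua = rho_ua * sd * phi_a
    mu = np.zeros(p + 1)
    if mu_upsilon is not None:
        mu[:p] = mu_upsilon
    return RandomEffectsJoint(mu, Phi_u, phi_ua, float(phi_a) ** 2)
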