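"""Marginal log-likelihood via reduction to a one-dimensional integral.

The model is nonlinear in the random scale effect a_i only.  Conditional on
a_i the remaining random location effects enter linearly, so they integrate
out analytically: y_i | a_i is multivariate normal with

    mu_{y.a}    = tau_i + Lambda_i Gamma_i mu_{beta.a}
    Sigma_{y.a} = Lambda_i (Z_i Phi_{u.a} Z_i' + Theta_eps(a)) Lambda_i' + Psi_i

where mu_{beta.a} shifts the random coefficients by (phi_ua / phi_a^2) a and
Phi_{u.a} is the conditional covariance of the location effects given a.  The
marginal density is then a single integral over a, evaluated by nonadaptive
Gauss-Hermite quadrature with the substitution a = sqrt(2) phi_a x, weights
folded in log space.  A manifest model is the special case Lambda = I, Psi = 0,
tau_i = 0.  With no random scale effect the single node a = 0 is exact.

Subjects sharing identical designs (and observation patterns) share their
conditional moments, so their density evaluations are batched; a brute-force
tensor-product quadrature over the full random-effect vector (upsilon, a) is
provided as an independent cross-check for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .data import DiaryDataset, ModelSpec, build_designs
from .parameters import ParameterSet

__all__ = [
    "QuadratureRule",
    "ConditionalMoments",
    "LikelihoodEngine",
    "marginal_loglik",
    "marginal_loglik_manifest",
    "marginal_loglik_bruteforce",
    "deviance",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite nodes/weights for integrals against exp(-x^2).

    Weights sum to sqrt(pi); nodes are symmetric about 0.
    """

    n_points: int
    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def gauss_hermite(cls, n_points: int = 10) -> "QuadratureRule":
        if n_points < 1:
            raise ValueError("need at least one quadrature point")
        nodes, weights = np.polynomial.hermite.hermgauss(n_points)
        return cls(n_points, nodes, weights)


@dataclass(frozen=True)
class ConditionalMoments:
    """Mean and covariance of a subject's observed responses given a_i."""

    mu_y_a: np.ndarray
    sigma_y_a: np.ndarray


class _Group:
    """Subjects with byte-identical designs and observation patterns."""

    __slots__ = (
        "Gamma", "Z", "V", "B", "Y", "members", "obs_idx",
        "lam_rows", "lam_cols", "m_idx", "t_idx", "d",
    )

    def __init__(self, key_arrays, latent):
        (self.Gamma, self.Z, self.V, self.B, self.obs_idx,
         self.m_idx, self.t_idx, self.lam_cols) = key_arrays
        self.members: list[int] = []
        self.Y: list[np.ndarray] = []
        self.d = len(self.obs_idx) if not latent else len(self.m_idx)
        self.lam_rows = np.arange(self.d) if latent else None


def _corr_matrix(p, rho_flat):
    R = np.eye(p)
    if p > 1:
        iu = np.triu_indices(p, 1)
        R[iu] = rho_flat
        R[(iu[1], iu[0])] = rho_flat
    return R


class LikelihoodEngine:
    """Precomputed per-subject designs + grouped, batched density evaluation."""

    def __init__(self, data: DiaryDataset, spec: ModelSpec,
                 rule: QuadratureRule | None = None):
        self.spec = spec
        self.latent = spec.is_latent
        self.rule = rule or QuadratureRule.gauss_hermite(10)
        if self.latent and not data.is_latent:
            raise ValueError("latent model spec requires item-level data")
        if not self.latent and data.is_latent:
            raise ValueError("manifest model spec requires an outcome column")
        designs = build_designs(data, spec)
        self.n_subjects = len(designs)
        self.subject_ids = [s.subject_id for s in designs]
        self._groups: dict[bytes, _Group] = {}
        self._blocks = []
        for idx, s in enumerate(designs):
            if self.latent:
                mspec = spec.measurement
                occ0 = s.occasions.astype(int) - 1  # occasions are 1-based
                if occ0.min() < 0 or occ0.max() >= mspec.n_occasions:
                    raise ValueError(
                        f"subject {s.subject_id}: occasion outside 1..{mspec.n_occasions}"
                    )
                obs = ~np.isnan(s.y)  # (n_i, M)
                # observed cells in occasion-major order
                occ_pos, m_idx, t_idx = [], [], []
                for j in range(len(occ0)):
                    for m in range(mspec.n_items):
                        if obs[j, m]:
                            occ_pos.append(j)
                            m_idx.append(m)
                            t_idx.append(occ0[j])
                y_obs = s.y[np.array(occ_pos, int), np.array(m_idx, int)] if occ_pos else np.zeros(0)
                key_arrays = (s.Gamma, s.Z, s.V, s.B, np.array(occ_pos, int),
                              np.array(m_idx, int), np.array(t_idx, int),
                              np.array(occ_pos, int))
            else:
                obs_idx = np.flatnonzero(~np.isnan(s.y))
                y_obs = s.y[obs_idx]
                key_arrays = (s.Gamma, s.Z, s.V, s.B, obs_idx,
                              np.zeros(0, int), np.zeros(0, int), np.zeros(0, int))
            key = b"".join(np.ascontiguousarray(a).tobytes() for a in key_arrays) \
                + str([a.shape for a in key_arrays]).encode()
            grp = self._groups.get(key)
            if grp is None:
                grp = self._groups[key] = _Group(key_arrays, self.latent)
            grp.members.append(idx)
            grp.Y.append(y_obs)
            self._blocks.append((grp, y_obs, s))
        for grp in self._groups.values():
            grp.Y = np.asarray(grp.Y)

    # -- random-effects law ------------------------------------------------
    def _joint(self, params: ParameterSet, B: np.ndarray):
        """(Phi_ua, shift, sd) for a subject with between-variance design B."""
        log_var = params.alpha @ B  # (p*,)
        sd = np.exp(0.5 * log_var)
        R = _corr_matrix(len(sd), params.rho_upsilon)
        Phi_u = R * np.outer(sd, sd)
        if self.spec.within_var.random_scale and params.phi_a > 0:
            phi_ua = params.rho_upsilon_a * sd * params.phi_a
            shift = phi_ua / params.phi_a**2
            Phi_ua = Phi_u - np.outer(phi_ua, shift)
        else:
            shift = np.zeros(len(sd))
            Phi_ua = Phi_u
        return Phi_ua, shift, sd

    def _nodes(self, params: ParameterSet):
        if self.spec.within_var.random_scale and params.phi_a > 0:
            a = np.sqrt(2.0) * params.phi_a * self.rule.nodes
            logw = np.log(self.rule.weights) - 0.5 * np.log(np.pi)
        else:
            a = np.zeros(1)
            logw = np.zeros(1)
        return a, logw

    def _group_moments(self, grp: _Group, params: ParameterSet, a: float):
        """Conditional moments (mu, Sigma) shared by a group's subjects."""
        Phi_ua, shift, _ = self._joint(params, grp.B)
        return self._moments_from(grp, params, Phi_ua, shift, a)

    def _moments_from(self, grp: _Group, params, Phi_ua, shift, a):
        mu_eta = grp.Gamma @ params.beta + (grp.Z @ shift) * a
        sig2 = np.exp(grp.V @ params.tau + a)
        ZPZ = grp.Z @ Phi_ua @ grp.Z.T
        if not self.latent:
            idx = grp.obs_idx
            mu = mu_eta[idx]
            Sigma = ZPZ[np.ix_(idx, idx)] + np.diag(sig2[idx])
            return mu, Sigma
        mp = params.measurement
        lam_vec = mp.lam[grp.m_idx, grp.t_idx]
        n_eta = grp.Gamma.shape[0]
        Lam = np.zeros((grp.d, n_eta))
        Lam[grp.lam_rows, grp.lam_cols] = lam_vec
        cov_eta = ZPZ + np.diag(sig2)
        mu = mp.tau[grp.m_idx, grp.t_idx] + Lam @ mu_eta
        Sigma = Lam @ cov_eta @ Lam.T + np.diag(mp.psi[grp.m_idx, grp.t_idx])
        return mu, Sigma

    # -- log-likelihood ----------------------------------------------------
    def subject_logliks(self, params: ParameterSet) -> np.ndarray:
        """Per-subject log marginal densities, in canonical subject order."""
        a_nodes, logw = self._nodes(params)
        K = len(a_nodes)
        out = np.empty(self.n_subjects)
        for grp in self._groups.values():
            if grp.d == 0:
                out[grp.members] = 0.0
                continue
            Phi_ua, shift, _ = self._joint(params, grp.B)
            lognode = np.empty((K, len(grp.members)))
            for k, a in enumerate(a_nodes):
                mu, Sigma = self._moments_from(grp, params, Phi_ua, shift, a)
                L = np.linalg.cholesky(Sigma)
                logdet = 2.0 * np.log(np.diag(L)).sum()
                resid = grp.Y - mu  # (n_g, d)
                q = solve_triangular(L, resid.T, lower=True, check_finite=False)
                lognode[k] = -0.5 * (grp.d * _LOG2PI + logdet + (q * q).sum(axis=0))
            out[grp.members] = logsumexp(lognode + logw[:, None], axis=0)
        return out

    def loglik(self, params: ParameterSet) -> float:
        return float(self.subject_logliks(params).sum())

    def loglik_safe(self, params: ParameterSet) -> float:
        """loglik, but -inf-like on numerically invalid covariance assemblies."""
        try:
            val = self.loglik(params)
        except np.linalg.LinAlgError:
            return -1e12
        return val if np.isfinite(val) else -1e12


def marginal_loglik(
    params: ParameterSet,
    data: DiaryDataset,
    spec: ModelSpec,
    rule: QuadratureRule | None = None,
) -> float:
    """Marginal log-likelihood sum_i log integral h(y_i | a) phi(a; 0, phi_a^2) da."""
    return LikelihoodEngine(data, spec, rule).loglik(params)


def marginal_loglik_manifest(params, data, spec, rule=None) -> float:
    """Manifest-model marginal log-likelihood (identity measurement)."""
    if spec.is_latent:
        raise ValueError("spec carries a measurement model; use marginal_loglik")
    return marginal_loglik(params, data, spec, rule)


def conditional_moments_latent(
    params: ParameterSet, data: DiaryDataset, spec: ModelSpec,
    subject_id, a: float,
) -> ConditionalMoments:
    """Conditional moments of one subject's observed items given a_i."""
    engine = LikelihoodEngine(data, spec)
    try:
        idx = engine.subject_ids.index(subject_id)
    except ValueError:
        raise KeyError(f"subject {subject_id!r} not in data") from None
    grp, _, _ = engine._blocks[idx]
    mu, Sigma = engine._group_moments(grp, params, a)
    return ConditionalMoments(mu, Sigma)


def marginal_loglik_bruteforce(
    params: ParameterSet,
    data: DiaryDataset,
    spec: ModelSpec,
    n_points: int = 200,
    box_half: float = 9.0,
) -> float:
    """Unreduced tensor-product quadrature over the full (upsilon, a) vector.

    Integrates the conditional density h(y | upsilon, a) against the joint
    random-effects normal, pointwise, on a tensor Gauss-Legendre grid covering
    ``box_half`` prior SDs in each of the p*+1 dimensions — no conditioning,
    no analytic reduction.  Exponential cost in the number of random effects:
    a testing oracle for toy instances only.
    """
    engine = LikelihoodEngine(data, spec)
    x1, w1 = np.polynomial.legendre.leggauss(n_points)
    p = spec.location.p_star
    use_a = spec.within_var.random_scale and params.phi_a > 0
    total = 0.0
    for grp, y_obs, s in engine._blocks:
        if grp.d == 0:
            continue
        _, _, sd = engine._joint(params, grp.B)
        R = _corr_matrix(p, params.rho_upsilon)
        Phi_u = R * np.outer(sd, sd)
        if use_a:
            phi_ua = params.rho_upsilon_a * sd * params.phi_a
            Phi_c = np.zeros((p + 1, p + 1))
            Phi_c[:p, :p] = Phi_u
            Phi_c[:p, p] = Phi_c[p, :p] = phi_ua
            Phi_c[p, p] = params.phi_a**2
        else:
            Phi_c = Phi_u
        Lc = np.linalg.cholesky(Phi_c)
        logdet_c = 2.0 * np.log(np.diag(Lc)).sum()
        r_dim = Phi_c.shape[0]
        # upsilon grid: tensor product of per-dimension box rules
        u_axes = [x1 * box_half * sd[j] for j in range(p)]
        u_logw = [np.log(w1 * box_half * sd[j]) for j in range(p)]
        U = np.array(list(product(*u_axes)))  # (nu, p)
        U_logw = np.array(list(product(*u_logw))).sum(axis=1)
        a_axis = x1 * box_half * params.phi_a if use_a else np.zeros(1)
        a_logw = np.log(w1 * box_half * params.phi_a) if use_a else np.zeros(1)
        mu_base = grp.Gamma @ params.beta
        log_sig_base = grp.V @ params.tau
        Eta = mu_base + U @ grp.Z.T  # (nu, n_i) latent means over the upsilon grid
        if engine.latent:
            mp = params.measurement
            Lam = np.zeros((grp.d, grp.Gamma.shape[0]))
            Lam[grp.lam_rows, grp.lam_cols] = mp.lam[grp.m_idx, grp.t_idx]
            Mu = mp.tau[grp.m_idx, grp.t_idx] + Eta @ Lam.T  # (nu, d)
            psi = mp.psi[grp.m_idx, grp.t_idx]
        node_logs = np.empty(len(a_axis))
        for k, a in enumerate(a_axis):
            sig2 = np.exp(log_sig_base + a)
            if engine.latent:
                Sigma = Lam @ np.diag(sig2) @ Lam.T + np.diag(psi)
                L = np.linalg.cholesky(Sigma)
                Rmat = y_obs - Mu  # (nu, d)
                q = solve_triangular(L, Rmat.T, lower=True, check_finite=False)
                logh = -0.5 * (
                    grp.d * _LOG2PI
                    + 2.0 * np.log(np.diag(L)).sum()
                    + (q * q).sum(axis=0)
                )
            else:
                idx = grp.obs_idx
                v = sig2[idx]
                Rmat = y_obs - Eta[:, idx]
                logh = -0.5 * (
                    grp.d * _LOG2PI + np.log(v).sum() + (Rmat**2 / v).sum(axis=1)
                )
            # joint normal prior density at (upsilon, a), evaluated pointwise
            if use_a:
                Cpts = np.column_stack([U, np.full(len(U), a)])
            else:
                Cpts = U
            z = solve_triangular(Lc, Cpts.T, lower=True, check_finite=False)
            logprior = -0.5 * (r_dim * _LOG2PI + logdet_c + (z * z).sum(axis=0))
            node_logs[k] = logsumexp(logh + logprior + U_logw) + a_logw[k]
        total += logsumexp(node_logs)
    return float(total)


def deviance(loglik: float) -> float:
    """Deviance convention: -2 times the log-likelihood."""
    return -2.0 * loglik
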