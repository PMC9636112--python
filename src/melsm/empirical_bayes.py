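"""Empirical Bayes prediction of subject-level random effects.

Posterior summaries are computed on the same Gauss-Hermite grid used for
estimation: the posterior over the scale effect a_i is the prior quadrature
weight times the subject's conditional density, renormalized; within each
node the location effects update by the usual linear-Gaussian (BLUP) formula,
and node summaries are mixed by the posterior weights.  Summaries are
posterior *means*; conditional residuals are the observed responses minus the
fitted means at the posterior means of both effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .data import DiaryDataset
from .inference import FitResult
from .likelihood import LikelihoodEngine, QuadratureRule, _LOG2PI

__all__ = ["EBEstimates", "eb_estimates"]


@dataclass(frozen=True)
class EBEstimates:
    """Per-subject posterior summaries and long-format conditional residuals.

    ``subjects`` has one row per subject: posterior means and SDs of each
    location effect (``upsilon_hat``, ``upsilon_sd``; suffixed by effect index
    when there are several) and of the scale effect (``a_hat``, ``a_sd``).
    ``residuals`` has one row per observed response cell.
    """

    subjects: pd.DataFrame
    residuals: pd.DataFrame


def eb_estimates(
    fit: FitResult,
    data: DiaryDataset,
    rule: QuadratureRule | None = None,
) -> EBEstimates:
    """Posterior means/SDs of (upsilon_i, a_i) and conditional residuals."""
    if not fit.converged:
        raise ValueError("empirical Bayes prediction requires a converged fit")
    spec = fit.spec
    params = fit.estimates
    engine = LikelihoodEngine(data, spec, rule or QuadratureRule.gauss_hermite(fit.n_quad))
    a_nodes, logw = engine._nodes(params)
    p_star = spec.location.p_star
    rows, resid_rows = [], []
    for idx, (grp, y_obs, s) in enumerate(engine._blocks):
        sid = engine.subject_ids[idx]
        Phi_ua, shift, _ = engine._joint(params, grp.B)
        if grp.d == 0:
            # no observations: prior means and SDs
            prior_sd = np.sqrt(np.diag(Phi_ua + np.outer(shift, shift) * params.phi_a**2))
            rows.append((sid, np.zeros(p_star), prior_sd, 0.0, params.phi_a))
            continue
        K = len(a_nodes)
        loghs = np.empty(K)
        Es = np.empty((K, p_star))
        Vs = np.empty((K, p_star, p_star))
        for k, a in enumerate(a_nodes):
            mu, Sigma = engine._moments_from(grp, params, Phi_ua, shift, a)
            # effective design of upsilon in the observed responses
            if engine.latent:
                mp = params.measurement
                Lam = np.zeros((grp.d, grp.Gamma.shape[0]))
                Lam[grp.lam_rows, grp.lam_cols] = mp.lam[grp.m_idx, grp.t_idx]
                D = Lam @ grp.Z
            else:
                D = grp.Z[grp.obs_idx]
            C = Phi_ua @ D.T  # cov(upsilon, y | a)
            cf = cho_factor(Sigma, lower=True)
            r = y_obs - mu
            loghs[k] = -0.5 * (
                grp.d * _LOG2PI + 2.0 * np.log(np.diag(cf[0])).sum()
                + float(r @ cho_solve(cf, r))
            )
            Es[k] = shift * a + C @ cho_solve(cf, r)
            Vs[k] = Phi_ua - C @ cho_solve(cf, C.T)
        logpost = loghs + logw
        logpost -= logsumexp(logpost)
        w = np.exp(logpost)
        ups_hat = w @ Es
        ups_cov = (
            np.einsum("k,kij->ij", w, Vs)
            + np.einsum("k,ki,kj->ij", w, Es, Es)
            - np.outer(ups_hat, ups_hat)
        )
        ups_sd = np.sqrt(np.clip(np.diag(ups_cov), 0, None))
        a_hat = float(w @ a_nodes)
        a_sd = float(np.sqrt(max(w @ a_nodes**2 - a_hat**2, 0.0)))
        rows.append((sid, ups_hat, ups_sd, a_hat, a_sd))
        # conditional residuals at the posterior means
        eta_fit = grp.Gamma @ params.beta + grp.Z @ ups_hat
        if engine.latent:
            mp = params.measurement
            fitted = mp.tau[grp.m_idx, grp.t_idx] + eta_fit[grp.lam_cols] * mp.lam[
                grp.m_idx, grp.t_idx
            ]
            occ = s.occasions[grp.lam_cols]
            for j in range(grp.d):
                resid_rows.append(
                    (sid, int(occ[j]), data.item_cols[grp.m_idx[j]],
                     float(y_obs[j] - fitted[j]))
                )
        else:
            fitted = eta_fit[grp.obs_idx]
            occ = s.occasions[grp.obs_idx]
            for j in range(grp.d):
                resid_rows.append((sid, int(occ[j]), data.outcome_col,
                                   float(y_obs[j] - fitted[j])))
    cols = {"subject_id": [r[0] for r in rows]}
    if p_star == 1:
        cols["upsilon_hat"] = [float(r[1][0]) for r in rows]
        cols["upsilon_sd"] = [float(r[2][0]) for r in rows]
    else:
        for j, term in enumerate(spec.location.random):
            cols[f"upsilon_hat[{term}]"] = [float(r[1][j]) for r in rows]
            cols[f"upsilon_sd[{term}]"] = [float(r[2][j]) for r in rows]
    cols["a_hat"] = [float(r[3]) for r in rows]
    cols["a_sd"] = [float(r[4]) for r in rows]
    subjects = pd.DataFrame(cols)
    residuals = pd.DataFrame(
        resid_rows, columns=["subject_id", "occasion", "variable", "residual"]
    )
    return EBEstimates(subjects, residuals)
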