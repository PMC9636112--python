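"""Maximum-likelihood fitting, standard errors, and model comparison.

Fitting follows the staged scheme used in practice for these models: a
fixed-effects fit supplies location and residual-variance starting values,
random location effects are added next (scale effect and its correlation
frozen at zero), and only then is the random scale effect freed, started at a
small positive SD with zero correlation.  Variance-model covariate effects
always start at 0.  Optimization is quasi-Newton on the unconstrained scale
with central-difference gradients; standard errors come from the numerically
differentiated observed information mapped to the natural scale by the delta
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .data import DiaryDataset, LocationSpec, ModelSpec, WithinVarSpec, build_designs
from .likelihood import LikelihoodEngine, QuadratureRule
from .measurement import MeasurementParams, pack_measurement
from .parameters import ParameterPacker, ParameterSet

__all__ = [
    "FitResult",
    "staged_start",
    "fit_ml",
    "fit_measurement_model",
    "lrt",
    "information_criteria",
    "wald_linear",
]

_START_PHI_A = 0.5  # small positive start for the scale-effect SD


@dataclass(frozen=True)
class FitResult:
    """ML estimates with uncertainty and fit statistics.

    ``se`` aligns with ``natural_names``/``natural_estimates`` (natural-scale
    quantities such as phi_a and rho, not their transforms).
    """

    estimates: ParameterSet
    se: np.ndarray
    natural_names: tuple[str, ...]
    natural_estimates: np.ndarray
    loglik: float
    deviance: float
    aic: float
    bic: float
    n_params: int
    n_subjects: int
    converged: bool
    grad_norm: float
    n_quad: int
    vcov: np.ndarray | None = None
    spec: ModelSpec | None = None

    def __post_init__(self):
        if abs(self.aic - (self.deviance + 2 * self.n_params)) > 1e-6:
            raise ValueError("AIC identity violated")
        if abs(self.bic - (self.deviance + self.n_params * np.log(self.n_subjects))) > 1e-6:
            raise ValueError("BIC identity violated")

    def summary(self) -> str:
        lines = [f"{'parameter':<22}{'estimate':>12}{'se':>12}"]
        for name, est, se in zip(self.natural_names, self.natural_estimates, self.se):
            se_s = f"{se:.4g}" if np.isfinite(se) else "--"
            lines.append(f"{name:<22}{est:>12.4g}{se_s:>12}")
        lines.append(
            f"loglik {self.loglik:.3f}  deviance {self.deviance:.3f}  "
            f"AIC {self.aic:.3f}  BIC {self.bic:.3f}  "
            f"({self.n_params} parameters, {self.n_subjects} subjects, "
            f"{self.n_quad} quadrature points, converged={self.converged})"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": dict(zip(self.natural_names, map(float, self.natural_estimates))),
            "se": dict(zip(self.natural_names, map(float, self.se))),
            "loglik": self.loglik,
            "deviance": self.deviance,
            "aic": self.aic,
            "bic": self.bic,
            "n_params": self.n_params,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "n_quad": self.n_quad,
        }


def _natural_names(spec: ModelSpec) -> tuple[str, ...]:
    loc, bv, wv = spec.location, spec.between_var, spec.within_var
    names = [f"beta[{t}]" for t in loc.x_terms + loc.w_terms]
    bv_terms = ("1",) + bv.terms
    for j, rt in enumerate(loc.random):
        prefix = f"alpha[{rt}]" if loc.p_star > 1 else "alpha"
        names += [f"{prefix}[{t}]" for t in bv_terms]
    names += [f"tau[{t}]" for t in ("1",) + wv.x_terms + wv.w_terms]
    if wv.random_scale:
        names.append("phi_a")
        names += [f"rho_ua[{t}]" for t in loc.random]
    for j in range(loc.p_star):
        for k in range(j + 1, loc.p_star):
            names.append(f"rho_u[{loc.random[j]},{loc.random[k]}]")
    if spec.is_latent:
        m = spec.measurement
        names += [str(lab) for lab in
                  m.intercept_labels + m.loading_labels + m.uniqueness_labels]
    return tuple(names)


def _natural_vector(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    parts = [params.beta, params.alpha.ravel(), params.tau]
    if spec.within_var.random_scale:
        parts.append([params.phi_a])
        parts.append(params.rho_upsilon_a)
    if spec.location.p_star > 1:
        parts.append(params.rho_upsilon)
    if spec.is_latent:
        parts.append(pack_measurement(spec.measurement, params.measurement))
    return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


# --------------------------------------------------------------------------
# starting values
# --------------------------------------------------------------------------

def _manifest_stage1(data: DiaryDataset, spec: ModelSpec) -> ParameterSet:
    """Closed-form fixed-effects start: pooled OLS + moment-based variance split."""
    designs = build_designs(data, spec)
    G = np.vstack([s.Gamma for s in designs])
    y = np.concatenate([np.atleast_1d(s.y) for s in designs])
    ok = ~np.isnan(y)
    beta, *_ = np.linalg.lstsq(G[ok], y[ok], rcond=None)
    resid = y - G @ beta
    s2 = float(np.nanvar(resid, ddof=len(beta)))
    # between variance from subject-mean residuals, net of sampling noise
    means, ns = [], []
    pos = 0
    for s in designs:
        n = len(np.atleast_1d(s.y))
        r = resid[pos : pos + n]
        pos += n
        r = r[~np.isnan(r)]
        if len(r):
            means.append(r.mean())
            ns.append(len(r))
    means = np.asarray(means)
    var_b = max(float(np.var(means) - s2 / np.mean(ns)), 1e-3)
    var_w = max(s2 - var_b, 1e-3)
    p_star = spec.location.p_star
    alpha = np.zeros((p_star, spec.between_var.n_coef))
    alpha[:, 0] = np.log(var_b)
    tau = np.zeros(spec.within_var.n_coef)
    tau[0] = np.log(var_w)
    return ParameterSet(
        beta=beta, alpha=alpha, tau=tau, phi_a=0.0,
        rho_upsilon_a=np.zeros(p_star),
        rho_upsilon=np.zeros(p_star * (p_star - 1) // 2),
    )


def _latent_stage1(data: DiaryDataset, spec: ModelSpec) -> ParameterSet:
    """Configural one-factor analysis supplies measurement starting values."""
    from sklearn.decomposition import FactorAnalysis

    mspec = spec.measurement
    items = data.frame[list(data.item_cols)].to_numpy(dtype=float)
    complete = items[~np.isnan(items).any(axis=1)]
    fa = FactorAnalysis(n_components=1, random_state=0).fit(complete)
    load = fa.components_.ravel()
    if load[mspec.anchor] < 0:
        load = -load
    lam_item = load / load[mspec.anchor]
    psi_item = np.maximum(fa.noise_variance_, 1e-2)
    col_means = complete.mean(axis=0)
    eta_mean = col_means[mspec.anchor]
    tau_item = col_means - lam_item * eta_mean
    tau_item[mspec.anchor] = 0.0
    T, M = mspec.n_occasions, mspec.n_items
    meas = MeasurementParams(
        tau=np.tile(tau_item[:, None], (1, T)),
        lam=np.tile(lam_item[:, None], (1, T)),
        psi=np.tile(psi_item[:, None], (1, T)),
    )
    eta_var = max(float(load[mspec.anchor] ** 2), 1e-2)
    p_star = spec.location.p_star
    beta = np.zeros(spec.location.p + spec.location.q)
    beta[spec.location.x_terms.index("1")] = eta_mean
    alpha = np.zeros((p_star, spec.between_var.n_coef))
    alpha[:, 0] = np.log(0.5 * eta_var)
    tau = np.zeros(spec.within_var.n_coef)
    tau[0] = np.log(0.5 * eta_var)
    return ParameterSet(
        beta=beta, alpha=alpha, tau=tau, phi_a=0.0,
        rho_upsilon_a=np.zeros(p_star),
        rho_upsilon=np.zeros(p_star * (p_star - 1) // 2),
        measurement=meas,
    )


def staged_start(
    data: DiaryDataset,
    spec: ModelSpec,
    *,
    n_quad: int = 10,
    refine: bool = True,
    options: dict | None = None,
) -> ParameterSet:
    """Staged starting values.

    Stage 1 is the closed-form fixed-effects start (for latent models, the
    configural factor analysis plus an even trait/state split of the factor
    variance).  Stage 2 (``refine=True``) fits the model without the random
    scale effect.  Stage 3 frees phi_a at a small positive value with zero
    correlation.
    """
    stage1 = _latent_stage1(data, spec) if spec.is_latent else _manifest_stage1(data, spec)
    if not spec.within_var.random_scale:
        return stage1
    if not refine:
        return stage1.replace(phi_a=_START_PHI_A)
    reduced_spec = replace(spec, within_var=replace(spec.within_var, random_scale=False))
    reduced = fit_ml(
        data, reduced_spec, start=stage1, n_quad=n_quad,
        compute_se=False, options=options,
    )
    if not reduced.converged:
        raise RuntimeError("stage-2 starting-value fit did not converge")
    return reduced.estimates.replace(
        phi_a=_START_PHI_A, rho_upsilon_a=np.zeros(spec.location.p_star)
    )


# --------------------------------------------------------------------------
# ML fitting
# --------------------------------------------------------------------------

def _num_hessian(f, z, step=1e-5):
    n = len(z)
    h = step * np.maximum(1.0, np.abs(z))
    H = np.empty((n, n))
    f0 = f(z)
    fp = np.empty(n)
    fm = np.empty(n)
    for j in range(n):
        e = np.zeros(n)
        e[j] = h[j]
        fp[j] = f(z + e)
        fm[j] = f(z - e)
        H[j, j] = (fp[j] + fm[j] - 2 * f0) / h[j] ** 2
    for j in range(n):
        for k in range(j + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            ek = np.zeros(n)
            ek[k] = h[k]
            H[j, k] = H[k, j] = (
                f(z + ej + ek) - f(z + ej - ek) - f(z - ej + ek) + f(z - ej - ek)
            ) / (4 * h[j] * h[k])
    return H


def _num_jacobian(f, z, step=1e-6):
    h = step * np.maximum(1.0, np.abs(z))
    cols = []
    for j in range(len(z)):
        e = np.zeros(len(z))
        e[j] = h[j]
        cols.append((f(z + e) - f(z - e)) / (2 * h[j]))
    return np.array(cols).T


def fit_ml(
    data: DiaryDataset,
    spec: ModelSpec,
    start: ParameterSet | None = None,
    *,
    n_quad: int = 10,
    compute_se: bool = True,
    options: dict | None = None,
) -> FitResult:
    """Fit by marginal maximum likelihood.

    The returned log-likelihood is never below the starting value; a fit that
    exhausts the iteration cap is flagged ``converged=False`` rather than
    silently returned as converged.
    """
    packer = ParameterPacker(spec)
    rule = QuadratureRule.gauss_hermite(n_quad)
    engine = LikelihoodEngine(data, spec, rule)
    if start is None:
        start = staged_start(data, spec, n_quad=n_quad, options=options)
    z0 = packer.pack(start)
    neg = lambda z: -engine.loglik_safe(packer.unpack(z))
    opts = {"maxiter": 500, "maxfun": 20000, "ftol": 1e-11, "gtol": 1e-7}
    if options:
        opts.update(options)
    # search with cheap forward-difference gradients, then polish from the
    # optimum with central differences for final accuracy
    res = optimize.minimize(neg, z0, method="L-BFGS-B", jac="2-point", options=opts)
    res2 = optimize.minimize(neg, res.x, method="L-BFGS-B", jac="3-point", options=opts)
    if -res2.fun >= -res.fun:
        res = res2
    z_hat = res.x
    ll = -res.fun
    ll0 = -neg(z0)
    if ll < ll0:  # optimizer wandered below the start; keep the start
        z_hat, ll = z0, ll0
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success or grad_norm < 1e-3)
    params = packer.unpack(z_hat)
    k = packer.n_params
    N = data.n_subjects
    dev = -2.0 * ll
    names = _natural_names(spec)
    nat = _natural_vector(params, spec)
    se = np.full(len(nat), np.nan)
    vcov = None
    if compute_se:
        H = _num_hessian(neg, z_hat)
        try:
            vz = np.linalg.inv(H)
            J = _num_jacobian(lambda z: _natural_vector(packer.unpack(z), spec), z_hat)
            vcov = J @ vz @ J.T
            d = np.diag(vcov)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; SEs unavailable")
    return FitResult(
        estimates=params,
        se=se,
        natural_names=names,
        natural_estimates=nat,
        loglik=ll,
        deviance=dev,
        aic=dev + 2 * k,
        bic=dev + k * np.log(N),
        n_params=k,
        n_subjects=N,
        converged=converged,
        grad_norm=grad_norm,
        n_quad=n_quad,
        vcov=vcov,
        spec=spec,
    )


def fit_measurement_model(data: DiaryDataset, mspec, *, n_quad: int = 10,
                          compute_se: bool = False, options=None) -> FitResult:
    """Fit a measurement model over an intercept-only structural model.

    The occasion-level latent scores follow a random-intercept model without a
    random scale effect — the measurement-invariance testing stage.
    """
    spec = ModelSpec(
        location=LocationSpec(),
        within_var=WithinVarSpec(random_scale=False),
        measurement=mspec,
    )
    return fit_ml(data, spec, n_quad=n_quad, compute_se=compute_se, options=options)


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

def lrt(deviance_reduced: float, deviance_full: float, df: int):
    """Likelihood-ratio test: statistic = deviance_reduced - deviance_full.

    The reduced (restricted) model has the larger deviance when fits are
    sound; a negative statistic is returned with a warning, signalling
    non-nesting or non-convergence.  df = 0 compares identical models.
    """
    stat = deviance_reduced - deviance_full
    if df < 0:
        raise ValueError("df must be nonnegative")
    if stat < -1e-8:
        warnings.warn(
            f"negative LRT statistic ({stat:.4g}): models may not be nested "
            "or a fit did not converge"
        )
    if df == 0:
        p = 1.0 if stat <= 1e-8 else 0.0
    else:
        p = float(chi2.sf(max(stat, 0.0), df))
    return stat, df, p


def information_criteria(deviance: float, n_params: int, n_subjects: int):
    """(AIC, BIC) = (deviance + 2k, deviance + k log N)."""
    return deviance + 2 * n_params, deviance + n_params * np.log(n_subjects)


def wald_linear(contrast, estimates, vcov):
    """Wald chi-square test of c'theta = 0 with 1 df: (c'theta)^2 / (c'Vc)."""
    c = np.asarray(contrast, float).ravel()
    theta = np.asarray(estimates, float).ravel()
    V = np.atleast_2d(np.asarray(vcov, float))
    if len(c) != len(theta):
        raise ValueError("contrast length must match estimate vector")
    denom = float(c @ V @ c)
    if denom <= 0:
        raise ValueError(f"contrast variance must be positive, got {denom}")
    stat = float(c @ theta) ** 2 / denom
    return stat, 1, float(chi2.sf(stat, 1))
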