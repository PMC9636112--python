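# Methods

## Model

The package fits two-level mixed-effects location scale models to long-format
repeated-measures data. For subject *i* (N subjects) at occasion *t* (n_i
occasions, ragged and possibly non-contiguous — the model has no time trend,
so only row membership matters):

* Location: `y_ti = x_ti'(beta_x + upsilon_i) + w_i' beta_w + eps_ti`, with
  p occasion-varying regressors (p* of them random) and q subject-level
  regressors.
* Between-subject variance: each random effect's variance is log-linear in
  subject covariates, `phi_j^2(w) = exp{alpha_j'(1, w)}`; correlations among
  random effects are covariate-free.
* Within-subject variance:
  `sigma_ti^2 = exp{tau_0 + tau_x' x_ti + tau_w' w_i + a_i}` with a normal
  random scale effect `a_i ~ N(0, phi_a^2)`. The stacked effects
  `c_i = (upsilon_i', a_i)'` are jointly normal with covariance assembled from
  SDs and correlations.

In the latent-variable form the located-and-scaled quantity is an
occasion-specific latent score measured by M items through a block-diagonal
longitudinal factor model (item intercepts nu_m, loadings lambda_m,
uniquenesses psi_m). The first item anchors the scale: loading fixed at 1 and
intercept at 0 at every occasion. Equality of item parameters across
occasions is encoded by constraint maps (item-by-occasion grids of parameter
labels); freed cells implement partial invariance. The manifest model is the
special case Lambda = I, Psi = 0.

Missing responses are assumed missing at random and handled by row/column
deletion in the subject's moment matrices; a subject keeps the remaining
items of an occasion. Person-mean centering of occasion-varying covariates
uses observed occasions only.

## Likelihood

The model is nonlinear only in `a_i`. Conditional on `a_i`, `upsilon_i | a_i`
is normal with mean `(phi_ua / phi_a^2) a_i` (deviation form) and covariance
`Phi_u - phi_ua phi_ua' / phi_a^2`, so the location effects integrate out
analytically, leaving per subject

    mu_{y.a}    = nu_i + Lambda_i Gamma_i mu_{beta.a}
    Sigma_{y.a} = Lambda_i (Z_i Phi_{u.a} Z_i' + Theta_eps(a)) Lambda_i' + Psi_i

and a one-dimensional marginal integral over `a`, evaluated by nonadaptive
Gauss–Hermite quadrature with the substitution `a = sqrt(2) phi_a x` (nodes
are parameter-independent; weights folded in log space via log-sum-exp).
Densities use Cholesky factorizations throughout; no explicit inverses.
Subjects with byte-identical designs and observation patterns share their
conditional moments, so their density evaluations are batched — with no
covariates and complete data the whole sample shares one covariance per node,
which is what makes simulation studies affordable.

With no random scale effect the single node a = 0 is exact (ordinary linear
mixed model / longitudinal factor model), verified in the tests against
closed-form multivariate-normal likelihoods and an independent mixed-model
fitter (agreement to 1e-4 in natural parameters).

An independent brute-force oracle evaluates the *unreduced* integral over the
full `(upsilon, a)` vector by a tensor Gauss–Legendre rule over a ±9-prior-SD
box (300 points per dimension), using only the conditional density
`h(y | upsilon, a)` and the joint normal prior evaluated pointwise. On the
toy instances used in the tests the reduced and unreduced values agree to
better than 1e-8. (A tensor Gauss–Hermite rule was tried first and converges
too slowly here: at strongly negative `a` the conditional density becomes a
sharp spike in `upsilon` that Hermite nodes cannot resolve.)

## Estimation

Optimization runs on an unconstrained scale: alpha and tau are already
log-linear coefficients, `phi_a` enters as its log, correlations as atanh,
uniquenesses as logs. L-BFGS-B with finite-difference gradients: forward
differences during the search pass, central differences in a polish pass from
the first optimum (identical optima, about half the runtime of a pure
central-difference search). Convergence requires optimizer success or a
gradient max-norm below 1e-3; a fit that exhausts the iteration cap is
flagged unconverged. A refit from a fitted solution reproduces the
log-likelihood to 1e-8.

Starting values are staged, mirroring how these models are fit in practice:

1. closed-form fixed-effects start (pooled OLS; for latent models a
   configural one-factor analysis supplies measurement values, with the
   factor variance split evenly between trait and state as a crude start);
2. a fit with the random scale effect frozen at zero;
3. `phi_a` freed at 0.5 with zero correlation. Variance-model covariate
   coefficients always start at 0.

Standard errors come from the central-difference Hessian of the negative
log-likelihood at the optimum, inverted and mapped to the natural scale by a
numerical delta method; singular information yields NaN standard errors with
a warning rather than silent failure. Likelihood-ratio tests for the
scale-effect addition use the naive 2-df chi-square reference (boundary-
corrected mixtures are out of scope); AIC = deviance + 2k and
BIC = deviance + k log N with N the subject count.

Invariance testing fits the ladder configural → equal loadings → equal
intercepts → equal both → equal uniquenesses, each as a measurement model
over an intercept-only random-intercept structural model without a random
scale effect (the structural model at the invariance stage is a modelling
choice; it is configurable by fitting any measurement spec directly). LRT
degrees of freedom are free-parameter-count differences from the constraint
maps; for the 5-item/8-day design the ladder reproduces dfs 28/27/53/35
(with the corresponding freed intercept cells).

## Empirical Bayes prediction

Posterior summaries reuse the estimation grid: posterior weights over `a`
are prior quadrature weights times the subject's conditional density,
renormalized; within each node the location effects update by the
linear-Gaussian (BLUP) formula, and node summaries are mixed by the posterior
weights. Summaries are posterior **means** (so labelled; modes are not
computed). Conditional residuals are observed responses minus fitted means at
the posterior means of both effects. Checks: exact agreement with the
closed-form random-intercept BLUP in the no-scale-effect limit, agreement to
1e-4 with a dense 2-D grid posterior on toys, shrinkage (posterior SD below
prior SD for any subject with data), and recovery of simulated scale effects
that improves with the number of occasions.

## Synthetic data

The simulator draws from the exact generative model: joint normal
`(upsilon_i, a_i)` (degenerate components allowed via an eigenvalue square
root), occasion residuals with variance `exp{tau'v + a_i}`, then items
through the measurement model. It emulates a daily-diary design: several
hundred subjects, about 8 days, 5 items on a 0–4 response scale treated as
continuous, and a daily stressor count. Defaults follow the published study
design (435 subjects, 8 occasions). Stressor counts are a subject-level
gamma-frailty Poisson truncated to [0, 7], calibrated so subjects' mean
daily counts have mean ≈ 0.53 and SD ≈ 0.42 across subjects (the published
summary statistics; the distributional form is our choice since only those
moments are reported). Continuous responses are *not* clipped to the 0–4
scale by default — the fitted model is normal-theory — but a clipping flag
exists to study ceiling effects.

What the simulator does not emulate: ordinal item scales (responses are
continuous), systematic time trends, non-MAR missingness, and serially
correlated occasion residuals. Passing recovery tests therefore show
correctness of the estimator under the model's own assumptions, not
robustness of the model to real diary data's discreteness or dynamics.

## Numerical choices and limitations

* Quadrature: 10 points by default (a config knob). Accuracy of nonadaptive
  Gauss–Hermite degrades as `phi_a` and the per-subject information grow
  (the integrand peaks far from the prior scale). On a small latent toy with
  `phi_a = 0.6` the 10- vs 30-point log-likelihoods agree to 1e-6; at
  `phi_a = 1.4` with 40 observations per subject they differ by ~0.2, and at
  10 points the manifest-model `phi_a` estimate carries a visible
  (~1%) integration bias that disappears by 20–30 points. Simulation studies
  that compare estimates to truth therefore run the manifest model at 30
  points; the latent model is smoother (measurement error flattens the
  integrand) and is run at 10. Adaptive quadrature is out of scope.
* PSD tolerance: conditional covariances tolerate eigenvalues down to −1e−10
  (clipped to zero); non-PD assemblies are rejected with the offending
  eigenvalue reported.
* Parameter-recovery studies use 50 replicates of N = 400 subjects × 8
  occasions (× 5 items in latent mode) and require every natural-scale
  parameter's mean bias within 3 Monte-Carlo standard errors — with 18
  parameters this criterion has a nonzero false-alarm rate by construction.
  Replicate fits are warm-started from the previous optimum (the ML optimum
  does not depend on the start; verified by the fixed-point test).
* Problem sizes in the test suite (toy instances of N ≤ 5 subjects for
  oracle comparisons, N in the hundreds for recovery) were chosen to make
  the oracles exact and the Monte-Carlo error calibrated, with the full
  435 × 8 × 5 default design exercised through the simulator's defaults.
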