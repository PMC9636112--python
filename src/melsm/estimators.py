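"""Scikit-learn style estimators for mixed-effects location scale models.

:class:`MELSM` fits the manifest model to a long-format DataFrame and
:class:`LatentMELSM` the second-order latent-variable extension to item-level
data.  Both follow the sklearn estimator contract — keyword-only constructor
parameters, ``fit``/``predict``, ``get_params``/``set_params``, fitted
attributes with a trailing underscore — so they compose with sklearn's
cloning and model-selection machinery; the module-level functions in
``inference`` remain the underlying engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import (
    BetweenVarSpec,
    DiaryDataset,
    LocationSpec,
    ModelSpec,
    WithinVarSpec,
)
from .empirical_bayes import eb_estimates
from .inference import fit_ml
from .measurement import MeasurementSpec

__all__ = ["MELSM", "LatentMELSM"]


class MELSM(BaseEstimator):
    """Mixed-effects location scale model for a manifest repeated measure.

    Parameters
    ----------
    x_terms, w_terms, random
        Mean-structure terms: occasion-varying regressor column names (the
        literal "1" is the intercept), subject-level regressor names, and the
        subset of ``x_terms`` with random subject effects.
    between_var_terms
        Subject-level regressors of the log random-effect variance.
    within_var_x_terms, within_var_w_terms
        Regressors of the log occasion-level residual variance.
    random_scale
        Include the random subject effect a_i in the residual-variance model.
    n_quad
        Gauss-Hermite points for the marginal-likelihood integral.
    """

    def __init__(
        self,
        *,
        x_terms=("1",),
        w_terms=(),
        random=("1",),
        between_var_terms=(),
        within_var_x_terms=(),
        within_var_w_terms=(),
        random_scale=True,
        n_quad=10,
        subject_col="subject",
        occasion_col="occasion",
        outcome_col="y",
        compute_se=True,
        optimizer_options=None,
    ):
        self.x_terms = x_terms
        self.w_terms = w_terms
        self.random = random
        self.between_var_terms = between_var_terms
        self.within_var_x_terms = within_var_x_terms
        self.within_var_w_terms = within_var_w_terms
        self.random_scale = random_scale
        self.n_quad = n_quad
        self.subject_col = subject_col
        self.occasion_col = occasion_col
        self.outcome_col = outcome_col
        self.compute_se = compute_se
        self.optimizer_options = optimizer_options

    # -- spec/data assembly ------------------------------------------------
    def _measurement_spec(self):
        return None

    def build_model_spec(self) -> ModelSpec:
        return ModelSpec(
            location=LocationSpec(
                x_terms=tuple(self.x_terms),
                w_terms=tuple(self.w_terms),
                random=tuple(self.random),
            ),
            between_var=BetweenVarSpec(terms=tuple(self.between_var_terms)),
            within_var=WithinVarSpec(
                x_terms=tuple(self.within_var_x_terms),
                w_terms=tuple(self.within_var_w_terms),
                random_scale=self.random_scale,
            ),
            measurement=self._measurement_spec(),
        )

    def _dataset(self, X) -> DiaryDataset:
        if isinstance(X, DiaryDataset):
            return X
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a long-format DataFrame or DiaryDataset")
        return DiaryDataset(
            X,
            subject_col=self.subject_col,
            occasion_col=self.occasion_col,
            outcome_col=self.outcome_col,
        )

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None, start=None):
        """Fit by marginal maximum likelihood. ``y`` is ignored (outcome is a
        column of ``X``)."""
        data = self._dataset(X)
        spec = self.build_model_spec()
        result = fit_ml(
            data,
            spec,
            start=start,
            n_quad=self.n_quad,
            compute_se=self.compute_se,
            options=self.optimizer_options,
        )
        self.result_ = result
        self.params_ = result.estimates
        self.se_ = dict(zip(result.natural_names, result.se))
        self.coef_ = dict(zip(result.natural_names, result.natural_estimates))
        self.loglik_ = result.loglik
        self.deviance_ = result.deviance
        self.aic_ = result.aic
        self.bic_ = result.bic
        self.n_params_ = result.n_params
        self.converged_ = result.converged
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("this estimator is not fitted yet; call fit first")

    def random_effects(self, X):
        """Empirical Bayes posterior summaries for the subjects in ``X``."""
        self._check_fitted()
        return eb_estimates(self.result_, self._dataset(X))

    def predict(self, X):
        """Fitted responses at the empirical Bayes posterior means, row-aligned
        with the observed rows of ``X`` (long format)."""
        self._check_fitted()
        data = self._dataset(X)
        eb = eb_estimates(self.result_, data)
        res = eb.residuals.set_index(["subject_id", "occasion", "variable"])["residual"]
        rows = []
        for _, row in data.frame.iterrows():
            for col in data.value_cols:
                key = (row[data.subject_col], int(row[data.occasion_col]), col)
                obs = row[col]
                rows.append(obs - res[key] if key in res.index and np.isfinite(obs) else np.nan)
        out = np.array(rows, dtype=float)
        return out if data.is_latent else out.reshape(-1)

    def score(self, X, y=None):
        """Average per-subject log marginal likelihood under the fitted model."""
        self._check_fitted()
        from .likelihood import LikelihoodEngine, QuadratureRule

        data = self._dataset(X)
        engine = LikelihoodEngine(
            data, self.result_.spec, QuadratureRule.gauss_hermite(self.n_quad)
        )
        return engine.loglik(self.params_) / data.n_subjects

    def summary(self) -> str:
        self._check_fitted()
        return self.result_.summary()


class LatentMELSM(MELSM):
    """Latent-variable (second-order) mixed-effects location scale model.

    The repeated measure is an occasion-specific latent score indicated by
    ``item_cols`` through a longitudinal factor model; the structural
    parameters then follow the same location scale model as :class:`MELSM`.
    The anchor item (first of ``item_cols`` by default) has loading 1 and
    intercept 0 at every occasion.  By default intercepts, loadings and
    uniquenesses are equal by item across occasions; pass a full
    :class:`MeasurementSpec` as ``measurement`` to override (e.g. freed cells).
    """

    def __init__(
        self,
        *,
        item_cols=("item1", "item2", "item3", "item4", "item5"),
        n_occasions=8,
        anchor=0,
        equal_loadings=True,
        equal_intercepts=True,
        equal_uniquenesses=True,
        measurement=None,
        x_terms=("1",),
        w_terms=(),
        random=("1",),
        between_var_terms=(),
        within_var_x_terms=(),
        within_var_w_terms=(),
        random_scale=True,
        n_quad=10,
        subject_col="subject",
        occasion_col="occasion",
        compute_se=True,
        optimizer_options=None,
    ):
        super().__init__(
            x_terms=x_terms,
            w_terms=w_terms,
            random=random,
            between_var_terms=between_var_terms,
            within_var_x_terms=within_var_x_terms,
            within_var_w_terms=within_var_w_terms,
            random_scale=random_scale,
            n_quad=n_quad,
            subject_col=subject_col,
            occasion_col=occasion_col,
            outcome_col=None,
            compute_se=compute_se,
            optimizer_options=optimizer_options,
        )
        self.item_cols = item_cols
        self.n_occasions = n_occasions
        self.anchor = anchor
        self.equal_loadings = equal_loadings
        self.equal_intercepts = equal_intercepts
        self.equal_uniquenesses = equal_uniquenesses
        self.measurement = measurement

    def _measurement_spec(self) -> MeasurementSpec:
        if self.measurement is not None:
            return self.measurement
        return MeasurementSpec.invariant(
            len(self.item_cols),
            self.n_occasions,
            anchor=self.anchor,
            equal_loadings=self.equal_loadings,
            equal_intercepts=self.equal_intercepts,
            equal_uniquenesses=self.equal_uniquenesses,
        )

    def _dataset(self, X) -> DiaryDataset:
        if isinstance(X, DiaryDataset):
            return X
        return DiaryDataset(
            X,
            subject_col=self.subject_col,
            occasion_col=self.occasion_col,
            outcome_col=None,
            item_cols=tuple(self.item_cols),
        )
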