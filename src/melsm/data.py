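"""Long-format diary data: container, CSV I/O, centering, and design assembly.

The data model is deliberately simple: one :class:`DiaryDataset` wraps a long
pandas DataFrame (one row per subject x occasion) together with the column
names that give it meaning.  A dataset is either *manifest* (a single outcome
column) or *latent* (several item-response columns measuring one construct per
occasion).  Occasions are 1-based integer indices, unique within subject, and
need not be contiguous: the models here carry no time trend, so only row
membership matters.  Missing outcome/item cells are retained as NaN and masked
at likelihood time (missing-at-random is assumed throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DiaryDataset",
    "LocationSpec",
    "BetweenVarSpec",
    "WithinVarSpec",
    "ModelSpec",
    "DesignMatrices",
    "SubjectDesign",
    "read_long_csv",
    "write_long_csv",
    "person_mean_center",
    "build_designs",
]

INTERCEPT = "1"


@dataclass(frozen=True)
class DiaryDataset:
    """Long-format repeated-measures data grouped by subject.

    Parameters
    ----------
    frame
        Long table, one row per (subject, occasion).
    subject_col, occasion_col
        Grouping columns.  Occasions are integer, unique within subject.
    outcome_col
        Outcome column for manifest data; ``None`` for item-level data.
    item_cols
        Item-response columns for latent data; empty for manifest data.
    """

    frame: pd.DataFrame
    subject_col: str = "subject"
    occasion_col: str = "occasion"
    outcome_col: str | None = "y"
    item_cols: tuple[str, ...] = ()

    def __post_init__(self):
        frame = self.frame
        for col in (self.subject_col, self.occasion_col):
            if col not in frame.columns:
                raise ValueError(f"column {col!r} not in data ({list(frame.columns)})")
        if self.item_cols:
            missing = [c for c in self.item_cols if c not in frame.columns]
            if missing:
                raise ValueError(f"item columns not in data: {missing}")
        elif self.outcome_col is None:
            raise ValueError("need either outcome_col or item_cols")
        elif self.outcome_col not in frame.columns:
            raise ValueError(f"outcome column {self.outcome_col!r} not in data")
        dup = frame.duplicated([self.subject_col, self.occasion_col])
        if dup.any():
            keys = frame.loc[dup, [self.subject_col, self.occasion_col]]
            raise ValueError(
                "duplicate (subject, occasion) rows: "
                + ", ".join(f"({r[0]}, {r[1]})" for r in keys.itertuples(index=False))
            )
        for col in self.value_cols:
            if not pd.api.types.is_numeric_dtype(frame[col]):
                raise ValueError(f"non-numeric response column {col!r}")
        # canonical row order: by subject (first appearance), then occasion
        order = pd.Categorical(
            frame[self.subject_col], categories=frame[self.subject_col].unique()
        )
        idx = frame.assign(_subj=order).sort_values(
            ["_subj", self.occasion_col], kind="stable"
        ).index
        object.__setattr__(self, "frame", frame.loc[idx].reset_index(drop=True))

    @property
    def is_latent(self) -> bool:
        return bool(self.item_cols)

    @property
    def value_cols(self) -> tuple[str, ...]:
        return self.item_cols if self.item_cols else (self.outcome_col,)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame[self.subject_col].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_frames(self):
        """Yield (subject_id, sub-frame) in canonical order."""
        for sid, grp in self.frame.groupby(self.subject_col, sort=False):
            yield sid, grp

    def with_frame(self, frame: pd.DataFrame) -> "DiaryDataset":
        return replace(self, frame=frame)

    def equals(self, other: "DiaryDataset") -> bool:
        cols = [self.subject_col, self.occasion_col, *self.value_cols]
        extra = [c for c in self.frame.columns if c not in cols]
        if set(self.frame.columns) != set(other.frame.columns):
            return False
        a = self.frame[cols + extra]
        b = other.frame[cols + extra]
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=False)
        except AssertionError:
            return False
        return True


@dataclass(frozen=True)
class LocationSpec:
    """Mean-structure submodel: fixed effects and which of them are random.

    ``x_terms`` are occasion-varying regressor names (the literal ``"1"``
    denotes the intercept), ``w_terms`` are subject-level regressor names, and
    ``random`` is the subset of ``x_terms`` carrying random subject effects.
    """

    x_terms: tuple[str, ...] = (INTERCEPT,)
    w_terms: tuple[str, ...] = ()
    random: tuple[str, ...] = (INTERCEPT,)

    def __post_init__(self):
        object.__setattr__(self, "x_terms", tuple(self.x_terms))
        object.__setattr__(self, "w_terms", tuple(self.w_terms))
        object.__setattr__(self, "random", tuple(self.random))
        bad = [t for t in self.random if t not in self.x_terms]
        if bad:
            raise ValueError(f"random terms {bad} not among x_terms {self.x_terms}")

    @property
    def p(self) -> int:
        return len(self.x_terms)

    @property
    def q(self) -> int:
        return len(self.w_terms)

    @property
    def p_star(self) -> int:
        return len(self.random)

    @property
    def random_indices(self) -> tuple[int, ...]:
        return tuple(self.x_terms.index(t) for t in self.random)


@dataclass(frozen=True)
class BetweenVarSpec:
    """Log-linear model for the random-effect (between-subject) variance.

    The intercept is always present; ``terms`` are additional subject-level
    regressors, so the variance of each random location effect is
    ``exp{alpha_0 + alpha' w}``.
    """

    terms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def n_coef(self) -> int:
        return 1 + len(self.terms)


@dataclass(frozen=True)
class WithinVarSpec:
    """Log-linear model for the occasion-level residual variance.

    ``exp{tau_0 + tau_x' x_ti + tau_w' w_i + a_i}`` with the random scale
    effect a_i included when ``random_scale`` is true.
    """

    x_terms: tuple[str, ...] = ()
    w_terms: tuple[str, ...] = ()
    random_scale: bool = True

    def __post_init__(self):
        object.__setattr__(self, "x_terms", tuple(self.x_terms))
        object.__setattr__(self, "w_terms", tuple(self.w_terms))

    @property
    def n_coef(self) -> int:
        return 1 + len(self.x_terms) + len(self.w_terms)


@dataclass(frozen=True)
class ModelSpec:
    """Bundle of the structural submodels (plus measurement model if latent)."""

    location: LocationSpec = field(default_factory=LocationSpec)
    between_var: BetweenVarSpec = field(default_factory=BetweenVarSpec)
    within_var: WithinVarSpec = field(default_factory=WithinVarSpec)
    measurement: "object | None" = None  # MeasurementSpec, kept untyped to avoid cycle

    @property
    def is_latent(self) -> bool:
        return self.measurement is not None


@dataclass(frozen=True)
class SubjectDesign:
    """Design matrices for one subject (row counts equal n_i observed occasions)."""

    subject_id: object
    occasions: np.ndarray  # (n_i,)
    y: np.ndarray  # (n_i,) manifest or (n_i, M) latent, NaN for missing
    Gamma: np.ndarray  # (n_i, p+q) stacked [x_ti, w_i]
    Z: np.ndarray  # (n_i, p*) random-effect columns of Gamma
    V: np.ndarray  # (n_i, n_wv) within-variance design rows
    B: np.ndarray  # (n_bv,) between-variance design row


@dataclass(frozen=True)
class DesignMatrices:
    subjects: tuple[SubjectDesign, ...]

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


def read_long_csv(
    path,
    *,
    subject_col: str = "subject",
    occasion_col: str = "occasion",
    outcome_col: str | None = "y",
    item_cols: tuple[str, ...] = (),
) -> DiaryDataset:
    """Read a long-format CSV (comma separated, header required, NA/empty missing)."""
    frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    return DiaryDataset(
        frame,
        subject_col=subject_col,
        occasion_col=occasion_col,
        outcome_col=None if item_cols else outcome_col,
        item_cols=tuple(item_cols),
    )


def write_long_csv(data: DiaryDataset, path) -> None:
    data.frame.to_csv(path, index=False, na_rep="NA")


def person_mean_center(
    data: DiaryDataset,
    column: str,
    *,
    centered_col: str | None = None,
    mean_col: str | None = None,
) -> DiaryDataset:
    """Split an occasion-varying covariate into person-mean and centered parts.

    The person mean is taken over the subject's *observed* occasions; the
    centered column then sums to zero within every subject.  New columns
    default to ``<column>_pmc`` (centered) and ``<column>_pm`` (person mean).
    """
    if column not in data.frame.columns:
        raise KeyError(f"column {column!r} not in data")
    centered_col = centered_col or f"{column}_pmc"
    mean_col = mean_col or f"{column}_pm"
    frame = data.frame.copy()
    pm = frame.groupby(data.subject_col, sort=False)[column].transform("mean")
    frame[mean_col] = pm
    frame[centered_col] = frame[column] - pm
    return data.with_frame(frame)


def _resolve_x(term: str, grp: pd.DataFrame, available) -> np.ndarray:
    if term == INTERCEPT:
        return np.ones(len(grp))
    if term not in grp.columns:
        raise KeyError(f"unknown term {term!r}; available columns: {sorted(available)}")
    vals = grp[term].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(f"missing values in covariate {term!r}")
    return vals


def _resolve_w(term: str, grp: pd.DataFrame, available) -> float:
    if term == INTERCEPT:
        return 1.0
    vals = _resolve_x(term, grp, available)
    if len(vals) > 1 and np.ptp(vals) > 1e-10 * max(1.0, np.abs(vals).max()):
        sid = grp.iloc[0, grp.columns.get_loc(term)]
        raise ValueError(
            f"subject-level term {term!r} is not constant within subject"
        )
    return float(vals[0])


def build_designs(data: DiaryDataset, spec: ModelSpec) -> DesignMatrices:
    """Assemble per-subject design matrices for a model specification.

    Column order is fixed by the packed parameter layout: Gamma holds the
    occasion-varying terms then the subject-level terms; V holds the
    within-variance intercept, occasion-varying terms, then subject-level
    terms; B holds the between-variance intercept then its terms.
    """
    loc, bv, wv = spec.location, spec.between_var, spec.within_var
    available = set(data.frame.columns)
    subjects = []
    for sid, grp in data.subject_frames():
        n = len(grp)
        X = np.column_stack([_resolve_x(t, grp, available) for t in loc.x_terms])
        W = np.array([_resolve_w(t, grp, available) for t in loc.w_terms])
        Gamma = np.hstack([X, np.tile(W, (n, 1))]) if loc.w_terms else X
        Z = X[:, list(loc.random_indices)]
        v_cols = [np.ones(n)]
        v_cols += [_resolve_x(t, grp, available) for t in wv.x_terms]
        v_cols += [np.full(n, _resolve_w(t, grp, available)) for t in wv.w_terms]
        V = np.column_stack(v_cols)
        B = np.array([1.0] + [_resolve_w(t, grp, available) for t in bv.terms])
        if data.is_latent:
            y = grp[list(data.item_cols)].to_numpy(dtype=float)
        else:
            y = grp[data.outcome_col].to_numpy(dtype=float)
        subjects.append(
            SubjectDesign(
                subject_id=sid,
                occasions=grp[data.occasion_col].to_numpy(),
                y=y,
                Gamma=Gamma,
                Z=Z,
                V=V,
                B=B,
            )
        )
    return DesignMatrices(tuple(subjects))
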