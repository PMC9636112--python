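"""Longitudinal measurement (confirmatory factor) model with invariance maps.

Each occasion's item responses load on that occasion's latent score through a
common item vector: the anchor item has intercept fixed at 0 and loading fixed
at 1 at every occasion, which gives the latent variable its scale over time.
Equality of intercepts, loadings, and uniquenesses across occasions is encoded
by *constraint maps*: an item-by-occasion grid of parameter labels where cells
sharing a label share a parameter and ``None`` marks a fixed anchor cell.
Freed cells (partial invariance) simply receive their own label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeasurementSpec",
    "MeasurementParams",
    "build_lambda",
    "pack_measurement",
    "unpack_measurement",
    "free_parameter_count",
    "invariance_sequence",
]

Map = tuple[tuple[object, ...], ...]  # (n_items, n_occasions) grid of labels/None


def _grid(n_items, n_occasions, fn):
    return tuple(tuple(fn(m, t) for t in range(n_occasions)) for m in range(n_items))


@dataclass(frozen=True)
class MeasurementSpec:
    """Item-by-occasion constraint maps for intercepts, loadings, uniquenesses.

    Build instances with :meth:`invariant` or :meth:`configural`; pass
    ``free_intercepts``/``free_loadings`` cells (0-based ``(item, occasion)``)
    to relax invariance for individual cells.
    """

    n_items: int
    n_occasions: int
    anchor: int = 0
    intercept_map: Map = ()
    loading_map: Map = ()
    uniqueness_map: Map = ()

    def __post_init__(self):
        for name in ("intercept_map", "loading_map", "uniqueness_map"):
            grid = getattr(self, name)
            if len(grid) != self.n_items or any(
                len(row) != self.n_occasions for row in grid
            ):
                raise ValueError(f"{name} must be an {self.n_items} x {self.n_occasions} grid")
        for t in range(self.n_occasions):
            if self.intercept_map[self.anchor][t] is not None:
                raise ValueError("anchor intercept must be fixed (None) at every occasion")
            if self.loading_map[self.anchor][t] is not None:
                raise ValueError("anchor loading must be fixed (None) at every occasion")
        if any(cell is None for row in self.uniqueness_map for cell in row):
            raise ValueError("uniquenesses carry no fixed cells; label every cell")

    # -- factories ---------------------------------------------------------
    @classmethod
    def invariant(
        cls,
        n_items: int,
        n_occasions: int,
        *,
        anchor: int = 0,
        equal_loadings: bool = True,
        equal_intercepts: bool = True,
        equal_uniquenesses: bool = False,
        free_intercepts: tuple[tuple[int, int], ...] = (),
        free_loadings: tuple[tuple[int, int], ...] = (),
    ) -> "MeasurementSpec":
        """Invariance pattern with optional freed cells.

        With everything equal by item across occasions, a 5-item/8-day design
        has 4 intercepts + 4 loadings + 5 uniquenesses = 13 free measurement
        parameters.
        """
        free_i, free_l = set(free_intercepts), set(free_loadings)

        def tau_label(m, t):
            if m == anchor:
                return None
            if not equal_intercepts or (m, t) in free_i:
                return f"nu[{m},{t}]"
            return f"nu[{m}]"

        def lam_label(m, t):
            if m == anchor:
                return None
            if not equal_loadings or (m, t) in free_l:
                return f"lambda[{m},{t}]"
            return f"lambda[{m}]"

        def psi_label(m, t):
            return f"psi[{m}]" if equal_uniquenesses else f"psi[{m},{t}]"

        return cls(
            n_items,
            n_occasions,
            anchor=anchor,
            intercept_map=_grid(n_items, n_occasions, tau_label),
            loading_map=_grid(n_items, n_occasions, lam_label),
            uniqueness_map=_grid(n_items, n_occasions, psi_label),
        )

    @classmethod
    def configural(cls, n_items: int, n_occasions: int, *, anchor: int = 0):
        """No cross-occasion equality constraints (anchor cells still fixed)."""
        return cls.invariant(
            n_items,
            n_occasions,
            anchor=anchor,
            equal_loadings=False,
            equal_intercepts=False,
            equal_uniquenesses=False,
        )

    # -- label bookkeeping -------------------------------------------------
    def _labels(self, grid: Map) -> tuple[object, ...]:
        seen: dict = {}
        for t in range(self.n_occasions):
            for m in range(self.n_items):
                lab = grid[m][t]
                if lab is not None and lab not in seen:
                    seen[lab] = len(seen)
        return tuple(seen)

    @property
    def intercept_labels(self):
        return self._labels(self.intercept_map)

    @property
    def loading_labels(self):
        return self._labels(self.loading_map)

    @property
    def uniqueness_labels(self):
        return self._labels(self.uniqueness_map)

    @property
    def n_free(self) -> int:
        return (
            len(self.intercept_labels)
            + len(self.loading_labels)
            + len(self.uniqueness_labels)
        )


@dataclass(frozen=True)
class MeasurementParams:
    """Full (n_items, n_occasions) parameter tables on the natural scale."""

    tau: np.ndarray
    lam: np.ndarray
    psi: np.ndarray


def _expand(grid: Map, labels, values, fixed_value) -> np.ndarray:
    lut = dict(zip(labels, values))
    return np.array(
        [[fixed_value if cell is None else lut[cell] for cell in row] for row in grid],
        dtype=float,
    )


def pack_measurement(spec: MeasurementSpec, params: MeasurementParams) -> np.ndarray:
    """Extract the free-parameter vector (tau block, lambda block, psi block).

    Cells sharing a label must agree in ``params``; the representative value
    is taken from the label's first cell in column-major (occasion) order.
    """
    out = []
    for grid, labels, table in (
        (spec.intercept_map, spec.intercept_labels, params.tau),
        (spec.loading_map, spec.loading_labels, params.lam),
        (spec.uniqueness_map, spec.uniqueness_labels, params.psi),
    ):
        vals = {}
        for t in range(spec.n_occasions):
            for m in range(spec.n_items):
                lab = grid[m][t]
                if lab is not None and lab not in vals:
                    vals[lab] = table[m, t]
        out.append([vals[lab] for lab in labels])
    return np.concatenate([np.asarray(v, float) for v in out])


def unpack_measurement(vector: np.ndarray, spec: MeasurementSpec) -> MeasurementParams:
    """Inverse of :func:`pack_measurement`; fixed cells get 0 (tau) and 1 (lambda)."""
    vector = np.asarray(vector, float).ravel()
    if len(vector) != spec.n_free:
        raise ValueError(f"expected {spec.n_free} free parameters, got {len(vector)}")
    n_t, n_l = len(spec.intercept_labels), len(spec.loading_labels)
    tau = _expand(spec.intercept_map, spec.intercept_labels, vector[:n_t], 0.0)
    lam = _expand(spec.loading_map, spec.loading_labels, vector[n_t : n_t + n_l], 1.0)
    psi = _expand(spec.uniqueness_map, spec.uniqueness_labels, vector[n_t + n_l :], np.nan)
    return MeasurementParams(tau, lam, psi)


def free_parameter_count(spec: MeasurementSpec) -> int:
    return spec.n_free


def build_lambda(
    spec: MeasurementSpec,
    lam: np.ndarray,
    occasions_present=None,
    item_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Block-diagonal loading matrix for one subject.

    ``lam`` is the full (n_items, n_occasions) loading table.  Rows are
    ordered occasion-major (occasion 1 items, occasion 2 items, ...); each
    occasion block places its item-loading column in that occasion's column.
    ``item_mask`` is an (n_occasions, n_items) boolean of observed cells;
    masked rows are removed.  Every retained occasion must observe the anchor.
    """
    lam = np.asarray(lam, float)
    occ = list(range(spec.n_occasions)) if occasions_present is None else list(occasions_present)
    T_i = len(occ)
    if item_mask is None:
        item_mask = np.ones((spec.n_occasions, spec.n_items), dtype=bool)
    rows = []
    for j, t in enumerate(occ):
        if not item_mask[t, spec.anchor]:
            raise ValueError(f"occasion {t} has no observed anchor item")
        for m in range(spec.n_items):
            if item_mask[t, m]:
                row = np.zeros(T_i)
                row[j] = lam[m, t]
                rows.append(row)
    return np.array(rows)


def invariance_sequence(data, n_items: int, n_occasions: int, fit_fn, *, anchor: int = 0):
    """Sequential invariance testing ladder.

    Fits configural, equal-loadings, equal-intercepts, equal-both, and
    equal-uniquenesses measurement models via ``fit_fn(data, spec)`` (which
    must return an object with ``deviance``, ``bic`` and ``n_params``) and
    reports the likelihood-ratio test of each against its reference model:
    the configural model for the first three restrictions, the equal-both
    model for the uniqueness restriction.  LRT degrees of freedom are the
    differences in free-parameter counts.
    """
    from .inference import lrt

    if n_occasions < 2:
        raise ValueError("invariance testing requires at least 2 occasions")
    mk = MeasurementSpec.invariant
    ladder = [
        ("configural", MeasurementSpec.configural(n_items, n_occasions, anchor=anchor), None),
        ("equal_loadings", mk(n_items, n_occasions, anchor=anchor, equal_intercepts=False), 0),
        ("equal_intercepts", mk(n_items, n_occasions, anchor=anchor, equal_loadings=False), 0),
        ("equal_loadings_intercepts", mk(n_items, n_occasions, anchor=anchor), 0),
        (
            "equal_uniquenesses",
            mk(n_items, n_occasions, anchor=anchor, equal_uniquenesses=True),
            3,
        ),
    ]
    rows = []
    fits = []
    for label, mspec, ref in ladder:
        fit = fit_fn(data, mspec)
        fits.append((mspec, fit))
        if ref is None:
            rows.append(
                {"model": label, "deviance": fit.deviance, "bic": fit.bic,
                 "lrt": None, "df": None, "p": None}
            )
        else:
            ref_spec, ref_fit = fits[ref]
            df = ref_spec.n_free - mspec.n_free
            if df < 0:
                raise ValueError(f"{label} is not nested in its reference model")
            stat, df_, p = lrt(fit.deviance, ref_fit.deviance, df)
            rows.append(
                {"model": label, "deviance": fit.deviance, "bic": fit.bic,
                 "lrt": stat, "df": df_, "p": p}
            )
    return rows
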