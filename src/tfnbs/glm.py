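"""Edge-wise general linear models for group contrasts.

Each connectome edge gets an ordinary-least-squares fit of its (log) weight
on an intercept, treatment-coded group indicators, and nuisance covariates
(age, sex by default). The tested quantity is a contrast ``c'beta`` with

    t_e = c'beta_e / sqrt(sigma_e^2 * c'(X'X)^{-1} c),   dof = n - rank(X)

assembled into a symmetric statistic graph. Subgroup analyses (e.g. seizure
history or cognitive-impairment clusters within patients) are the same
machinery with a different group column and level pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import CohortDataset

__all__ = ["DesignMatrix", "StatGraph", "build_design", "edge_tstats", "residualize_adjusted"]

logger = logging.getLogger(__name__)

#: cap applied to infinite / degenerate t-statistics so enhancement stays finite
T_CAP_DEFAULT = 1e6


@dataclass
class DesignMatrix:
    """Design for the edge-wise GLM plus the tested contrast.

    ``rows`` indexes the retained subjects in the originating covariate table
    (subjects outside the requested group levels are dropped).
    """

    X: np.ndarray  # (n_kept, p)
    columns: list
    contrast: np.ndarray  # (p,)
    rows: np.ndarray  # (n_kept,) int indices into the source covariates
    group_levels: tuple  # (reference, tested)
    permutation_block: np.ndarray = None  # exchangeability labels

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.shape[1] != len(self.contrast):
            raise ValueError("contrast length must equal design column count")
        if not np.any(self.contrast):
            raise ValueError("contrast must be nonzero")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if self.permutation_block is None:
            self.permutation_block = np.zeros(len(self.X), dtype=int)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def group_columns(self) -> np.ndarray:
        """Indices of the columns the contrast loads on (the tested effect)."""
        return np.flatnonzero(self.contrast)

    @property
    def nuisance_columns(self) -> np.ndarray:
        return np.flatnonzero(self.contrast == 0)


@dataclass
class StatGraph:
    """Symmetric matrix of per-edge t-statistics for one tested direction."""

    t: np.ndarray  # (n, n), zero off the edge support and on the diagonal
    dof: int
    direction: int = 1  # +1: contrast > 0 tested; -1: contrast < 0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if not np.allclose(self.t, self.t.T):
            raise ValueError("statistic matrix must be symmetric")
        if np.any(np.diag(self.t) != 0):
            raise ValueError("statistic matrix must have zero diagonal")


def build_design(
    covariates: pd.DataFrame,
    group_column: str = "group",
    levels: tuple | None = None,
    nuisance=("age", "sex"),
    contrast_spec: str = "pairwise",
) -> DesignMatrix:
    """Build an intercept + group + nuisance design with a pairwise contrast.

    ``levels=(reference, tested)`` selects the two compared levels (default:
    the sorted unique levels of ``group_column``, first as reference);
    subjects at other levels (or empty labels) are dropped and logged. Age is
    centered at the retained-sample mean; categorical nuisances are
    treatment-coded.
    """
    s = covariates[group_column].astype(str)
    present = sorted(v for v in pd.unique(s) if v != "" and v != "nan")
    if levels is None:
        levels = tuple(present)
    if len(levels) != 2:
        raise ValueError(
            f"exactly two group levels required for a pairwise contrast, got {levels}"
        )
    ref, tested = (str(levels[0]), str(levels[1]))
    for lev in (ref, tested):
        if (s == lev).sum() < 2:
            raise ValueError(f"group level {lev!r} has fewer than 2 subjects")
    keep = s.isin([ref, tested]).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "build_design: dropped %d subjects outside levels (%s, %s)",
            dropped, ref, tested,
        )
    rows = np.flatnonzero(keep)
    sub = covariates.iloc[rows]

    cols = [np.ones(len(rows))]
    names = ["intercept"]
    cols.append((sub[group_column].astype(str) == tested).to_numpy(float))
    names.append(f"{group_column}[{tested}]")
    for nc in nuisance:
        v = sub[nc]
        if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
            levs = sorted(pd.unique(v.astype(str)))
            for lev in levs[1:]:
                cols.append((v.astype(str) == lev).to_numpy(float))
                names.append(f"{nc}[{lev}]")
        else:
            x = v.to_numpy(float)
            if nc == "age":
                x = x - x.mean()  # centered: stabilizes the intercept
            cols.append(x)
            names.append(nc)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X, names, contrast, rows, (ref, tested))


def _tstat_vector(
    Y: np.ndarray, X: np.ndarray, contrast: np.ndarray, t_cap: float = T_CAP_DEFAULT
):
    """Vectorized OLS contrast t-statistics for all edges at once.

    Y: (m, n) edge values; returns (t (m,), dof). Zero-residual edges get
    ``+/- t_cap`` (with a warning upstream of enhancement).
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T  # (p, n)
    beta = proj @ Y.T  # (p, m)
    resid = Y.T - X @ beta  # (n, m)
    dof = n - p
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / dof  # (m,)
    cvar = float(contrast @ xtx_inv @ contrast)
    effect = contrast @ beta  # (m,)
    se = np.sqrt(sigma2 * cvar)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    degenerate = se == 0
    if degenerate.any():
        logger.warning(
            "%d edges with zero residual variance; t capped at %g",
            int(degenerate.sum()), t_cap,
        )
        t[degenerate] = np.sign(effect[degenerate]) * t_cap
        t[degenerate & (effect == 0)] = 0.0
    np.clip(t, -t_cap, t_cap, out=t)
    return t, dof


def edge_tstats(
    dataset: CohortDataset,
    design: DesignMatrix,
    direction: int = 1,
    t_cap: float = T_CAP_DEFAULT,
) -> StatGraph:
    """Per-edge GLM t-statistic graph for the design's contrast.

    ``direction=-1`` negates the contrast (tests the opposite tail); the
    returned matrix always holds ``direction * t`` so that positive entries
    are evidence for the tested direction.
    """
    Y = dataset.Y[:, design.rows]
    t, dof = _tstat_vector(Y, design.X, design.contrast * direction, t_cap=t_cap)
    return StatGraph(dataset.edge_matrix(t), dof=dof, direction=direction)


def residualize_adjusted(dataset: CohortDataset, design: DesignMatrix) -> np.ndarray:
    """Nuisance-adjusted edge values per subject (for box-plot style reporting).

    The nuisance coefficients are estimated with the group effect in the
    model; only the nuisance fit is removed and the grand mean re-added, so
    group differences of adjusted values equal the GLM group effect.
    Returns an (n_edges, n_kept_subjects) array aligned with ``design.rows``.
    """
    Y = dataset.Y[:, design.rows]
    X = design.X
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, m)
    nuis = design.nuisance_columns
    # keep the intercept: removing it would just shift everything to zero
    nuis = nuis[np.asarray(design.columns, dtype=object)[nuis] != "intercept"]
    nuis_fit = X[:, nuis] @ coef[nuis]  # (n, m)
    adjusted = Y.T - nuis_fit + nuis_fit.mean(axis=0, keepdims=True)
    return adjusted.T
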