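"""Batch harmonization of connectome edge weights.

Scanner or protocol changes shift the location and rescale the noise of
tractography-derived edge weights. This module removes those batch effects
from log-transformed edge values with a parametric empirical-Bayes
location/scale model (the ComBat family): per-edge batch effects are
estimated, shrunk toward batch-level priors fitted across edges, and removed
while the contributions of preserved covariates (group, age, sex) are kept
intact. The empirical-Bayes shrinkage is what makes the correction stable
when a batch holds few subjects.

The model for (log) edge value ``y_ge`` of subject ``g`` in batch ``b``::

    y_ge = alpha_e + x_g' beta_e + gamma_be + delta_be * eps_ge

``gamma`` (additive, on the bias) and ``delta`` (multiplicative, on the
variance) get conditional posterior means ``gamma*``, ``delta*`` under a
Normal and an inverse-gamma prior whose hyperparameters are moment-matched
across edges; harmonized data are::

    y_harm = (y_std - gamma*_be) / delta*_be * sigma_e + alpha_e + x_g' beta_e

with ``y_std`` the standardized residual data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import Parcellation

__all__ = [
    "CohortDataset",
    "HarmonizationModel",
    "ComBatConvergenceError",
    "EmptyDatasetError",
    "filter_edges",
    "log_transform",
    "vectorize_matrices",
    "build_dataset",
    "fit_combat",
    "apply_combat",
    "make_preserve_design",
]


class EmptyDatasetError(ValueError):
    """No edges survive filtering."""


class ComBatConvergenceError(RuntimeError):
    """Posterior-mean iteration failed to converge; carries the last iterates."""

    def __init__(self, message, gamma_star, delta_star_sq):
        super().__init__(message)
        self.gamma_star = gamma_star
        self.delta_star_sq = delta_star_sq


@dataclass
class CohortDataset:
    """Edge-by-subject value matrix plus covariates and parcellation.

    ``Y[k, s]`` is the value of edge ``edges[k] = (i, j)``, ``i < j``, for
    subject ``s`` (row ``s`` of ``covariates``). Values are on the log scale
    once :func:`log_transform` has been applied.
    """

    Y: np.ndarray  # (n_edges, n_subjects)
    edges: np.ndarray  # (n_edges, 2) int, i < j, lexicographic
    covariates: pd.DataFrame
    parcellation: Parcellation
    log_scale: bool = False

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        if self.Y.shape != (len(self.edges), len(self.covariates)):
            raise ValueError(
                f"Y shape {self.Y.shape} inconsistent with {len(self.edges)} "
                f"edges x {len(self.covariates)} subjects"
            )
        if len(self.edges) and not np.all(self.edges[:, 0] < self.edges[:, 1]):
            raise ValueError("edges must satisfy i < j")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            self.Y.copy(),
            self.edges.copy(),
            self.covariates.copy(),
            self.parcellation,
            self.log_scale,
        )

    def subset_subjects(self, rows) -> "CohortDataset":
        rows = np.asarray(rows)
        return CohortDataset(
            self.Y[:, rows],
            self.edges.copy(),
            self.covariates.iloc[rows].reset_index(drop=True),
            self.parcellation,
            self.log_scale,
        )

    def edge_matrix(self, values: np.ndarray) -> np.ndarray:
        """Scatter a per-edge vector into a symmetric node x node matrix."""
        n = self.parcellation.n_nodes
        mat = np.zeros((n, n), dtype=float)
        mat[self.edges[:, 0], self.edges[:, 1]] = values
        mat[self.edges[:, 1], self.edges[:, 0]] = values
        return mat


def filter_edges(matrices, min_prevalence: float = 1.0):
    """Retain upper-triangle edges nonzero in >= ``min_prevalence`` of subjects.

    Returns ``(edges, support_mask)``: the retained ``(i, j)`` pairs in
    lexicographic order and the symmetric boolean support matrix. Raises
    :class:`EmptyDatasetError` if nothing survives.
    """
    if not (0.0 <= min_prevalence <= 1.0):
        raise ValueError("min_prevalence must lie in [0, 1]")
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    n = stack.shape[1]
    prevalence = (stack != 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    iu, ju = np.triu_indices(n, k=1)
    sel = keep[iu, ju]
    edges = np.column_stack([iu[sel], ju[sel]])
    if len(edges) == 0:
        raise EmptyDatasetError(
            f"no edges reach prevalence {min_prevalence} across {len(matrices)} subjects"
        )
    support = np.zeros((n, n), dtype=bool)
    support[edges[:, 0], edges[:, 1]] = True
    support[edges[:, 1], edges[:, 0]] = True
    return edges, support


def vectorize_matrices(matrices, edges: np.ndarray) -> np.ndarray:
    """Stack per-subject matrices into an (n_edges, n_subjects) value matrix."""
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    return stack[:, edges[:, 0], edges[:, 1]].T


def log_transform(Y_raw: np.ndarray, offset: float | None = None) -> np.ndarray:
    """Elementwise natural log; ``offset`` is added to exact zeros only.

    With the default prevalence filter of 1.0 no zeros remain and no offset is
    needed; a zero entry with ``offset`` unset is an error.
    """
    Y_raw = np.asarray(Y_raw, dtype=float)
    if np.any(Y_raw < 0):
        raise ValueError("edge weights must be nonnegative")
    zeros = Y_raw == 0
    if zeros.any():
        if offset is None:
            raise ValueError(
                f"{int(zeros.sum())} zero entries present; pass a positive offset "
                "or filter edges at min_prevalence=1.0"
            )
        if offset <= 0:
            raise ValueError("offset must be > 0")
        Y_raw = np.where(zeros, offset, Y_raw)
    return np.log(Y_raw)


def build_dataset(
    matrices,
    covariates: pd.DataFrame,
    parcellation: Parcellation,
    min_prevalence: float = 1.0,
    log: bool = True,
    offset: float | None = None,
) -> CohortDataset:
    """Filter, vectorize, and (optionally) log-transform a cohort of SCMs."""
    if len(matrices) != len(covariates):
        raise ValueError("one matrix per covariate row required")
    edges, _ = filter_edges(matrices, min_prevalence)
    Y = vectorize_matrices(matrices, edges)
    if log:
        Y = log_transform(Y, offset=offset)
    return CohortDataset(Y, edges, covariates.reset_index(drop=True), parcellation, log_scale=log)


@dataclass
class HarmonizationModel:
    """Fitted batch location/scale effects and empirical-Bayes hyperpriors."""

    batches: list  # batch labels, fixed order
    batch_sizes: np.ndarray  # (B,)
    alpha_hat: np.ndarray  # (m,) grand intercept per edge
    beta_hat: np.ndarray  # (m, p) preserved-covariate coefficients
    pooled_var: np.ndarray  # (m,) residual variance per edge
    gamma_star: np.ndarray  # (B, m) posterior additive batch effects
    delta_star_sq: np.ndarray  # (B, m) posterior multiplicative effects (>0)
    gamma_hat: np.ndarray  # (B, m) naive standardized batch means
    delta_hat_sq: np.ndarray  # (B, m) naive standardized batch variances (MLE)
    hyperpriors: dict  # per batch: gamma_bar, tau_sq, lambda (shape), theta (scale)
    preserve_columns: list = field(default_factory=list)
    n_iter: int = 0

    @property
    def delta_star(self) -> np.ndarray:
        return np.sqrt(self.delta_star_sq)

    def to_dict(self) -> dict:
        return {
            "batches": [str(b) for b in self.batches],
            "batch_sizes": self.batch_sizes.tolist(),
            "alpha_hat": self.alpha_hat.tolist(),
            "beta_hat": self.beta_hat.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star_sq": self.delta_star_sq.tolist(),
            "hyperpriors": {
                str(b): {k: float(v) for k, v in hp.items()}
                for b, hp in self.hyperpriors.items()
            },
            "preserve_columns": list(self.preserve_columns),
            "n_iter": self.n_iter,
        }


def make_preserve_design(
    covariates: pd.DataFrame, columns=("group", "age", "sex")
) -> tuple[np.ndarray, list]:
    """Covariate design whose effects harmonization must preserve.

    Categorical columns are treatment-coded (first sorted level as reference);
    numeric columns enter as-is. No intercept: the batch indicators span it.
    """
    mats, names = [], []
    for col in columns:
        s = covariates[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                mats.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{col}[{lev}]")
        else:
            mats.append(s.to_numpy(float))
            names.append(col)
    X = np.column_stack(mats) if mats else np.empty((len(covariates), 0))
    return X, names


def _aprior_bprior(delta_hat_sq: np.ndarray):
    """Inverse-gamma hyperparameters by moment matching across edges.

    Degenerate case: if the across-edge variance of the naive batch variances
    is ~0 the prior collapses to a point mass; callers must special-case it.
    """
    m = float(np.mean(delta_hat_sq))
    s2 = float(np.var(delta_hat_sq, ddof=1)) if delta_hat_sq.size > 1 else 0.0
    if s2 <= 1e-12 * max(m * m, 1e-300):
        return None, None  # degenerate prior
    lam = (2.0 * s2 + m * m) / s2
    theta = (m * s2 + m**3) / s2
    return lam, theta


def fit_combat(
    dataset: CohortDataset,
    batch_labels=None,
    preserve_design: np.ndarray | None = None,
    preserve_columns=("group", "age", "sex"),
    tol: float = 1e-4,
    max_iter: int = 100,
) -> HarmonizationModel:
    """Fit the empirical-Bayes location/scale batch model.

    Steps: (1) per-edge least squares of the value on the preserved design
    plus batch indicators, with batch effects constrained to a size-weighted
    zero sum; (2) standardize residual data by the pooled residual SD;
    (3) naive per-batch per-edge means/variances of the standardized data;
    (4) moment-matched hyperpriors across edges; (5) iterate the conditional
    posterior means to convergence (max absolute change < ``tol`` on both
    ``gamma*`` and ``delta*^2``). ``max_iter=0`` returns the naive estimates.
    """
    Y = dataset.Y
    m, n = Y.shape
    if batch_labels is None:
        batch_labels = dataset.covariates["batch"].to_numpy()
    batch_labels = np.asarray(batch_labels)
    if len(batch_labels) != n:
        raise ValueError("batch_labels length must equal subject count")
    batches = sorted(pd.unique(batch_labels).tolist())
    B = len(batches)
    batch_onehot = np.column_stack([(batch_labels == b).astype(float) for b in batches])
    sizes = batch_onehot.sum(axis=0).astype(int)
    if np.any(sizes < 2):
        small = [b for b, s in zip(batches, sizes) if s < 2]
        raise ValueError(f"batches {small} have fewer than 2 subjects; variance undefined")

    if preserve_design is None:
        preserve_design, preserve_names = make_preserve_design(
            dataset.covariates, preserve_columns
        )
    else:
        preserve_design = np.asarray(preserve_design, dtype=float)
        preserve_names = [f"x{k}" for k in range(preserve_design.shape[1])]
    p = preserve_design.shape[1]

    design = np.column_stack([batch_onehot, preserve_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix (batch + preserved covariates) is rank deficient")

    # per-edge OLS, all edges at once: coef (B+p, m)
    coef, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    gamma_ols = coef[:B]  # batch-specific intercepts
    beta_hat = coef[B:].T  # (m, p)
    w = sizes / n
    alpha_hat = w @ gamma_ols  # size-weighted grand intercept per edge
    fitted = design @ coef  # (n, m)
    resid = Y.T - fitted
    pooled_var = np.mean(resid**2, axis=0)  # MLE over all subjects
    if np.any(pooled_var <= 0):
        raise ValueError("zero pooled residual variance on some edge")

    # standardized data: remove grand intercept + preserved effects only
    stand_mean = alpha_hat[None, :] + preserve_design @ beta_hat.T  # (n, m)
    Z = (Y.T - stand_mean) / np.sqrt(pooled_var)[None, :]  # (n, m)

    gamma_hat = np.empty((B, m))
    delta_hat_sq = np.empty((B, m))
    for bi in range(B):
        rows = batch_onehot[:, bi] == 1.0
        Zb = Z[rows]
        gamma_hat[bi] = Zb.mean(axis=0)
        delta_hat_sq[bi] = np.mean((Zb - gamma_hat[bi]) ** 2, axis=0)  # MLE (ddof=0)

    hyperpriors = {}
    gamma_star = gamma_hat.copy()
    delta_star_sq = delta_hat_sq.copy()
    n_iter_total = 0
    for bi, b in enumerate(batches):
        g_bar = float(np.mean(gamma_hat[bi]))
        tau_sq = float(np.var(gamma_hat[bi], ddof=1)) if m > 1 else 0.0
        lam, theta = _aprior_bprior(delta_hat_sq[bi])
        hyperpriors[b] = {
            "gamma_bar": g_bar,
            "tau_sq": tau_sq,
            "lambda": np.nan if lam is None else lam,
            "theta": np.nan if theta is None else theta,
        }
        if max_iter == 0:
            continue
        nb = sizes[bi]
        rows = batch_onehot[:, bi] == 1.0
        Zb = Z[rows]
        g_star = gamma_hat[bi].copy()
        d_star = delta_hat_sq[bi].copy()
        converged = False
        for it in range(1, max_iter + 1):
            if tau_sq > 1e-12:
                g_new = (nb * tau_sq * gamma_hat[bi] + d_star * g_bar) / (
                    nb * tau_sq + d_star
                )
            else:
                g_new = np.full(m, g_bar)
            ssq = np.sum((Zb - g_new[None, :]) ** 2, axis=0)
            if lam is None:
                d_new = delta_hat_sq[bi]
            else:
                d_new = (theta + 0.5 * ssq) / (nb / 2.0 + lam - 1.0)
            change = max(
                float(np.max(np.abs(g_new - g_star))),
                float(np.max(np.abs(d_new - d_star))),
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                converged = True
                n_iter_total = max(n_iter_total, it)
                break
        if not converged:
            raise ComBatConvergenceError(
                f"batch {b!r}: posterior-mean iteration did not converge in "
                f"{max_iter} iterations",
                g_star,
                d_star,
            )
        gamma_star[bi] = g_star
        delta_star_sq[bi] = d_star

    if np.any(delta_star_sq <= 0):
        raise ValueError("non-positive posterior batch variance")

    return HarmonizationModel(
        batches=batches,
        batch_sizes=sizes,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        pooled_var=pooled_var,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        gamma_hat=gamma_hat,
        delta_hat_sq=delta_hat_sq,
        hyperpriors=hyperpriors,
        preserve_columns=list(preserve_names),
        n_iter=n_iter_total,
    )


def apply_combat(
    model: HarmonizationModel,
    dataset: CohortDataset,
    batch_labels=None,
    preserve_design: np.ndarray | None = None,
    preserve_columns=("group", "age", "sex"),
) -> CohortDataset:
    """Remove fitted batch effects; preserved covariate effects are re-added."""
    Y = dataset.Y
    m, n = Y.shape
    if m != len(model.alpha_hat):
        raise ValueError("model fitted on a different edge set")
    if batch_labels is None:
        batch_labels = dataset.covariates["batch"].to_numpy()
    batch_labels = np.asarray(batch_labels)
    unseen = set(pd.unique(batch_labels)) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch labels {sorted(map(str, unseen))}")
    if preserve_design is None:
        preserve_design, _ = make_preserve_design(dataset.covariates, preserve_columns)
    else:
        preserve_design = np.asarray(preserve_design, dtype=float)

    stand_mean = model.alpha_hat[None, :] + preserve_design @ model.beta_hat.T  # (n, m)
    Z = (Y.T - stand_mean) / np.sqrt(model.pooled_var)[None, :]
    out = np.empty_like(Z)
    for bi, b in enumerate(model.batches):
        rows = batch_labels == b
        if not rows.any():
            continue
        out[rows] = (Z[rows] - model.gamma_star[bi][None, :]) / np.sqrt(
            model.delta_star_sq[bi]
        )[None, :]
    Y_harm = (out * np.sqrt(model.pooled_var)[None, :] + stand_mean).T
    result = dataset.copy()
    result.Y = Y_harm
    return result
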