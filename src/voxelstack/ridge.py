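"""First-level voxelwise ridge encoders.

Each feature space gets its own ridge model per voxel, with the penalty chosen
independently for every voxel by inner cross-validation over a log-spaced grid.
Fitting is vectorized over voxels and penalties by computing one spectral
factorization per training split and reusing it for every lambda and every
voxel: with ``X^T X = V diag(w) V^T``, the ridge solution at penalty ``lam``
is ``W(lam) = V diag(1/(w + lam)) V^T X^T Y`` for all voxels at once; when
the feature count exceeds the sample count the dual (Gram) form
``W(lam) = X^T (X X^T + lam I)^{-1} Y`` is used instead. Both are numerically
equivalent to solving ``(X^T X + lam I) w = X^T y`` per voxel, at a small
fraction of the cost.

Features and responses are mean-centered per training split; no intercept
column is penalized. Predictions add the training response means back.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from ._utils import DimensionError, ValidationError, kfold_indices
from .io import logger

__all__ = ["RidgeModel", "ridge_fit", "ridge_predict", "ridge_path"]


@dataclass
class RidgeModel:
    """Per-voxel ridge coefficients for one feature space.

    ``W`` is d x m (feature by voxel); ``lambda_per_voxel`` holds the grid
    value selected for each voxel. Means (and optional scales) are those of
    the training split and are reapplied at prediction time.
    """

    W: np.ndarray
    lambda_per_voxel: np.ndarray
    feature_means: np.ndarray
    response_means: np.ndarray
    feature_scales: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.W.shape[1]

    def save(self, group: h5py.Group) -> None:
        group.create_dataset("W", data=self.W)
        group.create_dataset("lambda", data=self.lambda_per_voxel)
        group.create_dataset("feature_means", data=self.feature_means)
        group.create_dataset("response_means", data=self.response_means)
        if self.feature_scales is not None:
            group.create_dataset("feature_scales", data=self.feature_scales)

    @classmethod
    def load(cls, group: h5py.Group) -> "RidgeModel":
        return cls(
            W=group["W"][()],
            lambda_per_voxel=group["lambda"][()],
            feature_means=group["feature_means"][()],
            response_means=group["response_means"][()],
            feature_scales=group["feature_scales"][()]
            if "feature_scales" in group
            else None,
        )


def _center(X: np.ndarray, Y: np.ndarray, standardize: bool):
    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    Xc = X - xm
    Yc = Y - ym
    scales = None
    if standardize:
        scales = Xc.std(axis=0)
        scales[scales == 0] = 1.0
        Xc = Xc / scales
    return Xc, Yc, xm, ym, scales


class _RidgeFactorization:
    """One spectral factorization of a training design, reused across the
    whole penalty grid and all voxels (primal d x d or dual n x n form)."""

    def __init__(self, Xc: np.ndarray):
        n, d = Xc.shape
        self.Xc = Xc
        self.primal = d <= n
        if self.primal:
            w, V = np.linalg.eigh(Xc.T @ Xc)
        else:
            w, V = np.linalg.eigh(Xc @ Xc.T)
        self.w = np.maximum(w, 0.0)  # PSD up to round-off
        self.V = V

    def basis_coeffs(self, Yc: np.ndarray) -> np.ndarray:
        """Response expressed in the factorization basis (r x m)."""
        if self.primal:
            return self.V.T @ (self.Xc.T @ Yc)
        return self.V.T @ Yc

    def weights(self, B: np.ndarray, lam: float) -> np.ndarray:
        """Coefficient matrix d x m at one penalty from basis coefficients."""
        Z = B / (self.w[:, None] + lam)
        if self.primal:
            return self.V @ Z
        return self.Xc.T @ (self.V @ Z)

    def val_projector(self, Xval_c: np.ndarray) -> np.ndarray:
        """Matrix P with validation predictions P @ (B / (w + lam))."""
        if self.primal:
            return Xval_c @ self.V
        return Xval_c @ self.Xc.T @ self.V


def ridge_path(Xc: np.ndarray, Yc: np.ndarray, lambdas) -> np.ndarray:
    """Ridge coefficients for every penalty at once from one factorization.

    Returns an array of shape (len(lambdas), d, m). ``Xc``/``Yc`` must
    already be centered.
    """
    fact = _RidgeFactorization(np.asarray(Xc, dtype=float))
    B = fact.basis_coeffs(np.asarray(Yc, dtype=float))
    return np.stack([fact.weights(B, lam) for lam in np.asarray(lambdas, dtype=float)])


def ridge_fit(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_grid=None,
    n_inner_folds: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> RidgeModel:
    """Fit per-voxel ridge models with the penalty chosen by inner CV.

    For each voxel the penalty minimizing the inner-CV mean squared error over
    the grid is selected (ties broken toward the larger, more regularized
    penalty); coefficients are then refit on the full centered data at the
    selected penalty.
    """
    from .io import DEFAULT_LAMBDA_GRID

    grid = np.sort(np.asarray(
        DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float
    ))
    if grid.size == 0 or np.any(grid <= 0):
        raise ValidationError("lambda_grid must be nonempty and positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = X.shape
    if Y.shape[0] != n:
        raise DimensionError(f"X has {n} rows but Y has {Y.shape[0]}")
    if n < n_inner_folds:
        raise ValidationError(
            f"cannot run {n_inner_folds}-fold inner CV on {n} samples"
        )
    m = Y.shape[1]

    constant = Y.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "%d constant response column(s); their coefficients will be zero",
            int(constant.sum()),
        )

    if grid.size == 1:
        lam_idx = np.zeros(m, dtype=int)
    else:
        sse = np.zeros((grid.size, m))
        for val in kfold_indices(n, n_inner_folds, seed):
            mask = np.ones(n, dtype=bool)
            mask[val] = False
            Xc, Yc, xm, ym, sc = _center(X[mask], Y[mask], standardize)
            Xv = X[val] - xm
            if sc is not None:
                Xv = Xv / sc
            fact = _RidgeFactorization(Xc)
            B = fact.basis_coeffs(Yc)
            P = fact.val_projector(Xv)
            for li, lam in enumerate(grid):
                pred = P @ (B / (fact.w[:, None] + lam)) + ym
                sse[li] += ((pred - Y[val]) ** 2).sum(axis=0)
        # ties toward larger lambda: scan the grid from the top
        lam_idx = grid.size - 1 - np.argmin(sse[::-1], axis=0)

    Xc, Yc, xm, ym, sc = _center(X, Y, standardize)
    fact = _RidgeFactorization(Xc)
    B = fact.basis_coeffs(Yc)
    W = np.empty((d, m))
    for lam in np.unique(grid[lam_idx]):
        cols = grid[lam_idx] == lam
        W[:, cols] = fact.weights(B[:, cols], lam)
    return RidgeModel(
        W=W,
        lambda_per_voxel=grid[lam_idx],
        feature_means=xm,
        response_means=ym,
        feature_scales=sc,
    )


def ridge_predict(model: RidgeModel, X: np.ndarray) -> np.ndarray:
    """Predict responses: centered X times W plus the training response means."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise DimensionError(
            f"model expects {model.n_features} features, got {X.shape[1]}"
        )
    Xc = X - model.feature_means
    if model.feature_scales is not None:
        Xc = Xc / model.feature_scales
    return Xc @ model.W + model.response_means
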