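"""Stacked regression over feature spaces: per-voxel convex combinations.

The stacked encoder predicts a voxel as ``yhat = sum_j alpha_j f_j(x_j)``,
where each ``f_j`` is a first-level ridge model for one feature space and the
weights ``alpha`` lie on the probability simplex (nonnegative, summing to 1).
The weights minimize the squared error of the combination on out-of-fold
first-level predictions, which reduces to the quadratic program

    min_alpha  alpha^T R alpha   s.t.  alpha >= 0,  sum(alpha) = 1,

with ``R`` the Gram matrix of out-of-fold residual vectors across feature
spaces: ``R[p, q] = sum_i (y_i - yhat_p_i)(y_i - yhat_q_i)``. Small diagonal
entries favor accurate spaces; small off-diagonals favor spaces whose errors
are uncorrelated, so complementary predictors share weight.

The QP is solved exactly by support enumeration: for every candidate set of
strictly positive weights the equality-constrained optimum has the closed form
``alpha_S = Q_SS^{-1} 1 / (1^T Q_SS^{-1} 1)``; the feasible candidate with the
lowest objective is the global optimum. A relative jitter ``eps * I`` makes
the objective strictly convex so that redundant predictors split weight evenly
and deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import h5py
import numpy as np

from ._utils import DimensionError, ValidationError, kfold_indices
from .io import EncodingDataset, FeatureSpace, RunConfig, logger
from .ridge import RidgeModel, ridge_fit, ridge_predict

__all__ = [
    "StackedModel",
    "out_of_fold_predictions",
    "residual_product_matrix",
    "solve_stacking_qp",
    "stack_fit",
    "stack_predict",
    "concat_fit",
    "concat_space",
]

_MAX_ENUM_K = 12  # 2^k - 1 support sets; plenty for layer hierarchies


@dataclass
class StackedModel:
    """Per-voxel simplex weights plus the refitted first-level ridge models."""

    alpha: np.ndarray  # m x k
    first_level: list[RidgeModel]
    space_names: list[str]
    config: RunConfig

    @property
    def n_voxels(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_spaces(self) -> int:
        return self.alpha.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("alpha", data=self.alpha)
            f.attrs["space_names"] = list(self.space_names)
            f.attrs["config"] = self.config.to_json()
            for name, model in zip(self.space_names, self.first_level):
                model.save(f.create_group(f"ridge/{name}"))

    @classmethod
    def load(cls, path) -> "StackedModel":
        import json

        with h5py.File(path, "r") as f:
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in f.attrs["space_names"]
            ]
            cfg = RunConfig.from_dict(json.loads(f.attrs["config"]))
            return cls(
                alpha=f["alpha"][()],
                first_level=[RidgeModel.load(f[f"ridge/{n}"]) for n in names],
                space_names=names,
                config=cfg,
            )


def out_of_fold_predictions(
    dataset: EncodingDataset, config: RunConfig
) -> list[np.ndarray]:
    """Cross-validated first-level predictions covering every training sample.

    For each of ``n_stack_folds`` folds, first-level ridge models (penalties
    re-selected by inner CV) are fit on the remaining folds and predict the
    held-out fold, so every sample's prediction comes from a model that never
    saw it. Returns one n x m matrix per feature space.
    """
    n, m = dataset.n_samples, dataset.n_voxels
    if n < config.n_stack_folds:
        raise ValidationError(
            f"{n} samples cannot be split into {config.n_stack_folds} stacking folds"
        )
    preds = [np.full((n, m), np.nan) for _ in dataset.spaces]
    folds = kfold_indices(n, config.n_stack_folds, config.seed + 1)
    for fi, val in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[val] = False
        for j, space in enumerate(dataset.spaces):
            model = ridge_fit(
                space.X[mask],
                dataset.Y[mask],
                config.lambda_grid,
                config.n_inner_folds,
                seed=config.seed + 101 * (fi + 1),
                standardize=config.standardize,
            )
            preds[j][val] = ridge_predict(model, space.X[val])
    return preds


def residual_product_matrix(Y: np.ndarray, oof_preds: list[np.ndarray]) -> np.ndarray:
    """Per-voxel Gram matrices of out-of-fold residuals.

    Returns an array of shape (m, k, k) with
    ``R[v, p, q] = sum_i (Y[i,v] - oof_preds[p][i,v]) (Y[i,v] - oof_preds[q][i,v])``.
    Each k x k slice is symmetric positive semidefinite by construction.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    resid = np.stack([Y - np.asarray(p, dtype=float).reshape(Y.shape)
                      for p in oof_preds])  # k x n x m
    return np.einsum("pnm,qnm->mpq", resid, resid, optimize=True)


def solve_stacking_qp(R: np.ndarray, jitter: float | None = None) -> np.ndarray:
    """Exact minimizer of ``a^T (R + eps I) a`` on the probability simplex.

    ``jitter`` is the relative jitter scale; the absolute jitter is
    ``jitter * trace(R) / k`` (default scale 1e-9). An all-zero ``R``
    (perfect predictors everywhere) has a degenerate optimum and returns
    uniform weights.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DimensionError(f"R must be square, got shape {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValidationError("R contains non-finite entries")
    k = R.shape[0]
    if k == 1:
        return np.ones(1)
    if k > _MAX_ENUM_K:
        raise ValidationError(
            f"support enumeration supports k <= {_MAX_ENUM_K}, got {k}"
        )
    R = 0.5 * (R + R.T)
    tr = float(np.trace(R))
    if tr <= 0:
        logger.debug("all-zero residual matrix; returning uniform weights")
        return np.full(k, 1.0 / k)
    eps = (1e-9 if jitter is None else jitter) * tr / k
    Q = R + eps * np.eye(k)

    best_obj = np.inf
    best_alpha = np.full(k, 1.0 / k)
    ones_cache = [np.ones(s) for s in range(k + 1)]
    for size in range(1, k + 1):
        for S in combinations(range(k), size):
            idx = np.asarray(S)
            try:
                z = np.linalg.solve(Q[np.ix_(idx, idx)], ones_cache[size])
            except np.linalg.LinAlgError:
                continue
            ssum = z.sum()
            if ssum <= 0 or np.any(z < -1e-12 * abs(ssum)):
                continue
            a_S = z / ssum
            obj = 1.0 / ssum  # = a_S^T Q_SS a_S at the stationary point
            if obj < best_obj:
                best_obj = obj
                best_alpha = np.zeros(k)
                best_alpha[idx] = a_S
    return best_alpha


def _export_alpha(alpha: np.ndarray) -> np.ndarray:
    """Clip solver-level negative round-off to zero and renormalize."""
    a = np.clip(alpha, 0.0, None)
    return a / a.sum(axis=-1, keepdims=True)


def concat_space(dataset: EncodingDataset, name: str = "concat") -> FeatureSpace:
    """The column-concatenation of all feature spaces, as one feature space."""
    return FeatureSpace(name, np.hstack([s.X for s in dataset.spaces]))


def stack_fit(dataset: EncodingDataset, config: RunConfig | None = None) -> StackedModel:
    """Fit the full stacked encoder on a training dataset.

    Pipeline per voxel: out-of-fold first-level predictions -> residual
    product matrix -> simplex QP for the weights; first-level models are then
    refit on the entire training data (penalties re-selected by inner CV).
    """
    config = config or RunConfig()
    if config.include_concat_space:
        dataset = EncodingDataset(
            dataset.spaces + [concat_space(dataset)], dataset.Y, dataset.sample_ids
        )
    oof = out_of_fold_predictions(dataset, config)
    Rs = residual_product_matrix(dataset.Y, oof)
    alpha = np.stack([solve_stacking_qp(Rs[v], config.jitter)
                      for v in range(dataset.n_voxels)])
    first_level = [
        ridge_fit(
            s.X,
            dataset.Y,
            config.lambda_grid,
            config.n_inner_folds,
            seed=config.seed,
            standardize=config.standardize,
        )
        for s in dataset.spaces
    ]
    return StackedModel(
        alpha=_export_alpha(alpha),
        first_level=first_level,
        space_names=dataset.space_names,
        config=config,
    )


def stack_predict(model: StackedModel, spaces: list[np.ndarray]) -> np.ndarray:
    """Weighted combination of first-level predictions, voxelwise.

    For a model fit with ``include_concat_space``, the concatenated input is
    rebuilt automatically when only the original spaces are supplied.
    """
    if (
        len(spaces) == model.n_spaces - 1
        and model.space_names[-1] == "concat"
    ):
        spaces = list(spaces) + [np.hstack([np.atleast_2d(X) for X in spaces])]
    if len(spaces) != model.n_spaces:
        raise DimensionError(
            f"model has {model.n_spaces} feature spaces, got {len(spaces)}"
        )
    out = None
    for j, (X, fl) in enumerate(zip(spaces, model.first_level)):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != fl.n_features:
            raise DimensionError(
                f"feature space '{model.space_names[j]}' expects "
                f"{fl.n_features} columns, got {X.shape[1]}"
            )
        contrib = ridge_predict(fl, X) * model.alpha[:, j]
        out = contrib if out is None else out + contrib
    return out


def concat_fit(dataset: EncodingDataset, config: RunConfig | None = None) -> RidgeModel:
    """Baseline: one ridge model on the column-concatenated feature matrix."""
    config = config or RunConfig()
    return ridge_fit(
        concat_space(dataset).X,
        dataset.Y,
        config.lambda_grid,
        config.n_inner_folds,
        seed=config.seed,
        standardize=config.standardize,
    )
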