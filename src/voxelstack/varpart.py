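"""Variance partitioning via stacked joint models, and structured sweeps.

Classical variance partitioning attributes to feature space ``j`` the unique
variance ``U(all spaces) - U(all spaces except j)``, where ``U(S)`` is the
held-out R-squared of a joint model over the subset ``S``. Estimating joint
models by stacking (rather than column concatenation) keeps the set
arithmetic meaningful: adding a feature space to a stacked model essentially
never hurts held-out performance, so unique variances stay (near-)nonnegative.

Structured variance partitioning exploits a known ordering of the feature
spaces (e.g. network depth, where each layer is a function of the previous
one). A forward sweep computes the cumulative performance of the prefixes
{1}, {1,2}, ..., {1..k} and records the first prefix reaching a threshold
fraction (default 95%) of the all-spaces performance — the latest layer that
must be included. A backward sweep does the same over suffixes {k}, {k-1..k},
..., {1..k} and records the last suffix start retaining the threshold — the
earliest layer that must be included. Together they bound an interval of
hierarchy levels needed to predict each voxel; the width can be negative when
information is redundant across distant layers, which is itself diagnostic.

All 2k-1 subset models in the sweeps share the same cached first-level
machinery (out-of-fold predictions and full-train refits per outer fold);
only the per-voxel quadratic program is re-solved per subset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import ValidationError, kfold_indices
from .io import EncodingDataset, RunConfig
from .ridge import ridge_fit, ridge_predict
from .stacking import (
    StackedModel,
    concat_space,
    out_of_fold_predictions,
    residual_product_matrix,
    solve_stacking_qp,
    _export_alpha,
)

__all__ = [
    "r2_score",
    "FirstLevelCV",
    "build_first_level_cv",
    "joint_performance",
    "concat_joint_performance",
    "unique_variance",
    "forward_sweep",
    "backward_sweep",
    "layer_interval",
    "attribution_maps",
    "VPResult",
]


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray | float:
    """Coefficient of determination, columnwise: 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of ``y_true``. Held-out R-squared may be
    negative; constant ``y_true`` columns yield NaN (undefined).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    scalar = y_true.ndim == 1
    if scalar:
        y_true, y_pred = y_true[:, None], y_pred[:, None]
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"shape mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    ss_res = ((y_true - y_pred) ** 2).sum(axis=0)
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    return float(out[0]) if scalar else out


@dataclass
class FirstLevelCV:
    """Cached per-outer-fold first-level products shared by all subset models.

    For each outer fold: indices of the train/test split, out-of-fold
    first-level predictions on the training rows (one n_train x m matrix per
    space, for the residual-product QP), and test-set predictions of the
    first-level models refit on the whole training split.
    """

    folds: list[tuple[np.ndarray, np.ndarray]]
    oof: list[list[np.ndarray]]  # [fold][space] n_train x m
    test_pred: list[list[np.ndarray]]  # [fold][space] n_test x m
    space_names: list[str]
    Y: np.ndarray
    config: RunConfig

    @property
    def n_spaces(self) -> int:
        return len(self.space_names)


def build_first_level_cv(dataset: EncodingDataset, config: RunConfig) -> FirstLevelCV:
    """Run the outer-CV first-level machinery once for reuse across subsets."""
    n = dataset.n_samples
    if n < 2 * config.n_outer_folds:
        raise ValidationError(
            f"{n} samples are too few for {config.n_outer_folds} outer folds"
        )
    folds = []
    oof, test_pred = [], []
    for fi, test_idx in enumerate(
        kfold_indices(n, config.n_outer_folds, config.seed, config.shuffle_outer)
    ):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        folds.append((train_idx, test_idx))
        train = dataset.rows(train_idx)
        fold_cfg = dataclasses.replace(config, seed=config.seed + 1000 * (fi + 1))
        oof.append(out_of_fold_predictions(train, fold_cfg))
        preds = []
        for j, s in enumerate(train.spaces):
            model = ridge_fit(
                s.X,
                train.Y,
                config.lambda_grid,
                config.n_inner_folds,
                seed=fold_cfg.seed,
                standardize=config.standardize,
            )
            preds.append(ridge_predict(model, dataset.spaces[j].X[test_idx]))
        test_pred.append(preds)
    return FirstLevelCV(
        folds=folds,
        oof=oof,
        test_pred=test_pred,
        space_names=dataset.space_names,
        Y=dataset.Y,
        config=config,
    )


def _pooled_stacked_predictions(
    cache: FirstLevelCV, subset: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled held-out predictions of the stacked model over a space subset.

    Returns (predictions, alpha_by_fold_mean); predictions cover every sample
    exactly once across the outer folds.
    """
    subset = list(subset)
    if not subset:
        raise ValidationError("subset must be nonempty")
    n, m = cache.Y.shape
    pooled = np.full((n, m), np.nan)
    alphas = []
    for (train_idx, test_idx), oof, test_pred in zip(
        cache.folds, cache.oof, cache.test_pred
    ):
        Rs = residual_product_matrix(cache.Y[train_idx], [oof[j] for j in subset])
        alpha = np.stack(
            [solve_stacking_qp(Rs[v], cache.config.jitter) for v in range(m)]
        )
        alpha = _export_alpha(alpha)
        alphas.append(alpha)
        pred = np.zeros((len(test_idx), m))
        for a_col, j in enumerate(subset):
            pred += test_pred[j] * alpha[:, a_col]
        pooled[test_idx] = pred
    return pooled, np.mean(alphas, axis=0)


def joint_performance(
    dataset: EncodingDataset | None,
    subset: Sequence[int],
    config: RunConfig | None = None,
    cache: FirstLevelCV | None = None,
) -> np.ndarray:
    """Held-out R-squared per voxel of the stacked joint model over a subset.

    Follows the outer-CV evaluation protocol: for each fold the stacked model
    is trained on 80% and predicts the held-out 20%; predictions are pooled
    over folds before computing R-squared. Passing a prebuilt ``cache`` skips
    the (dominant) first-level fitting cost; subsets then only pay for the QP.
    """
    if cache is None:
        if dataset is None or config is None:
            raise ValidationError("need either a cache or (dataset, config)")
        cache = build_first_level_cv(dataset, config)
    pooled, _ = _pooled_stacked_predictions(cache, subset)
    return r2_score(cache.Y, pooled)


def concat_joint_performance(
    dataset: EncodingDataset, subset: Sequence[int], config: RunConfig
) -> np.ndarray:
    """Held-out R-squared of the concatenation baseline over a space subset."""
    subset = list(subset)
    sub = dataset.subset(subset)
    X = concat_space(sub).X
    n, m = dataset.Y.shape
    pooled = np.full((n, m), np.nan)
    for fi, test_idx in enumerate(
        kfold_indices(n, config.n_outer_folds, config.seed, config.shuffle_outer)
    ):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = ridge_fit(
            X[train_idx],
            dataset.Y[train_idx],
            config.lambda_grid,
            config.n_inner_folds,
            seed=config.seed + 1000 * (fi + 1),
            standardize=config.standardize,
        )
        pooled[test_idx] = ridge_predict(model, X[test_idx])
    return r2_score(dataset.Y, pooled)


def unique_variance(
    dataset: EncodingDataset | None,
    j: int,
    config: RunConfig | None = None,
    cache: FirstLevelCV | None = None,
    method: str = "stacking",
) -> np.ndarray:
    """Unique variance of space ``j``: U(all) - U(all except j), per voxel."""
    if method == "concat":
        if dataset is None or config is None:
            raise ValidationError("concat method needs (dataset, config)")
        k = dataset.n_spaces
        rest = [i for i in range(k) if i != j]
        return concat_joint_performance(
            dataset, range(k), config
        ) - concat_joint_performance(dataset, rest, config)
    if cache is None:
        cache = build_first_level_cv(dataset, config)
    k = cache.n_spaces
    if k < 2:
        raise ValidationError("unique variance needs at least 2 feature spaces")
    rest = [i for i in range(k) if i != j]
    return joint_performance(None, range(k), cache=cache) - joint_performance(
        None, rest, cache=cache
    )


@dataclass
class VPResult:
    """Structured variance-partitioning output for one sweep direction (or both).

    Cumulative series are stored raw, exactly as computed; any near-monotone
    violations are data, not errors. Indices are 1-based layer numbers stored
    as floats with NaN marking voxels whose total performance is not positive
    (a threshold on a nonpositive total is meaningless).
    """

    space_names: list[str]
    threshold: float
    cumulative_forward: np.ndarray | None = None  # k x m
    cumulative_backward: np.ndarray | None = None  # k x m, row j-1 = suffix from j
    forward_index: np.ndarray | None = None
    backward_index: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        if self.forward_index is not None:
            cols["forward_index"] = self.forward_index
            cols["total_r2"] = self.cumulative_forward[-1]
        if self.backward_index is not None:
            cols["backward_index"] = self.backward_index
            cols.setdefault("total_r2", self.cumulative_backward[0])
        if self.forward_index is not None and self.backward_index is not None:
            lower, upper, width = layer_interval(
                self.forward_index, self.backward_index
            )
            cols["interval_lower"] = lower
            cols["interval_upper"] = upper
            cols["interval_width"] = width
        if self.cumulative_forward is not None:
            for j, name in enumerate(self.space_names):
                cols[f"cum_forward_{name}"] = self.cumulative_forward[j]
        if self.cumulative_backward is not None:
            for j, name in enumerate(self.space_names):
                cols[f"cum_backward_{name}"] = self.cumulative_backward[j]
        df = pd.DataFrame(cols)
        df.insert(0, "voxel", np.arange(len(df)))
        return df


def _threshold_cross(
    series: np.ndarray, total: np.ndarray, threshold: float, direction: str,
    envelope: bool,
) -> np.ndarray:
    """1-based crossing index per voxel; NaN where total <= 0 or undefined."""
    k, m = series.shape
    if envelope:
        series = (
            np.maximum.accumulate(series, axis=0)
            if direction == "forward"
            else np.maximum.accumulate(series[::-1], axis=0)[::-1]
        )
    idx = np.full(m, np.nan)
    defined = np.isfinite(total) & (total > 0)
    cut = threshold * total
    ok = series >= cut  # k x m
    if direction == "forward":
        # smallest prefix length reaching the cut
        any_ok = ok.any(axis=0)
        first = np.argmax(ok, axis=0) + 1.0
        idx[defined & any_ok] = first[defined & any_ok]
    else:
        # largest suffix start retaining the cut
        any_ok = ok.any(axis=0)
        last = k - np.argmax(ok[::-1], axis=0) + 0.0
        idx[defined & any_ok] = last[defined & any_ok]
    return idx


def forward_sweep(
    dataset: EncodingDataset | None,
    config: RunConfig | None = None,
    cache: FirstLevelCV | None = None,
) -> VPResult:
    """Cumulative prefix performances and the latest layer needed per voxel."""
    if cache is None:
        cache = build_first_level_cv(dataset, config)
    k = cache.n_spaces
    cum = np.stack(
        [joint_performance(None, range(j + 1), cache=cache) for j in range(k)]
    )
    total = cum[-1]
    fwd = _threshold_cross(
        cum, total, cache.config.threshold, "forward", cache.config.monotone_envelope
    )
    return VPResult(
        space_names=cache.space_names,
        threshold=cache.config.threshold,
        cumulative_forward=cum,
        forward_index=fwd,
    )


def backward_sweep(
    dataset: EncodingDataset | None,
    config: RunConfig | None = None,
    cache: FirstLevelCV | None = None,
) -> VPResult:
    """Suffix performances and the earliest layer needed per voxel."""
    if cache is None:
        cache = build_first_level_cv(dataset, config)
    k = cache.n_spaces
    cum = np.stack(
        [joint_performance(None, range(j, k), cache=cache) for j in range(k)]
    )
    total = cum[0]
    bwd = _threshold_cross(
        cum, total, cache.config.threshold, "backward", cache.config.monotone_envelope
    )
    return VPResult(
        space_names=cache.space_names,
        threshold=cache.config.threshold,
        cumulative_backward=cum,
        backward_index=bwd,
    )


def both_sweeps(
    dataset: EncodingDataset | None,
    config: RunConfig | None = None,
    cache: FirstLevelCV | None = None,
) -> VPResult:
    """Forward and backward sweeps on one shared first-level cache."""
    if cache is None:
        cache = build_first_level_cv(dataset, config)
    f = forward_sweep(None, cache=cache)
    b = backward_sweep(None, cache=cache)
    return VPResult(
        space_names=cache.space_names,
        threshold=cache.config.threshold,
        cumulative_forward=f.cumulative_forward,
        cumulative_backward=b.cumulative_backward,
        forward_index=f.forward_index,
        backward_index=b.backward_index,
    )


def layer_interval(
    forward_index: np.ndarray, backward_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interval of hierarchy levels per voxel: (lower, upper, width).

    Lower bound from the backward sweep, upper bound from the forward sweep.
    Width = upper - lower; negative widths are reported as-is (they flag
    redundant information across distant layers). NaN propagates from
    undefined indices.
    """
    lower = np.asarray(backward_index, dtype=float)
    upper = np.asarray(forward_index, dtype=float)
    return lower, upper, upper - lower


def attribution_maps(
    stacked: StackedModel | np.ndarray,
    individual_r2: np.ndarray,
    space_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-voxel best-space labels under two attribution rules.

    ``best_by_alpha`` picks the space with the largest stacking weight;
    ``best_by_r2`` picks the space whose individual encoder predicts the voxel
    best. Ties break toward the lowest (earliest) space index. Convenience
    columns: the second-largest-weight space and mean weights over an
    early/middle/late split of the hierarchy.
    """
    if isinstance(stacked, StackedModel):
        alpha = stacked.alpha
        space_names = space_names or stacked.space_names
    else:
        alpha = np.asarray(stacked, dtype=float)
    m, k = alpha.shape
    individual_r2 = np.asarray(individual_r2, dtype=float)
    if individual_r2.shape != (m, k):
        raise ValidationError(
            f"individual_r2 shape {individual_r2.shape} != alpha shape {(m, k)}"
        )
    names = space_names or [f"space{j + 1}" for j in range(k)]
    best_alpha = np.argmax(alpha, axis=1)  # argmax takes the first max: lowest index
    best_r2 = np.argmax(individual_r2, axis=1)
    # second-largest weight: mask out the winner, argmax again
    masked = alpha.copy()
    masked[np.arange(m), best_alpha] = -np.inf
    second_alpha = np.argmax(masked, axis=1)
    df = pd.DataFrame(
        {
            "voxel": np.arange(m),
            "best_by_alpha": [names[j] for j in best_alpha],
            "best_by_r2": [names[j] for j in best_r2],
            "second_by_alpha": [names[j] for j in second_alpha],
        }
    )
    bounds = np.array_split(np.arange(k), min(3, k))
    for label, cols in zip(("early", "middle", "late"), bounds):
        df[f"alpha_mean_{label}"] = alpha[:, cols].mean(axis=1)
    return df
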