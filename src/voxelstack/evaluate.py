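"""End-to-end evaluation: outer cross-validation and three-way comparison.

The whole dataset is split into ``n_outer_folds`` folds; at each fold 80% of
the samples train the stacked model, the concatenation baseline, and the k
individual ridge encoders, and all of them predict the held-out 20%. Held-out
predictions are pooled over folds (every sample predicted exactly once per
model) before computing per-voxel R-squared, and R = sqrt(R^2) where R^2 > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .io import EncodingDataset, RunConfig
from .ridge import ridge_fit, ridge_predict
from .varpart import (
    FirstLevelCV,
    build_first_level_cv,
    _pooled_stacked_predictions,
    r2_score,
)
from .stacking import concat_space

__all__ = ["EvaluationReport", "evaluate_all", "r_from_r2"]


def r_from_r2(r2):
    """R = sqrt(R^2) where R^2 > 0; NaN (undefined) otherwise."""
    r2 = np.asarray(r2, dtype=float)
    out = np.where(r2 > 0, np.sqrt(np.clip(r2, 0, None)), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class EvaluationReport:
    """Pooled held-out performance of stacked / concatenated / individual models."""

    r2_stacked: np.ndarray
    r2_concat: np.ndarray
    r2_individual: np.ndarray  # m x k
    space_names: list[str]
    alpha_mean: np.ndarray  # m x k, outer-fold mean stacking weights
    config: RunConfig

    @property
    def r2_max_individual(self) -> np.ndarray:
        return self.r2_individual.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        m = len(self.r2_stacked)
        max_ind = self.r2_max_individual
        df = pd.DataFrame(
            {
                "voxel": np.arange(m),
                "r2_stacked": self.r2_stacked,
                "r2_concat": self.r2_concat,
                "r2_max_individual": max_ind,
                "r_stacked": r_from_r2(self.r2_stacked),
                "r_concat": r_from_r2(self.r2_concat),
                "r_max_individual": r_from_r2(max_ind),
                "diff_stacked_max": self.r2_stacked - max_ind,
                "diff_stacked_concat": self.r2_stacked - self.r2_concat,
                "diff_concat_max": self.r2_concat - max_ind,
            }
        )
        for j, name in enumerate(self.space_names):
            df[f"r2_{name}"] = self.r2_individual[:, j]
        for j, name in enumerate(self.space_names):
            df[f"alpha_{name}"] = self.alpha_mean[:, j]
        return df

    def top_voxels(self, n: int = 2000) -> pd.DataFrame:
        """Top-n voxels ordered by decreasing max-individual R."""
        df = self.to_frame()
        order = np.argsort(-np.nan_to_num(df["r_max_individual"], nan=-np.inf))
        return df.iloc[order[:n]].reset_index(drop=True)


def evaluate_all(
    dataset: EncodingDataset,
    config: RunConfig | None = None,
    cache: FirstLevelCV | None = None,
) -> EvaluationReport:
    """Run the full outer-CV comparison on one dataset."""
    config = config or RunConfig()
    if dataset.n_samples < 2 * config.n_outer_folds:
        raise ValidationError(
            f"{dataset.n_samples} samples are too few for "
            f"{config.n_outer_folds} outer folds"
        )
    if cache is None:
        cache = build_first_level_cv(dataset, config)
    k, m, n = cache.n_spaces, dataset.n_voxels, dataset.n_samples

    pooled_stack, alpha_mean = _pooled_stacked_predictions(cache, range(k))
    r2_stacked = np.atleast_1d(r2_score(dataset.Y, pooled_stack))

    pooled_ind = np.full((k, n, m), np.nan)
    for (train_idx, test_idx), test_pred in zip(cache.folds, cache.test_pred):
        for j in range(k):
            pooled_ind[j, test_idx] = test_pred[j]
    r2_individual = np.stack(
        [np.atleast_1d(r2_score(dataset.Y, pooled_ind[j])) for j in range(k)], axis=1
    )

    Xcat = concat_space(dataset).X
    pooled_concat = np.full((n, m), np.nan)
    for fi, (train_idx, test_idx) in enumerate(cache.folds):
        model = ridge_fit(
            Xcat[train_idx],
            dataset.Y[train_idx],
            config.lambda_grid,
            config.n_inner_folds,
            seed=config.seed + 1000 * (fi + 1),
            standardize=config.standardize,
        )
        pooled_concat[test_idx] = ridge_predict(model, Xcat[test_idx])
    r2_concat = np.atleast_1d(r2_score(dataset.Y, pooled_concat))

    return EvaluationReport(
        r2_stacked=r2_stacked,
        r2_concat=r2_concat,
        r2_individual=r2_individual,
        space_names=cache.space_names,
        alpha_mean=alpha_mean,
        config=config,
    )
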