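"""Shared small utilities: fold assignment and validation errors."""

from __future__ import annotations

import numpy as np

__all__ = ["ValidationError", "DimensionError", "kfold_indices"]


class ValidationError(ValueError):
    """Input data violates a documented invariant (non-finite entries, bad config)."""


class DimensionError(ValidationError):
    """Matrix shapes disagree between feature spaces, responses, or models."""


def kfold_indices(
    n: int, n_folds: int, seed: int, shuffle: bool = True
) -> list[np.ndarray]:
    """Deterministic k-fold partition of ``range(n)``.

    Folds are contiguous blocks of a seeded permutation (or of the identity when
    ``shuffle=False``), so the same ``(n, n_folds, seed)`` always yields the same
    partition. Fold sizes differ by at most one sample.
    """
    if n_folds < 2:
        raise ValidationError(f"need at least 2 folds, got {n_folds}")
    if n < n_folds:
        raise ValidationError(f"cannot split {n} samples into {n_folds} folds")
    order = np.arange(n)
    if shuffle:
        order = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(order, n_folds)]
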