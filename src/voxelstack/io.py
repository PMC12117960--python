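"""Data containers, file I/O, and run configuration.

The package operates on extracted numeric matrices: ``k`` stimulus feature
spaces (each ``n`` samples x ``d_j`` features) and a response matrix
(``n`` samples x ``m`` voxels) with a shared sample ordering. Matrices travel
as TSV/CSV text tables or as HDF5 files (one dataset per feature space under
``/features/<name>``, responses under ``/responses``). Sample order is the row
order of the files; cross-validation operates on those row indices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from ._utils import DimensionError, ValidationError

__all__ = [
    "FeatureSpace",
    "EncodingDataset",
    "RunConfig",
    "DEFAULT_LAMBDA_GRID",
    "load_dataset",
    "save_dataset",
    "load_matrix",
    "save_table",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger("voxelstack")

#: Ridge penalty grid: 10^-6 ... 10^9, 16 logarithmically spaced values.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(10.0 ** np.arange(-6, 10))


def _as_dense_2d(X, what: str) -> np.ndarray:
    if sp.issparse(X):
        warnings.warn(f"{what}: sparse input densified", stacklevel=3)
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise DimensionError(f"{what}: expected a 2-D matrix, got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValidationError(
            f"{what}: non-finite entry at row {bad[0]}, column {bad[1]}"
        )
    return X


@dataclass
class FeatureSpace:
    """One named stimulus representation: an ``n x d`` matrix of features."""

    name: str
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = _as_dense_2d(self.X, f"feature space '{self.name}'")
        n, d = self.X.shape
        if n < 2:
            raise ValidationError(f"feature space '{self.name}': need n >= 2, got {n}")
        if d < 1:
            raise ValidationError(f"feature space '{self.name}': need d >= 1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class EncodingDataset:
    """Ordered feature spaces plus a response matrix with shared sample order.

    The order of ``spaces`` is semantically meaningful: it is the hierarchy
    order (e.g. network depth) used by the structured variance-partitioning
    sweeps.
    """

    spaces: list[FeatureSpace]
    Y: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.spaces) < 1:
            raise ValidationError("need at least one feature space")
        self.Y = _as_dense_2d(self.Y, "responses")
        n = self.Y.shape[0]
        for s in self.spaces:
            if s.n_samples != n:
                raise DimensionError(
                    f"feature space '{s.name}' has {s.n_samples} rows but "
                    f"responses have {n}"
                )
        names = [s.name for s in self.spaces]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate feature-space names: {names}")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise DimensionError(
                f"sample_ids has length {len(self.sample_ids)}, expected {n}"
            )

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Y.shape[1]

    @property
    def n_spaces(self) -> int:
        return len(self.spaces)

    @property
    def space_names(self) -> list[str]:
        return [s.name for s in self.spaces]

    def subset(self, indices: Sequence[int]) -> "EncodingDataset":
        """Dataset restricted to the given feature spaces (order preserved)."""
        return EncodingDataset(
            [self.spaces[i] for i in indices], self.Y, self.sample_ids
        )

    def rows(self, idx: np.ndarray) -> "EncodingDataset":
        """Dataset restricted to the given sample rows."""
        return EncodingDataset(
            [FeatureSpace(s.name, s.X[idx]) for s in self.spaces],
            self.Y[idx],
            [self.sample_ids[i] for i in idx] if self.sample_ids else None,
        )


@dataclass
class RunConfig:
    """Configuration shared across fitting, evaluation, and sweeps.

    Parameters
    ----------
    lambda_grid
        Candidate ridge penalties; the per-voxel penalty is chosen from this
        grid by inner cross-validation. Default spans 1e-6 ... 1e9.
    n_outer_folds, n_stack_folds, n_inner_folds
        Outer evaluation folds, stacking (out-of-fold residual) folds, and
        inner penalty-selection folds. All default to 5, i.e. 80/20 splits at
        every level.
    threshold
        Fraction of the all-spaces performance that a prefix/suffix of the
        hierarchy must reach in the sweeps (default 0.95).
    seed
        Master seed; every fold assignment derives from it deterministically.
    jitter
        Relative Tikhonov jitter added to the stacking QP objective,
        ``jitter * trace(R)/k * I``, making the optimum unique and splitting
        weight evenly across redundant predictors.
    standardize
        Scale feature columns to unit variance (in addition to the default
        mean-centering) before ridge fitting.
    shuffle_outer
        Outer folds from a seeded permutation (default) or contiguous blocks.
    include_concat_space
        Append the concatenation of all feature spaces as an extra stacking
        input.
    monotone_envelope
        Apply a running maximum to the cumulative sweep series before
        thresholding.
    """

    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_outer_folds: int = 5
    n_stack_folds: int = 5
    n_inner_folds: int = 5
    threshold: float = 0.95
    seed: int = 0
    jitter: float = 1e-9
    standardize: bool = False
    shuffle_outer: bool = True
    include_concat_space: bool = False
    monotone_envelope: bool = False

    def __post_init__(self) -> None:
        grid = tuple(float(v) for v in self.lambda_grid)
        if len(grid) == 0 or any(v <= 0 for v in grid):
            raise ValidationError("lambda_grid must be nonempty and positive")
        self.lambda_grid = tuple(sorted(grid))
        for name in ("n_outer_folds", "n_stack_folds", "n_inner_folds"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        if not 0.0 < self.threshold <= 1.0:
            raise ValidationError("threshold must be in (0, 1]")
        if self.jitter < 0:
            raise ValidationError("jitter must be nonnegative")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = list(d["lambda_grid"])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON (keys mirror the field names)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} did not parse to a mapping")
    return RunConfig.from_dict(data)


def load_matrix(path: str | Path, fmt: str | None = None, header: bool = True) -> np.ndarray:
    """Load one numeric matrix from a TSV/CSV file."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=0 if header else None)
    return _as_dense_2d(df.to_numpy(), str(path))


def load_dataset(
    feature_paths: dict[str, str | Path],
    response_path: str | Path,
    fmt: str = "tsv",
    header: bool = True,
) -> EncodingDataset:
    """Assemble an EncodingDataset from files.

    ``fmt`` is one of ``tsv``, ``csv``, or ``hdf5``. For HDF5,
    ``feature_paths`` values and ``response_path`` may all point at one file;
    feature spaces are read from ``/features/<name>`` and responses from
    ``/responses``. Feature-space order follows the order of ``feature_paths``.
    """
    if fmt == "hdf5":
        spaces = []
        for name, p in feature_paths.items():
            with h5py.File(p, "r") as f:
                spaces.append(FeatureSpace(name, f[f"features/{name}"][()]))
        with h5py.File(response_path, "r") as f:
            Y = f["responses"][()]
            ids = f["sample_ids"].asstr()[()].tolist() if "sample_ids" in f else None
        return EncodingDataset(spaces, Y, ids)
    if fmt not in ("tsv", "csv"):
        raise ValidationError(f"unknown format {fmt!r}")
    spaces = [
        FeatureSpace(name, load_matrix(p, fmt, header))
        for name, p in feature_paths.items()
    ]
    return EncodingDataset(spaces, load_matrix(response_path, fmt, header))


def save_dataset(dataset: EncodingDataset, path: str | Path) -> None:
    """Write a dataset to one HDF5 file (round-trips bit-exactly)."""
    with h5py.File(path, "w") as f:
        for s in dataset.spaces:
            f.create_dataset(f"features/{s.name}", data=s.X)
        f.create_dataset("responses", data=dataset.Y)
        f.attrs["space_order"] = json.dumps(dataset.space_names)
        if dataset.sample_ids is not None:
            f.create_dataset("sample_ids", data=dataset.sample_ids)


def load_dataset_h5(path: str | Path) -> EncodingDataset:
    """Reload a dataset written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        order = json.loads(f.attrs["space_order"])
        spaces = [FeatureSpace(name, f[f"features/{name}"][()]) for name in order]
        Y = f["responses"][()]
        ids = f["sample_ids"].asstr()[()].tolist() if "sample_ids" in f else None
    return EncodingDataset(spaces, Y, ids)


def save_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with full-precision floats."""
    if rows.columns.duplicated().any():
        raise ValidationError(f"duplicate column names: {list(rows.columns)}")
    rows.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    logger.setLevel(level)
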