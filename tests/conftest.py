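import numpy as np
import pytest

from voxelstack import EncodingDataset, FeatureSpace, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """Two informative feature spaces, 80 samples, 4 voxels."""
    X1 = rng.standard_normal((80, 6))
    X2 = rng.standard_normal((80, 5))
    W1 = rng.standard_normal((6, 4))
    W2 = rng.standard_normal((5, 4))
    Y = X1 @ W1 + X2 @ W2 + 0.5 * rng.standard_normal((80, 4))
    return EncodingDataset([FeatureSpace("low", X1), FeatureSpace("high", X2)], Y)


@pytest.fixture
def fast_config():
    """Small penalty grid to keep nested CV cheap in unit tests."""
    return RunConfig(lambda_grid=(1e-3, 1.0, 1e3), seed=7)


def grid_search_simplex(R, step):
    """Brute-force minimizer of a^T R a over the simplex (independent oracle).

    Full enumeration at the given step for k <= 3; for larger k a coarse pass
    followed by local refinement at the requested step.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]

    def enumerate_at(lo, hi, step):
        axes = [np.arange(max(0.0, l), min(1.0, h) + step / 2, step)
                for l, h in zip(lo, hi)]
        grids = np.meshgrid(*axes[: k - 1], indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        last = 1.0 - pts.sum(axis=1)
        ok = last >= -1e-12
        pts = np.column_stack([pts[ok], np.clip(last[ok], 0, None)])
        obj = np.einsum("ij,jk,ik->i", pts, R, pts)
        return pts[np.argmin(obj)]

    if k <= 3:
        return enumerate_at([0.0] * (k - 1), [1.0] * (k - 1), step)
    best = enumerate_at([0.0] * (k - 1), [1.0] * (k - 1), 0.02)
    lo = [b - 0.03 for b in best[: k - 1]]
    hi = [b + 0.03 for b in best[: k - 1]]
    return enumerate_at(lo, hi, step)
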