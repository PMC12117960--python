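import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import voxelstack as vs
from voxelstack import DimensionError, EncodingDataset, FeatureSpace, RunConfig
from conftest import grid_search_simplex


class TestOutOfFoldPredictions:
    def test_every_row_predicted_exactly_once(self, small_dataset, fast_config):
        preds = vs.out_of_fold_predictions(small_dataset, fast_config)
        assert len(preds) == small_dataset.n_spaces
        for p in preds:
            assert p.shape == small_dataset.Y.shape
            assert np.all(np.isfinite(p))

    def test_noiseless_single_space_recovered(self):
        X = np.linspace(-1, 1, 50)[:, None]
        y = 2 * X
        ds = EncodingDataset([FeatureSpace("x", X)], y)
        cfg = RunConfig(lambda_grid=(1e-6,), seed=0)
        preds = vs.out_of_fold_predictions(ds, cfg)
        np.testing.assert_allclose(preds[0], y, atol=1e-2)

    def test_oof_error_not_below_in_sample(self, rng, fast_config):
        # out-of-fold predictions must not leak training information
        X = rng.standard_normal((60, 10))
        Y = X @ rng.standard_normal((10, 3)) + rng.standard_normal((60, 3))
        ds = EncodingDataset([FeatureSpace("x", X)], Y)
        oof = vs.out_of_fold_predictions(ds, fast_config)[0]
        model = vs.ridge_fit(X, Y, fast_config.lambda_grid, seed=fast_config.seed)
        insample = vs.ridge_predict(model, X)
        mse_oof = ((Y - oof) ** 2).mean()
        mse_in = ((Y - insample) ** 2).mean()
        assert mse_oof >= mse_in


class TestResidualProductMatrix:
    def test_perfect_predictions_give_zero(self, rng):
        Y = rng.standard_normal((10, 3))
        R = vs.residual_product_matrix(Y, [Y.copy(), Y.copy()])
        np.testing.assert_allclose(R, 0, atol=1e-12)

    def test_hand_computed_two_sample_case(self):
        # y=(1,0), yhat1=(0,0), yhat2=(1,1): e1=(1,0), e2=(0,-1)
        Y = np.array([[1.0], [0.0]])
        p1 = np.array([[0.0], [0.0]])
        p2 = np.array([[1.0], [1.0]])
        R = vs.residual_product_matrix(Y, [p1, p2])
        np.testing.assert_allclose(R[0], [[1.0, 0.0], [0.0, 1.0]])

    def test_symmetric_and_psd(self, rng):
        Y = rng.standard_normal((30, 5))
        preds = [rng.standard_normal((30, 5)) for _ in range(4)]
        R = vs.residual_product_matrix(Y, preds)
        assert R.shape == (5, 4, 4)
        np.testing.assert_allclose(R, np.swapaxes(R, 1, 2))
        for v in range(5):
            assert np.linalg.eigvalsh(R[v]).min() >= -1e-10


class TestSolveStackingQP:
    def test_symmetric_diagonal_splits_evenly(self):
        np.testing.assert_allclose(
            vs.solve_stacking_qp(np.eye(2)), [0.5, 0.5], atol=1e-9
        )

    def test_k2_closed_form(self):
        R = np.array([[0.04, 0.0], [0.0, 0.64]])
        a = vs.solve_stacking_qp(R)
        # a1 = (R22 - R12) / (R11 + R22 - 2 R12)
        np.testing.assert_allclose(a, [0.64 / 0.68, 0.04 / 0.68], atol=1e-6)

    def test_identical_predictors_tie_evenly(self):
        R = np.full((2, 2), 3.7)
        np.testing.assert_allclose(vs.solve_stacking_qp(R), [0.5, 0.5], atol=1e-9)

    def test_all_zero_residuals_uniform(self):
        np.testing.assert_allclose(
            vs.solve_stacking_qp(np.zeros((4, 4))), 0.25, atol=1e-12
        )

    def test_matches_grid_search_k3(self, rng):
        for _ in range(10):
            A = rng.standard_normal((6, 3))
            R = A.T @ A
            a = vs.solve_stacking_qp(R)
            ref = grid_search_simplex(R, 1e-3)
            np.testing.assert_allclose(a, ref, atol=2e-3)

    @given(st.integers(2, 5), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_simplex_feasibility_and_optimality(self, k, seed):
        """Output is on the simplex and beats every vertex and the centroid."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((k + 2, k))
        R = A.T @ A
        a = vs.solve_stacking_qp(R)
        assert np.all(a >= -1e-8)
        assert abs(a.sum() - 1) <= 1e-6
        obj = a @ R @ a
        assert obj <= R.diagonal().min() + 1e-8  # every vertex is feasible
        u = np.full(k, 1 / k)
        assert obj <= u @ R @ u + 1e-8


class TestStackFit:
    def test_single_space_gets_weight_one(self, rng, fast_config):
        X = rng.standard_normal((60, 5))
        Y = X @ rng.standard_normal((5, 3)) + rng.standard_normal((60, 3))
        ds = EncodingDataset([FeatureSpace("only", X)], Y)
        model = vs.stack_fit(ds, fast_config)
        np.testing.assert_allclose(model.alpha, 1.0, atol=1e-12)

    def test_duplicated_space_splits_half_half(self, rng, fast_config):
        X = rng.standard_normal((80, 8))
        Y = X @ rng.standard_normal((8, 5)) + rng.standard_normal((80, 5))
        ds = EncodingDataset(
            [FeatureSpace("a", X), FeatureSpace("b", X.copy())], Y
        )
        model = vs.stack_fit(ds, fast_config)
        np.testing.assert_allclose(model.alpha, 0.5, atol=1e-6)

    def test_simplex_feasibility_of_export(self, small_dataset, fast_config):
        model = vs.stack_fit(small_dataset, fast_config)
        assert np.all(model.alpha >= 0)
        np.testing.assert_allclose(model.alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self, small_dataset, fast_config):
        model = vs.stack_fit(small_dataset, fast_config)
        flipped = EncodingDataset(
            [small_dataset.spaces[1], small_dataset.spaces[0]], small_dataset.Y
        )
        model_f = vs.stack_fit(flipped, fast_config)
        np.testing.assert_allclose(
            model.alpha, model_f.alpha[:, ::-1], atol=1e-6
        )

    def test_informative_space_dominates(self, rng, fast_config):
        X1 = rng.standard_normal((100, 6))
        X2 = rng.standard_normal((100, 6))
        Y = X1 @ rng.standard_normal((6, 3)) + 0.1 * rng.standard_normal((100, 3))
        ds = EncodingDataset([FeatureSpace("sig", X1), FeatureSpace("noise", X2)], Y)
        model = vs.stack_fit(ds, fast_config)
        assert np.all(model.alpha[:, 0] > 0.9)

    def test_concat_space_option_adds_one_input(self, small_dataset, fast_config):
        import dataclasses

        cfg = dataclasses.replace(fast_config, include_concat_space=True)
        model = vs.stack_fit(small_dataset, cfg)
        assert model.space_names[-1] == "concat"
        assert model.n_spaces == small_dataset.n_spaces + 1
        np.testing.assert_allclose(model.alpha.sum(axis=1), 1.0, atol=1e-6)
        # prediction accepts the original spaces and rebuilds the concat input
        Xs = [s.X for s in small_dataset.spaces]
        pred = vs.stack_predict(model, Xs)
        assert pred.shape == small_dataset.Y.shape

    def test_model_round_trip(self, tmp_path, small_dataset, fast_config):
        model = vs.stack_fit(small_dataset, fast_config)
        model.save(tmp_path / "m.h5")
        back = vs.StackedModel.load(tmp_path / "m.h5")
        np.testing.assert_array_equal(model.alpha, back.alpha)
        assert back.space_names == model.space_names
        assert back.config == model.config


class TestStackPredict:
    def test_single_space_equals_ridge(self, rng, fast_config):
        X = rng.standard_normal((60, 5))
        Y = X @ rng.standard_normal((5, 2)) + rng.standard_normal((60, 2))
        ds = EncodingDataset([FeatureSpace("x", X)], Y)
        model = vs.stack_fit(ds, fast_config)
        Xnew = rng.standard_normal((10, 5))
        np.testing.assert_allclose(
            vs.stack_predict(model, [Xnew]),
            vs.ridge_predict(model.first_level[0], Xnew),
            atol=1e-12,
        )

    def test_vertex_weight_selects_one_space(self, small_dataset, fast_config):
        model = vs.stack_fit(small_dataset, fast_config)
        model.alpha = np.tile([1.0, 0.0], (small_dataset.n_voxels, 1))
        Xs = [s.X for s in small_dataset.spaces]
        np.testing.assert_allclose(
            vs.stack_predict(model, Xs),
            vs.ridge_predict(model.first_level[0], Xs[0]),
            atol=1e-12,
        )

    def test_convexity_identity_on_equal_predictions(self, rng, fast_config):
        # identical feature spaces -> identical first-level predictions ->
        # the stacked output equals them for any simplex weights
        X = rng.standard_normal((60, 4))
        Y = X @ rng.standard_normal((4, 2)) + rng.standard_normal((60, 2))
        ds = EncodingDataset([FeatureSpace("a", X), FeatureSpace("b", X.copy())], Y)
        model = vs.stack_fit(ds, fast_config)
        model.alpha = np.tile([0.3, 0.7], (2, 1))
        pred = vs.stack_predict(model, [X, X])
        np.testing.assert_allclose(
            pred, vs.ridge_predict(model.first_level[0], X), atol=1e-8
        )

    def test_shape_mismatch_names_space(self, small_dataset, fast_config):
        model = vs.stack_fit(small_dataset, fast_config)
        bad = [small_dataset.spaces[0].X, small_dataset.spaces[0].X]
        with pytest.raises(DimensionError, match="high"):
            vs.stack_predict(model, bad)


class TestConcatFit:
    def test_single_space_identical_to_ridge(self, rng, fast_config):
        X = rng.standard_normal((50, 6))
        Y = X @ rng.standard_normal((6, 2)) + rng.standard_normal((50, 2))
        ds = EncodingDataset([FeatureSpace("x", X)], Y)
        cat = vs.concat_fit(ds, fast_config)
        ind = vs.ridge_fit(
            X, Y, fast_config.lambda_grid, seed=fast_config.seed
        )
        np.testing.assert_allclose(cat.W, ind.W, atol=1e-12)

    def test_closed_form_on_concatenated_columns(self, rng):
        from test_ridge import naive_ridge

        X1 = rng.standard_normal((40, 3))
        X2 = rng.standard_normal((40, 4))
        Y = rng.standard_normal((40, 2))
        ds = EncodingDataset([FeatureSpace("a", X1), FeatureSpace("b", X2)], Y)
        cat = vs.concat_fit(ds, RunConfig(lambda_grid=(5.0,), seed=0))
        Xcat = np.hstack([X1, X2])
        Xc, Yc = Xcat - Xcat.mean(0), Y - Y.mean(0)
        np.testing.assert_allclose(cat.W, naive_ridge(Xc, Yc, 5.0), atol=1e-8)
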