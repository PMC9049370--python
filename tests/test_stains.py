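import numpy as np
import pytest
from sklearn.linear_model import Lasso

from histopatch.exceptions import DegenerateInputError
from histopatch.stains import (
    DensityMaps,
    StainModel,
    StainSeparator,
    estimate_stains,
    od_to_rgb,
    order_stains,
    rgb_to_od,
    separate,
    snmf_objective,
    sparse_code,
)
from histopatch.synthetic import SceneSpec, make_scene, make_stain_matrix, render_rgb

from conftest import scene_image


class TestOpticalDensity:
    def test_white_image_has_zero_od(self):
        V = rgb_to_od(np.full((4, 4, 3), 255, np.uint8))
        assert V.shape == (3, 16)
        np.testing.assert_allclose(V, 0.0)

    @pytest.mark.parametrize(
        "value,expected",
        [(94, np.log(255 / 94)), (0, np.log(255.0)), (1, np.log(255.0))],
    )
    def test_pointwise_values_with_clamping(self, value, expected):
        V = rgb_to_od(np.full((1, 1, 3), value, np.uint8))
        np.testing.assert_allclose(V, expected, atol=1e-4)

    def test_od_zero_maps_to_white(self):
        assert (od_to_rgb(np.zeros((3, 1))) == 255).all()

    def test_od_ln2_maps_to_128(self):
        assert od_to_rgb(np.full((3, 1), np.log(2.0)))[0, 0] == 128

    def test_roundtrip_error_at_most_one_gray_level(self):
        vals = np.arange(256, dtype=np.uint8).reshape(1, -1)
        img = np.stack([vals] * 3, axis=-1)
        back = od_to_rgb(rgb_to_od(img), shape=(1, 256))
        assert np.abs(back.astype(int) - np.maximum(img, 1)).max() <= 1


class TestSparseCode:
    def test_unpenalized_exact_fit_in_cone(self):
        W = make_stain_matrix().W
        h_true = np.array([[1.3], [0.4]])
        v = W @ h_true
        h = sparse_code(v, W, lam=0.0, tol=1e-12, max_iter=2000)
        np.testing.assert_allclose(h, h_true, atol=1e-8)

    def test_orthogonal_soft_threshold(self):
        W = np.eye(3)[:, :2]
        h = sparse_code(2 * W[:, [0]], W, lam=0.2)
        np.testing.assert_allclose(h.ravel(), [1.8, 0.0], atol=1e-9)

    def test_kkt_all_zero_above_max_correlation(self):
        W = make_stain_matrix().W
        v = W @ np.array([[0.5], [0.2]])
        lam = float((W.T @ v).max()) + 1e-6
        assert (sparse_code(v, W, lam=lam) == 0).all()

    def test_objective_never_worse_than_zero_solution(self, rng):
        W = make_stain_matrix().W
        V = rng.uniform(0, 2, (3, 50))
        H = sparse_code(V, W, lam=0.2)
        assert snmf_objective(V, W, H, 0.2) <= snmf_objective(
            V, W, np.zeros_like(H), 0.2
        ) + 1e-12

    def test_matches_independent_lasso_solver(self, rng):
        """Cross-check against sklearn's positive LASSO on 2-dim problems."""
        for _ in range(20):
            W = rng.uniform(0.05, 1.0, (3, 2))
            W /= np.linalg.norm(W, axis=0)
            v = rng.uniform(0, 2, (3, 1))
            lam = 0.2
            ours = sparse_code(v, W, lam).ravel()
            ref = Lasso(
                alpha=lam / 3, positive=True, fit_intercept=False, tol=1e-12
            ).fit(W, v.ravel())
            obj_ours = 0.5 * np.sum((v.ravel() - W @ ours) ** 2) + lam * ours.sum()
            obj_ref = (
                0.5 * np.sum((v.ravel() - W @ ref.coef_) ** 2)
                + lam * ref.coef_.sum()
            )
            assert obj_ours <= obj_ref + 1e-4

    def test_nonfinite_input_raises(self):
        W = np.eye(3)[:, :2]
        with pytest.raises(ValueError):
            sparse_code(np.array([[np.nan], [0], [0]]), W, 0.2)


class TestEstimateStains:
    def test_recovers_true_stains_on_noiseless_render(self):
        gt, img = scene_image(seed=5)
        model, _ = estimate_stains(rgb_to_od(img))
        for j in range(2):
            cos = abs(model.W[:, j] @ gt.W_true.W[:, j])
            assert cos >= 0.99

    def test_unit_column_norms(self):
        _, img = scene_image(seed=2)
        model, _ = estimate_stains(rgb_to_od(img))
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-9)

    def test_single_stain_image_recovers_active_column(self):
        gt, _ = scene_image(seed=3)
        H = gt.H_true.copy()
        H[1] = 0.0  # hematoxylin only
        V = gt.W_true.W @ H
        img = np.rint(255 * np.exp(-V)).clip(0, 255).astype(np.uint8)
        img = img.T.reshape(gt.mask.shape[0], gt.mask.shape[1], 3)
        model, _ = estimate_stains(rgb_to_od(img))
        cosines = np.abs(model.W.T @ gt.W_true.W[:, 0])
        assert cosines.max() >= 0.99

    def test_objective_not_above_initialization(self):
        gt, img = scene_image(seed=7)
        V = rgb_to_od(img)
        model, maps = estimate_stains(V)
        mask = (V >= 0.15).any(axis=0)
        obj = snmf_objective(V[:, mask], model.W, maps.H[:, mask], 0.2)
        # initialization objective: zero H
        init = snmf_objective(V[:, mask], model.W, np.zeros_like(maps.H[:, mask]), 0.2)
        assert obj <= init

    def test_blank_image_is_degenerate(self):
        V = rgb_to_od(np.full((8, 8, 3), 255, np.uint8))
        with pytest.raises(DegenerateInputError):
            estimate_stains(V)


class TestOrderStains:
    def test_reference_vectors_put_hematoxylin_first(self):
        model = make_stain_matrix()
        ordered = order_stains(model)
        np.testing.assert_allclose(ordered.W, model.W)
        assert ordered.stain_order == ("hematoxylin", "eosin")

    def test_idempotent(self):
        model = order_stains(make_stain_matrix())
        np.testing.assert_allclose(order_stains(model).W, model.W)

    def test_swapped_input_swaps_columns_and_rows(self, rng):
        model = make_stain_matrix()
        H = rng.uniform(0, 1, (2, 10))
        swapped = StainModel(model.W[:, ::-1])
        back, maps = order_stains(swapped, DensityMaps(H[::-1].copy()))
        np.testing.assert_allclose(back.W, model.W)
        np.testing.assert_allclose(maps.H, H)

    def test_three_stain_model_unsupported(self):
        with pytest.raises(ValueError):
            order_stains(StainModel(np.ones((3, 3))))


class TestSeparate:
    def test_zero_eosin_gives_white_background(self):
        gt, _ = scene_image(seed=4)
        H = gt.H_true.copy()
        H[1] = 0.0
        img = np.rint(
            255 * np.exp(-(gt.W_true.W @ H))
        ).clip(0, 255).astype(np.uint8).T.reshape(128, 128, 3)
        _, back = separate(img, gt.W_true, DensityMaps(H))
        assert (back == 255).all()

    def test_foreground_dark_exactly_where_hematoxylin(self):
        gt, img = scene_image(seed=6)
        fore, _ = separate(img, gt.W_true, DensityMaps(gt.H_true))
        nonwhite = (fore < 255).any(axis=2).ravel()
        dense = gt.H_true[0] > 0.1
        # nuclei pixels must be nonwhite, and the foreground must be far
        # darker inside nuclei than over the stromal baseline
        assert nonwhite[dense].mean() > 0.99
        gray = fore.astype(float).mean(axis=2).ravel()
        assert gray[dense].mean() < gray[~dense].mean() - 50

    def test_reconstruction_close_to_original(self):
        gt, img = scene_image(seed=8)
        sep = StainSeparator().fit(img)
        V = rgb_to_od(img)
        resid = V - sep.stain_matrix_ @ sep.densities_.H
        # residual dominated by the L1 shrinkage bias, bounded well below signal
        assert np.sqrt((resid**2).mean()) < 0.2

    def test_shape_mismatch_raises(self):
        gt, img = scene_image(seed=4)
        with pytest.raises(Exception):
            separate(img[:50], gt.W_true, DensityMaps(gt.H_true))
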