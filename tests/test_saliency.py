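import math
from itertools import combinations

import numpy as np
import pytest

import lesionsubtype.nn as nnm
from lesionsubtype.cnn import CNNConfig, TrainedCNN, build_cnn
from lesionsubtype.errors import ArgumentError, NormalizationError, ShapeError
from lesionsubtype.saliency import (ROISet, build_rois, class_score,
                                    deep_attribution, grad_cam_pp,
                                    kernel_shap, normalize_saliency,
                                    roi_contrast)


@pytest.fixture(scope="module")
def random_cnn():
    cfg = CNNConfig(complexity_level=1, input_shape=(8, 8, 8))
    return TrainedCNN(model=build_cnn(cfg, seed=5), config=cfg)


def _passthrough_cnn(input_shape=(16, 16, 16)):
    """Network whose class-1 score sums last-conv channel 0, which itself
    passes the input through unchanged (center-tap identity convolutions)."""
    cfg = CNNConfig(complexity_level=1, input_shape=input_shape)
    model = build_cnn(cfg, seed=0)
    for layer in model.layers:
        if isinstance(layer, nnm.Conv3d):
            layer.w[...] = 0.0
            layer.w[0, 0, 1, 1, 1] = 1.0
            layer.b[...] = 0.0
        if isinstance(layer, nnm.Linear):
            layer.w[...] = 0.0
            layer.b[...] = 0.0
    lins = [l for l in model.layers if isinstance(l, nnm.Linear)]
    lins[0].w[0, :] = 1.0
    lins[1].w[0, 0] = 1.0
    lins[2].w[1, 0] = 1.0
    return TrainedCNN(model=model, config=cfg)


class TestGradCAMpp:
    def test_localizes_single_channel_stimulus(self):
        """With one pass-through channel and a positive gradient the map is
        proportional to relu(A): mass follows the stimulus corner."""
        trained = _passthrough_cnn()
        x1 = np.zeros((16, 16, 16))
        x1[:6, :6, :6] = 1.0
        x2 = np.zeros((16, 16, 16))
        x2[10:, 10:, 10:] = 1.0
        m1 = grad_cam_pp(trained, x1, 1).values
        m2 = grad_cam_pp(trained, x2, 1).values
        assert m1[:8, :8, :8].sum() > 100 * m1[8:, 8:, 8:].sum()
        assert m2[8:, 8:, 8:].sum() > 100 * m2[:8, :8, :8].sum()

    def test_nonnegative_on_random_inputs(self, random_cnn):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=(8, 8, 8))
            m = grad_cam_pp(random_cnn, x, int(rng.integers(2)))
            assert m.values.min() >= 0.0

    def test_constant_head_gives_zero_map(self):
        trained = _passthrough_cnn()
        lins = [l for l in trained.model.layers if isinstance(l, nnm.Linear)]
        lins[2].w[...] = 0.0  # class scores independent of features
        m = grad_cam_pp(trained, np.random.default_rng(1).normal(size=(16,) * 3), 1)
        assert np.allclose(m.values, 0.0)

    def test_output_aligned_to_input_grid(self, random_cnn):
        m = grad_cam_pp(random_cnn, np.zeros((8, 8, 8)), 0)
        assert m.values.shape == (8, 8, 8)
        assert m.sign_convention == "nonnegative"


class TestDeepAttribution:
    def test_linear_model_closed_form(self):
        """For an effectively linear score, attribution = w_i * (x_i - b_i)."""
        trained = _passthrough_cnn((8, 8, 8))
        # strictly positive inputs keep every ReLU on the linear branch
        rng = np.random.default_rng(2)
        x = rng.uniform(0.5, 1.0, size=(8, 8, 8))
        baseline = np.full((8, 8, 8), 0.25)
        att = deep_attribution(trained, x, 1, baseline[None], n_steps=4)
        f_x = class_score(trained, x[None], 1)[0]
        f_b = class_score(trained, baseline[None], 1)[0]
        assert att.values.sum() == pytest.approx(f_x - f_b, rel=1e-4)
        # identity pathway: max-pool selects block maxima; attribution is
        # concentrated on voxels and proportional to (x - b) there
        assert (att.values >= -1e-6).all()

    def test_input_equal_to_baseline_zero_attribution(self, random_cnn):
        x = np.full((8, 8, 8), 0.3)
        att = deep_attribution(random_cnn, x, 1, x[None])
        assert np.allclose(att.values, 0.0)

    def test_completeness_within_one_percent(self, random_cnn):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 8, 8)) * 0.5
        baseline = np.full((8, 8, 8), -1.0)
        att = deep_attribution(random_cnn, x, 1, baseline[None])
        f_x = class_score(random_cnn, x[None], 1)[0]
        f_b = class_score(random_cnn, baseline[None], 1)[0]
        gap = abs(att.values.sum() - (f_x - f_b))
        assert gap <= 1e-2 * abs(f_x - f_b)

    def test_no_baselines_raises(self, random_cnn):
        with pytest.raises(ArgumentError):
            deep_attribution(random_cnn, np.zeros((8, 8, 8)), 1,
                             np.zeros((0, 8, 8, 8)))


class TestKernelSHAP:
    def test_matches_brute_force_shapley(self):
        """Exhaustive kernel SHAP equals brute-force Shapley values under the
        same k-nearest-neighbor imputation value function."""
        rng = np.random.default_rng(0)
        m = 6
        w = rng.normal(size=m)

        def predict(Z):
            return np.atleast_2d(Z) @ w + 0.3

        x = rng.normal(size=m)
        bg = rng.normal(size=(20, m))
        phi = kernel_shap(predict, x, bg, n_coalitions=2 ** m, seed=0)

        k = math.ceil(0.1 * len(bg))
        refs = bg[np.argsort(((bg - x) ** 2).sum(1), kind="stable")[:k]]

        def value(S):
            mask = np.zeros(m, bool)
            mask[list(S)] = True
            return float(np.mean(predict(np.where(mask, x, refs))))

        brute = np.zeros(m)
        for j in range(m):
            others = [i for i in range(m) if i != j]
            for s in range(m):
                for S in combinations(others, s):
                    weight = (math.factorial(s) * math.factorial(m - s - 1)
                              / math.factorial(m))
                    brute[j] += weight * (value(S + (j,)) - value(S))
        assert np.abs(phi - brute).max() < 1e-8

    def test_efficiency_constraint(self):
        rng = np.random.default_rng(1)
        m = 5
        A = rng.normal(size=(m, m))

        def predict(Z):
            Z = np.atleast_2d(Z)
            return np.einsum("ni,ij,nj->n", Z, A, Z)  # nonlinear

        x = rng.normal(size=m)
        bg = rng.normal(size=(15, m))
        phi = kernel_shap(predict, x, bg, n_coalitions=2 ** m, seed=0)
        k = math.ceil(0.1 * 15)
        refs = bg[np.argsort(((bg - x) ** 2).sum(1), kind="stable")[:k]]
        v_empty = float(np.mean(predict(refs)))
        assert phi.sum() == pytest.approx(float(predict(x[None])[0]) - v_empty,
                                          abs=1e-6)

    def test_symmetric_features_equal_attribution(self):
        def predict(Z):
            Z = np.atleast_2d(Z)
            return Z[:, 0] + Z[:, 1] - 0.5 * Z[:, 2]

        x = np.array([2.0, 2.0, 1.0])
        bg = np.zeros((12, 3))
        phi = kernel_shap(predict, x, bg, n_coalitions=12, seed=0)
        assert phi[0] == pytest.approx(phi[1], abs=1e-6)

    def test_constant_predictor_all_zero(self):
        phi = kernel_shap(lambda Z: np.zeros(len(np.atleast_2d(Z))),
                          np.ones(4), np.zeros((10, 4)), n_coalitions=16)
        assert np.allclose(phi, 0.0)


class TestNormalize:
    def test_unit_sum(self):
        rng = np.random.default_rng(0)
        out = normalize_saliency(np.abs(rng.normal(size=(5, 5, 5))))
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_truncation_then_error_when_empty(self):
        with pytest.raises(NormalizationError):
            normalize_saliency(-np.ones((3, 3, 3)), zero_negatives=True)

    def test_truncation_noop_for_nonnegative_maps(self):
        v = np.abs(np.random.default_rng(1).normal(size=(4, 4, 4)))
        assert np.allclose(normalize_saliency(v, zero_negatives=True),
                           normalize_saliency(v, zero_negatives=False))


class TestROIs:
    @pytest.fixture()
    def geometry(self, small_template):
        t = small_template
        lesion = np.zeros(t.grid_shape, bool)
        seed = t.lesion_seed_voxel
        lesion[seed[0] - 1:seed[0] + 2, seed[1] - 1:seed[1] + 2,
               seed[2] - 1:seed[2] + 2] = True
        lesion &= t.left
        return t, lesion

    def test_left_rois_partition_left_brain(self, geometry):
        t, lesion = geometry
        rois = build_rois(lesion, t.brain, t.left, ring_width_voxels=1)
        combined = rois["lesion"] | rois["perilesional"] | rois["extralesional"]
        assert np.array_equal(combined, t.left)
        assert not (rois["lesion"] & rois["perilesional"]).any()
        assert not (rois["perilesional"] & rois["extralesional"]).any()

    def test_zero_ring_width_empty_perilesional(self, geometry):
        t, lesion = geometry
        rois = build_rois(lesion, t.brain, t.left, ring_width_voxels=0)
        assert not rois["perilesional"].any()

    def test_homologue_is_involutive_mirror(self, geometry):
        t, lesion = geometry
        rois = build_rois(lesion, t.brain, t.left)
        mirrored_back = rois["lesion_homologue"][::-1] & t.brain
        assert np.array_equal(mirrored_back, lesion & t.brain)

    def test_right_hemisphere_lesion_rejected(self, geometry):
        t, lesion = geometry
        with pytest.raises(ShapeError):
            build_rois(lesion[::-1], t.brain, t.left)


class TestROIContrast:
    def test_planted_class_difference_detected(self, small_template):
        t = small_template
        lesion = np.zeros(t.grid_shape, bool)
        seed = t.lesion_seed_voxel
        lesion[seed[0] - 1:seed[0] + 2, seed[1] - 1:seed[1] + 2,
               seed[2] - 1:seed[2] + 2] = True
        lesion &= t.left
        rois = build_rois(lesion, t.brain, t.left)
        rng = np.random.default_rng(0)
        n = 30
        labels = np.array([1] * 15 + [0] * 15)
        maps = np.abs(rng.normal(0.1, 0.01, size=(n,) + t.grid_shape))
        maps[labels == 1] += 5.0 * rois["lesion_homologue"]  # planted effect
        maps = np.stack([m / m.sum() for m in maps])
        out = roi_contrast(maps, rois, labels)
        assert out["lesion_homologue"]["p"] < 0.001
        assert out["lesion_homologue"]["mean_severe"] > \
            out["lesion_homologue"]["mean_nonsevere"]

    def test_null_classes_mostly_insignificant(self, small_template):
        t = small_template
        lesion = np.zeros(t.grid_shape, bool)
        s = t.lesion_seed_voxel
        lesion[s[0], s[1], s[2]] = True
        rois = build_rois(lesion, t.brain, t.left)
        rng = np.random.default_rng(1)
        hits = 0
        n_seeds = 10
        for _ in range(n_seeds):
            maps = np.abs(rng.normal(0.1, 0.02, size=(20,) + t.grid_shape))
            maps = np.stack([m / m.sum() for m in maps])
            labels = np.array([1] * 10 + [0] * 10)
            out = roi_contrast(maps, rois, labels)
            hits += out["extralesional"]["p"] > 0.05
        assert hits >= int(0.9 * n_seeds)

    def test_mass_confined_to_lesion(self, small_template):
        t = small_template
        lesion = np.zeros(t.grid_shape, bool)
        s = t.lesion_seed_voxel
        lesion[s[0] - 1:s[0] + 2, s[1] - 1:s[1] + 2, s[2] - 1:s[2] + 2] = True
        lesion &= t.left
        rois = build_rois(lesion, t.brain, t.left)
        maps = np.zeros((4,) + t.grid_shape)
        maps[:, lesion] = 1.0 / lesion.sum()
        out = roi_contrast(maps, rois, np.array([1, 1, 0, 0]))
        assert out["lesion"]["mean_severe"] == pytest.approx(1.0 / lesion.sum())
        assert out["extralesional"]["mean_severe"] == 0.0


class TestCrossMethodSimilarity:
    def test_shapley_style_maps_more_similar_to_each_other_than_gradcam(
            self, separable_cohort, trained_fixture_cnn):
        """Path-gradient attribution and kernel SHAP (both signed,
        voxel-resolution, Shapley-flavored) produce maps far more similar to
        each other under eta^2 than either is to Grad-CAM++, whose coarse
        nonnegative class-activation geometry is qualitatively different."""
        from lesionsubtype.subtyping import eta_squared_similarity
        from lesionsubtype.svm import SVMConfig, fit_svm

        X, y = separable_cohort["X"], separable_cohort["y"]
        trained = trained_fixture_cnn["trained"]
        tr = trained_fixture_cnn["train_idx"]
        va = trained_fixture_cnn["val_idx"]
        pred = np.argmax(trained_fixture_cnn["proba"], axis=1)
        Xf = X.reshape(len(X), -1)
        svm = fit_svm(Xf[tr], y[tr], SVMConfig(kernel="linear", cost=1.0),
                      seed=0)

        def svm_score(Z):
            return svm.decision_values(np.atleast_2d(Z))

        baseline = np.full(X.shape[1:], -1.0)
        sims = []
        for i in va[:3]:
            gc = grad_cam_pp(trained, X[i], int(pred[i])).values.ravel()
            da = deep_attribution(trained, X[i], int(pred[i]), baseline[None],
                                  n_steps=8, adaptive=False).values.ravel()
            ks = kernel_shap(svm_score, Xf[i], Xf[tr], n_coalitions=1300,
                             seed=int(i))
            sims.append((eta_squared_similarity(da, ks),
                         eta_squared_similarity(gc, ks),
                         eta_squared_similarity(gc, da)))
        sims = np.array(sims)
        assert (sims[:, 0] > sims[:, 1]).all()
        assert (sims[:, 0] > sims[:, 2]).all()
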