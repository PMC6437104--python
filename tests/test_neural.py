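"""MLP / RBFN training: gradients, determinism, benchmarks, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laughdx.acoustic_features import FeatureMatrix, FeatureSchema
from laughdx.neural_models import (MLPConfig, RBFNConfig, SplitSpec, Standardizer,
                                   MLPModel, holdout_split, kfold_split,
                                   mlp_forward, mlp_train, kmeans_centers,
                                   rbfn_train, predict_class, tanh_forward,
                                   tanh_backprop, _init_layers, _rbf_widths)


def _blobs(n=200, p=4, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([rng.normal(-sep / 2, 1.0, size=(half, p)),
                   rng.normal(+sep / 2, 1.0, size=(n - half, p))])
    y = np.concatenate([-np.ones(half), np.ones(n - half)])
    return X, y


class TestForward:
    def test_zero_weights_give_zero_score(self):
        cfg = MLPConfig(layer_sizes=(3, 16, 9, 1))
        model = MLPModel(config=cfg,
                         weights=[np.zeros((3, 16)), np.zeros((16, 9)), np.zeros((9, 1))],
                         biases=[np.zeros(16), np.zeros(9), np.zeros(1)])
        assert mlp_forward(model, np.ones(3))[0] == 0.0

    def test_toy_2_2_1_matches_hand_computation(self):
        W1 = np.array([[0.5, -0.25], [0.1, 0.3]])
        b1 = np.array([0.05, -0.1])
        W2 = np.array([[0.7], [-0.4]])
        b2 = np.array([0.2])
        cfg = MLPConfig(layer_sizes=(2, 2, 1), step_sizes=(1.0, 0.1))
        model = MLPModel(config=cfg, weights=[W1, W2], biases=[b1, b2])
        x = np.array([0.3, -0.6])
        h = np.tanh(x @ W1 + b1)
        expected = np.tanh(h @ W2 + b2)[0]
        assert abs(mlp_forward(model, x)[0] - expected) < 1e-12

    def test_input_dimensionality_enforced(self):
        cfg = MLPConfig(layer_sizes=(40, 16, 9, 1))
        rng = np.random.default_rng(0)
        Ws, bs = _init_layers(cfg.layer_sizes, rng)
        model = MLPModel(config=cfg, weights=Ws, biases=bs)
        assert mlp_forward(model, np.zeros(40)).shape == (1,)
        with pytest.raises(ValueError, match="40"):
            mlp_forward(model, np.zeros(39))


class TestGradients:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_backprop_matches_central_differences(self, seed):
        """Analytic gradients agree with finite differences to 1e-6
        relative error on random small nets."""
        rng = np.random.default_rng(seed)
        sizes = (3, 4, 2, 1)
        Ws, bs = _init_layers(sizes, rng)
        X = rng.normal(size=(5, 3))
        t = rng.choice([-1.0, 1.0], size=5)
        dWs, dbs, _ = tanh_backprop(Ws, bs, X, t)
        eps = 1e-6

        def loss():
            y = tanh_forward(Ws, bs, X)[-1]
            return float(np.mean((y - t[:, None]) ** 2))

        for l in range(len(Ws)):
            flat_idx = [(0, 0), (Ws[l].shape[0] - 1, Ws[l].shape[1] - 1)]
            for i, j in flat_idx:
                orig = Ws[l][i, j]
                Ws[l][i, j] = orig + eps
                up = loss()
                Ws[l][i, j] = orig - eps
                dn = loss()
                Ws[l][i, j] = orig
                num = (up - dn) / (2 * eps)
                scale = max(abs(num), abs(dWs[l][i, j]), 1e-8)
                assert abs(num - dWs[l][i, j]) / scale < 1e-5
            orig = bs[l][0]
            bs[l][0] = orig + eps
            up = loss()
            bs[l][0] = orig - eps
            dn = loss()
            bs[l][0] = orig
            num = (up - dn) / (2 * eps)
            scale = max(abs(num), abs(dbs[l][0]), 1e-8)
            assert abs(num - dbs[l][0]) / scale < 1e-5

    def test_zero_momentum_single_step_equals_gradient_descent(self):
        """With momentum 0 the first update is exactly -eta * gradient."""
        X, y = _blobs(n=20, p=3, seed=1)
        X = Standardizer().fit_transform(X)
        cfg = MLPConfig(layer_sizes=(3, 4, 2, 1), step_sizes=(0.01, 0.01, 0.01),
                        momentum=0.0, max_epochs=1, mse_stop_threshold=0.0, seed=5)
        rng = np.random.default_rng(5)
        Ws0, bs0 = _init_layers(cfg.layer_sizes, rng)
        dWs, dbs, _ = tanh_backprop(Ws0, bs0, X, y)
        model = mlp_train(cfg, X, y)
        for l in range(3):
            assert np.allclose(model.weights[l], Ws0[l] - 0.01 * dWs[l], atol=1e-12)
            assert np.allclose(model.biases[l], bs0[l] - 0.01 * dbs[l], atol=1e-12)

    def test_momentum_trajectory_reduces_to_plain_gd_when_zero(self):
        X, y = _blobs(n=30, p=2, seed=2)
        X = Standardizer().fit_transform(X)
        cfg = MLPConfig(layer_sizes=(2, 3, 2, 1), step_sizes=(0.05, 0.05, 0.05),
                        momentum=0.0, max_epochs=10, mse_stop_threshold=0.0, seed=3)
        model = mlp_train(cfg, X, y)
        # manual plain gradient descent
        rng = np.random.default_rng(3)
        Ws, bs = _init_layers(cfg.layer_sizes, rng)
        for _ in range(10):
            dWs, dbs, _ = tanh_backprop(Ws, bs, X, y)
            for l in range(3):
                Ws[l] = Ws[l] - 0.05 * dWs[l]
                bs[l] = bs[l] - 0.05 * dbs[l]
        for l in range(3):
            assert np.allclose(model.weights[l], Ws[l], atol=1e-12)


class TestTraining:
    def test_fixed_seed_bit_identical_weights(self):
        X, y = _blobs(seed=4)
        X = Standardizer().fit_transform(X)
        cfg = MLPConfig(layer_sizes=(4, 16, 9, 1), max_epochs=50, seed=11)
        m1 = mlp_train(cfg, X, y)
        m2 = mlp_train(cfg, X, y)
        for W1, W2 in zip(m1.weights, m2.weights):
            assert np.array_equal(W1, W2)

    def test_xor_learned_by_most_seeds(self):
        """Classic non-linear benchmark: the 2-16-9-1 tanh net with the
        study's step sizes reaches 100% training accuracy for >=8/10 seeds."""
        X = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
        y = np.array([-1.0, 1.0, 1.0, -1.0])
        wins = 0
        for seed in range(10):
            cfg = MLPConfig(layer_sizes=(2, 16, 9, 1), max_epochs=10_000,
                            mse_stop_threshold=1e-3, seed=seed)
            model = mlp_train(cfg, X, y)
            labels, _ = predict_class(model, X)
            wins += int(np.array_equal(labels, y))
        assert wins >= 8

    def test_separable_blobs_trained_to_99pct(self):
        X, y = _blobs(n=200, sep=4.0, seed=6)
        X = Standardizer().fit_transform(X)
        cfg = MLPConfig(layer_sizes=(4, 16, 9, 1), max_epochs=2000, seed=0)
        model = mlp_train(cfg, X, y)
        labels, _ = predict_class(model, X)
        assert np.mean(labels == y) >= 0.99

    def test_final_mse_not_above_initial(self):
        X, y = _blobs(n=100, seed=7)
        X = Standardizer().fit_transform(X)
        model = mlp_train(MLPConfig(layer_sizes=(4, 16, 9, 1), max_epochs=200), X, y)
        assert model.history[-1] <= model.history[0]

    def test_single_class_rejected(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError, match="both classes"):
            mlp_train(MLPConfig(layer_sizes=(4, 16, 9, 1)), X, np.ones(5))

    def test_divergence_aborts_with_diagnostic(self):
        X, y = _blobs(n=50, seed=8)
        # overflowing steps drive the weights non-finite within a few epochs
        cfg = MLPConfig(layer_sizes=(4, 16, 9, 1),
                        step_sizes=(1e308, 1e308, 1e308),
                        max_epochs=10, seed=0)
        with pytest.raises(RuntimeError, match="step size"):
            mlp_train(cfg, X, y)


class TestKMeans:
    def test_k_equals_n_centers_are_the_points(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 3))
        centers = kmeans_centers(X, n_centers=8, seed=0)
        d = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        assert np.allclose(d.min(axis=1), 0.0, atol=1e-12)

    def test_two_blob_centers_near_means(self):
        X, _ = _blobs(n=300, p=2, sep=8.0, seed=10)
        centers = kmeans_centers(X, n_centers=2, seed=1)
        centers = centers[np.argsort(centers[:, 0])]
        assert np.allclose(centers[0], [-4.0, -4.0], atol=0.1 * 1.0 * 3)
        assert np.allclose(centers[1], [4.0, 4.0], atol=0.3)

    def test_matches_sklearn_distortion_on_blobs(self):
        """Independent cross-check: on well-separated blobs our Lloyd
        iterations reach the same distortion as scikit-learn's k-means."""
        from sklearn.cluster import KMeans

        X, _ = _blobs(n=200, p=3, sep=8.0, seed=11)
        ours = kmeans_centers(X, n_centers=2, seed=0)
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)

        def distortion(centers):
            d = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            return float(d.min(axis=1).sum())

        assert abs(distortion(ours) - distortion(sk.cluster_centers_)) \
            < 1e-6 * distortion(sk.cluster_centers_)

    def test_same_seed_same_centers(self):
        X, _ = _blobs(n=60, seed=12)
        assert np.array_equal(kmeans_centers(X, 4, seed=3), kmeans_centers(X, 4, seed=3))

    def test_duplicate_points_warn(self):
        X = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (5, 1))
        with pytest.warns(UserWarning, match="distinct"):
            kmeans_centers(X, n_centers=4, seed=0)

    def test_too_few_exemplars_rejected(self):
        with pytest.raises(ValueError):
            kmeans_centers(np.zeros((3, 2)), n_centers=8)


class TestRBFN:
    def test_gaussian_limit_at_center(self):
        from laughdx.neural_models import RBFNModel

        centers = np.array([[0.0, 0.0], [10.0, 10.0]])
        model = RBFNModel(config=RBFNConfig(input_size=2, n_centers=2, hidden_size=2),
                          centers=centers, widths=np.array([0.01, 0.01]),
                          weights=[np.zeros((2, 2)), np.zeros((2, 1))],
                          biases=[np.zeros(2), np.zeros(1)])
        phi = model.rbf_layer(np.array([0.0, 0.0]))
        assert phi[0, 0] > 0.999 and phi[0, 1] < 1e-6

    def test_blobs_trained_above_95pct(self):
        X, y = _blobs(n=120, p=4, sep=4.0, seed=13)
        X = Standardizer().fit_transform(X)
        cfg = RBFNConfig(input_size=4, n_centers=8, supervised_epochs=2000, seed=0)
        model = rbfn_train(cfg, X, y)
        labels, _ = predict_class(model, X)
        assert np.mean(labels == y) >= 0.95

    def test_architecture_40_8_4_1(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 40))
        y = np.concatenate([np.ones(20), -np.ones(20)])
        cfg = RBFNConfig(supervised_epochs=5, seed=0)
        model = rbfn_train(cfg, X, y)
        assert model.centers.shape == (8, 40)
        assert model.weights[0].shape == (8, 4)
        assert model.weights[1].shape == (4, 1)
        with pytest.raises(ValueError, match="40"):
            model.forward(np.zeros((2, 39)))

    def test_width_heuristic_mean_of_two_nearest(self):
        centers = np.array([[0.0], [1.0], [10.0]])
        widths = _rbf_widths(centers)
        assert np.isclose(widths[0], (1.0 + 10.0) / 2)
        assert np.isclose(widths[1], (1.0 + 9.0) / 2)
        assert np.isclose(widths[2], (9.0 + 10.0) / 2)

    def test_tiny_widths_make_prototype_classifier(self):
        """As widths -> 0 with k = n the RBFN memorizes distinct training
        points (training accuracy 100%)."""
        rng = np.random.default_rng(15)
        X = rng.normal(size=(12, 3))
        y = np.concatenate([np.ones(6), -np.ones(6)])
        cfg = RBFNConfig(input_size=3, n_centers=12, hidden_size=4,
                         supervised_epochs=4000, seed=1)
        model = rbfn_train(cfg, X, y)
        model.widths = np.full(12, 0.05)
        # retrain the dense part on the sharpened prototypes
        phi = model.rbf_layer(X)
        from laughdx.neural_models import _train_tanh_layers, _init_layers
        Ws, bs = _init_layers((12, 4, 1), np.random.default_rng(1))
        Ws, bs, _ = _train_tanh_layers(Ws, bs, phi, y[:, None], (1.0, 0.1), 0.7,
                                       4000, 1e-4)
        model.weights, model.biases = Ws, bs
        labels, _ = predict_class(model, X)
        assert np.array_equal(labels, y)


class TestPredict:
    def _const_model(self, score):
        class M:
            def forward(self, X):
                return np.full(np.atleast_2d(X).shape[0], score)
        return M()

    def test_positive_score_is_depression(self):
        labels, scores = predict_class(self._const_model(0.9), np.zeros((3, 2)))
        assert np.all(labels == 1.0) and np.all(scores == 0.9)

    def test_score_at_threshold_is_control(self):
        labels, _ = predict_class(self._const_model(0.0), np.zeros((2, 2)))
        assert np.all(labels == -1.0)

    def test_extreme_thresholds(self):
        m = self._const_model(0.3)
        assert np.all(predict_class(m, np.zeros((4, 2)), threshold=-1.0)[0] == 1.0)
        assert np.all(predict_class(m, np.zeros((4, 2)), threshold=1.0)[0] == -1.0)


def _fm(n_subjects=10, laughs_each=4, p=3, seed=0):
    rng = np.random.default_rng(seed)
    rows, ys, sids, lids = [], [], [], []
    for s in range(n_subjects):
        label = 1.0 if s < n_subjects // 2 else -1.0
        for l in range(laughs_each):
            rows.append(rng.normal(size=p))
            ys.append(label)
            sids.append(f"S{s:02d}")
            lids.append(f"S{s:02d}_L{l}")
    schema = FeatureSchema("ANN40", p, tuple(f"x{i}" for i in range(p)))
    return FeatureMatrix(X=np.array(rows), y=np.array(ys),
                         subject_ids=np.array(sids, dtype=object),
                         laugh_ids=np.array(lids, dtype=object), schema=schema)


class TestSplitting:
    def test_stratified_8_2_subjects(self):
        fm = _fm(n_subjects=10)
        tr, te = holdout_split(fm, SplitSpec(seed=0))
        assert len(set(te.subject_ids)) == 2
        assert {1.0, -1.0} == set(te.y) == set(tr.y)

    def test_same_seed_same_split(self):
        fm = _fm()
        tr1, te1 = holdout_split(fm, SplitSpec(seed=5))
        tr2, te2 = holdout_split(fm, SplitSpec(seed=5))
        assert np.array_equal(tr1.laugh_ids, tr2.laugh_ids)

    def test_no_subject_straddles_the_split(self):
        fm = _fm(n_subjects=12, laughs_each=3)
        tr, te = holdout_split(fm, SplitSpec(seed=1))
        assert set(tr.subject_ids).isdisjoint(set(te.subject_ids))

    def test_kfold_each_subject_held_out_once(self):
        fm = _fm(n_subjects=10)
        folds = kfold_split(fm, k=5, seed=2)
        assert len(folds) == 5
        held = []
        for tr, te in folds:
            assert set(tr.subject_ids).isdisjoint(set(te.subject_ids))
            held.extend(sorted(set(te.subject_ids)))
        assert sorted(held) == sorted(set(fm.subject_ids))

    def test_standardizer_constant_column_maps_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        z = Standardizer().fit_transform(X)
        assert np.all(z[:, 1] == 0.0)
        assert abs(z[:, 0].std() - 1.0) < 1e-12
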