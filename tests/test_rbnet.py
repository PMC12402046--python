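"""Classifier construction, training recipe and data splitting."""

import numpy as np
import pytest

from erbnet._nn import BatchNorm3D, Conv3D, Dense, Dropout, GlobalAvgPool, MaxPool3D
from erbnet.rbnet import (RBNetClassifier, RBNetSpec, TrainConfig, build_model,
                          predict_proba, split_dataset, train_model, train_per_dose)


def separable_patches(n_per_class=10, side=32, seed=0):
    """All-high vs all-low intensity cubes: trivially separable."""
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(0.7, 0.05, size=(n_per_class, side, side, side)),
                        rng.normal(0.2, 0.05, size=(n_per_class, side, side, side))])
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return X.astype(np.float32), y


class TestArchitecture:
    def test_default_architecture_configuration(self):
        spec = RBNetSpec()
        assert spec.n_blocks == 4
        assert spec.filters_per_block == (64, 128, 192, 256)
        assert spec.scaled_filters() == (64, 128, 192, 256)

    def test_scaled_preset_filters(self):
        spec = RBNetSpec(scale=1 / 8, input_side=32)
        assert spec.scaled_filters() == (8, 16, 24, 32)

    def test_block_structure_of_built_network(self):
        model = build_model(RBNetSpec(scale=1 / 8, input_side=32))
        layers = model.net_.layers
        convs = [l for l in layers if isinstance(l, Conv3D)]
        assert [c.out_channels for c in convs] == [8, 16, 24, 32]
        # block = conv -> BN -> ReLU -> pool, repeated 4x, then GAP/dropout/dense
        assert len([l for l in layers if isinstance(l, BatchNorm3D)]) == 4
        assert len([l for l in layers if isinstance(l, MaxPool3D)]) == 4
        assert isinstance(layers[-3], GlobalAvgPool)
        assert isinstance(layers[-2], Dropout)
        assert isinstance(layers[-1], Dense)

    def test_indivisible_input_side_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            RBNetSpec(input_side=40)
        with pytest.raises(ValueError, match="divisible"):
            RBNetClassifier(filters_per_block=(4, 4, 4, 4), input_side=24).initialize()

    def test_untrained_outputs_in_open_unit_interval(self):
        model = RBNetClassifier.ci_preset(random_state=0).initialize()
        X = np.random.default_rng(0).random((3, 32, 32, 32), dtype=np.float32)
        p = model.predict_proba(X)[:, 1]
        assert np.all((p > 0) & (p < 1))

    def test_zeroed_head_outputs_half(self):
        model = RBNetClassifier.ci_preset(random_state=0).initialize()
        head = model.net_.layers[-1]
        head.w[...] = 0.0
        head.b[...] = 0.0
        X = np.random.default_rng(1).random((4, 32, 32, 32), dtype=np.float32)
        assert np.allclose(model.predict_proba(X)[:, 1], 0.5)


class TestSplit:
    def test_stratified_60_20_20(self):
        X = np.zeros((100, 2))
        y = np.array([0, 1] * 50)
        (Xtr, ytr), (Xv, yv), (Xte, yte) = split_dataset(X, y, TrainConfig(seed=0))
        assert len(ytr) == 60 and len(yv) == 20 and len(yte) == 20
        assert ytr.sum() == 30 and yv.sum() == 10 and yte.sum() == 10

    def test_split_is_a_partition(self):
        X = np.arange(50, dtype=float).reshape(-1, 1)
        y = np.array([0, 1] * 25)
        parts = split_dataset(X, y, TrainConfig(seed=3))
        seen = np.concatenate([p[0].ravel() for p in parts])
        assert sorted(seen) == list(np.arange(50, dtype=float))

    def test_seeded_determinism(self):
        X = np.arange(40, dtype=float).reshape(-1, 1)
        y = np.array([0, 1] * 20)
        a = split_dataset(X, y, TrainConfig(seed=5))
        b = split_dataset(X, y, TrainConfig(seed=5))
        for (Xa, ya), (Xb, yb) in zip(a, b):
            assert np.array_equal(Xa, Xb) and np.array_equal(ya, yb)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            split_dataset(np.zeros((10, 1)), np.ones(10), TrainConfig())


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        X, y = separable_patches(10)
        model = RBNetClassifier.ci_preset(random_state=1, n_restarts=1)
        model.fit(X, y)
        assert model.history_["accuracy"][-1] == 1.0
        assert np.array_equal(model.predict(X), y)

    def test_learning_rate_schedule_is_exponential(self):
        X, y = separable_patches(2, side=16, seed=2)
        model = RBNetClassifier(filters_per_block=(2, 2, 2, 2), input_side=16,
                                learning_rate=1e-4, decay_factor=0.96, epochs=5,
                                batch_size=4, random_state=0)
        model.fit(X, y)
        assert model.history_["lr"] == pytest.approx(
            [1e-4 * 0.96 ** e for e in range(5)])

    def test_training_is_deterministic(self):
        X, y = separable_patches(4, side=16, seed=3)
        kwargs = dict(filters_per_block=(2, 2, 2, 2), input_side=16, epochs=2,
                      batch_size=4, learning_rate=1e-3, random_state=9)
        p1 = RBNetClassifier(**kwargs).fit(X, y).predict_proba(X)
        p2 = RBNetClassifier(**kwargs).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_best_validation_weights_retained(self):
        X, y = separable_patches(6, side=16, seed=4)
        model = RBNetClassifier(filters_per_block=(2, 2, 2, 2), input_side=16,
                                epochs=4, batch_size=4, learning_rate=1e-3,
                                random_state=0)
        model.fit(X, y, validation_data=(X, y))
        assert model.best_epoch_ == int(np.argmin(model.history_["val_loss"]))

    def test_non_binary_labels_rejected(self):
        X, _ = separable_patches(2, side=16)
        with pytest.raises(ValueError, match="binary"):
            RBNetClassifier(filters_per_block=(2, 2, 2, 2), input_side=16).fit(
                X, np.array([0, 1, 2, 1]))


class TestInference:
    @pytest.fixture(scope="class")
    def fitted(self):
        X, y = separable_patches(4, side=16, seed=5)
        model = RBNetClassifier(filters_per_block=(2, 3, 4, 5), input_side=16,
                                epochs=2, batch_size=4, learning_rate=1e-3,
                                random_state=2)
        return model.fit(X, y), X

    def test_duplicated_patch_same_probability(self, fitted):
        model, X = fitted
        dup = np.stack([X[0], X[0], X[2]])
        p = model.predict_proba(dup)[:, 1]
        assert p[0] == p[1]

    def test_invariant_to_batch_partitioning(self, fitted):
        model, X = fitted
        whole = model.predict_proba(X)[:, 1]
        parts = np.concatenate([model.predict_proba(X[:3])[:, 1],
                                model.predict_proba(X[3:])[:, 1]])
        assert np.allclose(whole, parts, atol=1e-7)

    def test_shape_mismatch_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError, match="input_side"):
            model.predict_proba(np.zeros((2, 32, 32, 32), dtype=np.float32))

    def test_module_level_predict_proba_is_positive_class(self, fitted):
        model, X = fitted
        assert np.allclose(predict_proba(model, X), model.predict_proba(X)[:, 1])


class TestPerDoseRegistry:
    @staticmethod
    def tiny_factory():
        return RBNetClassifier(filters_per_block=(2, 2, 2, 2), input_side=16,
                               epochs=1, batch_size=4, learning_rate=1e-3)

    def test_missing_level_reported(self):
        X, y = separable_patches(2, side=16)
        with pytest.raises(ValueError, match=r"0\.1"):
            train_per_dose({1.0: (X, y)}, TrainConfig(epochs=1),
                           model_factory=self.tiny_factory,
                           expected_fractions=(1.0, 0.1))

    def test_registry_trains_one_model_per_level(self):
        X, y = separable_patches(3, side=16, seed=6)
        fractions = (1.0, 0.4)
        datasets = {f: (X, y) for f in fractions}
        reg = train_per_dose(datasets, TrainConfig(epochs=1, seed=4),
                             model_factory=self.tiny_factory,
                             expected_fractions=fractions)
        assert set(reg) == set(fractions)
        # independently trained instances with distinct derived seeds
        assert reg[1.0] is not reg[0.4]
        assert reg[1.0].random_state != reg[0.4].random_state

    def test_single_class_level_rejected(self):
        X, y = separable_patches(2, side=16)
        with pytest.raises(ValueError, match="class"):
            train_per_dose({1.0: (X, np.zeros_like(y))}, TrainConfig(epochs=1),
                           model_factory=self.tiny_factory,
                           expected_fractions=(1.0,))
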