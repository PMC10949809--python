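"""Multi-task network: loss algebra, training contracts, determinism."""

import numpy as np
import pandas as pd
import pytest

from mciprog.cnn import (DEFAULT_AUX_GRID, ImagingDataset, LossSpec,
                         MultiTaskCNN, NetworkConfig, class_weights,
                         combined_loss, train, weight_grid_search)
from mciprog.errors import (ConfigurationError, DegenerateLabelsError,
                            ShapeError)

SMALL = dict(input_shape=(8, 8, 8), clinical_dim=4)


def _toy_dataset(n, seed, shape=(8, 8, 8), clinical_dim=4,
                 informative=True):
    """Random volumes; labels tied to the clinical vector when informative."""
    rng = np.random.default_rng(seed)
    clin = rng.normal(size=(n, clinical_dim))
    labels = ((clin[:, 0] > 0).astype(int) if informative
              else rng.integers(0, 2, n))
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return ImagingDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        mri=rng.normal(size=(n, 1) + shape),
        jd=1.0 + 0.1 * rng.normal(size=(n, 1) + shape),
        clinical=clin, labels=labels,
        slopes=rng.normal(-1.0, 0.5, n),
        hippo=rng.normal(3000.0, 400.0, n))


class TestLossAlgebra:
    def test_published_weight_setting_exact_sum(self):
        spec = LossSpec(1.0, 0.025, 0.025)
        assert combined_loss(spec, 0.6, 4.0, 8.0) == pytest.approx(0.9,
                                                                   abs=1e-15)

    def test_single_task_reduction(self):
        spec = LossSpec(1.0, 0.0, 0.0)
        assert combined_loss(spec, 0.37, 5.0, 9.0) == 0.37

    def test_linearity_in_weights(self, rng):
        l1, l2, l3 = rng.random(3)
        base = combined_loss(LossSpec(1.0, 0.3, 0.6), l1, l2, l3)
        doubled = combined_loss(LossSpec(2.0, 0.6, 1.2), l1, l2, l3)
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            combined_loss(LossSpec(1.0, -0.1, 0.0), 1, 1, 1)


class TestClassWeights:
    def test_cohort_composition_weights(self):
        labels = np.array([0] * 223 + [1] * 109)
        w_neg, w_pos = class_weights(labels)
        assert w_neg == pytest.approx(332 / 446, abs=1e-12)
        assert w_pos == pytest.approx(332 / 218, abs=1e-12)

    def test_balanced_labels_unit_weights(self):
        assert class_weights(np.array([0, 1, 0, 1])) == (1.0, 1.0)

    def test_label_flip_symmetry(self):
        labels = np.array([0] * 30 + [1] * 10)
        assert class_weights(labels) == tuple(
            reversed(class_weights(1 - labels)))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            class_weights(np.zeros(5))


class TestBuild:
    def test_forward_contracts_on_zero_batch(self):
        from mciprog import nn
        config = NetworkConfig(**SMALL, seed=0)
        model = MultiTaskCNN(config)
        z1, z2, z3 = model.forward(np.zeros((2, 1, 8, 8, 8)),
                                   np.zeros((2, 1, 8, 8, 8)),
                                   np.zeros((2, 4)))
        for z in (z1, z2, z3):
            assert z.shape == (2,) and np.isfinite(z).all()
        assert ((nn.sigmoid(z1) >= 0) & (nn.sigmoid(z1) <= 1)).all()

    def test_identical_seed_identical_initialization(self):
        a = MultiTaskCNN(NetworkConfig(**SMALL, seed=5))
        b = MultiTaskCNN(NetworkConfig(**SMALL, seed=5))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = MultiTaskCNN(NetworkConfig(**SMALL, seed=6))
        assert any(not np.array_equal(pa.value, pc.value)
                   for pa, pc in zip(a.params(), c.params()))

    def test_parameter_budget_and_ceiling(self):
        model = MultiTaskCNN(NetworkConfig(seed=0))   # 32^3 default
        assert model.parameter_count <= model.config.param_ceiling
        with pytest.raises(ConfigurationError):
            MultiTaskCNN(NetworkConfig(param_ceiling=10, seed=0))

    def test_too_small_input_rejected(self):
        with pytest.raises(ShapeError):
            MultiTaskCNN(NetworkConfig(input_shape=(4, 4, 4),
                                       clinical_dim=2, seed=0))


class TestTraining:
    def test_history_logs_all_components_every_epoch(self):
        config = NetworkConfig(**SMALL, epochs=3, seed=1)
        model = MultiTaskCNN(config)
        data = _toy_dataset(12, 0)
        hist = train(model, data, data, LossSpec(1.0, 0.025, 0.025), config)
        assert list(hist["epoch"]) == [1, 2, 3]
        for col in ("L", "L1", "L2", "L3", "val_auc", "val_r2"):
            assert col in hist and hist[col].notna().all()
        np.testing.assert_allclose(
            hist["L"], hist["L1"] + 0.025 * hist["L2"] + 0.025 * hist["L3"],
            atol=1e-12)

    def test_same_seed_reproduces_final_losses(self):
        config = NetworkConfig(**SMALL, epochs=4, seed=2)
        data = _toy_dataset(10, 3)
        runs = []
        for _ in range(2):
            model = MultiTaskCNN(config)
            hist = train(model, data, None, LossSpec(), config)
            runs.append(hist["L"].to_numpy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_gradient_isolation_of_auxiliary_heads(self):
        """With w2 = w3 = 0 the auxiliary head weights never move."""
        config = NetworkConfig(**SMALL, epochs=2, seed=4)
        model = MultiTaskCNN(config)
        w2 = model.head_slope.W.value.copy()
        w3 = model.head_hippo.W.value.copy()
        train(model, _toy_dataset(8, 5), None, LossSpec(1.0, 0.0, 0.0),
              config)
        np.testing.assert_array_equal(model.head_slope.W.value, w2)
        np.testing.assert_array_equal(model.head_hippo.W.value, w3)
        assert not np.array_equal(
            model.head_progression.W.value,
            MultiTaskCNN(config).head_progression.W.value)

    def test_small_set_memorization_capacity(self):
        """Eight subjects, single-task training: the network must be able
        to drive its weighted cross-entropy below 0.05."""
        config = NetworkConfig(**SMALL, epochs=200, seed=6,
                               lr_milestones=(120, 180), dropout=0.0,
                               weight_decay=0.0)
        model = MultiTaskCNN(config)
        data = _toy_dataset(8, 7)
        hist = train(model, data, None, LossSpec(1.0, 0.0, 0.0), config)
        assert hist["L1"].iloc[-1] < 0.05


class TestWeightGridSearch:
    def _folds(self):
        return [(_toy_dataset(10, s), _toy_dataset(6, s + 100))
                for s in (0, 1)]

    def test_table_shape_and_deterministic_selection(self):
        config = NetworkConfig(**SMALL, epochs=2, seed=3)
        table, best = weight_grid_search((0.0, 0.025), self._folds(),
                                         config)
        assert len(table) == 2 * 2
        assert best in (0.0, 0.025)
        table2, best2 = weight_grid_search((0.0, 0.025), self._folds(),
                                           config)
        assert best2 == best and table2.equals(table)

    def test_ties_prefer_smaller_weight(self, monkeypatch):
        import mciprog.cnn as cnn_mod
        monkeypatch.setattr(
            cnn_mod, "train",
            lambda *a, **k: pd.DataFrame({"val_auc": [0.7]}))
        config = NetworkConfig(**SMALL, epochs=1, seed=0)
        _, best = weight_grid_search((0.0, 0.05, 0.025), self._folds(),
                                     config)
        assert best == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            weight_grid_search((), self._folds(),
                               NetworkConfig(**SMALL, seed=0))

    def test_default_grid_is_the_published_sweep(self):
        assert DEFAULT_AUX_GRID == (0.0, 0.025, 0.050, 0.075, 0.1)
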