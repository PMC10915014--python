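"""Fold planning, seeded network training, gradients, fusion, and CV hygiene."""

import numpy as np
import pandas as pd
import pytest

from harloc import models as md
from harloc._nn import CNNClassifier, LSTMClassifier, cross_entropy, softmax
from harloc.errors import ValidationError
from harloc.io_formats import FeatureMatrix


class TestFoldPlan:
    def test_even_split(self):
        plan = md.make_fold_plan(10, 5)
        assert [len(b) for b in plan.test_blocks] == [2, 2, 2, 2, 2]

    def test_balanced_remainder(self):
        plan = md.make_fold_plan(11, 5)
        assert sorted((len(b) for b in plan.test_blocks), reverse=True) == [3, 2, 2, 2, 2]

    def test_partition_property(self):
        plan = md.make_fold_plan(23, 4)
        all_rows = np.concatenate(plan.test_blocks)
        assert sorted(all_rows.tolist()) == list(range(23))
        for fold in range(4):
            assert not set(plan.train_indices(fold)) & set(plan.test_blocks[fold].tolist())

    def test_blocks_are_contiguous(self):
        plan = md.make_fold_plan(17, 3)
        for block in plan.test_blocks:
            assert np.all(np.diff(block) == 1)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValidationError):
            md.make_fold_plan(3, 5)


class TestSequences:
    def test_majority_label_with_earliest_tie_break(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        seqs, seq_labels, ends = md.build_sequences(X, labels, 4)
        assert seqs.shape == (3, 4, 2)
        assert list(seq_labels) == ["a", "b", "b"]
        assert list(ends) == [3, 4, 5]

    def test_too_few_rows_yield_no_instances(self):
        X = np.zeros((2, 3))
        seqs, seq_labels, _ = md.build_sequences(X, np.array(["a", "a"]), 5)
        assert len(seqs) == 0


def finite_diff_grads(loss_fn, params, eps=1e-6):
    grads = {}
    for key, value in params.items():
        g = np.zeros_like(value)
        it = np.nditer(value, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = value[idx]
            value[idx] = orig + eps
            lp = loss_fn()
            value[idx] = orig - eps
            lm = loss_fn()
            value[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
            it.iternext()
        grads[key] = g
    return grads


class TestGradients:
    def test_lstm_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        model = LSTMClassifier(hidden=4, seed=0)
        X = rng.normal(size=(3, 2, 5))
        y = np.array(["a", "b", "a"])
        y_idx = model._encode_labels(y)
        model._init_params(5, 2)

        def loss():
            logits, _, _ = model._forward(X)
            return cross_entropy(softmax(logits), y_idx)

        logits, h_last, cache = model._forward(X)
        analytic = model._backward(X, y_idx, softmax(logits), h_last, cache)
        numeric = finite_diff_grads(loss, model.params)
        for key in model.params:
            np.testing.assert_allclose(analytic[key], numeric[key], atol=1e-6)

    def test_cnn_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        model = CNNClassifier(filters=3, kernel=3, hidden=4, seed=0)
        X = rng.normal(size=(4, 12))
        y = np.array(["a", "b", "a", "b"])
        y_idx = model._encode_labels(y)
        model._init_params(12, 2)

        def loss():
            logits, _ = model._forward(X)
            return cross_entropy(softmax(logits), y_idx)

        logits, cache = model._forward(X)
        analytic = model._backward(y_idx, softmax(logits), cache)
        numeric = finite_diff_grads(loss, model.params)
        for key in model.params:
            np.testing.assert_allclose(analytic[key], numeric[key], atol=1e-6)


@pytest.fixture(scope="module")
def separable_matrix():
    """Four well-separated Gaussian classes in contiguous time runs."""
    rng = np.random.default_rng(42)
    centers = {"sitting": [3, 0, 0], "standing": [0, 3, 0],
               "walking": [0, 0, 3], "lying": [-3, -3, 0]}
    rows, labels = [], []
    for _ in range(6):  # 6 contiguous runs per class
        for cls, center in centers.items():
            rows.append(rng.normal(center, 0.3, size=(6, 3)))
            labels.extend([cls] * 6)
    df = pd.DataFrame(np.vstack(rows), columns=["f0", "f1", "f2"])
    return FeatureMatrix(values=df, labels=np.array(labels))


class TestTraining:
    def test_lstm_fits_separable_fixture(self, separable_matrix):
        cfg = md.ModelConfig(task="locomotion", seed=7, epochs=30)
        model = md.train_lstm(separable_matrix, cfg)
        seqs, seq_labels, _ = md.build_sequences(
            separable_matrix.to_array(), separable_matrix.labels, cfg.seq_len)
        acc = np.mean(model.predict(seqs) == seq_labels)
        assert acc >= 0.95
        assert model.loss_history[-1] <= model.loss_history[0]

    def test_lstm_seeded_determinism(self, separable_matrix):
        cfg = md.ModelConfig(task="locomotion", seed=7, epochs=5)
        m1 = md.train_lstm(separable_matrix, cfg)
        m2 = md.train_lstm(separable_matrix, cfg)
        assert m1.weights_checksum() == m2.weights_checksum()

    def test_more_epochs_do_not_raise_final_loss(self, separable_matrix):
        cfg1 = md.ModelConfig(task="locomotion", seed=7, epochs=1)
        cfg50 = md.ModelConfig(task="locomotion", seed=7, epochs=50)
        l1 = md.train_lstm(separable_matrix, cfg1).loss_history[-1]
        l50 = md.train_lstm(separable_matrix, cfg50).loss_history[-1]
        assert l50 <= l1

    def test_cnn_fits_separable_fixture(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, size=(40, 12)),
                       rng.normal(2, 0.3, size=(40, 12))])
        labels = np.array(["indoor"] * 40 + ["outdoor"] * 40)
        fm = FeatureMatrix(values=pd.DataFrame(X), labels=labels,
                           branch="localization")
        fm.values.columns = [f"f{i}" for i in range(12)]
        cfg = md.ModelConfig(task="localization", arch="cnn", seed=7, epochs=30)
        model = md.train_cnn(fm, cfg)
        assert np.mean(model.predict(X) == labels) >= 0.95

    def test_cnn_robust_to_fixed_column_permutation(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, size=(60, 12)),
                       rng.normal(2, 0.3, size=(60, 12))])
        labels = np.array(["indoor"] * 60 + ["outdoor"] * 60)
        order = rng.permutation(120)
        X, labels = X[order], labels[order]
        train, test = np.arange(80), np.arange(80, 120)
        perm = rng.permutation(12)
        accs = []
        for columns in (np.arange(12), perm):
            df = pd.DataFrame(X[:, columns], columns=[f"f{i}" for i in range(12)])
            fm = FeatureMatrix(values=df.iloc[train], labels=labels[train],
                               branch="localization")
            cfg = md.ModelConfig(task="localization", arch="cnn", seed=7, epochs=30)
            model = md.train_cnn(fm, cfg)
            accs.append(np.mean(model.predict(X[test][:, columns]) == labels[test]))
        assert abs(accs[0] - accs[1]) <= 0.05

    def test_cnn_feature_dim_too_small_rejected(self):
        fm = FeatureMatrix(values=pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)),
                                               columns=["a", "b"]),
                           labels=np.array(["x", "y"] * 5), branch="localization")
        cfg = md.ModelConfig(task="localization", arch="cnn", epochs=1)
        with pytest.raises(ValidationError):
            md.train_cnn(fm, cfg)

    def test_checkpoint_round_trip(self, separable_matrix, tmp_path):
        cfg = md.ModelConfig(task="locomotion", seed=7, epochs=3)
        model = md.train_lstm(separable_matrix, cfg)
        md.save_model(model, tmp_path / "model.npz", cfg)
        back = md.load_model(tmp_path / "model.npz")
        seqs, _, _ = md.build_sequences(separable_matrix.to_array(),
                                        separable_matrix.labels, cfg.seq_len)
        np.testing.assert_array_equal(model.predict(seqs), back.predict(seqs))


class TestHybrid:
    def test_dimensions_concatenate(self, separable_matrix):
        cfg = md.ModelConfig(task="locomotion", seed=7, epochs=5)
        model = md.train_lstm(separable_matrix, cfg)
        hyb = md.hybrid_features(model, separable_matrix, seq_len=cfg.seq_len)
        assert len(hyb.columns) == 3 + 64
        assert sum(c.startswith("deep__") for c in hyb.columns) == 64

    def test_deterministic_for_frozen_model(self, separable_matrix):
        cfg = md.ModelConfig(task="locomotion", seed=7, epochs=5)
        model = md.train_lstm(separable_matrix, cfg)
        h1 = md.hybrid_features(model, separable_matrix, seq_len=cfg.seq_len)
        h2 = md.hybrid_features(model, separable_matrix, seq_len=cfg.seq_len)
        np.testing.assert_array_equal(h1.to_array(), h2.to_array())


class TestCrossValidation:
    def test_oracle_feature_reaches_perfect_accuracy(self):
        # one feature equals the class id -> perfectly predictable; the
        # remaining columns are uninformative constants (pass-through)
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b", "c", "a", "b", "c"], 15)
        class_id = pd.Series(labels).map({"a": 0.0, "b": 1.0, "c": 2.0}).to_numpy()
        df = pd.DataFrame({
            "oracle": class_id + rng.normal(0, 0.01, len(labels)),
            **{f"pad{i}": np.zeros(len(labels)) for i in range(11)},
        })
        fm = FeatureMatrix(values=df, labels=labels, branch="localization")
        cfg = md.ModelConfig(task="localization", arch="cnn", seed=1, epochs=60)
        result = md.run_cv(fm, cfg, k=5)
        assert result.pooled.accuracy == 1.0

    def test_fold_indices_match_plan_and_stay_disjoint(self, separable_matrix):
        cfg = md.ModelConfig(task="locomotion", seed=7, epochs=2)
        result = md.run_cv(separable_matrix, cfg, k=4)
        plan = md.make_fold_plan(separable_matrix.n_rows, 4)
        for record in result.records:
            np.testing.assert_array_equal(
                record.test_rows, plan.test_blocks[record.fold])
            test = set(record.test_rows.tolist())
            assert not test & set(record.transform_fit_rows.tolist())
            assert not test & set(record.model_fit_rows.tolist())
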