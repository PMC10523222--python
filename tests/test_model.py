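import numpy as np
import pytest

import squatcheck as sq
from squatcheck.model import EvalReport, LABELS, predict_label
from squatcheck.nn import BiLSTM, Conv1D


def random_features(rng, T=30):
    return rng.normal(size=(T, 20)) * 0.05


class TestBuildModel:
    def test_valid_padding_shrinks_time_by_kernel_sum(self):
        # (5-1) + (3-1) + (3-1) = 8 frames lost across the conv stack
        model = sq.build_model(sq.ModelConfig(seed=0))
        x = np.zeros((20, 20))
        conv_out = x
        for layer in model.network.layers[:6]:  # conv/dropout stack
            conv_out = layer.forward(conv_out)
        assert conv_out.shape == (12, 64)
        assert model.min_length == 9

    def test_first_conv_parameter_count(self):
        # 20 channels * 32 filters * depth 5 weights + 32 biases = 3232
        model = sq.build_model(sq.ModelConfig(seed=0))
        assert model.network.layers[0].n_params == 3232

    def test_lstm_only_has_zero_conv_parameters(self):
        model = sq.build_model(sq.ModelConfig(variant="lstm_only", seed=0))
        assert model.network.conv_param_count == 0
        assert not any(isinstance(l, Conv1D) for l in model.network.layers)

    def test_conv_only_has_no_lstm(self):
        model = sq.build_model(sq.ModelConfig(variant="conv_only", seed=0))
        assert not any(isinstance(l, BiLSTM) for l in model.network.layers)

    def test_bilstm_output_dimensionality_is_total(self):
        model = sq.build_model(sq.ModelConfig(variant="lstm_only", seed=0))
        out = model.network.layers[0].forward(np.zeros((5, 20)))
        assert out.shape == (64,)  # 32 per direction, concatenated

    def test_inconsistent_config_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.ModelConfig(conv_kernel_depths=(5, 3), conv_filters=(32, 64, 64))
        with pytest.raises(sq.ValidationError):
            sq.ModelConfig(dropout=1.5)
        with pytest.raises(sq.ValidationError):
            sq.ModelConfig(variant="huge")


class TestClassify:
    def test_scores_sum_to_one_and_deterministic(self, trained_full_model):
        model, _ = trained_full_model
        rng = np.random.default_rng(0)
        x = random_features(rng)
        from squatcheck.nn import softmax

        p = softmax(model.network.forward(x))
        assert p[0] + p[1] == pytest.approx(1.0, abs=1e-6)
        assert sq.classify(model, x) == sq.classify(model, x.copy())

    def test_too_short_input_names_minimum(self):
        model = sq.build_model(sq.ModelConfig(seed=0))
        with pytest.raises(sq.TooShortError, match="9"):
            sq.classify(model, np.zeros((8, 20)))

    def test_held_out_correct_squat_scores_high(self, trained_full_model,
                                                separation_dataset):
        model, (_, _, te) = trained_full_model
        feats, labels, _ = separation_dataset
        scores = [sq.classify(model, feats[i]) for i in te if labels[i] == "correct"]
        assert np.mean([s > 0.5 for s in scores]) > 0.9


class TestTrain:
    def test_zero_learning_rate_changes_nothing(self):
        rng = np.random.default_rng(5)
        data = [(random_features(rng), i % 2) for i in range(8)]
        cfg = sq.ModelConfig(seed=3, learning_rate=0.0, dropout=0.0, max_epochs=3)
        model = sq.build_model(cfg)
        before = {k: v.copy() for k, v in model.network.named_params().items()}
        sq.train(model, data)
        losses = [r["loss"] for r in model.training_history]
        assert losses[0] == pytest.approx(losses[-1], rel=1e-12)
        for k, v in model.network.named_params().items():
            assert np.array_equal(before[k], v)

    def test_single_class_training_set_rejected(self):
        rng = np.random.default_rng(5)
        data = [(random_features(rng), 1) for _ in range(4)]
        with pytest.raises(sq.ValidationError):
            sq.train(sq.build_model(sq.ModelConfig(seed=0)), data)

    def test_empty_training_set_rejected(self):
        with pytest.raises(sq.EmptyInputError):
            sq.train(sq.build_model(sq.ModelConfig(seed=0)), [])

    def test_training_is_deterministic_per_seed(self):
        rng = np.random.default_rng(7)
        data = [(random_features(rng), i % 2) for i in range(12)]
        scores = []
        for _ in range(2):
            model = sq.build_model(sq.ModelConfig(seed=11, max_epochs=2))
            sq.train(model, data)
            scores.append(sq.classify(model, data[0][0]))
        assert scores[0] == scores[1]


class TestEvaluate:
    def test_metrics_match_brute_force_oracle(self):
        # independent oracle: count the four confusion cells directly
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(2, 40)
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            tp = int(np.sum((y_true == 1) & (y_pred == 1)))
            tn = int(np.sum((y_true == 0) & (y_pred == 0)))
            fp = int(np.sum((y_true == 0) & (y_pred == 1)))
            fn = int(np.sum((y_true == 1) & (y_pred == 0)))
            rep = EvalReport.from_predictions(y_true, y_pred)
            assert rep.accuracy == pytest.approx((tp + tn) / n)
            if tp + fp:
                assert rep.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert rep.recall == pytest.approx(tp / (tp + fn))

    def test_hand_computed_confusion_example(self):
        # TP=87, FP=13, FN=16, TN=84
        y_true = [1] * 87 + [0] * 13 + [1] * 16 + [0] * 84
        y_pred = [1] * 87 + [1] * 13 + [0] * 16 + [0] * 84
        rep = EvalReport.from_predictions(y_true, y_pred)
        assert rep.precision == pytest.approx(0.87)
        assert rep.recall == pytest.approx(87 / 103, abs=1e-4)
        assert rep.accuracy == pytest.approx(0.855)

    def test_degenerate_predictors(self):
        perfect = EvalReport.from_predictions([0, 1, 0, 1], [0, 1, 0, 1])
        assert perfect.accuracy == perfect.precision == perfect.recall == 1.0
        all_one = EvalReport.from_predictions([0, 1, 0, 1], [1, 1, 1, 1])
        assert all_one.accuracy == 0.5

    def test_permutation_invariance(self, trained_full_model, separation_dataset):
        model, (_, _, te) = trained_full_model
        feats, labels, _ = separation_dataset
        data = [(feats[i], labels[i]) for i in te]
        rep1 = sq.evaluate(model, data)
        rep2 = sq.evaluate(model, data[::-1])
        assert rep1.accuracy == rep2.accuracy
        assert np.array_equal(rep1.confusion, rep2.confusion)

    def test_empty_dataset_rejected(self, trained_full_model):
        model, _ = trained_full_model
        with pytest.raises(sq.EmptyInputError):
            sq.evaluate(model, [])


class TestSplitsAndGridSearch:
    def test_subject_split_keeps_groups_apart(self, separation_dataset):
        feats, _, groups = separation_dataset
        tr, va, te = sq.subject_split(len(feats), groups, seed=1)
        g = np.asarray(groups)
        assert not (set(g[tr]) & set(g[te]))
        assert not (set(g[tr]) & set(g[va]))
        assert len(tr) + len(va) + len(te) == len(feats)

    def test_subject_vs_sequence_split_differ(self, separation_dataset):
        feats, _, groups = separation_dataset
        _, _, te_subject = sq.subject_split(len(feats), groups, seed=1)
        _, _, te_seq = sq.subject_split(len(feats), list(range(len(feats))), seed=1)
        assert set(te_subject) != set(te_seq)

    def test_grid_of_one_returns_that_combination(self, separation_dataset):
        feats, labels, groups = separation_dataset
        tr, va, _ = sq.subject_split(len(feats), groups, seed=0)
        tr_correct = [i for i in tr if labels[i] == "correct"][:10]
        tr_shallow = [i for i in tr if labels[i] == "incorrect"][:10]
        train_set = [(feats[i], labels[i]) for i in tr_correct + tr_shallow]
        val_set = [(feats[i], labels[i]) for i in va[:10]]
        best, acc, table = sq.grid_search(
            train_set, val_set, {"learning_rate": [0.003]},
            base=sq.ModelConfig(seed=0, max_epochs=3),
        )
        assert best.learning_rate == 0.003
        assert len(table) == 1

    def test_grid_prefers_learning_over_frozen(self, separation_dataset):
        feats, labels, groups = separation_dataset
        tr, va, _ = sq.subject_split(len(feats), groups, seed=0)
        train_set = [(feats[i], labels[i]) for i in tr]
        val_set = [(feats[i], labels[i]) for i in va]
        best, acc, table = sq.grid_search(
            train_set, val_set, {"learning_rate": [0.0, 0.003]},
            base=sq.ModelConfig(seed=0, max_epochs=8, early_stop_patience=8),
        )
        assert best.learning_rate == 0.003
        assert len(table) == 2


class TestCheckpoint:
    def test_round_trip_preserves_scores(self, trained_full_model, tmp_path):
        model, _ = trained_full_model
        path = tmp_path / "model.npz"
        sq.save_checkpoint(model, path)
        back = sq.load_checkpoint(path)
        rng = np.random.default_rng(3)
        x = random_features(rng)
        assert sq.classify(back, x) == sq.classify(model, x)

    def test_channel_order_mismatch_refused(self, trained_full_model, tmp_path):
        model, _ = trained_full_model
        path = tmp_path / "model.npz"
        sq.save_checkpoint(model, path)
        with pytest.raises(sq.SchemaError, match="channel order"):
            sq.load_checkpoint(path, expect_channel_order=["bogus"])
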