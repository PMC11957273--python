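"""Metric panel, training loop contracts, cross-validation, ablation table."""

import dataclasses
import itertools

import numpy as np
import pytest

from gkan.architectures import ModelConfig, build_classifier
from gkan.optim import EMA, AdamW
from gkan.synthetic_data import LabeledSequenceSet, sample_background
from gkan.train_eval import (MetricsReport, TrainConfig, ablation_sweep,
                             compute_metrics, cross_validate, evaluate_fold,
                             matthews_corrcoef, train_classifier)
from _oracles import mcc_from_vectors

TINY_MODEL = dict(num_blocks=2, channels=(8, 8), seq_length=60, seed=0)


def tiny_labeled_set(n=120, length=60, seed=0, constant_label=None):
    seqs = sample_background(n, length, seed=seed)
    labels = (np.zeros(n, dtype=int) if constant_label is not None
              else np.arange(n) % 2)
    folds = np.arange(n) % 3
    return LabeledSequenceSet(sequences=seqs, labels=labels, fold_ids=folds,
                              motif_spans=[None] * n)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        s = np.array([0.1, 0.9, 0.2, 0.8, 0.7])
        row = compute_metrics(y, s)
        assert row["mcc"] == 1.0 and row["f1"] == 1.0 and row["roc_auc"] == 1.0

    def test_all_positive_predictor_on_balanced_labels(self):
        y = np.array([0, 1] * 10)
        s = np.full(20, 0.9)
        assert compute_metrics(y, s)["mcc"] == 0.0  # degenerate denominator

    def test_hand_confusion_table(self):
        # TP=45 FN=5 FP=10 TN=40
        y = np.array([1] * 50 + [0] * 50)
        s = np.array([0.9] * 45 + [0.1] * 5 + [0.9] * 10 + [0.1] * 40)
        row = compute_metrics(y, s)
        expected = (45 * 40 - 10 * 5) / np.sqrt(55 * 50 * 50 * 45)
        assert row["mcc"] == pytest.approx(expected, abs=1e-10)
        assert row["mcc"] == pytest.approx(0.7035, abs=5e-4)
        assert row["mcc"] == pytest.approx(mcc_from_vectors(45, 5, 10, 40),
                                           abs=1e-10)

    def test_mcc_agrees_with_correlation_oracle(self):
        """MCC from the confusion formula equals the Pearson correlation of
        the expanded label/prediction vectors, over all small tables."""
        for tp, fn, fp, tn in itertools.product(range(0, 9), repeat=4):
            if tp + fn + fp + tn == 0:
                continue
            assert matthews_corrcoef(tp, fn, fp, tn) == pytest.approx(
                mcc_from_vectors(tp, fn, fp, tn), abs=1e-10)

    def test_single_class_roc_undefined(self):
        row = compute_metrics(np.ones(5), np.linspace(0, 1, 5))
        assert row["roc_auc"] is None

    def test_mcc_label_score_symmetry(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.uniform(0, 1, 50)
        a = compute_metrics(y, s)["mcc"]
        b = compute_metrics(1 - y, 1 - s + 1e-9)["mcc"]
        assert a == pytest.approx(b, abs=1e-9)

    def test_roc_auc_complement(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.uniform(0, 1, 60)  # continuous, ties have measure zero
        a = compute_metrics(y, s)["roc_auc"]
        b = compute_metrics(y, -s)["roc_auc"]
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0.5])


class TestEMA:
    def test_decay_zero_tracks_raw_weights(self):
        model = build_classifier(ModelConfig(**TINY_MODEL))
        ema = EMA(model, 0.0)
        for p in model.parameters():
            p.data = p.data + 1.0
        ema.update()
        for k, p in model.named_parameters():
            assert np.array_equal(ema.shadow[k], p.data)

    def test_decay_near_one_freezes_at_initialization(self):
        model = build_classifier(ModelConfig(**TINY_MODEL))
        init = {k: p.data.copy() for k, p in model.named_parameters()}
        ema = EMA(model, 1.0 - 1e-12)
        for p in model.parameters():
            p.data = p.data + 100.0
        for _ in range(5):
            ema.update()
        for k in init:
            assert np.allclose(ema.shadow[k], init[k], atol=1e-6)

    def test_invalid_decay_rejected(self):
        model = build_classifier(ModelConfig(**TINY_MODEL))
        with pytest.raises(ValueError):
            EMA(model, 1.0)


class TestTrainClassifier:
    def test_zero_epochs_leaves_model_unchanged(self):
        data = tiny_labeled_set()
        model = build_classifier(ModelConfig(**TINY_MODEL))
        before = model.state_dict()
        model, history = train_classifier(model, data, 0,
                                          TrainConfig(epochs=0, seed=0))
        after = model.state_dict()
        assert history["train_loss"] == []
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_training_is_deterministic_under_seed(self):
        data = tiny_labeled_set()
        losses = []
        for _ in range(2):
            model = build_classifier(ModelConfig(**TINY_MODEL))
            _, h = train_classifier(model, data, 0,
                                    TrainConfig(epochs=2, batch_size=32, seed=5))
            losses.append((h["train_loss"], h["val_loss"]))
        assert losses[0] == losses[1]

    def test_ema_and_kan_penalty_paths_run(self):
        data = tiny_labeled_set()
        model = build_classifier(ModelConfig(**TINY_MODEL, variant="lkan"))
        _, h = train_classifier(
            model, data, 0,
            TrainConfig(epochs=1, batch_size=32, seed=1, use_ema=True,
                        ema_decay=0.9, kan_l1_weight=1e-4,
                        kan_entropy_weight=1e-5))
        assert len(h["train_loss"]) == 1 and np.isfinite(h["train_loss"][0])

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1).validate()
        with pytest.raises(ValueError):
            TrainConfig(ema_decay=1.0).validate()


class TestCrossValidate:
    def test_constant_labels_give_zero_mcc_everywhere(self):
        data = tiny_labeled_set(constant_label=0)
        report = cross_validate(ModelConfig(**TINY_MODEL),
                                data, TrainConfig(epochs=0, seed=0))
        assert len(report.per_fold) == 3
        assert all(row["mcc"] == 0.0 for row in report.per_fold)
        assert all(row["roc_auc"] is None for row in report.per_fold)

    def test_identical_folds_aggregate_with_zero_std(self):
        report = MetricsReport(per_fold=[
            {"mcc": 0.8, "accuracy": 0.9, "roc_auc": 0.95, "precision": 0.9,
             "recall": 0.9, "f1": 0.9}] * 2)
        agg = report.aggregate()
        assert agg["mcc"] == (0.8, 0.0)

    def test_report_dataframe_shape(self):
        data = tiny_labeled_set()
        report = cross_validate(ModelConfig(**TINY_MODEL), data,
                                TrainConfig(epochs=0, seed=0))
        df = report.to_dataframe()
        assert len(df) == 3 and "mcc" in df.columns


class TestAblation:
    def test_sweep_table_complete_and_param_scaling(self, zdna_small):
        tcfg = TrainConfig(epochs=1, batch_size=64, seed=2)
        base = ModelConfig(num_blocks=2, channels=(8, 8), seq_length=80, seed=2)
        table = ablation_sweep(base, [3, 6], [0, 2], zdna_small, tcfg)
        assert len(table) == 4
        assert set(zip(table.grid_size, table.replaced_blocks)) == {
            (3, 0), (3, 2), (6, 0), (6, 2)}
        # params strictly increasing in G for N > 0, flat for N = 0
        p = table.set_index(["grid_size", "replaced_blocks"])["params"]
        assert p[(6, 2)] > p[(3, 2)]
        assert p[(6, 0)] == p[(3, 0)]
        assert np.isfinite(table.sec_per_batch).all()

    def test_zero_replacement_rows_match_baseline_run(self, zdna_small):
        tcfg = TrainConfig(epochs=1, batch_size=64, seed=2)
        base = ModelConfig(num_blocks=2, channels=(8, 8), seq_length=80, seed=2)
        table = ablation_sweep(base, [4], [0], zdna_small, tcfg)
        model = build_classifier(dataclasses.replace(base, variant="baseline"))
        model, _ = train_classifier(model, zdna_small, 0, tcfg)
        row = evaluate_fold(model, zdna_small, 0)
        assert table.iloc[0]["f1"] == pytest.approx(row["f1"], abs=1e-12)
        assert table.iloc[0]["mcc"] == pytest.approx(row["mcc"], abs=1e-12)

    def test_out_of_range_replacement_rejected(self, zdna_small):
        base = ModelConfig(num_blocks=2, channels=(8, 8), seq_length=80)
        with pytest.raises(ValueError):
            ablation_sweep(base, [3], [5], zdna_small, TrainConfig(epochs=0))
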