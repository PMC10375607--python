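"""Confusion matrices, metric formulas, masking, and per-lead evaluation."""

import numpy as np
import pytest

from ecgdelin.network import ModelConfig, TrainConfig, build_network
from ecgdelin.segmentation import WINDOW_LENGTH, BeatWindow
from ecgdelin.synthetic_ecg import SynthConfig, synth_beats
from ecgdelin.training_eval import (
    confusion_matrix,
    evaluate,
    evaluate_per_lead,
    masked_sample_accuracy,
    per_class_metrics,
    train_model,
)


def _oracle_confusion(true, pred, mask):
    cm = np.zeros((4, 4), dtype=int)
    for t, p, m in zip(true.ravel(), pred.ravel(), mask.ravel()):
        if m:
            cm[t, p] += 1
    return cm


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([[0, 1, 2, 3, 2, 1]])
        cm = confusion_matrix(y, y)
        assert (cm == np.diag([1, 2, 2, 1])).all()

    def test_single_off_diagonal_cell(self):
        true = np.full((1, 10), 1)
        pred = np.full((1, 10), 3)
        cm = confusion_matrix(true, pred)
        assert cm[1, 3] == 10 and cm.sum() == 10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            confusion_matrix(np.zeros(5, dtype=int), np.zeros(6, dtype=int))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        true = rng.integers(0, 4, (5, 200))
        pred = rng.integers(0, 4, (5, 200))
        mask = rng.random((5, 200)) > 0.3
        np.testing.assert_array_equal(
            confusion_matrix(true, pred, mask), _oracle_confusion(true, pred, mask)
        )

    def test_conservation_equals_unmasked_count(self):
        rng = np.random.default_rng(1)
        true = rng.integers(0, 4, (3, 100))
        pred = rng.integers(0, 4, (3, 100))
        mask = rng.random((3, 100)) > 0.5
        assert confusion_matrix(true, pred, mask).sum() == mask.sum()


class TestPerClassMetrics:
    def test_perfect_diagonal_all_100(self):
        report = per_class_metrics(np.diag([10, 20, 30, 40]))
        for metric in ("ACC", "SEN", "SPE", "PRE", "F1"):
            np.testing.assert_allclose(report.per_class[metric], 100.0)
            assert report.macro[metric] == pytest.approx(100.0)

    def test_hand_computed_two_class_case(self):
        """Confusion [[50,10],[10,30]] in classes 0/1 (classes 2/3 empty):
        class 0 has SEN = PRE = 50/60, SPE = 30/40, ACC = 80/100."""
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 50, 10, 10, 30
        report = per_class_metrics(cm)
        row = report.per_class.set_index("class").loc["iso"]
        assert row["SEN"] == pytest.approx(100 * 50 / 60, abs=1e-9)
        assert row["PRE"] == pytest.approx(100 * 50 / 60, abs=1e-9)
        assert row["SPE"] == pytest.approx(75.0, abs=1e-9)
        assert row["ACC"] == pytest.approx(80.0, abs=1e-9)
        assert row["F1"] == pytest.approx(100 * 50 / 60, abs=1e-9)

    def test_empty_class_excluded_from_macro(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0], cm[1, 1] = 10, 10
        report = per_class_metrics(cm)
        by_class = report.per_class.set_index("class")
        assert np.isnan(by_class.loc["QRS", "SEN"])
        # macro SEN averages only the classes with true samples
        assert report.macro["SEN"] == pytest.approx(100.0)

    def test_negative_entries_rejected(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0] = -1
        with pytest.raises(ValueError, match="non-negative"):
            per_class_metrics(cm)

    @pytest.mark.parametrize("seed", range(100))
    def test_metrics_match_naive_recount(self, seed):
        """Formula check against an independent per-class recount."""
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 50, (4, 4))
        report = per_class_metrics(cm)
        n = cm.sum()
        for c in range(4):
            tp = cm[c, c]
            fn = cm[c].sum() - tp
            fp = cm[:, c].sum() - tp
            tn = n - tp - fn - fp
            row = report.per_class.iloc[c]
            if tp + fn:
                assert row["SEN"] == pytest.approx(100 * tp / (tp + fn))
            if tp + fp:
                assert row["PRE"] == pytest.approx(100 * tp / (tp + fp))
            if tn + fp:
                assert row["SPE"] == pytest.approx(100 * tn / (tn + fp))
            assert row["ACC"] == pytest.approx(100 * (tp + tn) / n)
            # harmonic-mean property
            if np.isfinite(row["F1"]):
                assert min(row["PRE"], row["SEN"]) - 1e-9 <= row["F1"]
                assert row["F1"] <= max(row["PRE"], row["SEN"]) + 1e-9
            for metric in ("ACC", "SEN", "SPE", "PRE", "F1"):
                value = row[metric]
                assert np.isnan(value) or 0.0 <= value <= 100.0


def _label_beats(n, seed=0, lead="II"):
    """Tiny labeled beats with ramp signals, for training plumbing tests."""
    rng = np.random.default_rng(seed)
    beats = []
    for i in range(n):
        labels = np.zeros(WINDOW_LENGTH, dtype=np.int64)
        labels[50:80] = 1
        beats.append(BeatWindow(
            record_id=str(i), lead=lead, beat_index=0,
            signal=rng.standard_normal(WINDOW_LENGTH) * 0.1,
            labels=labels, valid_length=WINDOW_LENGTH, start_sample=0,
        ))
    return beats


REDUCED = ModelConfig(model_id="reduced", conv_filters=(8, 16), head="BiLSTM",
                      head_units=16)
TINY = ModelConfig(model_id="tiny", conv_filters=(8,), head="GRU", head_units=4)


class TestTrainModel:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_model(TINY, TrainConfig(epochs=1), [])

    def test_one_epoch_yields_one_log_entry(self):
        beats = _label_beats(8)
        _, log = train_model(TINY, TrainConfig(epochs=1, learning_rate=1e-3), beats)
        assert len(log) == 1
        assert {"epoch", "train_loss"} <= set(log.columns)

    def test_fixed_seed_reproducible_loss_trajectory(self):
        beats = _label_beats(8)
        tc = TrainConfig(epochs=2, learning_rate=1e-3, seed=7)
        _, log1 = train_model(TINY, tc, beats)
        _, log2 = train_model(TINY, tc, beats)
        assert log1["train_loss"].tolist() == log2["train_loss"].tolist()

    def test_padded_samples_excluded_from_loss(self):
        """Corrupting labels inside the padded region must not change training."""
        beats = _label_beats(8)
        short = []
        for b in beats:
            labels = b.labels.copy()
            signal = b.signal.copy()
            signal[400:] = 0.0
            short.append(BeatWindow(
                record_id=b.record_id, lead=b.lead, beat_index=b.beat_index,
                signal=signal, labels=labels, valid_length=400, start_sample=0,
            ))
        tc = TrainConfig(epochs=1, learning_rate=1e-3, seed=0)
        _, log_a = train_model(TINY, tc, short)
        corrupted = [
            BeatWindow(
                record_id=b.record_id, lead=b.lead, beat_index=b.beat_index,
                signal=b.signal,
                labels=np.where(np.arange(WINDOW_LENGTH) >= 400, 3, b.labels),
                valid_length=400, start_sample=0,
            )
            for b in short
        ]
        _, log_b = train_model(TINY, tc, corrupted)
        assert log_a["train_loss"].tolist() == log_b["train_loss"].tolist()


class TestEvaluation:
    def test_single_lead_report_matches_all(self):
        beats = synth_beats(12, SynthConfig(), seed=4)
        lead = beats[0].lead
        one_lead = [b for b in beats if b.lead == lead]
        model = build_network(
            ModelConfig(model_id="e", conv_filters=(8,), head="GRU", head_units=4),
            seed=0,
        )
        reports = evaluate_per_lead(model, one_lead)
        assert set(reports) == {lead, "all"}
        np.testing.assert_array_equal(
            reports[lead].confusion, reports["all"].confusion
        )

    def test_masked_accuracy_equals_confusion_trace(self):
        beats = synth_beats(6, SynthConfig(), seed=9)
        model = build_network(
            ModelConfig(model_id="e", conv_filters=(8,), head="GRU", head_units=4),
            seed=1,
        )
        report = evaluate(model, beats)
        from ecgdelin.training_eval import _predict_batch

        y, p, m = _predict_batch(model, beats)
        acc = masked_sample_accuracy(y, p, m)
        assert acc == pytest.approx(
            100.0 * np.trace(report.confusion) / report.confusion.sum()
        )
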