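"""Training and evaluation of sample-wise wave classifiers.

Loss is categorical cross-entropy computed over non-padded samples only
(positions past a beat's ``valid_length`` are masked out of both the loss
and every metric — trailing zeros labeled "isoelectric" would otherwise
inflate all scores).  One model is trained on beats pooled from all 12
leads and evaluated per lead; every position of the 512-sample window is
one classification event, so the confusion matrix counts samples.

Metrics follow the one-vs-rest convention per class c:
SEN = TP/(TP+FN), SPE = TN/(TN+FP), PRE = TP/(TP+FP), ACC = (TP+TN)/N,
F1 = 2*PRE*SEN/(PRE+SEN), all in percent; the macro row is the unweighted
mean over classes, skipping classes whose ratio is undefined (zero
denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ludb_io import WAVE_CLASSES
from .network import (
    Adam,
    ModelConfig,
    SequenceLabeler,
    TrainConfig,
    build_network,
    softmax,
)
from .segmentation import BeatWindow

logger = logging.getLogger(__name__)

N_CLASSES = 4
METRIC_NAMES = ("ACC", "SEN", "SPE", "PRE", "F1")


@dataclass
class MetricsReport:
    """Per-class and macro classification metrics for one evaluation scope."""

    confusion: np.ndarray  # (4, 4) int, rows true, columns predicted
    per_class: pd.DataFrame  # columns: class, ACC, SEN, SPE, PRE, F1 (percent)
    macro: dict[str, float]
    scope: str
    n_samples: int


def _stack_beats(beats: Sequence[BeatWindow]):
    x = np.stack([b.signal for b in beats])
    y = np.stack([b.labels for b in beats])
    mask = np.stack([b.mask for b in beats])
    return x, y, mask


def confusion_matrix(
    true: np.ndarray, predicted: np.ndarray, masks: np.ndarray | None = None
) -> np.ndarray:
    """4x4 count matrix over unmasked samples; entry (i, j) = true i, predicted j."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {true.shape} vs {predicted.shape}")
    if masks is None:
        masks = np.ones_like(true, dtype=bool)
    elif masks.shape != true.shape:
        raise ValueError(f"mask shape {masks.shape} does not match {true.shape}")
    t = true[masks].ravel()
    p = predicted[masks].ravel()
    return np.bincount(t * N_CLASSES + p, minlength=N_CLASSES**2).reshape(
        N_CLASSES, N_CLASSES
    )


def per_class_metrics(confusion: np.ndarray, scope: str = "all") -> MetricsReport:
    """One-vs-rest ACC/SEN/SPE/PRE/F1 per class plus unweighted macro means.

    Undefined ratios (zero denominator) are reported as NaN, excluded from
    the macro means, and logged.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (N_CLASSES, N_CLASSES) or (confusion < 0).any():
        raise ValueError("confusion must be a non-negative 4x4 matrix")
    n = int(confusion.sum())
    rows = []
    for c in range(N_CLASSES):
        tp = confusion[c, c]
        fn = confusion[c].sum() - tp
        fp = confusion[:, c].sum() - tp
        tn = n - tp - fn - fp

        def ratio(num, den, name):
            if den == 0:
                logger.info("class %s: %s undefined (zero denominator)",
                            WAVE_CLASSES[c], name)
                return np.nan
            return 100.0 * num / den

        sen = ratio(tp, tp + fn, "SEN")
        spe = ratio(tn, tn + fp, "SPE")
        pre = ratio(tp, tp + fp, "PRE")
        acc = ratio(tp + tn, n, "ACC")
        f1 = (
            2 * pre * sen / (pre + sen)
            if np.isfinite(pre) and np.isfinite(sen) and (pre + sen) > 0
            else np.nan
        )
        rows.append({"class": WAVE_CLASSES[c], "ACC": acc, "SEN": sen,
                     "SPE": spe, "PRE": pre, "F1": f1})
    table = pd.DataFrame(rows)
    macro = {m: float(np.nanmean(table[m])) for m in METRIC_NAMES}
    return MetricsReport(
        confusion=confusion, per_class=table, macro=macro, scope=scope, n_samples=n
    )


def masked_sample_accuracy(
    true: np.ndarray, predicted: np.ndarray, masks: np.ndarray
) -> float:
    """Fraction (percent) of unmasked samples classified correctly."""
    return 100.0 * float((true[masks] == predicted[masks]).mean())


def train_model(
    config: ModelConfig,
    train_config: TrainConfig,
    train_beats: Sequence[BeatWindow],
    val_beats: Sequence[BeatWindow] = (),
) -> tuple[SequenceLabeler, pd.DataFrame]:
    """Train one model; returns (model, per-epoch log).

    The log records epoch, mean training loss, and (when a validation set
    is given) masked validation sample accuracy and macro F1.
    """
    train_beats = list(train_beats)
    if not train_beats:
        raise ValueError("training set is empty")
    if any(b.signal.shape != (config.input_length,) for b in train_beats):
        raise ValueError(f"all beats must have length {config.input_length}")
    rng = np.random.default_rng(train_config.seed)
    model = build_network(config, seed=train_config.seed)
    optimizer = Adam(model, train_config.learning_rate)
    x, y, mask = _stack_beats(train_beats)
    n = len(train_beats)
    log_rows = []
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            model.zero_grads()
            loss = model.loss_and_grad(x[idx], y[idx], mask[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or inspect the input scaling"
                )
            optimizer.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_beats:
            yv, pv, mv = _predict_batch(model, val_beats)
            report = per_class_metrics(confusion_matrix(yv, pv, mv), scope="val")
            row["val_accuracy"] = masked_sample_accuracy(yv, pv, mv)
            row["val_macro_f1"] = report.macro["F1"]
            logger.info("epoch %d: loss %.4f, val acc %.2f%%",
                        epoch, row["train_loss"], row["val_accuracy"])
        log_rows.append(row)
    return model, pd.DataFrame(log_rows)


def _predict_batch(
    model: SequenceLabeler, beats: Sequence[BeatWindow], batch_size: int = 32
):
    x, y, mask = _stack_beats(beats)
    preds = np.zeros_like(y)
    for start in range(0, len(beats), batch_size):
        logits = model.forward_logits(x[start : start + batch_size])
        preds[start : start + batch_size] = np.argmax(softmax(logits), axis=-1)
    return y, preds, mask


def evaluate(
    model: SequenceLabeler, beats: Sequence[BeatWindow], scope: str = "all"
) -> MetricsReport:
    """Masked sample-wise metrics over a beat collection."""
    y, preds, mask = _predict_batch(model, beats)
    return per_class_metrics(confusion_matrix(y, preds, mask), scope=scope)


def evaluate_per_lead(
    model: SequenceLabeler, beats: Sequence[BeatWindow]
) -> dict[str, MetricsReport]:
    """One MetricsReport per lead present plus a pooled "all" report."""
    by_lead: dict[str, list[BeatWindow]] = {}
    for beat in beats:
        by_lead.setdefault(beat.lead, []).append(beat)
    reports = {
        lead: evaluate(model, group, scope=lead)
        for lead, group in sorted(by_lead.items())
    }
    reports["all"] = evaluate(model, list(beats), scope="all")
    return reports


def compare_heads(
    heads: Iterable[str],
    conv_filters: tuple[int, ...],
    train_config: TrainConfig,
    train_beats: Sequence[BeatWindow],
    eval_beats: Sequence[BeatWindow],
    head_units: int = 64,
    input_length: int = 512,
) -> pd.DataFrame:
    """Train one model per recurrent head on identical data and seed; rank by macro F1."""
    rows = []
    for head in heads:
        config = ModelConfig(
            model_id=f"head-{head}", conv_filters=conv_filters, head=head,
            head_units=head_units, input_length=input_length,
        )
        model, _ = train_model(config, train_config, train_beats)
        report = evaluate(model, eval_beats, scope=head)
        rows.append({"head": head, **{m: report.macro[m] for m in METRIC_NAMES}})
    return (
        pd.DataFrame(rows).sort_values("F1", ascending=False).reset_index(drop=True)
    )


def metrics_to_csv(reports: dict[str, MetricsReport], path) -> None:
    """Write per-scope, per-class metrics as one tidy CSV."""
    frames = []
    for scope, report in reports.items():
        t = report.per_class.copy()
        t.insert(0, "scope", scope)
        macro = {"scope": scope, "class": "macro", **report.macro}
        frames.append(pd.concat([t, pd.DataFrame([macro])], ignore_index=True))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def plot_confusion(report: MetricsReport, path) -> None:
    """Confusion-matrix heatmap (row-normalized annotation of raw counts)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    cm = report.confusion
    ax.imshow(cm, cmap="Blues")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=8)
    ax.set_xticks(range(N_CLASSES), WAVE_CLASSES)
    ax.set_yticks(range(N_CLASSES), WAVE_CLASSES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"confusion ({report.scope})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
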