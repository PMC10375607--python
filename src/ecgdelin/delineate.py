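"""From per-sample class labels to delineated wave intervals.

A predicted label stream is smoothed (maximal constant non-zero runs
shorter than ``min_run`` samples are relabeled isoelectric — by default
10 samples, i.e. 20 ms at 500 Hz, enough to suppress single-sample
flicker without deleting plausible waves) and its remaining runs become
wave intervals.  Predicted intervals are matched one-to-one to ground
truth greedily by overlap within a tolerance window (default 75 samples,
150 ms at 500 Hz — the conventional delineation acceptance window), and
boundary errors are reported for matched pairs.

``run_pipeline`` chains the whole tool: generate or load a corpus,
denoise, segment, split, train, evaluate, and delineate, writing CSV
artifacts and a manifest that records every setting and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import denoise as denoise_mod
from . import ludb_io, segmentation, synthetic_ecg, training_eval
from .network import ModelConfig, TrainConfig, enumerate_configs, predict_labels

logger = logging.getLogger(__name__)

CLASS_TO_WAVE = {1: "P", 2: "QRS", 3: "T"}

DEFAULT_MIN_RUN = 10  # samples; 20 ms at 500 Hz
DEFAULT_TOLERANCE = 75  # samples; 150 ms at 500 Hz


@dataclass(frozen=True)
class WaveInterval:
    lead: str
    wave_type: str
    onset: int
    offset: int
    source: str  # "ground_truth" | "predicted"

    def __post_init__(self) -> None:
        if self.onset > self.offset:
            raise ValueError(f"onset {self.onset} exceeds offset {self.offset}")

    @property
    def length(self) -> int:
        return self.offset - self.onset + 1


def labels_to_intervals(
    stream: np.ndarray,
    min_run: int = DEFAULT_MIN_RUN,
    lead: str = "",
    source: str = "predicted",
) -> list[WaveInterval]:
    """Extract maximal constant non-zero runs as closed wave intervals.

    Runs shorter than ``min_run`` are relabeled to isoelectric first.
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    labels = np.asarray(stream).copy()
    n = labels.size
    intervals: list[WaveInterval] = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])  # half-open run ends
    for start, end in zip(starts, ends):
        value = int(labels[start])
        if value == 0:
            continue
        if end - start < min_run:
            continue  # smoothing: short runs treated as isoelectric
        intervals.append(WaveInterval(
            lead=lead, wave_type=CLASS_TO_WAVE[value],
            onset=int(start), offset=int(end) - 1, source=source,
        ))
    return intervals


def _overlap(a: WaveInterval, b: WaveInterval) -> int:
    return max(0, min(a.offset, b.offset) - max(a.onset, b.onset) + 1)


def match_intervals(
    predicted: Sequence[WaveInterval],
    truth: Sequence[WaveInterval],
    tolerance: int = DEFAULT_TOLERANCE,
    fs: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy one-to-one overlap matching of predicted to true intervals.

    Per wave type, candidate pairs are ranked by overlap (descending) and
    matched greedily; a pair counts as matched only if it overlaps and both
    boundary errors are within ``tolerance`` samples.  Returns
    (summary per wave type: matched/missed/spurious + mean absolute onset
    and offset errors, table of matched pairs with signed errors in samples
    and ms).
    """
    summary_rows = []
    pair_rows = []
    for wave in ("P", "QRS", "T"):
        preds = sorted([i for i in predicted if i.wave_type == wave],
                       key=lambda i: i.onset)
        trues = sorted([i for i in truth if i.wave_type == wave],
                       key=lambda i: i.onset)
        candidates = sorted(
            (
                (-_overlap(p, t), pi, ti)
                for pi, p in enumerate(preds)
                for ti, t in enumerate(trues)
                if _overlap(p, t) > 0
                and abs(p.onset - t.onset) <= tolerance
                and abs(p.offset - t.offset) <= tolerance
            ),
        )
        used_p: set[int] = set()
        used_t: set[int] = set()
        for neg_ov, pi, ti in candidates:
            if pi in used_p or ti in used_t:
                continue
            used_p.add(pi)
            used_t.add(ti)
            p, t = preds[pi], trues[ti]
            pair_rows.append({
                "lead": t.lead, "wave_type": wave,
                "true_onset": t.onset, "true_offset": t.offset,
                "pred_onset": p.onset, "pred_offset": p.offset,
                "onset_error_samples": p.onset - t.onset,
                "offset_error_samples": p.offset - t.offset,
                "onset_error_ms": 1000.0 * (p.onset - t.onset) / fs,
                "offset_error_ms": 1000.0 * (p.offset - t.offset) / fs,
            })
        matched = len(used_t)
        onset_errors = [abs(r["onset_error_samples"]) for r in pair_rows
                        if r["wave_type"] == wave]
        offset_errors = [abs(r["offset_error_samples"]) for r in pair_rows
                         if r["wave_type"] == wave]
        summary_rows.append({
            "wave_type": wave,
            "matched": matched,
            "missed": len(trues) - matched,
            "spurious": len(preds) - matched,
            "mean_abs_onset_error_samples": float(np.mean(onset_errors)) if onset_errors else np.nan,
            "mean_abs_offset_error_samples": float(np.mean(offset_errors)) if offset_errors else np.nan,
        })
    return pd.DataFrame(summary_rows), pd.DataFrame(pair_rows)


def plot_overlay(beat, predicted_stream: np.ndarray, path) -> None:
    """Ground-truth vs predicted wave bands over one beat's signal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {1: "tab:red", 2: "tab:blue", 3: "gold"}
    fig, axes = plt.subplots(2, 1, figsize=(8, 4), sharex=True)
    for ax, stream, title in (
        (axes[0], np.asarray(beat.labels), "ground truth"),
        (axes[1], np.asarray(predicted_stream), "predicted"),
    ):
        ax.plot(beat.signal[: beat.valid_length], color="k", lw=0.8)
        for iv in labels_to_intervals(stream, min_run=1):
            ax.axvspan(iv.onset, iv.offset, color=colors[
                {"P": 1, "QRS": 2, "T": 3}[iv.wave_type]], alpha=0.3)
        ax.set_ylabel("mV")
        ax.set_title(f"{beat.record_id} {beat.lead} beat {beat.beat_index} — {title}",
                     fontsize=9)
    axes[1].set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

PIPELINE_STAGES = ("synth", "denoise", "segment", "split",
                   "train", "evaluate", "delineate")

#: Pipeline config schema: field -> (type, default).  ``None`` default means
#: the field is required when its stage runs.
CONFIG_SCHEMA: dict[str, tuple[type, object]] = {
    "data_dir": (str, None),  # existing WFDB corpus; generated if absent
    "out_dir": (str, None),
    "n_records": (int, 10),
    "seed": (int, 0),
    "noise_sigma": (float, 0.05),
    "wander_amplitude": (float, 0.1),
    "denoise_wavelet": (str, "bior6.8"),
    "denoise_level": (int, 8),
    "split_mode": (str, "patient_based"),
    "model_id": (int, 11),
    "head_units": (int, 64),
    "epochs": (int, 300),
    "batch_size": (int, 8),
    "learning_rate": (float, 1e-5),
    "min_run": (int, DEFAULT_MIN_RUN),
    "tolerance": (int, DEFAULT_TOLERANCE),
}


class ConfigError(ValueError):
    pass


def validate_config(raw: dict) -> dict:
    """Fill defaults and type-check a pipeline config mapping."""
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    cfg = {}
    for name, (typ, default) in CONFIG_SCHEMA.items():
        if name in raw:
            value = raw[name]
            if typ in (int, float) and isinstance(value, (int, float)) and not isinstance(value, bool):
                value = typ(value)
            if not isinstance(value, typ):
                raise ConfigError(
                    f"config field {name!r} must be {typ.__name__}, "
                    f"got {type(value).__name__}"
                )
            cfg[name] = value
        else:
            cfg[name] = default
    if cfg["out_dir"] is None:
        raise ConfigError("config field 'out_dir' is required")
    if cfg["split_mode"] not in ("patient_based", "beat_based"):
        raise ConfigError("config field 'split_mode' must be patient_based or beat_based")
    if not 1 <= cfg["model_id"] <= 13:
        raise ConfigError("config field 'model_id' must be in 1..13")
    return cfg


def run_pipeline(config: dict | str | Path) -> Path:
    """Execute the full pipeline from a config mapping or YAML file path.

    Stages: synth (or load) -> denoise -> segment -> split -> train ->
    evaluate -> delineate.  Writes metrics, intervals, confusion and log
    CSVs plus ``manifest.json`` under the configured output directory and
    returns that directory.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = validate_config(dict(config))
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}}
    t0 = time.time()

    def stage_done(name: str, **info) -> None:
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t0, 2), **info}
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    try:
        # -- synth / load ---------------------------------------------------
        if cfg["data_dir"] is not None and Path(cfg["data_dir"]).exists():
            data_dir = Path(cfg["data_dir"])
            record_ids = sorted(
                {p.stem for p in data_dir.glob("*.hea")}, key=lambda s: (len(s), s)
            )
            stage_done("synth", loaded_from=str(data_dir), n_records=len(record_ids))
        else:
            data_dir = out_dir / "corpus"
            synth_cfg = synthetic_ecg.SynthConfig(
                noise_sigma=cfg["noise_sigma"],
                wander_amplitude=cfg["wander_amplitude"],
                seed=cfg["seed"],
            )
            record_ids = synthetic_ecg.synth_dataset(
                data_dir, cfg["n_records"], synth_cfg, seed=cfg["seed"]
            )
            stage_done("synth", generated=str(data_dir), n_records=len(record_ids))

        # -- denoise --------------------------------------------------------
        den_cfg = denoise_mod.DenoiseConfig(
            wavelet=cfg["denoise_wavelet"], level=cfg["denoise_level"]
        )
        records = {}
        snr_rows = []
        for record_id in record_ids:
            raw = ludb_io.read_record(data_dir, record_id)
            clean = denoise_mod.denoise_record(raw, den_cfg)
            records[record_id] = clean
            for li, lead in enumerate(ludb_io.LEAD_NAMES):
                snr_rows.append({
                    "record_id": record_id, "lead": lead, "wavelet": den_cfg.wavelet,
                    "snr_db": denoise_mod.snr_db(raw.signals[li], clean.signals[li]),
                })
        pd.DataFrame(snr_rows).to_csv(out_dir / "snr.csv", index=False)
        stage_done("denoise", wavelet=den_cfg.wavelet, level=den_cfg.level)

        # -- segment --------------------------------------------------------
        beats = []
        for record_id in record_ids:
            for lead in ludb_io.LEAD_NAMES:
                triplets, _ = ludb_io.read_lead_triplets(data_dir, record_id, lead)
                beats += segmentation.extract_beat_windows(
                    records[record_id], triplets, lead
                )
        stage_done("segment", n_beats=len(beats))

        # -- split ----------------------------------------------------------
        if cfg["split_mode"] == "patient_based":
            numbers = [int("".join(c for c in r if c.isdigit())) for r in record_ids]
            ranges = segmentation.auto_patient_ranges(numbers)
            spec = segmentation.SplitSpec(mode="patient_based", patient_ranges=ranges,
                                          seed=cfg["seed"])
        else:
            spec = segmentation.SplitSpec(mode="beat_based", seed=cfg["seed"])
        split = segmentation.make_split(beats, spec)
        segmentation.split_counts(split).to_csv(out_dir / "split_counts.csv", index=False)
        stage_done("split", mode=cfg["split_mode"],
                   counts={k: len(v) for k, v in split.items()})

        # -- train ----------------------------------------------------------
        model_cfg = next(
            c for c in enumerate_configs(head_units=cfg["head_units"])
            if c.model_id == cfg["model_id"]
        )
        train_cfg = TrainConfig(
            epochs=cfg["epochs"], batch_size=cfg["batch_size"],
            learning_rate=cfg["learning_rate"], seed=cfg["seed"],
        )
        model, log = training_eval.train_model(
            model_cfg, train_cfg, split["train"], split["val"]
        )
        log.to_csv(out_dir / "training_log.csv", index=False)
        stage_done("train", model_id=cfg["model_id"], epochs=cfg["epochs"],
                   final_loss=float(log["train_loss"].iloc[-1]))

        # -- evaluate -------------------------------------------------------
        eval_beats = split["test"] if split["test"] else split["train"]
        reports = training_eval.evaluate_per_lead(model, eval_beats)
        training_eval.metrics_to_csv(reports, out_dir / "metrics.csv")
        np.savetxt(out_dir / "confusion.csv", reports["all"].confusion,
                   fmt="%d", delimiter=",")
        stage_done("evaluate", macro=reports["all"].macro,
                   n_samples=reports["all"].n_samples)

        # -- delineate ------------------------------------------------------
        interval_rows = []
        summaries, pair_frames = [], []
        for beat_i, beat in enumerate(eval_beats):
            pred_stream = predict_labels(model, beat)
            pred_stream[beat.valid_length:] = 0
            if beat_i < 3:
                plot_overlay(beat, pred_stream, out_dir / f"overlay_{beat_i}.png")
            pred = labels_to_intervals(pred_stream, min_run=cfg["min_run"],
                                       lead=beat.lead, source="predicted")
            true = labels_to_intervals(beat.labels, min_run=1,
                                       lead=beat.lead, source="ground_truth")
            # windows share the 0..511 coordinate space, so matching is per beat
            beat_summary, beat_pairs = match_intervals(pred, true,
                                                       tolerance=cfg["tolerance"])
            summaries.append(beat_summary)
            if len(beat_pairs):
                beat_pairs.insert(0, "record_id", beat.record_id)
                pair_frames.append(beat_pairs)
            for iv in pred + true:
                interval_rows.append({
                    "record_id": beat.record_id, "lead": iv.lead,
                    "wave_type": iv.wave_type, "onset": iv.onset,
                    "offset": iv.offset, "source": iv.source,
                })
        summary = (
            pd.concat(summaries, ignore_index=True)
            .groupby("wave_type", sort=False)
            .agg(
                matched=("matched", "sum"), missed=("missed", "sum"),
                spurious=("spurious", "sum"),
                mean_abs_onset_error_samples=("mean_abs_onset_error_samples", "mean"),
                mean_abs_offset_error_samples=("mean_abs_offset_error_samples", "mean"),
            )
            .reset_index()
        )
        pairs = (
            pd.concat(pair_frames, ignore_index=True)
            if pair_frames else pd.DataFrame()
        )
        pd.DataFrame(interval_rows).to_csv(out_dir / "intervals.csv", index=False)
        summary.to_csv(out_dir / "delineation_summary.csv", index=False)
        pairs.to_csv(out_dir / "delineation_pairs.csv", index=False)
        stage_done("delineate",
                   matched=int(summary["matched"].sum()),
                   missed=int(summary["missed"].sum()),
                   spurious=int(summary["spurious"].sum()))
    except Exception as exc:
        failed = next((s for s in PIPELINE_STAGES if s not in manifest["stages"]),
                      "unknown")
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
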