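"""Beat-to-beat segmentation and train/val/test split construction.

A beat window runs from one P-wave onset to the next P-wave onset on the
same lead.  Windows are standardized to 512 samples: shorter beats are
zero-padded on the right (the padded region carries ``valid_length`` so it
can be masked out of losses and metrics), longer beats are clipped at 512.
A beat is emitted only when the span contains a complete P and QRS wave.

Two split modes exist.  *Beat-based* shuffles each lead's beats with a
seed and partitions by fractions (default 0.80/0.12/0.08); *patient-based*
partitions whole subjects by record-id range (default 1-180 / 181-190 /
191-200), which prevents any subject's beats leaking across splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ludb_io import LEAD_NAMES, WaveTriplet, ECGRecord, build_label_stream

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 512


@dataclass(frozen=True)
class BeatWindow:
    """A fixed 512-sample beat with aligned labels and provenance."""

    record_id: str
    lead: str
    beat_index: int
    signal: np.ndarray  # (512,) float, mV; zeros at positions >= valid_length
    labels: np.ndarray  # (512,) int in {0,1,2,3}; zeros at positions >= valid_length
    valid_length: int
    start_sample: int

    def __post_init__(self) -> None:
        if self.signal.shape != (WINDOW_LENGTH,) or self.labels.shape != (WINDOW_LENGTH,):
            raise ValueError("beat window signal and labels must both have length 512")
        if not (1 <= self.valid_length <= WINDOW_LENGTH):
            raise ValueError(f"valid_length must be in [1, 512], got {self.valid_length}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the sample is real (not padding)."""
        m = np.zeros(WINDOW_LENGTH, dtype=bool)
        m[: self.valid_length] = True
        return m


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "patient_based"
    fractions: tuple[float, float, float] = (0.80, 0.12, 0.08)
    patient_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (1, 180), (181, 190), (191, 200),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("beat_based", "patient_based"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "beat_based":
            if any(f < 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError(
                    f"fractions must be non-negative and sum to 1, got {self.fractions}"
                )
        else:
            spans = sorted(self.patient_ranges)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if b1 >= a2:
                    raise ValueError(f"patient ranges overlap: {self.patient_ranges}")
            if any(a > b for a, b in self.patient_ranges):
                raise ValueError(f"empty patient range in {self.patient_ranges}")


def locate_beat_boundaries(
    triplets: Sequence[WaveTriplet],
) -> list[tuple[int, int]]:
    """Beat spans [start, end) between consecutive P-wave onsets.

    A span is emitted only if it fully contains a complete P wave and a
    complete QRS wave; the trailing partial beat after the last P onset is
    dropped.  Empty input yields empty output.
    """
    ordered = sorted(triplets, key=lambda t: (t.onset, t.peak))
    p_onsets = [t.onset for t in ordered if t.wave_type == "P"]
    spans = []
    for start, end in zip(p_onsets, p_onsets[1:]):
        has_p = any(
            t.wave_type == "P" and start <= t.onset and t.offset < end
            for t in ordered
        )
        has_qrs = any(
            t.wave_type == "QRS" and start <= t.onset and t.offset < end
            for t in ordered
        )
        if has_p and has_qrs:
            spans.append((start, end))
    return spans


def extract_beat_windows(
    record: ECGRecord,
    triplets: Sequence[WaveTriplet],
    lead: str,
) -> list[BeatWindow]:
    """Cut one lead into 512-sample beat windows with aligned label streams."""
    signal = record.lead(lead)
    full_labels = build_label_stream(triplets, record.n_samples)
    windows = []
    n_clipped = 0
    for beat_index, (start, end) in enumerate(locate_beat_boundaries(triplets)):
        if end <= start:
            raise ValueError(f"inconsistent beat span ({start}, {end})")
        span = end - start
        valid = min(span, WINDOW_LENGTH)
        if span > WINDOW_LENGTH:
            n_clipped += 1
        sig = np.zeros(WINDOW_LENGTH, dtype=np.float64)
        lab = np.zeros(WINDOW_LENGTH, dtype=np.int64)
        sig[:valid] = signal[start : start + valid]
        lab[:valid] = full_labels[start : start + valid]
        windows.append(BeatWindow(
            record_id=record.record_id, lead=lead, beat_index=beat_index,
            signal=sig, labels=lab, valid_length=valid, start_sample=start,
        ))
    if n_clipped:
        logger.info(
            "%s lead %s: clipped %d beat(s) longer than %d samples",
            record.record_id, lead, n_clipped, WINDOW_LENGTH,
        )
    return windows


def _record_number(record_id: str) -> int:
    digits = "".join(ch for ch in record_id if ch.isdigit())
    if not digits:
        raise ValueError(
            f"record id {record_id!r} carries no number; patient-based "
            "splitting needs numeric record ids"
        )
    return int(digits)


def auto_patient_ranges(
    record_numbers: Iterable[int],
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Patient-id ranges splitting ~90/5/5 by subject.

    On the canonical 200-record corpus this yields exactly
    (1, 180) / (181, 190) / (191, 200).
    """
    numbers = sorted(record_numbers)
    n = len(numbers)
    if n < 3:
        raise ValueError(f"patient-based splitting needs >= 3 records, got {n}")
    n_val = max(1, round(0.05 * n))
    n_test = max(1, round(0.05 * n))
    n_train = n - n_val - n_test
    return (
        (numbers[0], numbers[n_train - 1]),
        (numbers[n_train], numbers[n_train + n_val - 1]),
        (numbers[n_train + n_val], numbers[-1]),
    )


def make_split(
    beats: Iterable[BeatWindow], spec: SplitSpec
) -> dict[str, list[BeatWindow]]:
    """Partition beats into disjoint train/val/test collections.

    Beat-based mode shuffles within each lead with the spec's seed and
    splits by fractions; patient-based mode assigns each record id's beats
    to the range that contains its number (deterministic, no shuffling).
    """
    beats = list(beats)
    out: dict[str, list[BeatWindow]] = {"train": [], "val": [], "test": []}
    if spec.mode == "patient_based":
        for beat in beats:
            number = _record_number(beat.record_id)
            for name, (lo, hi) in zip(out, spec.patient_ranges):
                if lo <= number <= hi:
                    out[name].append(beat)
                    break
            else:
                raise ValueError(
                    f"record {beat.record_id} falls outside every patient range "
                    f"{spec.patient_ranges}"
                )
        return out

    rng = np.random.default_rng(spec.seed)
    by_lead: dict[str, list[BeatWindow]] = {}
    for beat in beats:
        by_lead.setdefault(beat.lead, []).append(beat)
    for lead in sorted(by_lead):
        group = by_lead[lead]
        order = rng.permutation(len(group))
        shuffled = [group[i] for i in order]
        n = len(shuffled)
        n_train = int(np.floor(spec.fractions[0] * n))
        n_val = int(np.floor(spec.fractions[1] * n))
        out["train"] += shuffled[:n_train]
        out["val"] += shuffled[n_train : n_train + n_val]
        out["test"] += shuffled[n_train + n_val :]
    return out


def split_counts(split: dict[str, list[BeatWindow]]) -> pd.DataFrame:
    """Per-lead beat counts for each collection, mirroring a split summary table."""
    rows = []
    for name, beats in split.items():
        counts = {lead: 0 for lead in LEAD_NAMES}
        for beat in beats:
            counts[beat.lead] += 1
        rows.append({"split": name, **counts, "total": len(beats)})
    return pd.DataFrame(rows)


def save_beats(
    split: dict[str, list[BeatWindow]], out_path: Path | str, manifest_path: Path | str
) -> None:
    """Write beats as one .npz (signals, labels, valid_length) + CSV manifest."""
    all_beats = [(name, b) for name in ("train", "val", "test") for b in split[name]]
    signals = np.stack([b.signal for _, b in all_beats]) if all_beats else np.zeros((0, WINDOW_LENGTH))
    labels = np.stack([b.labels for _, b in all_beats]) if all_beats else np.zeros((0, WINDOW_LENGTH), dtype=np.int64)
    valid = np.array([b.valid_length for _, b in all_beats], dtype=np.int64)
    np.savez_compressed(out_path, signals=signals, labels=labels, valid_length=valid)
    manifest = pd.DataFrame(
        [
            {
                "record_id": b.record_id, "lead": b.lead, "beat_index": b.beat_index,
                "start_sample": b.start_sample, "split": name,
            }
            for name, b in all_beats
        ]
    )
    manifest.to_csv(manifest_path, index=False)


def load_beats(npz_path: Path | str, manifest_path: Path | str) -> dict[str, list[BeatWindow]]:
    data = np.load(npz_path)
    manifest = pd.read_csv(manifest_path)
    split: dict[str, list[BeatWindow]] = {"train": [], "val": [], "test": []}
    for i, row in manifest.iterrows():
        split[row["split"]].append(BeatWindow(
            record_id=str(row["record_id"]), lead=row["lead"],
            beat_index=int(row["beat_index"]), signal=data["signals"][i],
            labels=data["labels"][i], valid_length=int(data["valid_length"][i]),
            start_sample=int(row["start_sample"]),
        ))
    return split
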