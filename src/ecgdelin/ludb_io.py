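"""Reading 12-lead WFDB ECG records with per-lead wave annotations.

The annotation dialect is the one the Lobachevsky University database
(LUDB) uses: one annotation file per lead, named after the lowercase lead
name, where each annotated wave is a run of three symbols — onset ``(``,
a peak symbol (``p`` for P-waves, ``N`` for QRS complexes, ``t`` for
T-waves), and offset ``)``.  Waves whose run is incomplete are excluded
rather than repaired, and the exclusion count is reported so that corpus
totals remain diagnosable.

Per-sample class labels use the four-class scheme 0 = isoelectric,
1 = P, 2 = QRS, 3 = T.  Wave intervals are closed ``[onset, offset]`` in
0-based sample indices; where annotated waves overlap, the precedence is
QRS > T > P (QRS boundaries are the most reliably annotated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import wfdb_lite

logger = logging.getLogger(__name__)

#: Canonical 12-lead order: limb leads then chest leads.
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: Annotation-file extensions, lowercase lead names per the LUDB layout.
LEAD_EXTENSIONS = tuple(name.lower() for name in LEAD_NAMES)

WAVE_CLASSES = ("iso", "P", "QRS", "T")
CLASS_OF_WAVE = {"P": 1, "QRS": 2, "T": 3}

#: Peak-symbol -> wave type, the LUDB convention.  Other WFDB dialects can
#: pass their own table to pair_wave_triplets.
PEAK_SYMBOLS = {"p": "P", "N": "QRS", "t": "T"}

VALID_SYMBOLS = frozenset({"(", ")", *PEAK_SYMBOLS})


class AnnotationFormatError(ValueError):
    """An annotation stream contains symbols outside the supported dialect."""


@dataclass(frozen=True)
class ECGRecord:
    """One subject's 12-lead signal matrix plus sampling metadata.

    ``signals`` has shape (12, n_samples), rows in canonical lead order,
    units millivolts.
    """

    record_id: str
    fs: float
    signals: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signals.ndim != 2 or self.signals.shape[0] != len(LEAD_NAMES):
            raise ValueError(
                f"signals must be ({len(LEAD_NAMES)}, n) in canonical lead "
                f"order, got shape {self.signals.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def lead(self, name: str) -> np.ndarray:
        return self.signals[LEAD_NAMES.index(name)]


@dataclass(frozen=True)
class WaveTriplet:
    """One annotated wave on one lead: closed interval [onset, offset]."""

    lead: str
    wave_type: str
    onset: int
    peak: int
    offset: int

    def __post_init__(self) -> None:
        if not (self.onset <= self.peak <= self.offset):
            raise ValueError(
                f"wave triplet must satisfy onset <= peak <= offset, got "
                f"({self.onset}, {self.peak}, {self.offset})"
            )
        if self.wave_type not in CLASS_OF_WAVE:
            raise ValueError(f"unknown wave type {self.wave_type!r}")


def read_record(path: Path | str, record_id: str) -> ECGRecord:
    """Read a WFDB record into canonical 12-lead order, in millivolts."""
    fs, signals, descriptions = wfdb_lite.read_signals(Path(path), record_id)
    index = {d.strip().lower(): i for i, d in enumerate(descriptions)}
    missing = [name for name in LEAD_NAMES if name.lower() not in index]
    if missing:
        raise wfdb_lite.WfdbFormatError(
            f"record {record_id} is missing leads: {', '.join(missing)}"
        )
    order = [index[name.lower()] for name in LEAD_NAMES]
    return ECGRecord(record_id=record_id, fs=fs, signals=signals[order])


def write_record(
    path: Path | str,
    record: ECGRecord,
    triplets_per_lead: dict[str, Sequence[WaveTriplet]] | None = None,
) -> None:
    """Write an ECGRecord (and optional per-lead annotations) as WFDB files."""
    wfdb_lite.write_record_files(
        Path(path), record.record_id, record.fs, record.signals,
        [name.lower() for name in LEAD_NAMES],
    )
    if triplets_per_lead is not None:
        for lead, triplets in triplets_per_lead.items():
            annotations: list[tuple[str, int]] = []
            peak_of = {v: k for k, v in PEAK_SYMBOLS.items()}
            for t in sorted(triplets, key=lambda t: t.onset):
                annotations += [
                    ("(", t.onset), (peak_of[t.wave_type], t.peak), (")", t.offset)
                ]
            wfdb_lite.write_annotations(
                Path(path), record.record_id, lead.lower(), annotations
            )


def read_lead_annotations(
    path: Path | str, record_id: str, lead: str
) -> list[tuple[str, int]]:
    """Read one lead's annotation stream as ordered (symbol, sample) pairs."""
    raw = wfdb_lite.read_annotations(Path(path), record_id, lead.lower())
    for i, (symbol, sample) in enumerate(raw):
        if symbol not in VALID_SYMBOLS:
            raise AnnotationFormatError(
                f"unknown symbol {symbol!r} at position {i} (sample {sample}) "
                f"in {record_id}.{lead.lower()}"
            )
    return raw


def pair_wave_triplets(
    raw: Sequence[tuple[str, int]],
    lead: str = "",
    peak_symbols: dict[str, str] = PEAK_SYMBOLS,
) -> tuple[list[WaveTriplet], int]:
    """Pair an ordered symbol stream into wave triplets.

    Each triplet is a maximal ``('(', peak, ')')`` run.  Runs missing their
    onset or offset — including consecutive peak symbols with no boundary
    between them — are dropped and counted in the returned exclusion tally.

    Returns (triplets, n_excluded).
    """
    for symbol, _ in raw:
        if symbol not in VALID_SYMBOLS and symbol not in peak_symbols:
            raise AnnotationFormatError(f"unknown symbol {symbol!r}")
    triplets: list[WaveTriplet] = []
    excluded = 0
    onset: int | None = None
    peaks: list[tuple[str, int]] = []

    def flush_incomplete() -> None:
        nonlocal excluded, onset, peaks
        # an aborted run drops every peak it contained; a bare boundary
        # with no peak still counts as one exclusion event
        excluded += max(len(peaks), 1) if (onset is not None or peaks) else 0
        onset, peaks = None, []

    for symbol, sample in raw:
        if symbol == "(":
            if onset is not None or peaks:
                flush_incomplete()
            onset = sample
        elif symbol in peak_symbols:
            peaks.append((symbol, sample))
        else:  # ')'
            if onset is not None and len(peaks) == 1:
                psym, psample = peaks[0]
                triplets.append(WaveTriplet(
                    lead=lead, wave_type=peak_symbols[psym],
                    onset=onset, peak=psample, offset=sample,
                ))
                onset, peaks = None, []
            else:
                if len(peaks) > 1:
                    logger.warning(
                        "%s: %d consecutive peak symbols with no boundary "
                        "between them; all dropped", lead or "stream", len(peaks),
                    )
                flush_incomplete()
    flush_incomplete()
    return triplets, excluded


def read_lead_triplets(
    path: Path | str, record_id: str, lead: str
) -> tuple[list[WaveTriplet], int]:
    """Read + pair one lead's annotations; returns (triplets, n_excluded)."""
    raw = read_lead_annotations(path, record_id, lead)
    return pair_wave_triplets(raw, lead=lead)


def read_corpus_triplets(
    path: Path | str, record_ids: Iterable[str]
) -> tuple[pd.DataFrame, int]:
    """Parse every lead of every record into a tidy triplet table.

    Returns (table with columns record_id/lead/wave_type/onset/peak/offset,
    total exclusion count).
    """
    rows = []
    excluded_total = 0
    for record_id in record_ids:
        for lead in LEAD_NAMES:
            triplets, excluded = read_lead_triplets(path, record_id, lead)
            excluded_total += excluded
            rows += [
                (record_id, lead, t.wave_type, t.onset, t.peak, t.offset)
                for t in triplets
            ]
    table = pd.DataFrame(
        rows, columns=["record_id", "lead", "wave_type", "onset", "peak", "offset"]
    )
    return table, excluded_total


def write_triplet_table(table: pd.DataFrame, path: Path | str) -> None:
    table.to_csv(path, sep="\t", index=False)


def build_label_stream(
    triplets: Iterable[WaveTriplet], n: int
) -> np.ndarray:
    """Per-sample class labels of length n from wave triplets.

    Samples inside any closed [onset, offset] get the wave's class; overlap
    resolves with precedence QRS > T > P (painted lowest precedence first).
    """
    labels = np.zeros(n, dtype=np.int64)
    by_precedence = sorted(triplets, key=lambda t: {"P": 0, "T": 1, "QRS": 2}[t.wave_type])
    for t in by_precedence:
        if t.onset < 0 or t.offset >= n:
            raise ValueError(
                f"triplet {t} out of range for a stream of length {n}"
            )
        labels[t.onset : t.offset + 1] = CLASS_OF_WAVE[t.wave_type]
    return labels
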