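"""Minimal WFDB codec for 12-lead ECG records.

Covers exactly the subset of the WFDB standard that the Lobachevsky-style
corpora use: a ``.hea`` header, a single interleaved format-16 ``.dat``
signal file, and one binary MIT-format annotation file per lead whose file
extension is the lowercase lead name.  Both directions (read and write) are
implemented so synthetic corpora can round-trip through the same path that
real records take.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "WfdbFormatError",
    "SignalHeader",
    "read_header",
    "read_signals",
    "write_record_files",
    "read_annotations",
    "write_annotations",
    "SYMBOL_TO_CODE",
    "CODE_TO_SYMBOL",
]


class WfdbFormatError(ValueError):
    """A header, signal, or annotation file violates the expected dialect."""


# MIT annotation codes for the symbols the LUDB dialect uses.
# 'N' marks the QRS peak, 'p'/'t' the P/T peaks, '(' / ')' wave onset/offset.
SYMBOL_TO_CODE = {"N": 1, "p": 24, "t": 27, "(": 39, ")": 40}
CODE_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CODE.items()}

_SKIP = 59  # long time-interval escape
_NUM, _SUB, _CHN, _AUX = 60, 61, 62, 63  # modifier pseudo-codes (ignored)


@dataclass(frozen=True)
class SignalHeader:
    """One signal line of a ``.hea`` file (format-16 subset)."""

    file_name: str
    fmt: int
    gain: float  # ADC units per millivolt
    baseline: int  # ADC value corresponding to 0 mV
    description: str


def read_header(path: Path, record_id: str) -> tuple[float, int, list[SignalHeader]]:
    """Parse ``<record_id>.hea``; returns (fs, n_samples, signal headers)."""
    hea = Path(path) / f"{record_id}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"header file not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec = lines[0].split()
    if len(rec) < 4:
        raise WfdbFormatError(f"malformed record line in {hea}: {lines[0]!r}")
    n_sig = int(rec[1])
    fs = float(rec[2])
    n_samples = int(rec[3])
    sig_headers: list[SignalHeader] = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        file_name, fmt_field, gain_field = parts[0], parts[1], parts[2]
        fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
        if fmt != 16:
            raise WfdbFormatError(f"unsupported signal format {fmt} in {hea}")
        # gain field looks like "1000/mV" or "1000(0)/mV"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part[:-1].split("(")
            baseline = int(base_str)
        else:
            gain_str = gain_part
            baseline = 0
        gain = float(gain_str) if float(gain_str) != 0 else 200.0
        description = parts[-1] if len(parts) >= 9 else parts[-1]
        sig_headers.append(SignalHeader(file_name, fmt, gain, baseline, description))
    return fs, n_samples, sig_headers


def read_signals(path: Path, record_id: str) -> tuple[float, np.ndarray, list[str]]:
    """Read the record's signal matrix in millivolts.

    Returns (fs, signals of shape (n_signals, n_samples), descriptions).
    All signals must live in one interleaved format-16 ``.dat`` file.
    """
    fs, n_samples, sig_headers = read_header(path, record_id)
    dat_names = {h.file_name for h in sig_headers}
    if len(dat_names) != 1:
        raise WfdbFormatError(f"expected a single .dat file, got {sorted(dat_names)}")
    dat = Path(path) / dat_names.pop()
    if not dat.exists():
        raise FileNotFoundError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    n_sig = len(sig_headers)
    if raw.size < n_sig * n_samples:
        raise WfdbFormatError(
            f"{dat} holds {raw.size} samples, need {n_sig * n_samples}"
        )
    adc = raw[: n_sig * n_samples].reshape(n_samples, n_sig).T.astype(np.float64)
    gains = np.array([h.gain for h in sig_headers])[:, None]
    baselines = np.array([h.baseline for h in sig_headers])[:, None]
    signals = (adc - baselines) / gains
    return fs, signals, [h.description for h in sig_headers]


def write_record_files(
    path: Path,
    record_id: str,
    fs: float,
    signals: np.ndarray,
    descriptions: Sequence[str],
    gain: float = 1000.0,
) -> None:
    """Write ``<record_id>.hea`` + format-16 ``<record_id>.dat`` (signals in mV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_sig, n_samples = signals.shape
    adc = np.rint(signals * gain)
    if np.abs(adc).max(initial=0) > 32767:
        raise WfdbFormatError("signal amplitude exceeds 16-bit ADC range at this gain")
    adc = adc.astype("<i2")
    dat_name = f"{record_id}.dat"
    adc.T.reshape(-1).tofile(path / dat_name)
    lines = [f"{record_id} {n_sig} {fs:g} {n_samples}"]
    for i, desc in enumerate(descriptions):
        first = int(adc[i, 0])
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {desc}")
    (path / f"{record_id}.hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MIT annotation format: a stream of little-endian 16-bit words.  The top 6
# bits are the annotation code, the low 10 bits the time increment from the
# previous annotation.  Increments over 1023 samples are escaped with a SKIP
# word followed by a 4-byte interval (high word first).  A zero word ends the
# stream.
# ---------------------------------------------------------------------------


def write_annotations(
    path: Path, record_id: str, extension: str, annotations: Sequence[tuple[str, int]]
) -> None:
    """Write (symbol, sample) pairs as a binary MIT annotation file."""
    out = bytearray()
    prev = 0
    for symbol, sample in annotations:
        if symbol not in SYMBOL_TO_CODE:
            raise WfdbFormatError(f"unsupported annotation symbol {symbol!r}")
        if sample < prev:
            raise WfdbFormatError("annotation samples must be non-decreasing")
        delta = sample - prev
        code = SYMBOL_TO_CODE[symbol]
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = sample
    out += struct.pack("<H", 0)
    Path(path).mkdir(parents=True, exist_ok=True)
    (Path(path) / f"{record_id}.{extension}").write_bytes(bytes(out))


def read_annotations(
    path: Path, record_id: str, extension: str
) -> list[tuple[str, int]]:
    """Read a binary MIT annotation file into (symbol, sample) pairs."""
    fn = Path(path) / f"{record_id}.{extension}"
    if not fn.exists():
        raise FileNotFoundError(f"annotation file not found: {fn}")
    data = fn.read_bytes()
    if len(data) % 2:
        raise WfdbFormatError(f"{fn}: odd byte count")
    words = struct.unpack(f"<{len(data) // 2}H", data)
    out: list[tuple[str, int]] = []
    time = 0
    pending_skip = 0
    i = 0
    while i < len(words):
        word = words[i]
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 2 >= len(words):
                raise WfdbFormatError(f"{fn}: truncated SKIP escape")
            pending_skip = (words[i + 1] << 16) | words[i + 2]
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN, _AUX):
            if code == _AUX:  # AUX carries delta bytes of payload
                i += 1 + (delta + 1) // 2
            else:
                i += 1
            continue
        time += delta + pending_skip
        pending_skip = 0
        if code not in CODE_TO_SYMBOL:
            raise WfdbFormatError(
                f"{fn}: unknown annotation code {code} at sample {time}"
            )
        out.append((CODE_TO_SYMBOL[code], time))
        i += 1
    return out
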