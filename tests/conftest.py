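"""Shared fixtures: small synthetic corpora generated at test time."""

from __future__ import annotations

from dataclasses import replace

import pytest

from ecgdelin.ludb_io import write_record
from ecgdelin.synthetic_ecg import SynthConfig, SynthRecord, synth_record


@pytest.fixture(scope="session")
def noisy_config() -> SynthConfig:
    """Moderate white noise + baseline wander, fixed seed."""
    return SynthConfig(noise_sigma=0.05, wander_amplitude=0.1, seed=42)


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    return SynthConfig(seed=42)


@pytest.fixture(scope="session")
def synth_corpus(tmp_path_factory, noisy_config):
    """A 3-record noisy WFDB corpus on disk plus its generator-side truth.

    Returns (directory, {record_id: SynthRecord}).
    """
    corpus_dir = tmp_path_factory.mktemp("corpus")
    truth: dict[str, SynthRecord] = {}
    for i in (1, 2, 3):
        sr = synth_record(replace(noisy_config, seed=1000 + i), record_id=str(i))
        write_record(corpus_dir, sr.record, sr.triplets)
        truth[str(i)] = sr
    return corpus_dir, truth


@pytest.fixture(scope="session")
def clean_record(clean_config) -> SynthRecord:
    """One noise-free record with exact annotations."""
    return synth_record(clean_config, record_id="1")
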