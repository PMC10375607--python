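"""Beat windowing and split construction."""

import numpy as np
import pytest

from ecgdelin.ludb_io import LEAD_NAMES, ECGRecord, WaveTriplet
from ecgdelin.segmentation import (
    WINDOW_LENGTH,
    BeatWindow,
    SplitSpec,
    auto_patient_ranges,
    extract_beat_windows,
    locate_beat_boundaries,
    make_split,
    split_counts,
)


def _triplets(lead="II", *spans):
    """spans: (wave_type, onset, peak, offset)."""
    return [WaveTriplet(lead, w, a, b, c) for w, a, b, c in spans]


def _record(n=2000, fs=500.0):
    rng = np.random.default_rng(0)
    return ECGRecord("1", fs, rng.standard_normal((12, n)) * 0.1)


class TestBeatBoundaries:
    def test_two_p_onsets_one_beat(self):
        triplets = _triplets(
            "II",
            ("P", 100, 110, 120), ("QRS", 200, 210, 220), ("T", 300, 330, 360),
            ("P", 550, 560, 570), ("QRS", 650, 660, 670),
        )
        assert locate_beat_boundaries(triplets) == [(100, 550)]

    def test_single_p_wave_no_beat(self):
        triplets = _triplets("II", ("P", 100, 110, 120), ("QRS", 200, 210, 220))
        assert locate_beat_boundaries(triplets) == []

    def test_empty_input(self):
        assert locate_beat_boundaries([]) == []

    def test_span_without_qrs_excluded(self):
        triplets = _triplets(
            "II",
            ("P", 100, 110, 120),
            ("P", 550, 560, 570), ("QRS", 650, 660, 670),
            ("P", 1000, 1010, 1020), ("QRS", 1100, 1110, 1120),
        )
        # first span (100, 550) lacks a QRS; second span (550, 1000) has one
        assert locate_beat_boundaries(triplets) == [(550, 1000)]

    def test_beats_per_lead_equals_p_onset_count_minus_one(self, synth_corpus):
        corpus_dir, truth = synth_corpus
        for sr in truth.values():
            for lead in LEAD_NAMES:
                p_onsets = [t for t in sr.triplets[lead] if t.wave_type == "P"]
                spans = locate_beat_boundaries(sr.triplets[lead])
                assert len(spans) == len(p_onsets) - 1


class TestExtractBeatWindows:
    def test_short_span_zero_padded(self):
        triplets = _triplets(
            "II",
            ("P", 100, 110, 120), ("QRS", 200, 210, 220),
            ("P", 500, 510, 520), ("QRS", 600, 610, 620),
        )
        record = _record()
        (window,) = extract_beat_windows(record, triplets, "II")
        assert window.valid_length == 400
        np.testing.assert_array_equal(window.signal[400:], 0.0)
        np.testing.assert_array_equal(window.labels[400:], 0)
        np.testing.assert_array_equal(window.signal[:400], record.lead("II")[100:500])

    def test_exact_span_unchanged(self):
        triplets = _triplets(
            "II",
            ("P", 0, 10, 20), ("QRS", 100, 110, 120),
            ("P", 512, 520, 530), ("QRS", 600, 610, 620),
        )
        record = _record()
        (window,) = extract_beat_windows(record, triplets, "II")
        assert window.valid_length == WINDOW_LENGTH
        np.testing.assert_array_equal(window.signal, record.lead("II")[:512])

    def test_long_span_clipped_with_labels(self):
        triplets = _triplets(
            "II",
            ("P", 0, 10, 20), ("QRS", 100, 110, 120), ("T", 530, 540, 550),
            ("P", 600, 610, 620), ("QRS", 700, 710, 720),
        )
        (window,) = extract_beat_windows(_record(), triplets, "II")
        assert window.valid_length == WINDOW_LENGTH
        # the T wave at 530..550 falls beyond the clip and is cut
        assert (window.labels == 3).sum() == 0
        assert (window.labels[:21] == 1).all()

    def test_labels_rebased_to_window(self):
        triplets = _triplets(
            "II",
            ("P", 100, 110, 120), ("QRS", 200, 210, 220), ("T", 300, 330, 360),
            ("P", 550, 560, 570), ("QRS", 650, 660, 670),
        )
        (window,) = extract_beat_windows(_record(), triplets, "II")
        assert window.start_sample == 100
        assert (window.labels[0:21] == 1).all()  # P at 100..120 -> 0..20
        assert (window.labels[100:121] == 2).all()
        assert (window.labels[200:261] == 3).all()

    def test_window_invariant_padding_is_zero(self, synth_corpus):
        _, truth = synth_corpus
        for sr in truth.values():
            for lead in ("I", "aVR", "V6"):
                for w in extract_beat_windows(sr.record, sr.triplets[lead], lead):
                    assert w.signal.shape == (WINDOW_LENGTH,)
                    np.testing.assert_array_equal(w.labels[w.valid_length:], 0)
                    np.testing.assert_array_equal(w.signal[w.valid_length:], 0.0)


def _beat_stub(record_id, lead, i):
    return BeatWindow(
        record_id=record_id, lead=lead, beat_index=i,
        signal=np.zeros(WINDOW_LENGTH), labels=np.zeros(WINDOW_LENGTH, dtype=np.int64),
        valid_length=400, start_sample=i * 500,
    )


@pytest.fixture()
def beat_pool():
    return [
        _beat_stub(str(rid), lead, i)
        for rid in range(1, 21)
        for lead in LEAD_NAMES
        for i in range(3)
    ]


class TestMakeSplit:
    def test_patient_based_no_record_overlap(self, beat_pool):
        spec = SplitSpec(mode="patient_based", patient_ranges=((1, 16), (17, 18), (19, 20)))
        split = make_split(beat_pool, spec)
        ids = {k: {b.record_id for b in v} for k, v in split.items()}
        assert ids["train"] & ids["val"] == set()
        assert ids["train"] & ids["test"] == set()
        assert ids["val"] & ids["test"] == set()

    def test_conservation_both_modes(self, beat_pool):
        for spec in (
            SplitSpec(mode="patient_based", patient_ranges=((1, 16), (17, 18), (19, 20))),
            SplitSpec(mode="beat_based", seed=1),
        ):
            split = make_split(beat_pool, spec)
            assert sum(len(v) for v in split.values()) == len(beat_pool)

    def test_patient_counts_exact(self, beat_pool):
        spec = SplitSpec(mode="patient_based", patient_ranges=((1, 16), (17, 18), (19, 20)))
        split = make_split(beat_pool, spec)
        # 3 beats x 12 leads per record
        assert len(split["train"]) == 16 * 36
        assert len(split["val"]) == 2 * 36
        assert len(split["test"]) == 2 * 36

    def test_beat_based_all_to_train(self, beat_pool):
        spec = SplitSpec(mode="beat_based", fractions=(1.0, 0.0, 0.0))
        split = make_split(beat_pool, spec)
        assert len(split["train"]) == len(beat_pool)
        assert not split["val"] and not split["test"]

    def test_beat_based_deterministic(self, beat_pool):
        spec = SplitSpec(mode="beat_based", seed=99)
        s1 = make_split(beat_pool, spec)
        s2 = make_split(beat_pool, spec)
        for name in ("train", "val", "test"):
            assert [id(b) for b in s1[name]] == [id(b) for b in s2[name]]

    def test_beat_based_fractions_per_lead(self, beat_pool):
        split = make_split(beat_pool, SplitSpec(mode="beat_based", seed=0))
        counts = split_counts(split).set_index("split")
        # 60 beats per lead: floor(.8*60)=48, floor(.12*60)=7, rest 5
        assert (counts.loc["train", list(LEAD_NAMES)] == 48).all()
        assert (counts.loc["val", list(LEAD_NAMES)] == 7).all()
        assert (counts.loc["test", list(LEAD_NAMES)] == 5).all()

    def test_record_outside_ranges_rejected(self, beat_pool):
        spec = SplitSpec(mode="patient_based", patient_ranges=((1, 10), (11, 12), (13, 14)))
        with pytest.raises(ValueError, match="outside every patient range"):
            make_split(beat_pool, spec)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            SplitSpec(mode="beat_based", fractions=(0.5, 0.2, 0.2))

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitSpec(mode="patient_based", patient_ranges=((1, 10), (10, 12), (13, 14)))


def test_auto_patient_ranges_canonical_200():
    assert auto_patient_ranges(range(1, 201)) == ((1, 180), (181, 190), (191, 200))
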