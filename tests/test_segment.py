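import numpy as np
import pytest

from qrsnet import (
    RawSignal,
    SynthConfig,
    average_difference,
    build_dataset,
    difference,
    extract_pair,
    generate_record,
    label_center,
)
from qrsnet.records import BeatAnnotationSet, RecordBundle
from qrsnet.segment import (
    WINDOW_LENGTH,
    ClassLabel,
    center_raw_index,
    locate_qs_landmarks,
    valid_center_range,
)


def _signals(n=600, n_i=5, seed=0):
    rng = np.random.default_rng(seed)
    sig = RawSignal(rng.normal(size=n), 360.0)
    return difference(sig), average_difference(sig, n_i)


class TestExtractPair:
    def test_boundary_arithmetic_at_first_center(self):
        sd, sad = _signals()
        pair = extract_pair(sd, sad, 22)
        assert np.array_equal(pair.object_window, sad.samples[0:56])
        assert pair.center_raw_index == 112
        assert np.array_equal(pair.part_window, sd.samples[112 - 22 : 112 + 34])

    def test_windows_always_56_and_centers_linked(self):
        sd, sad = _signals()
        for c in (22, 40, 60):
            pair = extract_pair(sd, sad, c)
            assert pair.part_window.shape == (WINDOW_LENGTH,)
            assert pair.object_window.shape == (WINDOW_LENGTH,)
            assert pair.center_raw_index == c * 5 + 2

    def test_window_durations_at_mlii_rates(self):
        """At 360 Hz with an averaging factor of 5 the 56-sample windows span
        0.16 s (difference) and 0.78 s (averaged difference)."""
        sd, sad = _signals()
        assert round(WINDOW_LENGTH / sd.sampling_rate, 2) == 0.16
        assert round(WINDOW_LENGTH / sad.effective_rate, 2) == 0.78

    def test_last_valid_center_touches_final_sample(self):
        sd, sad = _signals(n=300)
        lo, hi = valid_center_range(len(sd), len(sad), 5)
        assert (lo, hi) == (22, 27)
        pair = extract_pair(sd, sad, hi - 1)
        assert np.array_equal(pair.object_window, sad.samples[hi - 1 - 22 :])
        with pytest.raises(IndexError):
            extract_pair(sd, sad, hi)
        with pytest.raises(IndexError):
            extract_pair(sd, sad, lo - 1)

    def test_translation_consistency(self):
        """Shifting the record by n_i raw samples shifts the averaged centre
        by one and reproduces the object window."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=700)
        n_i = 5
        a = average_difference(RawSignal(x, 360.0), n_i)
        b = average_difference(RawSignal(x[n_i:], 360.0), n_i)
        da = difference(RawSignal(x, 360.0))
        db = difference(RawSignal(x[n_i:], 360.0))
        p1 = extract_pair(da, a, 40)
        p2 = extract_pair(db, b, 39)
        assert np.allclose(p1.object_window[1:], p2.object_window[1:], atol=1e-12)


@pytest.fixture(scope="module")
def annotated():
    sig, ann = generate_record(SynthConfig(duration=30.0, hr_jitter=0.0), seed=2)
    return sig, locate_qs_landmarks(sig, ann)


class TestLabelCenter:
    def test_exact_r_center(self, annotated):
        sig, ann = annotated
        r = int(ann.r_indices[3])
        assert label_center(r, ann, sig.sampling_rate, 5) is ClassLabel.R

    def test_far_field_is_nonqrs(self, annotated):
        sig, ann = annotated
        c = int(ann.r_indices[3]) + int(0.5 * sig.sampling_rate)
        assert label_center(c, ann, sig.sampling_rate, 5) is ClassLabel.NONQRS

    def test_known_q_landmark(self, annotated):
        """The generator puts Q at R - 0.04 s; a centre there labels Q."""
        sig, ann = annotated
        q = int(ann.q_indices[3])
        r = int(ann.r_indices[3])
        assert r - q == round(0.04 * sig.sampling_rate)
        assert label_center(q, ann, sig.sampling_rate, 5) is ClassLabel.Q

    def test_known_s_landmark(self, annotated):
        sig, ann = annotated
        s = int(ann.s_indices[3])
        assert label_center(s, ann, sig.sampling_rate, 5) is ClassLabel.S

    def test_ambiguous_band_excluded(self, annotated):
        sig, ann = annotated
        c = int(ann.r_indices[3]) + int(0.1 * sig.sampling_rate)
        assert label_center(c, ann, sig.sampling_rate, 5) is None

    def test_empty_reference_is_far_field(self):
        empty = BeatAnnotationSet(r_indices=np.asarray([], dtype=np.int64))
        assert label_center(100, empty, 360.0, 5) is ClassLabel.NONQRS


class TestLocateLandmarks:
    def test_minima_found_beside_r(self):
        sig, ann = generate_record(SynthConfig(duration=20.0), seed=8)
        bare = BeatAnnotationSet(r_indices=ann.r_indices)
        filled = locate_qs_landmarks(sig, bare)
        # the signal trough sits within ~0.015 s of the generator's wave
        # centre (the R upstroke pulls the summed minimum slightly outward)
        assert np.all(np.abs(filled.q_indices - ann.q_indices) <= 5)
        assert np.all(np.abs(filled.s_indices - ann.s_indices) <= 5)
        assert np.all(filled.q_indices < ann.r_indices)
        assert np.all(filled.s_indices > ann.r_indices)


class TestBuildDataset:
    def test_requested_counts_and_determinism(self, clean_record):
        balance = {"R": 10, "Q": 10, "S": 10, "NONQRS": 10}
        a = build_dataset(clean_record, n_i=5, balance=balance, seed=3)
        b = build_dataset(clean_record, n_i=5, balance=balance, seed=3)
        assert len(a) == 40
        assert a.class_counts() == {"Q": 10, "R": 10, "S": 10, "NONQRS": 10}
        assert np.array_equal(a.part, b.part)
        assert np.array_equal(a.centers_raw, b.centers_raw)

    def test_insufficient_centers_names_the_class(self, clean_record):
        with pytest.raises(ValueError, match="R"):
            build_dataset(clean_record, n_i=5, balance={"R": 10_000}, seed=0)

    def test_unannotated_record_rejected(self, clean_record):
        bare = RecordBundle(signal=clean_record.signal)
        with pytest.raises(ValueError):
            build_dataset(bare, n_i=5, balance={"R": 1}, seed=0)

    def test_no_pair_from_ambiguous_band(self, clean_record):
        ds = build_dataset(
            clean_record, n_i=5, balance={"R": 20, "Q": 20, "S": 20, "NONQRS": 20}, seed=1
        )
        ann = clean_record.annotations
        fs = clean_record.signal.sampling_rate
        for c, lab in zip(ds.centers_raw, ds.labels):
            d = np.min(np.abs(ann.r_indices - c))
            if lab == int(ClassLabel.NONQRS):
                assert d > 0.2 * fs
            else:
                assert d <= 0.2 * fs

    def test_roundtrip_npz(self, clean_record, tmp_path):
        ds = build_dataset(clean_record, n_i=5, balance={"R": 5, "Q": 5, "S": 5, "NONQRS": 5}, seed=1)
        path = tmp_path / "ds.npz"
        ds.save(path)
        from qrsnet import SegmentDataset

        back = SegmentDataset.load(path)
        assert np.array_equal(back.objects, ds.objects)
        assert np.array_equal(back.labels, ds.labels)


def test_center_raw_index_formula():
    assert center_raw_index(22, 5) == 112
    assert center_raw_index(0, 1) == 0
    assert center_raw_index(7, 4) == 30
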