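"""Segmentation windows, resampling, baseline removal and RR ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from advbeat.mitdb import BeatAnnotation, EcgRecord
from advbeat.preprocess import (
    RawSegment,
    assemble_input,
    compute_rr_ratios,
    preprocess_record,
    remove_baseline,
    resample_to_128,
    segment_heartbeats,
)


def _ann(positions):
    return [BeatAnnotation(int(p), "N") for p in positions]


class TestSegmentation:
    def test_window_bounds_and_length_identity(self, flat_record):
        segs = segment_heartbeats(flat_record, _ann([1000, 1300]))
        assert len(segs) == 1
        s = segs[0]
        assert (s.prev_r, s.cur_r) == (1000, 1300)
        assert s.samples.shape == (350, 2)  # [1050, 1400)

    def test_one_segment_per_beat_after_the_first(self, flat_record):
        segs = segment_heartbeats(flat_record, _ann(range(100, 3100, 300)))
        assert len(segs) == 9

    @given(rr=st.integers(min_value=80, max_value=500))
    @settings(max_examples=20, deadline=None)
    def test_window_length_is_rr_plus_50(self, rr):
        record = EcgRecord("x", 360.0, np.zeros((rr * 4 + 300, 2)), ("a", "b"))
        segs = segment_heartbeats(record, _ann([100, 100 + rr, 100 + 2 * rr]))
        assert all(s.samples.shape[0] == rr + 50 for s in segs)

    def test_overrun_is_edge_replicated(self):
        sig = np.arange(20, dtype=float).reshape(10, 2)
        record = EcgRecord("x", 360.0, sig, ("a", "b"))
        segs = segment_heartbeats(record, _ann([0, 5]))
        # window [50, 105) starts past the record end -> skipped
        assert segs == []
        record2 = EcgRecord("x", 360.0, np.vstack([sig] * 10), ("a", "b"))
        segs2 = segment_heartbeats(record2, _ann([20, 40]))
        (s,) = segs2
        assert s.samples.shape[0] == 70
        # tail beyond sample 100 replicates the final row
        np.testing.assert_array_equal(s.samples[-1], record2.signal[-1])

    def test_fewer_than_two_annotations(self, flat_record):
        assert segment_heartbeats(flat_record, _ann([100])) == []
        assert segment_heartbeats(flat_record, []) == []


class TestResampling:
    def test_constant_signal_stays_constant(self):
        out = resample_to_128(np.full((77, 2), 3.25))
        assert out.shape == (128, 2)
        np.testing.assert_allclose(out, 3.25)

    @pytest.mark.parametrize("length", [50, 128, 350])
    def test_affine_signals_reproduced_exactly(self, length):
        ramp = np.linspace(0, 1, length)
        seg = np.stack([ramp, 2 - 3 * ramp], axis=1)
        out = resample_to_128(seg)
        expect = np.stack([np.linspace(0, 1, 128),
                           2 - 3 * np.linspace(0, 1, 128)], axis=1)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_identity_on_length_128(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(size=(128, 2))
        np.testing.assert_array_equal(resample_to_128(seg), seg)

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(1)
        seg = rng.normal(size=(37, 2))
        out = resample_to_128(seg)
        np.testing.assert_allclose(out[0], seg[0])
        np.testing.assert_allclose(out[-1], seg[-1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            resample_to_128(np.zeros((1, 2)))


class TestBaseline:
    def test_constant_beat_becomes_zero(self):
        out = remove_baseline(np.full((3, 128, 2), 5.0))
        np.testing.assert_allclose(out, 0.0)

    def test_zero_mean_beat_unchanged_and_means_vanish(self):
        rng = np.random.default_rng(2)
        beats = rng.normal(size=(4, 128, 2))
        centred = beats - beats.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(remove_baseline(centred), centred)
        out = remove_baseline(beats)
        assert np.max(np.abs(out.mean(axis=1))) < 1e-9

    def test_template_mode_removes_cross_beat_mean(self):
        rng = np.random.default_rng(3)
        beats = rng.normal(size=(5, 128, 2))
        out = remove_baseline(beats, mode="template")
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)


class TestRrRatios:
    def test_constant_rr_gives_unit_ratios(self, constant_rr_annotations):
        r = compute_rr_ratios(constant_rr_annotations, 5)
        assert r.pre_rr_ratio == pytest.approx(1.0)
        assert r.near_pre_rr_ratio == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # R peaks at [0, 300, 600, 900, 1500]: last pre-RR = 600,
        # record mean = 375 -> 1.6; previous-3 mean = 300 -> 2.0
        anns = _ann([0, 300, 600, 900, 1500])
        r = compute_rr_ratios(anns, 4)
        assert r.pre_rr_ratio == pytest.approx(1.6)
        assert r.near_pre_rr_ratio == pytest.approx(2.0)

    def test_first_interval_defaults_near_ratio_to_one(self):
        anns = _ann([0, 250, 500])
        r = compute_rr_ratios(anns, 1)
        assert r.near_pre_rr_ratio == 1.0

    def test_beat_zero_rejected(self, constant_rr_annotations):
        with pytest.raises(ValueError):
            compute_rr_ratios(constant_rr_annotations, 0)

    @given(scale=st.integers(min_value=2, max_value=9),
           seed=st.integers(min_value=0, max_value=50))
    @settings(max_examples=25, deadline=None)
    def test_time_rescaling_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.integers(200, 500, size=8))
        idx = int(rng.integers(1, 8))
        a = compute_rr_ratios(_ann(pos), idx)
        b = compute_rr_ratios(_ann(pos * scale), idx)
        assert a.pre_rr_ratio == pytest.approx(b.pre_rr_ratio, rel=1e-12)
        assert a.near_pre_rr_ratio == pytest.approx(b.near_pre_rr_ratio, rel=1e-12)


class TestAssembly:
    def test_tensor_layout_and_size(self):
        rng = np.random.default_rng(4)
        beat = rng.normal(size=(128, 2))
        from advbeat.preprocess import RrRatios
        x = assemble_input(beat, RrRatios(1.3, 0.7))
        assert x.shape == (3, 128, 2) and x.size == 768
        np.testing.assert_array_equal(x[0], beat)
        np.testing.assert_allclose(x[1], 1.3)
        np.testing.assert_allclose(x[2], 0.7)

    def test_unit_ratios_give_all_ones_rows(self):
        from advbeat.preprocess import RrRatios
        x = assemble_input(np.zeros((128, 2)), RrRatios(1.0, 1.0))
        np.testing.assert_array_equal(x[1:], 1.0)


class TestRecordPipeline:
    def test_drops_first_beat_and_is_deterministic(self, small_record):
        rec = small_record.as_ecg_record()
        anns = small_record.beat_annotations()
        x1, beats1 = preprocess_record(rec, anns)
        x2, beats2 = preprocess_record(rec, anns)
        assert len(beats1) == len(anns) - 1
        assert x1.shape == (len(anns) - 1, 3, 128, 2)
        np.testing.assert_array_equal(x1, x2)
        assert beats1 == beats2

    def test_synthetic_s_beat_has_short_pre_rr_ratio(self, small_record):
        rec = small_record.as_ecg_record()
        anns = small_record.beat_annotations()
        x, beats = preprocess_record(rec, anns)
        labels = np.array([b.aami_class for b in beats])
        s_rows = x[labels == 1]
        n_rows = x[labels == 0]
        # the premature S beat's pre-RR ratio sits well below the N average
        assert s_rows[0, 1, 0, 0] < 0.85
        assert abs(np.median(n_rows[:, 1, 0, 0]) - 1.0) < 0.15
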