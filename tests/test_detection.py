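"""Detector unit behaviour and whole-pipeline properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgval import (
    DetectorConfig,
    ECGRecord,
    MorphologyConfig,
    detect_in_interval,
    detect_r_peaks,
    flag_abnormal_rr,
    local_repeak_search,
    match_peaks,
    merge_branches,
    segment_intervals,
    synthesize_ecg,
)

EPOCH = 1_700_000_000_000.0
CFG = DetectorConfig()


def _clean_window(n_beats=10, fs=500.0, rr_ms=1000.0, first_ms=500.0):
    beats = EPOCH + first_ms + rr_ms * np.arange(n_beats)
    rec = synthesize_ecg(
        beats, fs=fs,
        morphology=MorphologyConfig(noise_sd_uv=0.0, wander_amplitude_uv=0.0),
        start_epoch_ms=EPOCH,
    )
    return rec, beats


class TestSegmentation:
    def test_partition_of_ten_seconds_into_fours(self):
        rec = ECGRecord(np.zeros(10_000) + 1.0, 1000.0, EPOCH)
        ranges = segment_intervals(rec, 4.0)
        assert [(r.start, r.stop) for r in ranges] == [(0, 4000), (4000, 8000), (8000, 10_000)]
        assert all(r.fs == 1000.0 for r in ranges)

    def test_interval_longer_than_record_gives_one_range(self):
        rec = ECGRecord(np.ones(100), 500.0, EPOCH)
        ranges = segment_intervals(rec, 60.0)
        assert [(r.start, r.stop) for r in ranges] == [(0, 100)]

    @settings(max_examples=50, derandomize=True)
    @given(n=st.integers(1, 5000), interval_s=st.floats(0.01, 20.0))
    def test_ranges_partition_the_index_set(self, n, interval_s):
        rec = ECGRecord(np.ones(n), 250.0, EPOCH)
        ranges = segment_intervals(rec, interval_s)
        covered = np.concatenate([np.arange(r.start, r.stop) for r in ranges])
        np.testing.assert_array_equal(covered, np.arange(n))  # union + disjoint + ordered


class TestIntervalDetection:
    def test_clean_upright_beats_found_at_true_times(self):
        rec, beats = _clean_window()
        idx, volts, thr = detect_in_interval(rec.samples, "R", CFG, rec.fs)
        assert idx.size == 10
        np.testing.assert_allclose(rec.sample_time_ms(idx), beats, atol=rec.period_ms)
        assert np.all(volts > 0)

    def test_inverted_pass_sees_the_same_events(self):
        rec, beats = _clean_window()
        idx_r, _, _ = detect_in_interval(rec.samples, "R", CFG, rec.fs)
        idx_s, volts_s, _ = detect_in_interval(-rec.samples, "S", CFG, rec.fs)
        np.testing.assert_array_equal(idx_r, idx_s)
        assert np.all(volts_s < 0)  # voltages reported in the window's own sign

    def test_white_noise_yields_at_most_one_candidate(self):
        rng = np.random.default_rng(7)
        idx, _, _ = detect_in_interval(rng.normal(0, 50, 5000), "R", CFG, 500.0)
        assert idx.size <= 1

    def test_flat_window_yields_nothing(self):
        idx, _, thr = detect_in_interval(np.zeros(1000), "R", CFG, 500.0)
        assert idx.size == 0 and np.isnan(thr)


class TestMergeBranches:
    def test_nearby_cross_branch_candidates_collapse(self):
        t, v, b = merge_branches(
            ([1000.0, 2000.0], [500.0, 500.0]),
            ([1005.0, 3000.0], [-500.0, -500.0]),
            refractory_ms=200.0,
        )
        np.testing.assert_array_equal(t, [1000.0, 2000.0, 3000.0])
        assert list(b) == ["R", "R", "S"]

    def test_identical_lists_merge_to_identity(self):
        t, v, b = merge_branches(([1000.0, 2000.0], [1, 1]), ([1000.0, 2000.0], [1, 1]), 200.0)
        np.testing.assert_array_equal(t, [1000.0, 2000.0])

    def test_dominant_deflection_keeps_its_time(self):
        # S-dominant morphology: the larger |voltage| wins the collapse
        t, _, b = merge_branches(([1030.0], [300.0]), ([1000.0], [-900.0]), 200.0)
        np.testing.assert_array_equal(t, [1000.0])
        assert list(b) == ["S"]

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_merged_list_respects_refractory(self, data):
        rt = sorted(data.draw(st.lists(st.floats(0, 10_000), max_size=20, unique=True)))
        s_times = sorted(data.draw(st.lists(st.floats(0, 10_000), max_size=20, unique=True)))
        rv = [1.0] * len(rt)
        sv = [-1.0] * len(s_times)
        t, _, _ = merge_branches((rt, rv), (s_times, sv), 200.0)
        if t.size > 1:
            assert np.min(np.diff(t)) >= 200.0


class TestAnomalyScreen:
    def test_single_doubled_gap_is_flagged_as_missed(self):
        # steady 800 ms train with one beat removed: a single 1600 ms gap
        t = np.delete(EPOCH + 800.0 * np.arange(41), 20)
        out = flag_abnormal_rr(t, CFG)
        assert len(out) == 1
        assert out.iloc[0]["kind"] == "missed"
        assert out.iloc[0]["rr_ms"] == pytest.approx(1600.0, abs=1e-9)

    def test_steady_series_is_clean(self):
        t = EPOCH + 800.0 * np.arange(50)
        assert len(flag_abnormal_rr(t, CFG)) == 0

    def test_incremental_ramp_is_tolerated(self):
        # RR drifting 1000 -> 300 ms over five minutes, as in a ramp test
        rr = np.linspace(1000.0, 300.0, 460)
        t = EPOCH + np.concatenate([[0.0], np.cumsum(rr)])
        assert len(flag_abnormal_rr(t, CFG)) == 0

    def test_short_gap_is_flagged_as_extra(self):
        t = EPOCH + np.concatenate([800.0 * np.arange(20), [15200 + 250], [16000 + 800 * k for k in range(20)]])
        t = np.sort(t)
        out = flag_abnormal_rr(t, CFG)
        assert (out["kind"] == "extra").any()


class TestLocalResearch:
    def test_recovers_a_suppressed_beat(self):
        rec, beats = _clean_window()
        target = beats[4] + 40.0  # imperfect gap midpoint
        found = local_repeak_search(rec, target, halfwidth_ms=150.0, threshold_uv=800.0)
        assert found is not None
        _, t, v = found
        assert abs(t - beats[4]) <= rec.period_ms
        assert v > 0

    def test_flat_gap_yields_nothing(self):
        rec = ECGRecord(np.zeros(5000), 500.0, EPOCH)
        assert local_repeak_search(rec, EPOCH + 5000.0, 300.0, 500.0) is None

    def test_target_outside_record_yields_nothing(self):
        rec, _ = _clean_window()
        assert local_repeak_search(rec, rec.end_epoch_ms + 1000.0, 300.0, 500.0) is None


class TestFullPipeline:
    def test_clean_protocol_signal_is_fully_detected(self, protocol_beats, clean_record):
        beats, _ = protocol_beats
        peaks, diag = detect_r_peaks(clean_record)
        m = match_peaks(beats, peaks, threshold_ms=100.0)
        assert m.fn == 0 and m.fp == 0
        assert m.tp == beats.size

    def test_noisy_signal_keeps_sensitivity_high(self, protocol_beats):
        beats, _ = protocol_beats
        rec = synthesize_ecg(
            beats, fs=500.0,
            morphology=MorphologyConfig(noise_sd_uv=100.0, wander_amplitude_uv=120.0),
            seed=11,
        )
        peaks, _ = detect_r_peaks(rec)
        m = match_peaks(beats, peaks, threshold_ms=100.0)
        assert 100.0 * m.tp / (m.tp + m.fn) >= 99.0

    def test_polarity_invariance(self, clean_record):
        p_up, _ = detect_r_peaks(clean_record)
        flipped = ECGRecord(-clean_record.samples, clean_record.fs, clean_record.start_epoch_ms)
        p_down, _ = detect_r_peaks(flipped)
        assert p_up.n_peaks == p_down.n_peaks
        np.testing.assert_allclose(
            p_up.peak_epoch_ms, p_down.peak_epoch_ms, atol=clean_record.period_ms
        )

    def test_inverted_morphology_detected_unchanged(self, protocol_beats):
        beats, _ = protocol_beats
        rec = synthesize_ecg(
            beats, fs=500.0, morphology=MorphologyConfig(rs_ratio=-3.0, noise_sd_uv=5.0), seed=5
        )
        peaks, _ = detect_r_peaks(rec)
        m = match_peaks(beats, peaks, threshold_ms=100.0)
        assert m.fn == 0 and m.fp == 0

    def test_determinism(self, clean_record):
        p1, d1 = detect_r_peaks(clean_record)
        p2, d2 = detect_r_peaks(clean_record)
        np.testing.assert_array_equal(p1.peak_epoch_ms, p2.peak_epoch_ms)
        np.testing.assert_array_equal(p1.sample_index, p2.sample_index)
        assert d1.as_dict() == d2.as_dict()

    def test_output_invariants(self, clean_record):
        peaks, diag = detect_r_peaks(clean_record)
        assert np.all(np.diff(peaks.peak_epoch_ms) >= CFG.refractory_ms)
        np.testing.assert_array_equal(
            peaks.peak_epoch_ms, clean_record.sample_time_ms(peaks.sample_index)
        )

    def test_convergence_means_no_trailing_repairs(self, clean_record):
        _, diag = detect_r_peaks(clean_record)
        assert diag.iterations <= CFG.max_iterations
        assert diag.last_iteration_repairs == 0

    def test_flat_record_yields_empty_peaklist(self):
        rec = ECGRecord(np.full(5000, 2.0), 500.0, EPOCH)
        peaks, diag = detect_r_peaks(rec)
        assert peaks.n_peaks == 0
        assert any("flat" in n for n in diag.notes)

    def test_repair_recovers_a_beat_hidden_from_thresholding(self):
        # attenuate one beat so the threshold pass skips it; the RR screen
        # plus local re-search must bring it back
        beats = EPOCH + 500.0 + 900.0 * np.arange(40)
        rec = synthesize_ecg(
            beats, fs=500.0,
            morphology=MorphologyConfig(noise_sd_uv=0.0, wander_amplitude_uv=0.0),
        )
        lo = rec.index_at(beats[20] - 120.0)
        hi = rec.index_at(beats[20] + 120.0)
        attenuated = rec.samples.copy()
        attenuated[lo:hi] *= 0.6
        peaks, diag = detect_r_peaks(ECGRecord(attenuated, rec.fs, rec.start_epoch_ms))
        m = match_peaks(beats, peaks, threshold_ms=100.0)
        assert m.fn == 0
        assert diag.repairs_made >= 1 or peaks.n_peaks == beats.size
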