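import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrsdet import (DetectorConfig, SyntheticSpec, detect, find_peaks,
                    generate_synthetic, init_state, match_beats, preprocess,
                    run_detector, to_raw_fiducials, update_ave_rr)
from qrsdet.peak_finder import CandidatePeak


def make_state(m_val=100.0, fs=360.0, config=None):
    x = np.zeros(400)
    x[10] = m_val
    return init_state(x, fs, config)


class TestInitState:
    @pytest.mark.parametrize("m,spk,npk,thr", [
        (100.0, 13.0, 1.3, 4.225),
        (1.0, 0.13, 0.013, 0.04225),
    ])
    def test_initialisation_arithmetic(self, m, spk, npk, thr):
        """SPK = 0.13 M, NPK = 0.1 SPK, THRESHOLD = 0.25 SPK + 0.75 NPK."""
        s = make_state(m)
        assert np.isclose(s.spk, spk)
        assert np.isclose(s.npk, npk)
        assert np.isclose(s.threshold, thr)

    def test_all_zero_window_gives_zero_state(self):
        s = init_state(np.zeros(500), 360)
        assert s.spk == s.npk == s.threshold == 0.0

    def test_window_uses_first_300_samples_scaled(self):
        x = np.zeros(500)
        x[299] = 10.0  # inside the window at 360 Hz
        x[400] = 99.0  # outside
        assert np.isclose(init_state(x, 360).spk, 1.3)
        # at 180 Hz the window is 150 samples; both spikes fall outside
        x2 = np.zeros(500)
        x2[200] = 10.0
        assert init_state(x2, 180).spk == 0.0

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            init_state(np.empty(0), 360)


class TestAveRr:
    def test_push_into_full_buffer(self):
        s = make_state()
        for _ in range(10):
            update_ave_rr(s, 300)
        update_ave_rr(s, 400)
        assert np.isclose(s.ave_rr, 310.0)  # mean of [300]*9 + [400]

    def test_single_element(self):
        s = make_state()
        update_ave_rr(s, 360)
        assert s.ave_rr == 360.0

    def test_fifo_eviction(self):
        s = make_state()
        for _ in range(11):
            update_ave_rr(s, 100)
        update_ave_rr(s, 200)
        assert list(s.rr_buffer) == [100.0] * 9 + [200.0]
        assert np.isclose(s.ave_rr, 110.0)

    def test_non_positive_rr_fails(self):
        s = make_state()
        with pytest.raises(ValueError):
            update_ave_rr(s, 0)


class TestDetect:
    def test_all_supra_threshold_peaks_accepted(self):
        """Regularly spaced peaks far above threshold: all accepted,
        none via search-back, RR buffer filled with the spacing."""
        x = np.zeros(4000)
        x[:300] = 0.0
        x[10] = 1.0
        peaks = [CandidatePeak(100 + 300 * k, 10.0) for k in range(10)]
        state = init_state(x, 360)
        res = detect(peaks, x, 360, state)
        assert len(res.detections) == 10
        assert not any(d.via_searchback for d in res.detections)
        assert np.all(res.rr_intervals == 300)
        assert np.isclose(state.ave_rr, 300.0)

    def test_weak_trailing_peak_recovered_by_searchback(self):
        """Hand-traced scenario: 9 strong peaks then one weak peak at
        0.4x the running threshold followed by a long silence.  SPK
        halving (two halvings here) lowers the threshold below the weak
        amplitude and the peak is accepted, flagged via_searchback."""
        cfg = DetectorConfig()
        x = np.zeros(3600)
        x[10] = 100.0  # M=100 -> SPK 13, NPK 1.3
        state = init_state(x, 360, cfg)
        # hand-trace SPK after 9 acceptances of amplitude 100:
        spk = 13.0
        for _ in range(9):
            spk = 0.125 * 100 + 0.875 * spk
        thr = 0.25 * spk + 0.75 * 1.3
        weak = 0.4 * thr
        peaks = [CandidatePeak(300 * k, 100.0) for k in range(9)]
        peaks.append(CandidatePeak(2700, weak))
        res = detect(peaks, x, 360, state, cfg)
        assert len(res.detections) == 10
        assert res.detections[-1].via_searchback
        assert res.detections[-1].integrated_index == 2700
        # exactly the two final halvings were needed
        assert np.isclose(state.spk,
                          0.125 * weak + 0.875 * (spk * 0.25))

    def test_empty_peaks_empty_result(self):
        res = detect([], np.zeros(100), 360)
        assert res.detections == []
        assert len(res.rr_intervals) == 0

    def test_unsorted_peaks_rejected(self):
        with pytest.raises(ValueError):
            detect([CandidatePeak(100, 1.0), CandidatePeak(50, 1.0)],
                   np.zeros(400), 360)

    def test_threshold_invariant_along_trace(self, noisy_record):
        """THRESHOLD == 0.25 SPK + 0.75 NPK after every decision."""
        pre = preprocess(noisy_record)
        peaks = find_peaks(pre.integrated, pre.fs)
        res = detect(peaks, pre.integrated, pre.fs, trace=True)
        assert len(res.state_trace) == len(peaks)
        for _, spk, npk, thr, _ in res.state_trace:
            assert np.isclose(thr, 0.25 * spk + 0.75 * npk)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_of_decisions(self, seed, c):
        """Scaling the integrated signal (hence peaks and initial state)
        by c > 0 leaves the accept/reject pattern unchanged."""
        r = np.random.default_rng(seed)
        x = np.abs(r.standard_normal(3000))
        x[r.integers(0, 3000, 8)] += 20.0
        peaks = find_peaks(x, 360)
        base = detect(peaks, x, 360)
        scaled_peaks = [CandidatePeak(p.index, p.amplitude * c, p.forced)
                        for p in peaks]
        scaled = detect(scaled_peaks, x * c, 360)
        assert [(d.integrated_index, d.via_searchback)
                for d in base.detections] == \
            [(d.integrated_index, d.via_searchback)
             for d in scaled.detections]

    def test_detections_strictly_increasing_and_separated(self, noisy_record):
        pre, res = run_detector(noisy_record)
        idx = res.integrated_indices
        assert np.all(np.diff(idx) >= 80)

    def test_attenuated_beat_recovered_via_searchback(self):
        """One QRS at 30% amplitude drops below threshold, then the
        >1.5 AVE_RR gap triggers SPK halving and the beat is recovered."""
        spec = SyntheticSpec(duration_s=60, heart_rate_bpm=75,
                             rr_jitter_frac=0, drift_amp=0, powerline_amp=0,
                             noise_sd=0, attenuated_beats={20: 0.3}, seed=5)
        rec = generate_synthetic(spec)
        _, res = run_detector(rec)
        tp, fp, fn, _ = match_beats(res.raw_indices, rec.annotations, rec.fs)
        assert (tp, fp, fn) == (len(rec.annotations), 0, 0)
        sb = [d for d in res.detections if d.via_searchback]
        assert len(sb) == 1
        truth = rec.annotations.indices[20]
        assert abs(sb[0].raw_index - truth) <= 5


class TestRawFiducials:
    def test_zero_refine_window_is_pure_delay_subtraction(self, clean_record):
        pre = preprocess(clean_record)
        peaks = find_peaks(pre.integrated, pre.fs)
        res = detect(peaks, pre.integrated, pre.fs)
        out = to_raw_fiducials(res, pre, refine_window=0)
        delay = round(pre.total_delay)
        for d_in, d_out in zip(res.detections, out.detections):
            assert d_out.raw_index == d_in.integrated_index - delay

    def test_refined_fiducials_hit_ground_truth(self, clean_record):
        """On a noise-free record every refined fiducial lands within
        ±1 sample of the known QRS template center."""
        _, res = run_detector(clean_record)
        truth = clean_record.annotations.indices
        assert len(res.detections) == len(truth)
        assert np.abs(res.raw_indices - truth).max() <= 1

    def test_translation_equivariance(self, clean_record):
        """Shifting the input k samples shifts all raw fiducials by k."""
        k = 37
        pre = preprocess(clean_record)
        shifted = np.concatenate([np.zeros(k), pre.raw])
        pre_s = preprocess(shifted, fs=clean_record.fs)
        peaks = find_peaks(pre.integrated, pre.fs)
        res = detect(peaks, pre.integrated, pre.fs)
        res_shift = detect([CandidatePeak(p.index + k, p.amplitude, p.forced)
                            for p in peaks],
                           pre_s.integrated, pre_s.fs,
                           init_state(pre.integrated, pre.fs))
        a = to_raw_fiducials(res, pre).raw_indices
        b = to_raw_fiducials(res_shift, pre_s).raw_indices
        assert np.array_equal(b, a + k)
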