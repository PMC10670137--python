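import numpy as np
import pytest
from scipy.signal import freqz

from fdnirs import (
    FilterSpec,
    HemodynamicResponseModel,
    NoiseModel,
    apply_event_qc,
    apply_filter,
    design_bandpass,
    segment_events,
)
from fdnirs.preprocess import detect_artifact_windows
from fdnirs.types import ChromophoreSeries, StimulusEvent

FS = 10.4


def make_series(hbo2, hhb, valid=None, fs=FS):
    hbo2 = np.asarray(hbo2, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    valid = np.ones(hbo2.size, dtype=bool) if valid is None else valid
    return ChromophoreSeries(
        time_s=np.arange(hbo2.size) / fs,
        hbo2_uM=hbo2, hhb_uM=hhb, thb_uM=hbo2 + hhb,
        valid=valid, fs_hz=fs,
    )


def event(onset, modality="real", epoch="post", paradigm="cTBS", block=3):
    return StimulusEvent(onset_s=onset, modality=modality, epoch=epoch,
                         paradigm=paradigm, block_index=block)


class TestBandpassDesign:
    def test_gain_contract(self):
        k = design_bandpass(FilterSpec(), FS)

        def gain(f):
            _, h = freqz(k, worN=[max(f, 1e-12)], fs=FS)
            return abs(h[0])

        assert gain(0.0) <= 0.01  # DC removed
        assert 0.95 <= gain(0.1) <= 1.05  # passband
        assert abs(gain(np.sqrt(0.02 * 0.7)) - 1.0) <= 0.01
        assert gain(1.1) <= 0.1  # cardiac band

    def test_kernel_symmetric(self):
        k = design_bandpass(FilterSpec(), FS)
        assert np.allclose(k, k[::-1])

    def test_even_taps_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            FilterSpec(taps=1000)

    def test_cutoffs_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            design_bandpass(FilterSpec(low_cut_hz=0.02, high_cut_hz=6.0), FS)


class TestApplyFilter:
    def test_cardiac_sinusoid_attenuated(self):
        n = 4000
        t = np.arange(n) / FS
        a = 2.0
        x = 60.0 + a * np.sin(2 * np.pi * 1.1 * t)
        out = apply_filter(make_series(0.8 * x, 0.2 * x),
                           design_bandpass(FilterSpec(), FS))
        core = out.thb_uM[1200:-1200]
        assert np.sqrt(2.0) * core.std() <= 0.1 * a

    def test_constant_series_goes_to_zero(self):
        out = apply_filter(make_series(np.full(3000, 42.0), np.full(3000, 18.0)),
                           design_bandpass(FilterSpec(), FS))
        assert np.max(np.abs(out.thb_uM)) < 1e-9

    def test_zero_phase_impulse(self):
        n = 3001
        x = np.zeros(n)
        x[1700] = 5.0
        out = apply_filter(make_series(60.0 + x, np.full(n, 18.0)),
                           design_bandpass(FilterSpec(), FS))
        assert np.argmax(out.hbo2_uM) == 1700

    def test_thb_additivity_survives_filtering(self):
        rng = np.random.default_rng(0)
        out = apply_filter(
            make_series(42 + rng.normal(0, 1, 2500), 18 + rng.normal(0, 1, 2500)),
            design_bandpass(FilterSpec(), FS),
        )
        assert np.array_equal(out.thb_uM, out.hbo2_uM + out.hhb_uM)

    def test_short_series_rejected_with_minimum_length(self):
        with pytest.raises(ValueError, match="1001"):
            apply_filter(make_series(np.ones(100), np.ones(100)),
                         design_bandpass(FilterSpec(), FS))

    def test_invalid_run_dilated_by_half_kernel(self):
        n = 5000
        valid = np.ones(n, dtype=bool)
        valid[2500] = False
        out = apply_filter(make_series(np.full(n, 42.0), np.full(n, 18.0), valid),
                           design_bandpass(FilterSpec(), FS))
        assert not out.valid[2500 - 500] and not out.valid[2500 + 500]
        assert out.valid[2500 - 501] and out.valid[2500 + 501]


class TestSegmentation:
    def test_constant_series_normalizes_to_zero(self):
        series = make_series(np.full(2000, 42.0), np.full(2000, 18.0))
        segs = segment_events(series, [event(30.0)])
        assert len(segs) == 3  # BV, HbO2, HHb
        for s in segs:
            assert np.allclose(s.normalized_pct, 0.0)
            assert s.valid_fraction == 1.0

    def test_window_length_and_mean_matches_kernel(self, silent_noise):
        # one real post-cTBS event, amplitude a, no noise, no filtering:
        # the window mean must equal a x the kernel's window mean
        from fdnirs.types import SessionSchedule
        a = 14.0
        ev = event(30.0)
        sched = SessionSchedule(events=[ev], tbs_pulse_times_s=np.empty(0),
                                paradigm="cTBS", subject_id="x", seed=0)
        from fdnirs import simulate_chromophores
        tissue = simulate_chromophores(sched, noise=silent_noise,
                                       baseline_uM=(42.0, 18.0))
        series = make_series(tissue.c_hbo2_uM, tissue.c_hhb_uM)
        segs = [s for s in segment_events(series, [ev]) if s.signal == "BV"]
        hrf = HemodynamicResponseModel()
        win = int(np.floor(6.0 * FS))
        i0 = int(round(30.0 * FS))
        grid = (np.arange(i0 + 1, i0 + win + 1) / FS) - 30.0
        expected = a * hrf.kernel(grid).mean()
        assert segs[0].normalized_pct.size == win
        measured = segs[0].normalized_pct.mean()
        assert measured == pytest.approx(expected, rel=1e-2)

    def test_event_near_recording_end_dropped(self):
        series = make_series(np.full(400, 42.0), np.full(400, 18.0))
        segs = segment_events(series, [event(400 / FS - 1.0)])
        assert segs == []

    def test_pre_window_baseline_mode(self):
        n = 2000
        x = np.full(n, 42.0)
        i0 = int(round(30.0 * FS))
        x[i0] = 50.0  # spike exactly at onset: pre-window mode dilutes it
        series = make_series(x, np.full(n, 18.0))
        on = [s for s in segment_events(series, [event(30.0)],
                                        baseline_mode="onset-sample")
              if s.signal == "HbO2"][0]
        pre = [s for s in segment_events(series, [event(30.0)],
                                         baseline_mode="pre-window")
               if s.signal == "HbO2"][0]
        assert on.baseline_uM == pytest.approx(50.0)
        assert 42.0 < pre.baseline_uM < 44.0

    def test_tiny_absolute_level_flagged_unstable(self):
        series = make_series(np.full(2000, 1e-5), np.full(2000, 18.0))
        segs = [s for s in segment_events(series, [event(30.0)])
                if s.signal == "HbO2"]
        assert segs[0].flag == "unstable baseline"

    def test_scale_invariance_of_normalization(self):
        rng = np.random.default_rng(3)
        base = 42.0 + np.cumsum(rng.normal(0, 0.01, 2000))
        s1 = make_series(base, 18.0 * np.ones(2000))
        s2 = make_series(7.0 * base, 7.0 * 18.0 * np.ones(2000))
        a = [s for s in segment_events(s1, [event(30.0)]) if s.signal == "HbO2"][0]
        b = [s for s in segment_events(s2, [event(30.0)]) if s.signal == "HbO2"][0]
        assert np.allclose(a.normalized_pct, b.normalized_pct, atol=1e-9)


class TestEventQC:
    def test_low_valid_fraction_discarded(self):
        n = 2000
        valid = np.ones(n, dtype=bool)
        i0 = int(round(30.0 * FS))
        valid[i0 + 1: i0 + 32] = False  # 31 of 62 window samples invalid
        series = make_series(np.full(n, 42.0), np.full(n, 18.0), valid)
        segs = segment_events(series, [event(30.0)])
        out = apply_event_qc(segs, [])
        assert all(not s.kept and s.reason == "low valid fraction" for s in out)

    def test_fully_valid_no_artifacts_kept(self):
        series = make_series(np.full(2000, 42.0), np.full(2000, 18.0))
        out = apply_event_qc(segment_events(series, [event(30.0)]), [])
        assert all(s.kept for s in out)

    def test_artifact_overlap_counted_exactly(self):
        # 100 events; artifact windows built to overlap exactly the first 40
        n = int(900 * FS)
        series = make_series(np.full(n, 42.0), np.full(n, 18.0))
        events = [event(10.0 + 8.0 * i) for i in range(100)]
        windows = [(10.0 + 8.0 * i + 2.0, 10.0 + 8.0 * i + 2.5) for i in range(40)]
        out = apply_event_qc(segment_events(series, events), windows)
        bv = [s for s in out if s.signal == "BV"]
        assert sum(s.kept for s in bv) == 60
        assert sum(s.reason == "artifact overlap" for s in bv) == 40

    def test_detection_flags_injected_jump(self, clean_session):
        _, _, recording = clean_session
        import copy
        rec = copy.deepcopy(recording)
        i0 = 5000
        rec.iac[i0:i0 + 10] *= 5.0
        windows = detect_artifact_windows(rec)
        fs = rec.fs_hz
        assert any(t0 <= i0 / fs <= t1 for t0, t1 in windows)
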