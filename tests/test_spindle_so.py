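import numpy as np
import pytest

from sleepscope import preprocess as pp
from sleepscope import spindle_so as ss
from sleepscope import synthetic_cohort as sc
from sleepscope.types import EEGRecording, Hypnogram, SOEvent, SpindleEvent

from conftest import sinusoid_recording


def _amplitude_at(x, fs, freq):
    spec = np.abs(np.fft.rfft(x)) * 2 / len(x)
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


def _overlap_frac(a0, a1, b0, b1):
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    return inter / (b1 - b0)


def _burst_recording(burst_spec, fs=128.0, seconds=120.0, noise_rms=20.0,
                     burst_amp=100.0, seed=0, envelope="hann"):
    """Background noise plus 13.5 Hz bursts at given (start, dur) list.

    ``envelope`` "hann" gives gradually waxing/waning bursts; "flat"
    gives near-constant amplitude with short cosine ramps.
    """
    rng = np.random.default_rng(seed)
    n = int(seconds * fs)
    x = noise_rms * rng.standard_normal(n)
    from scipy import signal as spsig

    sos = spsig.butter(4, [0.5, 45.0], btype="bandpass", fs=fs, output="sos")
    x = noise_rms * spsig.sosfiltfilt(sos, x) / spsig.sosfiltfilt(sos, x).std()
    for start, dur in burst_spec:
        i0 = int(start * fs)
        m = int(dur * fs)
        t = np.arange(m) / fs
        if envelope == "hann":
            env = spsig.windows.hann(m)
        else:
            env = spsig.windows.tukey(m, alpha=min(0.2 / dur, 1.0))
        x[i0 : i0 + m] += burst_amp * np.sin(2 * np.pi * 13.5 * t) * env
    return EEGRecording(channels={"C3": x, "C4": x.copy()}, sample_rate=fs)


class TestPrepareSignal:
    def test_output_rate_128(self, preprocessed):
        out = ss.prepare_signal(preprocessed)
        assert out.sample_rate == 128.0

    def test_10hz_preserved(self):
        rec = sinusoid_recording(10.0, seconds=60)
        out = ss.prepare_signal(rec)
        ratio = _amplitude_at(out.channels["C3"], 128.0, 10.0) / _amplitude_at(
            rec.channels["C3"], 200.0, 10.0
        )
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_45hz_attenuated(self):
        rec = sinusoid_recording(45.0, seconds=60)
        out = ss.prepare_signal(rec)
        ratio = _amplitude_at(out.channels["C3"], 128.0, 45.0) / _amplitude_at(
            rec.channels["C3"], 200.0, 45.0
        )
        assert 20 * np.log10(max(ratio, 1e-12)) < -20.0


class TestDeltaMask:
    def test_homogeneous_signal_nothing_rejected(self):
        rng = np.random.default_rng(0)
        n_epochs = 20
        x = 30.0 * rng.standard_normal(int(128 * 30 * n_epochs))
        rec = EEGRecording(channels={"C3": x}, sample_rate=128.0)
        hyp = Hypnogram(stages=np.array(["N2"] * n_epochs))
        assert not ss.delta_artifact_epoch_mask(rec, hyp).any()

    def test_delta_burst_epoch_rejected(self):
        rng = np.random.default_rng(1)
        fs, n_epochs = 128.0, 20
        per = int(30 * fs)
        x = 30.0 * rng.standard_normal(per * n_epochs)
        t = np.arange(per) / fs
        x[7 * per : 8 * per] += 300.0 * np.sin(2 * np.pi * 2.0 * t)  # 10x delta
        rec = EEGRecording(channels={"C3": x}, sample_rate=fs)
        hyp = Hypnogram(stages=np.array(["N2"] * n_epochs))
        rejected = ss.delta_artifact_epoch_mask(rec, hyp)
        assert rejected[7]
        assert rejected.sum() == 1


class TestSpindleDetection:
    def test_single_planted_burst_recovered(self):
        rec = _burst_recording([(60.0, 1.0)], burst_amp=120.0, envelope="flat")
        hyp_epochs = np.arange(4)  # all four 30-s epochs are N2
        events = ss.detect_spindles(rec, hyp_epochs, "C3")
        assert len(events) == 1
        ev = events[0]
        assert _overlap_frac(ev.start, ev.end, 60.0, 61.0) >= 0.8

    def test_close_cores_merge_into_one_event(self):
        # burst gap 0.2 s leaves the above-threshold cores < 0.5 s apart
        rec = _burst_recording([(60.0, 0.8), (61.0, 0.8)], burst_amp=120.0)
        events = ss.detect_spindles(rec, np.arange(4), "C3")
        assert len(events) == 1
        assert events[0].start < 60.5 and events[0].end > 61.5

    def test_distant_cores_stay_separate(self):
        # burst gap 0.4 s puts the cores > 0.5 s apart: no merge
        rec = _burst_recording([(60.0, 0.8), (61.2, 0.8)], burst_amp=120.0)
        events = ss.detect_spindles(rec, np.arange(4), "C3")
        assert len(events) == 2

    def test_long_burst_rejected(self):
        rec = _burst_recording([(60.0, 3.5)], burst_amp=120.0, envelope="flat")
        events = ss.detect_spindles(rec, np.arange(4), "C3")
        assert events == []

    def test_borderline_burst_accepted(self):
        rec = _burst_recording([(60.0, 2.5)], burst_amp=120.0, envelope="flat")
        events = ss.detect_spindles(rec, np.arange(4), "C3")
        assert len(events) == 1

    def test_no_n2_warns_and_returns_empty(self):
        rec = _burst_recording([], seconds=60.0)
        with pytest.warns(UserWarning):
            assert ss.detect_spindles(rec, np.array([]), "C3") == []

    def test_duration_invariants_on_random_signals(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            spec = sorted((rng.uniform(5, 110), rng.uniform(0.4, 1.4)) for _ in range(4))
            rec = _burst_recording(spec, burst_amp=rng.uniform(80, 150), seed=seed)
            for ev in ss.detect_spindles(rec, np.arange(4), "C3"):
                assert 0.3 <= ev.duration <= 3.0
                assert ev.start <= ev.peak_time <= ev.end
                assert ev.frequency_class in ("slow", "fast")


class TestSODetection:
    def test_1hz_sinusoid_one_per_cycle(self):
        rec = sinusoid_recording(1.0, fs=128.0, seconds=120)
        events = ss.detect_slow_oscillations(rec, np.arange(4), "C3")
        assert len(events) >= 100
        durs = np.array([e.duration for e in events])
        assert np.allclose(durs, 1.0, atol=0.02)

    def test_3hz_too_short(self):
        rec = sinusoid_recording(3.0, fs=128.0, seconds=120)
        assert ss.detect_slow_oscillations(rec, np.arange(4), "C3") == []

    def test_0p4hz_too_long(self):
        rec = sinusoid_recording(0.4, fs=128.0, seconds=120)
        assert ss.detect_slow_oscillations(rec, np.arange(4), "C3") == []

    def test_restricted_to_n2(self):
        rec = sinusoid_recording(1.0, fs=128.0, seconds=120)
        ev_all = ss.detect_slow_oscillations(rec, np.arange(4), "C3")
        ev_half = ss.detect_slow_oscillations(rec, np.arange(2), "C3")
        assert 0 < len(ev_half) < len(ev_all)
        assert all(e.end <= 60.0 for e in ev_half)


class TestPhase:
    def _spindle(self, peak):
        return SpindleEvent(channel="C3", start=peak - 0.3, end=peak + 0.3,
                            peak_time=peak, frequency=13.5, frequency_class="fast")

    def test_peak_at_start(self):
        so = SOEvent(channel="C3", start=10.0, end=11.0)
        assert ss.so_phase_at_peak(self._spindle(10.0), so) == 0.0

    def test_peak_at_midpoint(self):
        so = SOEvent(channel="C3", start=10.0, end=11.6)
        assert ss.so_phase_at_peak(self._spindle(10.8), so) == pytest.approx(180.0)

    def test_peak_at_quarter(self):
        so = SOEvent(channel="C3", start=10.0, end=12.0)
        assert ss.so_phase_at_peak(self._spindle(10.5), so) == pytest.approx(90.0)

    def test_peak_outside_raises(self):
        so = SOEvent(channel="C3", start=10.0, end=11.0)
        with pytest.raises(ValueError):
            ss.so_phase_at_peak(self._spindle(12.0), so)


class TestFeatureSet:
    def test_one_spindle_per_epoch(self):
        n2 = np.arange(10)
        spindles = [
            SpindleEvent("C3", 30.0 * e + 10, 30.0 * e + 11, 30.0 * e + 10.5,
                         13.5, "fast")
            for e in n2
        ]
        feats = ss.spindle_feature_set({"C3": spindles}, {"C3": []}, n2)
        assert feats.density["C3"] == pytest.approx(2.0)
        assert feats.dispersion["C3"] == pytest.approx(0.0)

    def test_poisson_counts_fano_near_one(self):
        rng = np.random.default_rng(3)
        n2 = np.arange(500)
        spindles = []
        for e in n2:
            for k in range(rng.poisson(1.5)):
                t = 30.0 * e + 1.0 + k
                spindles.append(SpindleEvent("C3", t, t + 0.5, t + 0.25, 13.5, "fast"))
        feats = ss.spindle_feature_set({"C3": spindles}, {"C3": []}, n2)
        assert abs(feats.dispersion["C3"] - 1.0) < 0.15

    def test_zero_spindles(self):
        feats = ss.spindle_feature_set({"C3": []}, {"C3": []}, np.arange(5))
        assert feats.density["C3"] == 0.0
        assert feats.dispersion["C3"] is None
        assert feats.phase_fast["C3"] is None

    def test_planted_coupling_phase_recovered(self, small_recording, preprocessed,
                                              small_hypnogram):
        _, truth = small_recording
        prepared = ss.prepare_signal(preprocessed)
        rejected = ss.delta_artifact_epoch_mask(prepared, small_hypnogram)
        n2 = ss.accepted_n2_epochs(small_hypnogram, rejected)
        spindles = {"C3": ss.detect_spindles(prepared, n2, "C3")}
        sos = {"C3": ss.detect_slow_oscillations(prepared, n2, "C3")}
        feats = ss.spindle_feature_set(spindles, sos, n2)
        phases = [v for v in (feats.phase_fast["C3"], feats.phase_slow["C3"]) if v is not None]
        assert phases, "no coupled spindles found"
        # planted coupling phase is 180 degrees
        assert min(abs(p - 180.0) for p in phases) < 30.0


def test_recall_precision_on_synthetic_n2(small_recording, preprocessed, small_hypnogram):
    _, truth = small_recording
    prepared = ss.prepare_signal(preprocessed)
    rejected = ss.delta_artifact_epoch_mask(prepared, small_hypnogram)
    n2 = ss.accepted_n2_epochs(small_hypnogram, rejected)
    events = ss.detect_spindles(prepared, n2, "C3")
    planted = truth.spindles
    hits = sum(
        any(_overlap_frac(ev.start, ev.end, s, e) >= 0.5 for ev in events)
        for s, e, _ in planted
    )
    tp = sum(
        any(_overlap_frac(s, e, ev.start, ev.end) >= 0.5
            or _overlap_frac(ev.start, ev.end, s, e) >= 0.5 for s, e, _ in planted)
        for ev in events
    )
    assert hits / len(planted) >= 0.9
    assert tp / len(events) >= 0.9
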