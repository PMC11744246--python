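"""Spindle and slow-oscillation detection in N2 plus the 8-feature set.

Detection follows the wavelet-thresholding convention: a 13.5 Hz Morlet
convolution, magnitude smoothed over 0.1 s, a core threshold of 4.5x
the mean over accepted N2 and a 2x flank criterion, merging of
candidates closer than 0.5 s and rejection of events longer than 3 s.
Slow oscillations are intervals between consecutive positive-to-negative
zero-crossings of the 4.5 Hz low-passed signal lasting 0.8-2 s.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import lowpass_filter, resample_to_target
from .types import EEGRecording, Hypnogram, SOEvent, SpindleEvent

SPINDLE_FREQ = 13.5
SPINDLE_RATE = 128.0
WAVELET_CYCLES = 7.0
CORE_THRESHOLD = 4.5
FLANK_THRESHOLD = 2.0
CORE_MIN_SECONDS = 0.3
FLANK_SECONDS = 0.5
MERGE_GAP_SECONDS = 0.5
MAX_SPINDLE_SECONDS = 3.0
SO_LOWPASS = 4.5
SO_MIN_SECONDS = 0.8
SO_MAX_SECONDS = 2.0
DELTA_REJECT_FACTOR = 2.5
DELTA_WINDOW_EPOCHS = 15


@dataclass
class SpindleFeatureSet:
    """Per-channel density, dispersion and SO-phase features (8 values)."""

    density: dict[str, float]
    dispersion: dict[str, float | None]
    phase_fast: dict[str, float | None]
    phase_slow: dict[str, float | None]

    def as_dict(self) -> dict[str, float | None]:
        out = {}
        for ch in self.density:
            out[f"density_{ch}"] = self.density[ch]
            out[f"dispersion_{ch}"] = self.dispersion[ch]
            out[f"so_phase_fast_{ch}"] = self.phase_fast[ch]
            out[f"so_phase_slow_{ch}"] = self.phase_slow[ch]
        return out


def prepare_signal(recording: EEGRecording) -> EEGRecording:
    """Resample to 128 Hz and low-pass at 35 Hz (high-pass carried over)."""
    rec = resample_to_target(recording, SPINDLE_RATE)
    return lowpass_filter(rec, cutoff=35.0, transition_width=8.0)


def _epoch_band_power(x: np.ndarray, fs: float, n_epochs: int, epoch_seconds: float,
                      lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    per = int(round(epoch_seconds * fs))
    usable = min(n_epochs, len(filt) // per)
    power = np.full(n_epochs, np.nan)
    power[:usable] = (filt[: usable * per].reshape(usable, per) ** 2).mean(axis=1)
    return power


def delta_artifact_epoch_mask(prepared: EEGRecording, hyp: Hypnogram,
                              channel: str | None = None) -> np.ndarray:
    """True where an epoch's delta power exceeds 2.5x its local 15-epoch mean.

    The comparison window is centered and truncated at record edges.
    When ``channel`` is None the epoch is rejected if any channel trips
    the criterion.
    """
    n = len(hyp)
    channels = [channel] if channel else list(prepared.channels)
    rejected = np.zeros(n, dtype=bool)
    half = DELTA_WINDOW_EPOCHS // 2
    for ch in channels:
        power = _epoch_band_power(prepared.channels[ch], prepared.sample_rate, n,
                                  hyp.epoch_seconds, 0.5, 4.0)
        for e in range(n):
            lo, hi = max(0, e - half), min(n, e + half + 1)
            local = np.nanmean(power[lo:hi])
            if np.isfinite(power[e]) and power[e] > DELTA_REJECT_FACTOR * local:
                rejected[e] = True
    return rejected


def accepted_n2_epochs(hyp: Hypnogram, rejected: np.ndarray | None = None) -> np.ndarray:
    """Indices of N2 epochs surviving delta-artifact rejection."""
    n2 = np.flatnonzero(hyp.stages == "N2")
    if rejected is None:
        return n2
    return n2[~rejected[n2]]


def _sample_mask_for_epochs(epochs: np.ndarray, n_samples: int, fs: float,
                            epoch_seconds: float) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    per = int(round(epoch_seconds * fs))
    for e in epochs:
        mask[e * per : min((e + 1) * per, n_samples)] = True
    return mask


def morlet_magnitude(x: np.ndarray, fs: float, freq: float = SPINDLE_FREQ,
                     n_cycles: float = WAVELET_CYCLES,
                     smooth_seconds: float = 0.1) -> np.ndarray:
    """|Morlet wavelet convolution| smoothed with a moving average."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    t = np.arange(-4 * sigma_t, 4 * sigma_t + 1.0 / fs, 1.0 / fs)
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2))
    mag = np.abs(signal.fftconvolve(x, kernel, mode="same"))
    w = max(int(round(smooth_seconds * fs)), 1)
    return signal.fftconvolve(mag, np.ones(w) / w, mode="same")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    return list(zip(starts.tolist(), stops.tolist()))


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    n = max(len(x), int(4 * fs))  # zero-pad for resolution
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.abs(np.fft.rfft(x * signal.windows.hann(len(x)), n=n))
    sel = (freqs >= 11.0) & (freqs <= 15.0)
    if not sel.any() or spec[sel].max() == 0:
        return SPINDLE_FREQ
    return float(freqs[sel][np.argmax(spec[sel])])


def detect_spindles(
    prepared: EEGRecording,
    n2_epochs: np.ndarray,
    channel: str,
    epoch_seconds: float = 30.0,
    core_threshold: float = CORE_THRESHOLD,
    flank_threshold: float = FLANK_THRESHOLD,
    wavelet_cycles: float = WAVELET_CYCLES,
    flank_mode: str = "mean",
) -> list[SpindleEvent]:
    """Detect spindles on one channel within accepted N2 epochs.

    ``flank_mode`` controls the secondary 2x criterion over the 0.5-s
    surround of a core: "mean" (default) requires the average smoothed
    magnitude there to clear the threshold; "min" requires every sample
    to, which is stricter than any plausible signal can satisfy and is
    kept only for sensitivity analyses.
    """
    fs = prepared.sample_rate
    x = prepared.channels[channel]
    if len(n2_epochs) == 0:
        warnings.warn("no accepted N2 epochs; returning no spindles", stacklevel=2)
        return []
    smoothed = morlet_magnitude(x, fs, n_cycles=wavelet_cycles)
    n2_mask = _sample_mask_for_epochs(np.asarray(n2_epochs), len(x), fs, epoch_seconds)
    baseline = smoothed[n2_mask].mean()

    above = (smoothed > core_threshold * baseline) & n2_mask
    min_core = int(round(CORE_MIN_SECONDS * fs))
    flank = int(round(FLANK_SECONDS * fs))
    candidates = []
    for start, stop in _runs(above):
        if stop - start < min_core:
            continue
        lo = max(0, start - flank)
        hi = min(len(x), stop + flank)
        stat = smoothed[lo:hi].mean() if flank_mode == "mean" else smoothed[lo:hi].min()
        if stat <= flank_threshold * baseline:
            continue
        # event extent: grow the core outward while the smoothed magnitude
        # stays above the secondary 2x threshold
        lo2 = start
        while lo2 > 0 and smoothed[lo2 - 1] > flank_threshold * baseline:
            lo2 -= 1
        hi2 = stop
        while hi2 < len(x) and smoothed[hi2] > flank_threshold * baseline:
            hi2 += 1
        candidates.append((lo2, hi2))

    merged: list[list[int]] = []
    gap = int(round(MERGE_GAP_SECONDS * fs))
    for start, stop in candidates:
        if merged and start - merged[-1][1] < gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    events = []
    for start, stop in merged:
        dur = (stop - start) / fs
        if dur > MAX_SPINDLE_SECONDS or dur < CORE_MIN_SECONDS:
            continue
        peak = start + int(np.argmax(smoothed[start:stop]))
        freq = _dominant_frequency(x[start:stop], fs)
        events.append(
            SpindleEvent(
                channel=channel,
                start=start / fs,
                end=stop / fs,
                peak_time=peak / fs,
                frequency=freq,
                frequency_class="fast" if freq >= 13.0 else "slow",
            )
        )
    return events


def detect_slow_oscillations(
    prepared: EEGRecording, n2_epochs: np.ndarray, channel: str,
    epoch_seconds: float = 30.0,
) -> list[SOEvent]:
    """Slow oscillations: positive-to-negative zero-crossing intervals of 0.8-2 s.

    Crossings are extracted from the 4.5 Hz low-passed full signal;
    events fully inside accepted N2 epochs are retained.
    """
    fs = prepared.sample_rate
    x = prepared.channels[channel]
    taps_rec = lowpass_filter(
        prepared.copy_with(channels={channel: x}), cutoff=SO_LOWPASS, transition_width=2.0
    )
    low = taps_rec.channels[channel]
    pos = low > 0
    p2n = np.flatnonzero(pos[:-1] & ~pos[1:])  # index i: crossing in (i, i+1]
    # linear interpolation for sub-sample crossing times
    times = (p2n + low[p2n] / (low[p2n] - low[p2n + 1])) / fs
    n2_mask = _sample_mask_for_epochs(np.asarray(n2_epochs), len(x), fs, epoch_seconds)
    events = []
    for t0, t1 in zip(times[:-1], times[1:]):
        dur = t1 - t0
        if not (SO_MIN_SECONDS <= dur <= SO_MAX_SECONDS):
            continue
        i0, i1 = int(t0 * fs), min(int(t1 * fs) + 1, len(x))
        if n2_mask[i0:i1].all():
            events.append(SOEvent(channel=channel, start=float(t0), end=float(t1)))
    return events


def so_phase_at_peak(spindle: SpindleEvent, so: SOEvent) -> float:
    """Peak position inside the SO mapped linearly to [0, 360) degrees."""
    if not (so.start <= spindle.peak_time <= so.end):
        raise ValueError("spindle peak outside the slow oscillation")
    return 360.0 * (spindle.peak_time - so.start) / (so.end - so.start)


def _circular_mean_deg(angles: np.ndarray) -> float:
    rad = np.deg2rad(angles)
    mean = np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())
    return float(np.rad2deg(mean) % 360.0)


def _pair_phases(spindles: list[SpindleEvent], sos: list[SOEvent]) -> list[tuple[SpindleEvent, float]]:
    pairs = []
    for sp in spindles:
        for so in sos:
            if so.start <= sp.peak_time <= so.end:
                pairs.append((sp, so_phase_at_peak(sp, so)))
                break
    return pairs


def spindle_feature_set(
    spindles_per_channel: dict[str, list[SpindleEvent]],
    sos_per_channel: dict[str, list[SOEvent]],
    n2_epochs: np.ndarray,
    epoch_seconds: float = 30.0,
) -> SpindleFeatureSet:
    """Density, dispersion and circular-mean SO phase (fast/slow) per channel."""
    n2_minutes = len(n2_epochs) * epoch_seconds / 60.0
    density, dispersion, phase_fast, phase_slow = {}, {}, {}, {}
    epoch_starts = {int(e): i for i, e in enumerate(np.asarray(n2_epochs))}
    for ch, spindles in spindles_per_channel.items():
        density[ch] = len(spindles) / n2_minutes if n2_minutes > 0 else 0.0
        counts = np.zeros(len(n2_epochs))
        for sp in spindles:
            e = int(sp.start // epoch_seconds)
            if e in epoch_starts:
                counts[epoch_starts[e]] += 1
        if len(spindles) == 0 or counts.mean() == 0:
            dispersion[ch] = None
        else:
            dispersion[ch] = float(counts.var(ddof=1) / counts.mean()) if len(counts) > 1 else 0.0
        pairs = _pair_phases(spindles, sos_per_channel.get(ch, []))
        fast = np.array([ph for sp, ph in pairs if sp.frequency_class == "fast"])
        slow = np.array([ph for sp, ph in pairs if sp.frequency_class == "slow"])
        phase_fast[ch] = _circular_mean_deg(fast) if len(fast) else None
        phase_slow[ch] = _circular_mean_deg(slow) if len(slow) else None
    return SpindleFeatureSet(
        density=density, dispersion=dispersion, phase_fast=phase_fast, phase_slow=phase_slow
    )
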