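"""Recording harmonization and RMS artifact masking.

The public pipeline entry point :func:`preprocess_recording` applies, in
fixed order: contralateral mastoid re-referencing, polyphase resampling
to 200 Hz, a zero-phase 0.5 Hz high-pass, and a zero-phase 50 Hz
low-pass band limit.  All downstream modules consume its output.
"""
from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .edfio import read_edf
from .types import ArtifactMask, EEGRecording, Hypnogram, STAGES, UnusableRecordingError

REQUIRED_CHANNELS = ("C3", "C4", "M1", "M2")
TARGET_RATE = 200.0
HP_CUTOFF = 0.5
LP_CUTOFF = 50.0


def read_recording(path, annotation_path) -> tuple[EEGRecording, Hypnogram]:
    """Load an EDF recording and its 30-s stage annotations.

    The annotation file is CSV with a ``stage`` column (optionally an
    ``epoch_index`` column, which must be 0..n-1 in order) or one stage
    label per line.
    """
    rec = read_edf(path)
    missing = [c for c in REQUIRED_CHANNELS if c not in rec.channels]
    if missing:
        raise UnusableRecordingError([f"missing channel {c}" for c in missing])
    hyp = read_hypnogram(annotation_path)
    return rec, hyp


def read_hypnogram(path) -> Hypnogram:
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if "," in text[0] or text[0].strip().lower() in ("stage", "epoch_index"):
        df = pd.read_csv(path)
        if "stage" not in df.columns:
            raise ValueError("hypnogram CSV needs a 'stage' column")
        if "epoch_index" in df.columns:
            df = df.sort_values("epoch_index")
            if not np.array_equal(df["epoch_index"].to_numpy(), np.arange(len(df))):
                raise ValueError("epoch_index must be contiguous from 0")
        stages = df["stage"].astype(str).str.strip().to_numpy()
    else:
        stages = np.array([line.strip() for line in text])
    bad = sorted(set(stages.tolist()) - set(STAGES))
    if bad:
        raise ValueError(f"invalid stage labels in {path.name}: {bad}")
    return Hypnogram(stages=stages)


def rereference_contralateral(recording: EEGRecording) -> EEGRecording:
    """Return C3-M2 and C4-M1 derivations; mastoids are dropped."""
    missing = []
    for need in ("C3", "M2", "C4", "M1"):
        if need not in recording.channels:
            missing.append(f"missing channel {need}")
    if missing:
        raise UnusableRecordingError(missing)
    return recording.copy_with(
        channels={
            "C3": recording.channels["C3"] - recording.channels["M2"],
            "C4": recording.channels["C4"] - recording.channels["M1"],
        }
    )


def resample_to_target(recording: EEGRecording, target: float = TARGET_RATE) -> EEGRecording:
    """Polyphase resample to ``target`` Hz (Kaiser-window FIR low-pass).

    Up-sampling cannot introduce content above the original Nyquist:
    the polyphase filter cuts at the lower of the two Nyquists.
    """
    if target <= 0:
        raise ValueError("target rate must be positive")
    fs = recording.sample_rate
    if abs(fs - target) < 1e-9:
        return recording
    frac = Fraction(target / fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    channels = {
        k: signal.resample_poly(v, up, down, window=("kaiser", 5.0))
        for k, v in recording.channels.items()
    }
    return recording.copy_with(channels=channels, sample_rate=target)


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # linear-phase FIR applied via 'same' convolution == zero phase
    return signal.fftconvolve(x, taps, mode="same")


def _fir_taps(fs: float, cutoff: float, width: float, pass_zero: bool) -> np.ndarray:
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    return signal.firwin(numtaps, cutoff, width=None, pass_zero=pass_zero, fs=fs)


def highpass_filter(
    recording: EEGRecording, cutoff: float = HP_CUTOFF, transition_width: float | None = None
) -> EEGRecording:
    """Zero-phase FIR high-pass (default 0.5 Hz).

    The transition width defaults to ``cutoff`` Hz which gives >= 50 dB
    attenuation below ``cutoff/2`` and unity gain (within 1 dB) above
    ``2 * cutoff``.
    """
    fs = recording.sample_rate
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie below Nyquist")
    width = transition_width if transition_width is not None else cutoff
    taps = _fir_taps(fs, cutoff, width, pass_zero=False)
    channels = {k: _zero_phase_fir(v, taps) for k, v in recording.channels.items()}
    return recording.copy_with(channels=channels)


def lowpass_filter(
    recording: EEGRecording, cutoff: float = LP_CUTOFF, transition_width: float = 8.0
) -> EEGRecording:
    """Zero-phase FIR low-pass used for the 50 Hz band limit."""
    fs = recording.sample_rate
    if not 0 < cutoff:
        raise ValueError("cutoff must be positive")
    if cutoff >= fs / 2:
        return recording  # nothing above Nyquist to remove
    taps = _fir_taps(fs, cutoff, transition_width, pass_zero=True)
    channels = {k: _zero_phase_fir(v, taps) for k, v in recording.channels.items()}
    return recording.copy_with(channels=channels)


def preprocess_recording(
    recording: EEGRecording,
    target_rate: float = TARGET_RATE,
    hp_cutoff: float = HP_CUTOFF,
    lp_cutoff: float = LP_CUTOFF,
) -> EEGRecording:
    """Fixed-order harmonization: re-reference -> resample -> high-pass -> band limit."""
    rec = rereference_contralateral(recording)
    rec = resample_to_target(rec, target_rate)
    rec = highpass_filter(rec, hp_cutoff)
    rec = lowpass_filter(rec, lp_cutoff)
    return rec


def rms_artifact_mask(
    recording: EEGRecording,
    segment_seconds: float = 3.0,
    low: float = 1.0,
    high: float = 250.0,
) -> ArtifactMask:
    """Flag 3-s segments whose RMS amplitude is <= ``low`` or >= ``high`` uV.

    The segment grid is anchored at lights-off; a partial trailing
    segment is dropped.  Masking depends only on the signal.
    """
    fs = recording.sample_rate
    seg = int(round(segment_seconds * fs))
    start = int(round(recording.lights_off * fs))
    n_seg = (recording.n_samples - start) // seg
    if n_seg < 1:
        raise ValueError("recording shorter than one segment")
    flags = {}
    for name, x in recording.channels.items():
        chunk = x[start : start + n_seg * seg].reshape(n_seg, seg)
        rms = np.sqrt(np.mean(chunk**2, axis=1))
        flags[name] = (rms <= low) | (rms >= high)
    return ArtifactMask(flags=flags, segment_seconds=segment_seconds, anchor=recording.lights_off)
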