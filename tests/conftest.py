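"""Shared fixtures: small synthetic recordings generated at test time."""
from __future__ import annotations

import numpy as np
import pytest

from sleepscope import preprocess as pp
from sleepscope import synthetic_cohort as sc
from sleepscope.types import EEGRecording, Hypnogram


@pytest.fixture(scope="session")
def small_hypnogram() -> Hypnogram:
    """20-minute hypnogram containing all five stages."""
    stages = (
        ["W"] * 4 + ["N1"] * 4 + ["N2"] * 14 + ["N3"] * 8 + ["N2"] * 4 + ["R"] * 6
    )
    return Hypnogram(stages=np.array(stages))


@pytest.fixture(scope="session")
def small_recording(small_hypnogram):
    """Synthetic raw recording (C3/C4/M1/M2 at 200 Hz) plus ground truth."""
    rec, truth = sc.synthesize_recording(
        small_hypnogram, spindle_density=2.0, so_rate=3.0, seed=42
    )
    return rec, truth


@pytest.fixture(scope="session")
def preprocessed(small_recording):
    rec, _ = small_recording
    return pp.preprocess_recording(rec)


def sinusoid_recording(freq: float, fs: float = 200.0, seconds: float = 60.0,
                       amplitude: float = 50.0) -> EEGRecording:
    t = np.arange(int(seconds * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return EEGRecording(channels={"C3": x.copy(), "C4": x.copy()}, sample_rate=fs)
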