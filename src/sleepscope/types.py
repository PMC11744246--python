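"""Core domain types shared across the pipeline.

Stage order is fixed as (W, N1, N2, N3, R) for every matrix and feature
vector in the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical stage order used by every matrix/feature in the package.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Frequency bands (Hz); half-open intervals [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta")

EPOCH_SECONDS: float = 30.0


class UnusableRecordingError(ValueError):
    """A recording cannot enter the pipeline (missing/duplicate/corrupt channels)."""

    def __init__(self, reasons):
        if isinstance(reasons, str):
            reasons = [reasons]
        self.reasons = list(reasons)
        super().__init__("unusable recording: " + "; ".join(self.reasons))


@dataclass
class Hypnogram:
    """30-s AASM stage sequence with a lights-off/lights-on window.

    Parameters
    ----------
    stages : sequence of str
        One label per 30-s epoch, each in ``STAGES``.
    lights_off_epoch, lights_on_epoch : int
        Window bounds as epoch indices; analysis is restricted to
        ``[lights_off_epoch, lights_on_epoch)``.  Defaults cover the
        whole hypnogram.
    """

    stages: np.ndarray
    epoch_seconds: float = EPOCH_SECONDS
    lights_off_epoch: int = 0
    lights_on_epoch: int | None = None

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype="U2")
        if self.stages.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = sorted(set(self.stages.tolist()) - set(STAGES))
        if bad:
            raise ValueError(f"invalid stage labels: {bad}")
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError("epoch length is fixed at 30 s")
        if self.lights_on_epoch is None:
            self.lights_on_epoch = len(self.stages)
        if not (0 <= self.lights_off_epoch < self.lights_on_epoch <= len(self.stages)):
            raise ValueError("invalid lights-off/lights-on window")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def window_stages(self) -> np.ndarray:
        """Stages within the lights-off -> lights-on window."""
        return self.stages[self.lights_off_epoch : self.lights_on_epoch]

    @property
    def n_window_epochs(self) -> int:
        return self.lights_on_epoch - self.lights_off_epoch

    def codes(self) -> np.ndarray:
        """Integer stage codes (W=0 ... R=4) for the full hypnogram."""
        return np.array([STAGE_INDEX[s] for s in self.stages], dtype=np.int64)

    def epoch_of_time(self, t: float) -> int:
        """Epoch index containing time ``t`` (seconds from recording start)."""
        return int(t // self.epoch_seconds)


@dataclass
class EEGRecording:
    """Multichannel EEG time series in microvolts.

    ``lights_off``/``lights_on`` are seconds from recording start; they
    default to the full extent of the recording.
    """

    channels: dict[str, np.ndarray]
    sample_rate: float
    lights_off: float = 0.0
    lights_on: float | None = None
    start_time: str = "00.00.00"

    def __post_init__(self):
        if not self.channels:
            raise ValueError("recording has no channels")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}
        if self.lights_on is None:
            self.lights_on = self.duration
        if not (0 <= self.lights_off < self.lights_on <= self.duration + 1e-9):
            raise ValueError("lights window must lie within the recording")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def copy_with(self, channels=None, sample_rate=None) -> "EEGRecording":
        return EEGRecording(
            channels={k: v.copy() for k, v in (channels or self.channels).items()},
            sample_rate=sample_rate or self.sample_rate,
            lights_off=self.lights_off,
            lights_on=self.lights_on,
            start_time=self.start_time,
        )


@dataclass
class SpindleEvent:
    """A detected spindle: times in seconds from recording start."""

    channel: str
    start: float
    end: float
    peak_time: float
    frequency: float
    frequency_class: str  # "slow" (11-<13 Hz) or "fast" (>=13-15 Hz)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SOEvent:
    """A slow oscillation delimited by positive-to-negative zero-crossings."""

    channel: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str  # "female" | "male"
    group: str  # "insomnia" | "non-insomnia"
    site: str

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"invalid sex: {self.sex}")
        if self.group not in ("insomnia", "non-insomnia"):
            raise ValueError(f"invalid group: {self.group}")


@dataclass
class ArtifactMask:
    """Per-channel boolean flags over consecutive fixed-length segments.

    ``flags[channel][i]`` is True when segment ``i`` (anchored at
    ``anchor`` seconds, length ``segment_seconds``) is artefactual.
    """

    flags: dict[str, np.ndarray]
    segment_seconds: float
    anchor: float = 0.0

    @property
    def n_segments(self) -> int:
        return len(next(iter(self.flags.values())))

    def combined(self) -> np.ndarray:
        """Segment flagged on any channel."""
        out = np.zeros(self.n_segments, dtype=bool)
        for v in self.flags.values():
            out |= v
        return out

    def fraction_flagged(self) -> float:
        return float(self.combined().mean()) if self.n_segments else 0.0

    def overlaps_artifact(self, t0: float, t1: float, channel: str | None = None) -> bool:
        """True if [t0, t1) overlaps a flagged segment (any channel by default)."""
        flags = self.combined() if channel is None else self.flags[channel]
        first = int(np.floor((t0 - self.anchor) / self.segment_seconds))
        last = int(np.ceil((t1 - self.anchor) / self.segment_seconds))
        first = max(first, 0)
        last = min(last, self.n_segments)
        if first >= last:
            return False
        return bool(flags[first:last].any())


@dataclass
class GroundTruth:
    """Planted structure of one synthetic recording (oracle for detectors)."""

    transition_matrix: np.ndarray | None = None
    spindles: list[tuple[float, float, float]] = field(default_factory=list)  # start, end, peak
    slow_oscillations: list[tuple[float, float]] = field(default_factory=list)  # start, end
    stage_band_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
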