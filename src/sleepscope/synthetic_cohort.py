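"""Synthetic PSG cohort generator.

Produces Markov-chain hypnograms with group-dependent transition
matrices, two-channel EEG whose per-stage relative band powers follow
requested fractions (band-limited Gaussian noise mixtures), N2 spindle
bursts coupled to planted slow oscillations, artifact segments, and
subject metadata with configurable group effects.  Everything is
deterministic given the seed; ground truth for every planted event is
returned for detector oracles.

The generative model is artifact-internal: it exists to exercise the
analysis with known structure, not to mimic physiological morphology.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .types import (
    BAND_NAMES,
    BANDS,
    EEGRecording,
    GroundTruth,
    Hypnogram,
    STAGE_INDEX,
    STAGES,
    SubjectRecord,
)

#: Baseline (control) transition matrix, canonical stage order.
CONTROL_TRANSITIONS = np.array(
    [
        [0.70, 0.15, 0.10, 0.02, 0.03],  # W
        [0.12, 0.45, 0.35, 0.03, 0.05],  # N1
        [0.04, 0.05, 0.78, 0.08, 0.05],  # N2
        [0.02, 0.02, 0.15, 0.78, 0.03],  # N3
        [0.05, 0.05, 0.05, 0.01, 0.84],  # R
    ]
)

#: Baseline per-stage band-power fractions (delta, theta, alpha, beta).
CONTROL_STAGE_SPECTRA = {
    "W": {"delta": 0.45, "theta": 0.17, "alpha": 0.17, "beta": 0.21},
    "N1": {"delta": 0.48, "theta": 0.24, "alpha": 0.14, "beta": 0.14},
    "N2": {"delta": 0.55, "theta": 0.20, "alpha": 0.12, "beta": 0.13},
    "N3": {"delta": 0.78, "theta": 0.11, "alpha": 0.06, "beta": 0.05},
    "R": {"delta": 0.45, "theta": 0.25, "alpha": 0.15, "beta": 0.15},
}

DEFAULT_EFFECTS = {
    "wake_transition": 0.05,   # absolute increase of every stage->W probability
    "wake_alpha": 0.03,        # absolute relative-alpha shift in W and N1
    "spindle_density": -0.5,   # per-minute deficit
}

SPINDLE_BURST_FREQ = 13.5
BACKGROUND_RMS = 30.0  # uV, inside the physiological RMS range


@dataclass
class CohortConfig:
    n_insomnia: int = 10
    n_control: int = 10
    recording_minutes: float = 30.0
    sample_rate: float = 200.0
    seed: int = 0
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    n_sites: int = 2
    spindle_density: float = 2.0       # per minute, control baseline
    so_rate: float = 3.0               # per minute of N2
    coupling_phase: float = 180.0      # degrees within the SO
    with_eeg: bool = True
    age_mean_insomnia: float = 56.0
    age_mean_control: float = 50.0
    age_sd: float = 14.0
    female_fraction_insomnia: float = 0.66
    female_fraction_control: float = 0.50

    def __post_init__(self):
        if self.n_insomnia < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        if self.sample_rate < 100:
            raise ValueError("sample_rate must be >= 100 Hz")
        n_epochs = self.recording_minutes * 60.0 / 30.0
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ValueError("duration must be a whole number of 30-s epochs")

    @property
    def n_epochs(self) -> int:
        return int(round(self.recording_minutes * 2))


def generate_hypnogram(transition_matrix: np.ndarray, n_epochs: int, seed: int) -> Hypnogram:
    """First-order Markov chain over the five stages, starting in W."""
    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (5, 5) or np.any(P < -1e-12):
        raise ValueError("transition matrix must be 5x5 and non-negative")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each transition-matrix row must sum to 1")
    if n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = STAGE_INDEX["W"]
    u = rng.random(n_epochs - 1)
    for i in range(1, n_epochs):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1], side="right")
    return Hypnogram(stages=np.array(STAGES)[np.minimum(states, 4)])


def _band_limited_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    nyq = fs / 2
    hi = min(hi, nyq * 0.98)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _spindle_burst(duration: float, fs: float, peak_frac: float = 0.5) -> np.ndarray:
    """13.5 Hz burst with a Hann envelope; peak at ``peak_frac`` of duration."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = signal.windows.hann(n)
    return np.sin(2 * np.pi * SPINDLE_BURST_FREQ * t) * env


def synthesize_recording(
    hypnogram: Hypnogram,
    stage_spectra: dict[str, dict[str, float]] | None = None,
    spindle_density: float = 2.0,
    so_rate: float = 3.0,
    coupling_phase: float = 180.0,
    sample_rate: float = 200.0,
    seed: int = 0,
    background_rms: float = BACKGROUND_RMS,
    spindle_amplitude: float | None = None,
    so_amplitude: float = 60.0,
) -> tuple[EEGRecording, GroundTruth]:
    """Render a hypnogram into two-channel EEG plus mastoid references.

    Each epoch mixes four unit-variance band-limited noise carriers with
    weights ``sqrt(fraction)`` so expected relative band powers match
    ``stage_spectra``.  N2 epochs receive 13.5 Hz bursts (0.5-1.5 s) at
    ``spindle_density`` per minute whose peaks sit at ``coupling_phase``
    degrees inside co-planted slow-oscillation half-waves; every planted
    event is listed in the returned ground truth.
    """
    if len(hypnogram) == 0:
        raise ValueError("zero-length hypnogram")
    if spindle_density < 0 or so_rate < 0:
        raise ValueError("rates must be >= 0")
    spectra = stage_spectra or CONTROL_STAGE_SPECTRA
    for st, fr in spectra.items():
        if abs(sum(fr[b] for b in BAND_NAMES) - 1.0) > 1e-6:
            raise ValueError(f"band fractions for stage {st} must sum to 1")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    per = int(round(hypnogram.epoch_seconds * fs))
    n = per * len(hypnogram)

    carriers = np.stack(
        [_band_limited_noise(n, fs, *BANDS[b], rng) for b in BAND_NAMES]
    )
    weights = np.empty((len(BAND_NAMES), n))
    for e, st in enumerate(hypnogram.stages):
        fr = spectra[st]
        for b, name in enumerate(BAND_NAMES):
            weights[b, e * per : (e + 1) * per] = np.sqrt(fr[name])
    base = (carriers * weights).sum(axis=0)
    base *= background_rms / base.std()

    amp = spindle_amplitude if spindle_amplitude is not None else 5.0 * background_rms
    truth = GroundTruth(stage_band_fractions=spectra)
    events = np.zeros(n)
    n2_epochs = np.flatnonzero(hypnogram.stages == "N2")
    p_spindle = spindle_density * 0.5  # expected spindles per 30-s epoch
    p_so = so_rate * 0.5
    for e in n2_epochs:
        t0 = e * hypnogram.epoch_seconds
        n_so = rng.poisson(p_so)
        n_sp = rng.poisson(p_spindle)
        placed_so = []
        # plant SOs first, spindles coupled into as many SOs as available
        cursor = t0 + 0.3
        for _ in range(n_so):
            dur = rng.uniform(0.9, 1.5)
            if cursor + dur > t0 + hypnogram.epoch_seconds - 0.3:
                break
            start = cursor
            end = start + dur
            idx = slice(int(start * fs), int(end * fs))
            tt = np.arange(int(start * fs), int(end * fs)) / fs - start
            # one full -sin cycle: positive-to-negative crossings at both ends
            events[idx] += -so_amplitude * np.sin(2 * np.pi * tt / dur)
            placed_so.append((start, end))
            truth.slow_oscillations.append((start, end))
            cursor = end + rng.uniform(0.5, 2.0)
        for k in range(n_sp):
            dur = rng.uniform(0.5, 1.5)
            if k < len(placed_so):
                so_start, so_end = placed_so[k]
                peak = so_start + (coupling_phase / 360.0) * (so_end - so_start)
                start = peak - dur / 2
            else:
                start = t0 + rng.uniform(0.3, hypnogram.epoch_seconds - dur - 0.3)
                peak = start + dur / 2
            if start < t0 or start + dur > t0 + hypnogram.epoch_seconds:
                continue
            i0 = int(round(start * fs))
            burst = amp * _spindle_burst(dur, fs)
            if i0 + len(burst) > n:
                continue
            events[i0 : i0 + len(burst)] += burst
            truth.spindles.append((start, start + len(burst) / fs, peak))

    clean = base + events
    # mastoids carry small independent noise so re-referencing is non-trivial
    m1 = 2.0 * _band_limited_noise(n, fs, 0.5, 30.0, rng)
    m2 = 2.0 * _band_limited_noise(n, fs, 0.5, 30.0, rng)
    c3 = clean + 0.5 * _band_limited_noise(n, fs, 0.5, 45.0, rng) + m2
    c4 = clean + 0.5 * _band_limited_noise(n, fs, 0.5, 45.0, rng) + m1
    rec = EEGRecording(
        channels={"C3": c3, "C4": c4, "M1": m1, "M2": m2}, sample_rate=fs
    )
    return rec, truth


def inject_artifacts(
    recording: EEGRecording, n_flat: int, n_high: int, seed: int,
    segment_seconds: float = 3.0,
) -> tuple[EEGRecording, list[tuple[float, float, str]]]:
    """Insert 3-s flat (RMS <= 1 uV) and high-amplitude (RMS > 250 uV) segments.

    Segments are aligned to the 3-s artifact grid and non-overlapping;
    the injected intervals are returned as (start_s, end_s, kind).
    """
    if n_flat < 0 or n_high < 0:
        raise ValueError("counts must be >= 0")
    fs = recording.sample_rate
    seg = int(round(segment_seconds * fs))
    n_segments = recording.n_samples // seg
    if n_flat + n_high > n_segments:
        raise ValueError("recording too short for requested artifact count")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_segments, size=n_flat + n_high, replace=False)
    channels = {k: v.copy() for k, v in recording.channels.items()}
    intervals = []
    for j, s in enumerate(chosen):
        kind = "flat" if j < n_flat else "high"
        sl = slice(s * seg, (s + 1) * seg)
        for name in ("C3", "C4"):
            if name not in channels:
                continue
            if kind == "flat":
                channels[name][sl] = 0.0
            else:
                channels[name][sl] = 320.0 * rng.standard_normal(seg)
        intervals.append((s * segment_seconds, (s + 1) * segment_seconds, kind))
    out = recording.copy_with(channels=channels)
    return out, intervals


def shift_transitions_to_wake(P: np.ndarray, delta: float) -> np.ndarray:
    """Raise every row's W-column probability by ``delta`` (renormalizing the rest)."""
    P = np.asarray(P, dtype=float).copy()
    w = STAGE_INDEX["W"]
    for i in range(5):
        new_w = np.clip(P[i, w] + delta, 0.0, 0.98)
        others = np.delete(P[i], w)
        scale = (1.0 - new_w) / others.sum()
        row = np.insert(others * scale, w, new_w)
        P[i] = row
    return P


def shift_alpha_fraction(spectra: dict[str, dict[str, float]], delta: float,
                         stages: tuple[str, ...] = ("W", "N1")) -> dict[str, dict[str, float]]:
    """Move ``delta`` of relative power into alpha (taken from delta band)."""
    out = {s: dict(fr) for s, fr in spectra.items()}
    for st in stages:
        out[st]["alpha"] += delta
        out[st]["delta"] -= delta
    return out


def generate_subjects(config: CohortConfig) -> list[SubjectRecord]:
    """Metadata only: ages, sexes, groups, round-robin sites."""
    rng = np.random.default_rng(config.seed)
    records = []
    spec = [("insomnia", config.n_insomnia, config.age_mean_insomnia,
             config.female_fraction_insomnia),
            ("non-insomnia", config.n_control, config.age_mean_control,
             config.female_fraction_control)]
    i = 0
    for group, count, age_mean, f_frac in spec:
        for _ in range(count):
            age = max(18.0, rng.normal(age_mean, config.age_sd))
            sex = "female" if rng.random() < f_frac else "male"
            records.append(
                SubjectRecord(
                    subject_id=f"S{i:04d}", age=float(age), sex=sex, group=group,
                    site=f"site{i % config.n_sites}",
                )
            )
            i += 1
    return records


def generate_cohort(config: CohortConfig):
    """Full cohort: metadata plus per-subject hypnogram/EEG/ground truth.

    Insomnia subjects draw from a wake-shifted transition matrix,
    alpha-shifted Wake/N1 spectra and a reduced spindle density, scaled
    by ``config.effect_sizes``.  Deterministic given the seed.
    """
    subjects = generate_subjects(config)
    eff = config.effect_sizes
    data = {}
    for k, rec in enumerate(subjects):
        sub_seed = np.random.SeedSequence([config.seed, k]).generate_state(1)[0]
        if rec.group == "insomnia":
            P = shift_transitions_to_wake(CONTROL_TRANSITIONS, eff.get("wake_transition", 0.0))
            spectra = shift_alpha_fraction(CONTROL_STAGE_SPECTRA, eff.get("wake_alpha", 0.0))
            density = max(config.spindle_density + eff.get("spindle_density", 0.0), 0.0)
        else:
            P = CONTROL_TRANSITIONS
            spectra = CONTROL_STAGE_SPECTRA
            density = config.spindle_density
        hyp = generate_hypnogram(P, config.n_epochs, seed=int(sub_seed))
        truth = GroundTruth(transition_matrix=P, stage_band_fractions=spectra)
        recording = None
        if config.with_eeg:
            recording, truth = synthesize_recording(
                hyp,
                stage_spectra=spectra,
                spindle_density=density,
                so_rate=config.so_rate,
                coupling_phase=config.coupling_phase,
                sample_rate=config.sample_rate,
                seed=int(sub_seed) + 1,
            )
            truth.transition_matrix = P
        data[rec.subject_id] = {"hypnogram": hyp, "recording": recording, "truth": truth}
    return subjects, data


def subjects_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in subjects])


def simulate_feature_table(
    n_per_group: int,
    effect: float,
    seed: int,
    n_sites: int = 3,
    noise_sd: float = 1.0,
    site_sd: float = 0.3,
    age_slope: float = 0.01,
    sex_shift: float = 0.1,
) -> pd.DataFrame:
    """Subject-level feature values with known group effect (for calibration).

    The feature is ``age_slope * (age - 50) + sex_shift * male + site
    intercept + effect * insomnia + noise``; used to measure type-I
    error and directional power of the group-stats machinery without
    synthesizing EEG.
    """
    cfg = CohortConfig(n_insomnia=n_per_group, n_control=n_per_group, seed=seed,
                       n_sites=n_sites, with_eeg=False)
    subjects = generate_subjects(cfg)
    rng = np.random.default_rng(seed + 1)
    site_effects = {f"site{i}": rng.normal(0, site_sd) for i in range(n_sites)}
    rows = []
    for s in subjects:
        value = (
            age_slope * (s.age - 50.0)
            + sex_shift * (s.sex == "male")
            + site_effects[s.site]
            + effect * (s.group == "insomnia")
            + rng.normal(0, noise_sd)
        )
        rows.append({**s.__dict__, "value": value})
    return pd.DataFrame(rows)
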