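"""Multitaper band powers and per-stage relative spectral features.

Power is estimated in 2-s DPSS multitaper windows with a 1-s hop,
integrated over delta/theta/alpha/beta, averaged to the 30-s hypnogram
grid, summed across C3+C4, normalized to relative power, and finally
aggregated per stage as the natural log of the stage mean (20 features
when all five stages are present).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .types import ArtifactMask, BAND_NAMES, BANDS, EEGRecording, Hypnogram, STAGES

DEFAULT_NW = 2.0
DEFAULT_N_TAPERS = 3


@dataclass
class BandPowerSeries:
    """Per-window absolute band powers (uV^2) for each channel."""

    starts: np.ndarray  # window start times, s
    powers: dict[str, np.ndarray]  # channel -> (n_windows, 4) in BAND_NAMES order
    valid: dict[str, np.ndarray]  # channel -> (n_windows,) bool
    window_seconds: float

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def valid_all_channels(self) -> np.ndarray:
        out = np.ones(self.n_windows, dtype=bool)
        for v in self.valid.values():
            out &= v
        return out


def multitaper_psd(x: np.ndarray, fs: float, nw: float = DEFAULT_NW, n_tapers: int = DEFAULT_N_TAPERS):
    """One-sided multitaper PSD (uV^2/Hz) of a single window.

    DPSS tapers have unit energy, so ``sum(psd) * df`` matches the
    window's mean square (Parseval).
    """
    n = len(x)
    tapers = dpss(n, nw, n_tapers)
    spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    psd = spec.mean(axis=0) * 2.0 / fs
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def band_powers_from_psd(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Integrate PSD over the four canonical bands ([low, high) bins)."""
    df = freqs[1] - freqs[0]
    out = np.empty(len(BAND_NAMES))
    for b, name in enumerate(BAND_NAMES):
        lo, hi = BANDS[name]
        sel = (freqs >= lo) & (freqs < hi)
        out[b] = psd[sel].sum() * df
    return out


def multitaper_band_powers(
    recording: EEGRecording,
    mask: ArtifactMask | None = None,
    window_seconds: float = 2.0,
    hop_seconds: float = 1.0,
    nw: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_N_TAPERS,
) -> BandPowerSeries:
    """Sliding multitaper band powers; windows overlapping artifacts are invalid."""
    fs = recording.sample_rate
    nwin = int(round(window_seconds * fs))
    hop = int(round(hop_seconds * fs))
    start0 = int(round(recording.lights_off * fs))
    n_samples = recording.n_samples
    starts_idx = np.arange(start0, n_samples - nwin + 1, hop)
    starts = starts_idx / fs
    if len(starts_idx) == 0:
        return BandPowerSeries(
            starts=np.array([]), powers={c: np.empty((0, 4)) for c in recording.channels},
            valid={c: np.array([], dtype=bool) for c in recording.channels},
            window_seconds=window_seconds,
        )
    n = len(starts_idx)
    tapers = dpss(nwin, nw, n_tapers)
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    df = freqs[1] - freqs[0]
    band_sel = [(freqs >= BANDS[b][0]) & (freqs < BANDS[b][1]) for b in BAND_NAMES]
    powers, valid = {}, {}
    for name, x in recording.channels.items():
        # (n_windows, nwin) strided view -> tapered FFT in batch
        windows = np.lib.stride_tricks.as_strided(
            x[start0:], shape=(n, nwin), strides=(x.strides[0] * hop, x.strides[0])
        )
        spec = np.abs(np.fft.rfft(windows[:, None, :] * tapers[None, :, :], axis=2)) ** 2
        psd = spec.mean(axis=1) * 2.0 / fs
        psd[:, 0] /= 2.0
        if nwin % 2 == 0:
            psd[:, -1] /= 2.0
        bp = np.stack([psd[:, sel].sum(axis=1) * df for sel in band_sel], axis=1)
        powers[name] = bp
        if mask is not None:
            valid[name] = np.array(
                [not mask.overlaps_artifact(t, t + window_seconds, channel=name) for t in starts]
            )
        else:
            valid[name] = np.ones(n, dtype=bool)
    return BandPowerSeries(starts=starts, powers=powers, valid=valid, window_seconds=window_seconds)


def relative_band_powers(series: BandPowerSeries, hyp: Hypnogram) -> pd.DataFrame:
    """Per-epoch relative band powers (C3+C4 summed before normalizing).

    A 2-s window belongs to the epoch containing its start.  Windows
    invalid on either channel are excluded; epochs with no valid window
    are missing (NaN).
    """
    n_epochs = len(hyp)
    epoch_idx = np.floor(series.starts / hyp.epoch_seconds).astype(int)
    valid = series.valid_all_channels()
    summed = np.zeros((series.n_windows, 4))
    for bp in series.powers.values():
        summed += bp
    rel = np.full((n_epochs, 4), np.nan)
    for e in range(n_epochs):
        sel = valid & (epoch_idx == e)
        if not sel.any():
            continue
        mean_bands = summed[sel].mean(axis=0)
        total = mean_bands.sum()
        if total > 0:
            rel[e] = mean_bands / total
    return pd.DataFrame(rel, columns=list(BAND_NAMES)).assign(stage=list(hyp.stages))


def stage_aggregate(relatives: pd.DataFrame, hyp: Hypnogram | None = None) -> pd.DataFrame:
    """Log of the stage-mean relative power: up to 20 (stage, band) features.

    Stages absent from the hypnogram (or with no valid epochs) are NaN.
    """
    rows = []
    for stage in STAGES:
        sub = relatives.loc[relatives["stage"] == stage, list(BAND_NAMES)].dropna()
        for band in BAND_NAMES:
            value = np.log(sub[band].mean()) if len(sub) else np.nan
            rows.append({"stage": stage, "band": band, "value": value})
    return pd.DataFrame(rows)


def stage_features_vector(agg: pd.DataFrame) -> dict[str, float]:
    """Flatten the stage aggregate into ``{stage}_{band}`` feature names."""
    return {
        f"{r.stage}_{r.band}": r.value for r in agg.itertuples(index=False)
    }
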