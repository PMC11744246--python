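"""Minimal EDF (European Data Format) reader/writer.

Supports the plain EDF subset this package needs: uniform sampling rate
across signals, 1-s data records, 16-bit little-endian samples with
per-signal physical/digital scaling.  Amplitudes are in microvolts.
"""
from __future__ import annotations

import numpy as np

from .types import EEGRecording, UnusableRecordingError

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics without losing magnitude
        s = f"{float(value):.{max(width - 7, 0)}e}" if width >= 8 else s[:width]
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, recording: EEGRecording, patient: str = "X", rec_id: str = "X") -> None:
    """Write a recording as plain EDF with 1-s data records.

    The sample rate must be a whole number of Hz.  Signals are padded
    with zeros to a whole number of records.
    """
    fs = recording.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    labels = recording.channel_names
    n_sig = len(labels)
    data = np.vstack([recording.channels[c] for c in labels])
    n_records = int(np.ceil(data.shape[1] / fs))
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, : data.shape[1]] = data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-3)
    header = b""
    header += _fixed("0", 8)
    header += _fixed(patient, 80)
    header += _fixed(rec_id, 80)
    header += _fixed("01.01.01", 8)
    header += _fixed(recording.start_time[:8], 8)
    header += _fixed(256 + 256 * n_sig, 8)
    header += _fixed("", 44)
    header += _fixed(n_records, 8)
    header += _fixed(1, 8)
    header += _fixed(n_sig, 4)
    for i, lab in enumerate(labels):
        header += _fixed(lab, 16)
    header += b"".join(_fixed("", 80) for _ in labels)  # transducer
    header += b"".join(_fixed("uV", 8) for _ in labels)
    header += b"".join(_fixed(f"{-phys_max[i]:.6g}"[:8], 8) for i in range(n_sig))
    header += b"".join(_fixed(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_sig))
    header += b"".join(_fixed(_DIG_MIN, 8) for _ in labels)
    header += b"".join(_fixed(_DIG_MAX, 8) for _ in labels)
    header += b"".join(_fixed("", 80) for _ in labels)  # prefiltering
    header += b"".join(_fixed(fs, 8) for _ in labels)
    header += b"".join(_fixed("", 32) for _ in labels)

    # re-parse physical bounds exactly as a reader will, so scaling matches
    pmin = np.array([float(f"{-phys_max[i]:.6g}"[:8]) for i in range(n_sig)])
    pmax = np.array([float(f"{phys_max[i]:.6g}"[:8]) for i in range(n_sig)])
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records are interleaved: all samples of signal 0, then signal 1, ...
        rec = digital.reshape(n_sig, n_records, fs)
        for r in range(n_records):
            fh.write(rec[:, r, :].tobytes())


def read_edf(path) -> EEGRecording:
    """Read a plain EDF file written in the subset above.

    Raises
    ------
    UnusableRecordingError
        On duplicate channel labels or truncated signal data.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise UnusableRecordingError("truncated EDF header")
        try:
            n_records = int(head[236:244])
            record_dur = float(head[244:252])
            n_sig = int(head[252:256])
        except ValueError as exc:
            raise UnusableRecordingError(f"corrupt EDF header: {exc}") from exc
        sig_head = fh.read(256 * n_sig)
        if len(sig_head) < 256 * n_sig:
            raise UnusableRecordingError("truncated EDF signal header")

        def field(width, offset):
            base = offset * n_sig
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_sig)
            ]

        labels = field(16, 0)
        # offsets in bytes within the signal header block
        off = 16 * n_sig + 80 * n_sig + 8 * n_sig
        pmin = np.array([float(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_sig)])
        off += 8 * n_sig
        pmax = np.array([float(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_sig)])
        off += 8 * n_sig
        dmin = np.array([float(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_sig)])
        off += 8 * n_sig
        dmax = np.array([float(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_sig)])
        off += 8 * n_sig + 80 * n_sig
        spr = np.array([int(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_sig)])

        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise UnusableRecordingError([f"duplicate channel {d}" for d in dupes])
        rates = spr / record_dur
        if len(set(rates.tolist())) != 1:
            raise UnusableRecordingError("signals have differing sample rates")

        payload = fh.read()
        rec_bytes = int(spr.sum()) * 2
        if len(payload) < rec_bytes * n_records:
            raise UnusableRecordingError("corrupt signal data (short read)")
        raw = np.frombuffer(payload[: rec_bytes * n_records], dtype="<i2")
        raw = raw.reshape(n_records, n_sig, spr[0])
        scale = (pmax - pmin) / (dmax - dmin)
        channels = {}
        for i, lab in enumerate(labels):
            x = raw[:, i, :].reshape(-1).astype(np.float64)
            channels[lab] = (x - dmin[i]) * scale[i] + pmin[i]
    return EEGRecording(channels=channels, sample_rate=float(rates[0]))
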