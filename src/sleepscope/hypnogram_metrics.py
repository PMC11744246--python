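"""Macro-architecture summaries and 5x5 stage-transition statistics.

All quantities are computed strictly within the lights-off -> lights-on
window; times are minutes.  Latency to persistent sleep (LPS) is the
time from lights-off to the first epoch starting a run of >= 20
consecutive non-wake epochs; WASO is wake time from that onset until
lights-on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Hypnogram, STAGES, STAGE_INDEX

PERSISTENT_SLEEP_EPOCHS = 20


@dataclass
class SleepSummary:
    tst_min: float
    sleep_efficiency: float
    waso_min: float | None
    lps_min: float | None
    awake_min: float
    stage_minutes: dict[str, float] = field(default_factory=dict)
    stage_percent: dict[str, float] = field(default_factory=dict)
    window_min: float = 0.0


@dataclass
class TransitionCounts:
    counts: np.ndarray  # 5x5 (from, to), canonical stage order

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5):
            raise ValueError("transition counts must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("negative transition count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _persistent_sleep_onset(hyp: Hypnogram) -> int | None:
    """Window-relative epoch index starting >=20 consecutive non-W epochs."""
    nonwake = hyp.window_stages != "W"
    run = 0
    for i, nw in enumerate(nonwake):
        run = run + 1 if nw else 0
        if run == PERSISTENT_SLEEP_EPOCHS:
            return i - PERSISTENT_SLEEP_EPOCHS + 1
    return None


def latency_to_persistent_sleep(hyp: Hypnogram) -> float | None:
    """LPS in minutes; None when no persistent sleep occurs."""
    onset = _persistent_sleep_onset(hyp)
    if onset is None:
        return None
    return onset * hyp.epoch_seconds / 60.0


def sleep_summary(hyp: Hypnogram) -> SleepSummary:
    stages = hyp.window_stages
    epoch_min = hyp.epoch_seconds / 60.0
    window_min = len(stages) * epoch_min
    stage_minutes = {s: float((stages == s).sum() * epoch_min) for s in STAGES}
    tst = window_min - stage_minutes["W"]
    onset = _persistent_sleep_onset(hyp)
    if onset is None:
        waso = None
        lps = None
    else:
        lps = onset * epoch_min
        waso = float((stages[onset:] == "W").sum() * epoch_min)
    return SleepSummary(
        tst_min=tst,
        sleep_efficiency=tst / window_min,
        waso_min=waso,
        lps_min=lps,
        awake_min=stage_minutes["W"],
        stage_minutes=stage_minutes,
        stage_percent={s: 100.0 * m / window_min for s, m in stage_minutes.items()},
        window_min=window_min,
    )


def psg_insomnia_criteria(summary: SleepSummary) -> bool:
    """Objective insomnia screen: WASO >= 30 min, LPS >= 20 min, SE < 85%."""
    if summary.waso_min is None or summary.lps_min is None:
        return False
    return (
        summary.waso_min >= 30.0
        and summary.lps_min >= 20.0
        and summary.sleep_efficiency < 0.85
    )


def control_criteria(summary: SleepSummary) -> bool:
    """Objective non-insomnia screen: sleep efficiency >= 85%."""
    return summary.sleep_efficiency >= 0.85


def count_transitions(hyp: Hypnogram) -> TransitionCounts:
    """Count consecutive-epoch transitions (self-transitions included)."""
    stages = hyp.window_stages
    if len(stages) < 2:
        raise ValueError("need at least 2 epochs between lights-off and lights-on")
    codes = np.array([STAGE_INDEX[s] for s in stages])
    counts = np.zeros((5, 5), dtype=np.int64)
    np.add.at(counts, (codes[:-1], codes[1:]), 1)
    return TransitionCounts(counts=counts)


def transition_probabilities(counts: TransitionCounts) -> np.ndarray:
    """Row-normalized 5x5 matrix; rows with zero total are NaN."""
    c = counts.counts.astype(np.float64)
    row = c.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = c / row
    probs[row[:, 0] == 0] = np.nan
    return probs


def transition_feature_frame(counts: TransitionCounts, subject_id: str = "") -> pd.DataFrame:
    """The 25 transition features as tidy rows (count + probability)."""
    probs = transition_probabilities(counts)
    rows = []
    for i, src in enumerate(STAGES):
        for j, dst in enumerate(STAGES):
            rows.append(
                {
                    "subject_id": subject_id,
                    "from_stage": src,
                    "to_stage": dst,
                    "count": int(counts.counts[i, j]),
                    "probability": probs[i, j],
                }
            )
    return pd.DataFrame(rows)
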