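"""End-to-end orchestration: per-subject features -> group statistics -> report.

Per-subject failures are isolated and logged; the run continues with
the remaining subjects.  Every reported number is written to a module
output CSV first.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import group_stats, hypnogram_metrics, preprocess, spectral, spindle_so, wesi
from .synthetic_cohort import CohortConfig, generate_cohort, subjects_frame
from .types import STAGES, SubjectRecord


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    recordings: list[dict] = field(default_factory=list)  # files mode: edf/hypnogram/metadata
    out_dir: str = "sleepscope_out"
    seed: int = 0
    screen: bool = False  # apply the objective PSG criteria before stats
    target_rate: float = 200.0
    hp_cutoff: float = 0.5
    wesi_lambda: float = 0.1
    wesi_delta: float = 3.0
    wesi_split: float = 0.8

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")


def screen_subjects(
    summaries: dict[str, hypnogram_metrics.SleepSummary],
    groups: dict[str, str],
) -> tuple[set[str], dict[str, str]]:
    """Apply objective PSG criteria; returns (included ids, exclusion reasons)."""
    included, reasons = set(), {}
    for sid, summary in summaries.items():
        if groups[sid] == "insomnia":
            if hypnogram_metrics.psg_insomnia_criteria(summary):
                included.add(sid)
            else:
                parts = []
                if summary.waso_min is None or summary.waso_min < 30:
                    parts.append("WASO < 30 min")
                if summary.lps_min is None or summary.lps_min < 20:
                    parts.append("LPS < 20 min")
                if summary.sleep_efficiency >= 0.85:
                    parts.append("efficiency >= 85%")
                reasons[sid] = "; ".join(parts) or "criteria"
        else:
            if hypnogram_metrics.control_criteria(summary):
                included.add(sid)
            else:
                reasons[sid] = "efficiency"
    return included, reasons


def extract_subject_features(recording, hypnogram) -> dict:
    """All per-subject features except WESI (which needs the cohort model)."""
    pre = preprocess.preprocess_recording(recording)
    mask = preprocess.rms_artifact_mask(pre)

    series = spectral.multitaper_band_powers(pre, mask)
    rel = spectral.relative_band_powers(series, hypnogram)
    spectral_feats = spectral.stage_features_vector(spectral.stage_aggregate(rel))

    prepared = spindle_so.prepare_signal(pre)
    rejected = spindle_so.delta_artifact_epoch_mask(prepared, hypnogram)
    n2 = spindle_so.accepted_n2_epochs(hypnogram, rejected)
    spindles = {ch: spindle_so.detect_spindles(prepared, n2, ch) for ch in prepared.channels}
    sos = {ch: spindle_so.detect_slow_oscillations(prepared, n2, ch) for ch in prepared.channels}
    spindle_feats = spindle_so.spindle_feature_set(spindles, sos, n2).as_dict()

    counts = hypnogram_metrics.count_transitions(hypnogram)
    summary = hypnogram_metrics.sleep_summary(hypnogram)

    starts, relatives = wesi.window_band_powers_3s(pre, mask)
    return {
        "spectral": spectral_feats,
        "spindle": spindle_feats,
        "transitions": counts,
        "summary": summary,
        "artifact_fraction": mask.fraction_flagged(),
        "wesi_windows": (starts, relatives),
    }


def _transition_frames(per_subject: dict[str, hypnogram_metrics.TransitionCounts]):
    cols = [f"{a}->{b}" for a in STAGES for b in STAGES]
    counts, totals = {}, {}
    for sid, tc in per_subject.items():
        c = tc.counts
        counts[sid] = c.reshape(-1)
        totals[sid] = np.repeat(c.sum(axis=1), 5)
    count_df = pd.DataFrame.from_dict(counts, orient="index", columns=cols)
    total_df = pd.DataFrame.from_dict(totals, orient="index", columns=cols)
    return count_df, total_df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    if config.mode == "synthetic":
        subjects, data = generate_cohort(config.cohort)
    else:
        subjects, data = [], {}
        for spec in config.recordings:
            try:
                rec, hyp = preprocess.read_recording(spec["edf"], spec["hypnogram"])
            except Exception as exc:  # noqa: BLE001 - per-subject isolation
                log.append(f"{spec.get('subject_id', '?')}: excluded ({exc})")
                continue
            sr = SubjectRecord(
                subject_id=spec["subject_id"], age=spec["age"], sex=spec["sex"],
                group=spec["group"], site=spec.get("site", "site0"),
            )
            subjects.append(sr)
            data[sr.subject_id] = {"hypnogram": hyp, "recording": rec, "truth": None}

    meta = subjects_frame(subjects)
    features: dict[str, dict] = {}
    wesi_windows: dict[str, tuple] = {}
    for sr in subjects:
        entry = data[sr.subject_id]
        try:
            if entry["recording"] is None:
                raise ValueError("no EEG available")
            feats = extract_subject_features(entry["recording"], entry["hypnogram"])
        except Exception as exc:  # noqa: BLE001
            log.append(f"{sr.subject_id}: excluded ({exc})")
            continue
        features[sr.subject_id] = feats
        wesi_windows[sr.subject_id] = feats.pop("wesi_windows")

    ok_ids = list(features)
    meta = meta[meta["subject_id"].isin(ok_ids)].reset_index(drop=True)

    # descriptive table (Table-1 style) from hypnograms alone
    summary_rows = []
    for sid in ok_ids:
        s = features[sid]["summary"]
        summary_rows.append(
            {
                "subject_id": sid, "TST_min": s.tst_min,
                "sleep_efficiency": s.sleep_efficiency, "WASO_min": s.waso_min,
                "LPS_min": s.lps_min, "awake_min": s.awake_min,
                **{f"{st}_min": s.stage_minutes[st] for st in STAGES},
                **{f"{st}_pct": s.stage_percent[st] for st in STAGES},
            }
        )
    pd.DataFrame(summary_rows).to_csv(out / "sleep_summary.csv", index=False)

    if config.screen:
        groups = dict(zip(meta["subject_id"], meta["group"]))
        summaries = {sid: features[sid]["summary"] for sid in ok_ids}
        included, reasons = screen_subjects(summaries, groups)
        for sid, why in reasons.items():
            log.append(f"{sid}: screened out ({why})")
        ok_ids = [sid for sid in ok_ids if sid in included]
        meta = meta[meta["subject_id"].isin(ok_ids)].reset_index(drop=True)

    # WESI: train once on the pooled cohort windows, score everyone
    wesi_feats: dict[str, dict[str, float]] = {}
    pooled_rel, pooled_lab, pooled_grp = [], [], []
    for sid in ok_ids:
        starts, rel = wesi_windows[sid]
        hyp = data[sid]["hypnogram"]
        epochs = np.floor(starts / hyp.epoch_seconds).astype(int)
        valid = epochs < len(hyp)
        labels = np.array([1.0 if hyp.stages[e] == "W" else 0.0 for e in epochs[valid]])
        pooled_rel.append(rel[valid])
        pooled_lab.append(labels)
        pooled_grp.append(np.repeat(sid, valid.sum()))
    if pooled_rel:
        R = np.vstack(pooled_rel)
        L = np.concatenate(pooled_lab)
        G = np.concatenate(pooled_grp)
        try:
            model = wesi.train(R, L, groups=G, split=config.wesi_split,
                               lam=config.wesi_lambda, delta=config.wesi_delta,
                               seed=config.seed)
            (out / "wesi_model.json").write_text(model.to_json())
            for sid in ok_ids:
                starts, rel = wesi_windows[sid]
                if len(rel) == 0:
                    continue
                s = wesi.score(model, rel)
                wesi_feats[sid] = wesi.stage_means(s, starts, data[sid]["hypnogram"])
        except ValueError as exc:
            log.append(f"WESI training skipped: {exc}")

    # tidy feature table
    rows = []
    for sid in ok_ids:
        for name, value in features[sid]["spectral"].items():
            rows.append({"subject_id": sid, "family": "spectral", "feature": name, "value": value})
        for name, value in features[sid]["spindle"].items():
            rows.append({"subject_id": sid, "family": "spindle", "feature": name, "value": value})
        for st, value in wesi_feats.get(sid, {}).items():
            logit_v = wesi.logit_stage_means({st: value})[st]
            rows.append({"subject_id": sid, "family": "wesi", "feature": f"wesi_{st}",
                         "value": logit_v})
        tframe = hypnogram_metrics.transition_feature_frame(features[sid]["transitions"], sid)
        for r in tframe.itertuples(index=False):
            rows.append({"subject_id": sid, "family": "transition",
                         "feature": f"{r.from_stage}->{r.to_stage}", "value": r.count})
    feature_table = pd.DataFrame(rows)
    feature_table.to_csv(out / "features.csv", index=False)

    # group statistics per family
    results = {}
    for family in ("spectral", "spindle", "wesi"):
        fam = feature_table[feature_table["family"] == family]
        frames = {}
        for name, sub in fam.groupby("feature"):
            df = sub.merge(meta, on="subject_id")[["value", "age", "sex", "group", "site"]]
            usable = df.dropna(subset=["value"])
            if min((usable["group"] == g).sum() for g in ("insomnia", "non-insomnia")) >= 2:
                frames[name] = df
        if frames:
            try:
                res = group_stats.compare_family(frames, family)
                res.to_csv(out / f"results_{family}.csv", index=False)
                results[family] = res
            except ValueError as exc:
                log.append(f"{family} family skipped: {exc}")

    count_df, total_df = _transition_frames(
        {sid: features[sid]["transitions"] for sid in ok_ids}
    )
    if len(count_df) >= 4 and meta["group"].nunique() == 2:
        tres = group_stats.analyze_transitions(
            count_df.loc[ok_ids], total_df.loc[ok_ids],
            meta.set_index("subject_id").loc[ok_ids].reset_index(),
        )
        tres.to_csv(out / "results_transition.csv", index=False)
        results["transition"] = tres
        grid = tres.assign(
            from_stage=tres["feature"].str.split("->").str[0],
            to_stage=tres["feature"].str.split("->").str[1],
        ).pivot(index="from_stage", columns="to_stage", values="significant")
        grid.reindex(index=list(STAGES), columns=list(STAGES)).to_csv(
            out / "transition_grid.csv"
        )

    meta.to_csv(out / "subjects.csv", index=False)
    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "n_subjects": len(ok_ids),
        "log": log,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"results": results, "features": feature_table, "metadata": meta, "log": log}
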