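"""End-to-end driver: synthetic cohort -> preprocessing -> features ->
committees -> three-level validation -> report bundle.

The bundle is a plain nested dict (JSON-serializable) so two runs with the
same config produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import eeg_features as ef
from .cardiac_features import (UnusableSignalError, cardiac_window_features,
                               detect_r_peaks)
from .config import PipelineConfig
from .models import (FEATURE_SETS, feature_consistency, predict_trace,
                     train_committee)
from .novel_task import (evaluate_trace_against_trials,
                         proportion_significant_curve)
from .preprocessing import preprocess
from .recording import Recording
from .synthetic import default_profile, make_session, synthesize_behavior
from .validation import (K_FOLDS, SubjectRegression,
                         intermediate_regression_test, kfold_cv, loo_bounds)

logger = logging.getLogger(__name__)

CALIBRATION_TASKS = ("breath_count", "nback3", "nback1")
THREAT_TYPES = ("person", "object")


def _attach_cardiac(windows, rec: Recording, context: float) -> bool:
    """Attach HRV features to each window from the recording's ECG lead."""
    ecg_idx = rec.indices("ECG")
    if ecg_idx.size == 0:
        return False
    try:
        beats = detect_r_peaks(rec.data[ecg_idx[0]], rec.fs)
    except UnusableSignalError as exc:
        logger.warning("unusable ECG: %s", exc)
        return False
    feats = cardiac_window_features(
        beats, [(w.start, w.end) for w in windows], "Ps2_bands",
        context=context, recording_span=(0.0, rec.duration))
    for w, f in zip(windows, feats):
        w.cardiac = f
    return True


def build_subject(profile, config: PipelineConfig, *, with_nback1=True):
    """Synthesize, preprocess and featurize one subject's calibration data."""
    durations = {"breath_count": config.breath_duration,
                 "nback1": config.nback_duration,
                 "nback3": config.nback_duration}
    recs = {}
    for task in CALIBRATION_TASKS:
        if task == "nback1" and not with_nback1:
            continue
        raw = make_session(profile, task, duration=durations[task],
                           fs=config.fs, n_channels=config.n_channels)
        recs[task] = preprocess(raw, ica_seed=profile.seed,
                                run_ica=config.run_ica)
        recs[task].meta.setdefault("task", task)
        recs[task].meta["latents"] = raw.meta["latents"]
        recs[task].meta["beat_times"] = raw.meta["beat_times"]

    windows = {}
    for bio in ("fatigue", "stress"):
        ws = (ef.training_windows(recs["breath_count"], bio, "breath_count")
              + ef.training_windows(recs["nback3"], bio, "nback3"))
        windows[bio] = ws
    # HRV features ride along with the stress windows, per source task
    n_breath = sum(1 for w in windows["stress"] if w.task == "breath_count")
    _attach_cardiac(windows["stress"][:n_breath], recs["breath_count"],
                    config.hrv_context)
    _attach_cardiac(windows["stress"][n_breath:], recs["nback3"],
                    config.hrv_context)
    windows["attention"] = ef.attention_windows(recs["breath_count"])
    return recs, windows


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run the complete synthetic study and return the report bundle."""
    # out_dir is a filesystem detail, not part of the reproducible result
    cfg_doc = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    bundle: dict = {"config": cfg_doc, "subjects": {},
                    "cv": {}, "regression": {}, "consistency": {},
                    "permutation": {"curves": {}, "per_subject": {}}}
    per_subject_models: dict[str, list] = {fs: [] for fs in
                                           config.regression_sets}
    regression_subjects: dict[str, list[SubjectRegression]] = {
        fs: [] for fs in config.regression_sets}
    perm_scores: dict[str, list] = {}

    if not config.include_nback1:
        bundle["regression"] = {
            "skipped": "no 1-back recordings configured; "
                       "intermediate regression test not run"}

    for si in range(config.n_subjects):
        sid = f"S{si:02d}"
        profile = default_profile(seed=config.seed * 1000 + si)
        recs, windows = build_subject(profile, config,
                                      with_nback1=config.include_nback1)
        bundle["subjects"][sid] = {
            "rejected_channels": recs["breath_count"].meta.get(
                "rejected_channels", []),
            "rejected_ics": recs["breath_count"].meta.get("rejected_ics", []),
            "attention_excluded": not windows["attention"],
            "n_mw_events": len(
                recs["breath_count"].event_times("mw_event")),
        }

        # --- level 1: balanced k-fold CV per feature set -----------------
        cv_row = {}
        for fsid in config.feature_sets:
            spec = FEATURE_SETS[fsid]
            ws = windows[spec.biometric]
            if not ws:
                cv_row[fsid] = None
                continue
            try:
                res = kfold_cv(ws, spec, K_FOLDS[spec.biometric],
                               seed=config.seed + si,
                               ridge=config.ridge,
                               transform=config.transform)
                cv_row[fsid] = round(res.subject_accuracy, 6)
            except ValueError as exc:
                logger.warning("%s %s CV skipped: %s", sid, fsid, exc)
                cv_row[fsid] = None
        bundle["cv"][sid] = cv_row

        # --- level 2: LOO bounds + intermediate (1-back) ------------------
        committees = {}
        for fsid in config.regression_sets:
            spec = FEATURE_SETS[fsid]
            ws = windows[spec.biometric]
            try:
                committee = train_committee(ws, spec, ridge=config.ridge,
                                            transform=config.transform)
                committees[fsid] = committee
                per_subject_models[fsid].append(
                    {m.channel: m for m in committee.members})
                if not config.include_nback1:
                    continue
                lo, hi = loo_bounds(ws, spec, ridge=config.ridge,
                                    transform=config.transform)
                if "nback1" in recs:
                    trace = predict_trace(committee, recs["nback1"],
                                          transform=config.transform,
                                          hrv_context=config.hrv_context)
                    mid = float(np.nanmean(trace.values))
                else:
                    trace, mid = None, float("nan")
                regression_subjects[fsid].append(SubjectRegression(
                    subject=sid, low_bound=lo, high_bound=hi,
                    intermediate_score=mid, trace=trace))
            except (ValueError, RuntimeError) as exc:
                logger.warning("%s %s regression skipped: %s", sid, fsid, exc)

        # --- level 3: novel threat-detection task -------------------------
        # subj_perm[(biometric, metric)][threat_type][window] -> significant
        subj_perm: dict[tuple[str, str], dict[str, dict[int, bool]]] = {}
        for tt in THREAT_TYPES:
            threat = make_session(profile, "threat_detection",
                                  duration=config.threat_duration,
                                  fs=config.fs,
                                  n_channels=config.n_channels, tag=tt)
            threat_clean = preprocess(threat, ica_seed=profile.seed,
                                      run_ica=config.run_ica)
            threat_clean.meta["task"] = "threat_detection"
            trials = synthesize_behavior(
                threat.meta["latents"], profile, config.n_trials,
                threat_type=tt, trial_duration=config.trial_duration)
            for fsid, committee in committees.items():
                trace = predict_trace(committee, threat_clean,
                                      transform=config.transform,
                                      hrv_context=config.hrv_context)
                results = evaluate_trace_against_trials(
                    trace, trials, n_iter=config.n_permutations,
                    seed=config.seed * 100 + si)
                bio = committee.spec.biometric
                for r in results:
                    subj_perm.setdefault((bio, r.metric), {}) \
                        .setdefault(tt, {})[r.window] = r.significant
        for key, day_map in subj_perm.items():
            perm_scores.setdefault(key, []).append(day_map)
        bundle["permutation"]["per_subject"][sid] = {
            f"{bio}_{metric}": {
                tt: {str(w): bool(s) for w, s in wins.items()}
                for tt, wins in day_map.items()}
            for (bio, metric), day_map in subj_perm.items()
        }

    # --- cohort-level aggregation ----------------------------------------
    bundle["cv_mean"] = {}
    for fsid in config.feature_sets:
        vals = [row[fsid] for row in bundle["cv"].values()
                if row.get(fsid) is not None]
        bundle["cv_mean"][fsid] = round(float(np.mean(vals)), 6) \
            if vals else None

    for fsid, subjects in regression_subjects.items():
        if not subjects:
            continue
        rep = intermediate_regression_test(
            subjects, biometric=FEATURE_SETS[fsid].biometric,
            feature_set=fsid, tails=config.regression_tails)
        bundle["regression"][fsid] = {
            "low_bound": round(rep.low_bound, 6),
            "high_bound": round(rep.high_bound, 6),
            "intermediate_score": round(rep.intermediate_score, 6),
            "t_low": [_num(v) for v in rep.t_low],
            "t_high": [_num(v) for v in rep.t_high],
            "time_effect": [_num(v) for v in rep.time_effect],
        }

    for fsid, models in per_subject_models.items():
        if len(models) >= 2:
            spec = FEATURE_SETS[fsid]
            if spec.source == "ECG_only" or not spec.eeg_bands:
                continue
            rows = feature_consistency(models, spec.eeg_bands)
            bundle["consistency"][fsid] = rows

    for (bio, metric), per_subj in perm_scores.items():
        curve = proportion_significant_curve(per_subj)
        bundle["permutation"]["curves"][f"{bio}_{metric}"] = {
            str(w): _num(v) for w, v in curve.items()}

    return bundle


def _num(v) -> float | None:
    v = float(v)
    return None if not np.isfinite(v) else round(v, 6)


def write_bundle(bundle: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(bundle, sort_keys=True, indent=1))
    return path
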