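"""Canonical desk-scale synthetic experiments for validating the pipeline.

These constructions fix the study conditions used by the test suite and
the results-reproduction script: cohort sizes, task durations, effect
sizes and channel montages.  Sessions are 5 min at 250 Hz (full-length
protocol sessions remain available through the config); effect sizes are
chosen large enough that recovery is limited by the method, not the SNR.
"""

from __future__ import annotations

import numpy as np

from . import eeg_features as ef
from .cardiac_features import BeatSeries, cardiac_window_features
from .models import FEATURE_SETS, predict_trace, train_committee
from .novel_task import permutation_test
from .recording import CHANNEL_GROUPS, Recording
from .synthetic import default_profile, generate_latents, synthesize_behavior, \
    synthesize_ecg, synthesize_eeg
from .validation import SubjectRegression, kfold_cv, loo_bounds

FRONTAL = list(CHANNEL_GROUPS["frontal"])

#: High-SNR fatigue direction table with effects outside theta/alpha, so
#: the two-band feature set has nothing to work with while the all-band
#: set recovers the state.
FATIGUE_EFFECTS = {("fatigue", "gamma", "frontal"): 0.8,
                   ("fatigue", "delta", "frontal"): -0.5}

#: Stress cohort: moderate EEG effects plus an autonomic LF/HF shift, so
#: EEG-only, ECG-only and combined feature sets can be ranked.
STRESS_EFFECTS = {("stress", "theta", "frontal"): 0.4,
                  ("stress", "alpha", "frontal"): -0.35}
STRESS_HRV = dict(lf_gain=0.06, hf_gain=0.045)

TASK_SECONDS = 300.0
FS = 250.0


def _eeg_with_task(profile, task, channels, duration=TASK_SECONDS, fs=FS):
    lat = generate_latents(task, duration, profile)
    rec = synthesize_eeg(lat, profile, fs=fs, channels=channels)
    rec.meta["task"] = task
    return rec


def _append_ecg(rec: Recording, profile, fs=FS) -> Recording:
    ecg = synthesize_ecg(rec.meta["latents"], profile, fs=fs)
    n = min(rec.n_samples, ecg.n_samples)
    rec.data = np.vstack([rec.data[:, :n], ecg.data[:, :n]])
    rec.channel_names = list(rec.channel_names) + ["ECG"]
    rec.channel_roles = list(rec.channel_roles) + ["ECG"]
    rec.meta["beat_times"] = ecg.meta["beat_times"]
    return rec


def fatigue_windows_for_subject(seed: int, channels=None,
                                duration=TASK_SECONDS):
    """Labeled fatigue windows from one subject's calibration pair."""
    channels = channels or FRONTAL
    prof = default_profile(seed, effects=dict(FATIGUE_EFFECTS))
    out = []
    for task in ("breath_count", "nback3"):
        rec = _eeg_with_task(prof, task, channels, duration)
        out += ef.training_windows(rec, "fatigue", task)
    return out


def stress_windows_for_subject(seed: int, channels=None,
                               duration=TASK_SECONDS):
    """Labeled stress windows (with HRV features) from one subject."""
    channels = channels or FRONTAL
    prof = default_profile(seed, effects=dict(STRESS_EFFECTS), **STRESS_HRV)
    out = []
    for task in ("breath_count", "nback3"):
        rec = _eeg_with_task(prof, task, channels, duration)
        ecg = synthesize_ecg(rec.meta["latents"], prof, fs=FS)
        ws = ef.training_windows(rec, "stress", task)
        beats = BeatSeries(ecg.meta["beat_times"])
        feats = cardiac_window_features(beats, [(w.start, w.end) for w in ws],
                                        "Ps2_bands",
                                        recording_span=(0, duration))
        for w, f in zip(ws, feats):
            w.cardiac = f
        out += ws
    return out


def fatigue_cv_accuracies(seed: int = 7) -> dict[str, float]:
    ws = fatigue_windows_for_subject(seed)
    return {fsid: kfold_cv(ws, FEATURE_SETS[fsid], 10,
                           seed=seed).subject_accuracy
            for fsid in ("Pf1", "Pf2")}


def stress_cv_accuracies(seed: int = 11) -> dict[str, float]:
    ws = stress_windows_for_subject(seed)
    return {fsid: kfold_cv(ws, FEATURE_SETS[fsid], 10,
                           seed=seed).subject_accuracy
            for fsid in ("Ps2", "Ps3", "Ps4")}


def regression_cohort(biometric: str, n_subjects: int = 10, seed: int = 0,
                      channels=None) -> list[SubjectRegression]:
    """LOO bounds + held-out 1-back scores for a synthetic cohort.

    The fatigue cohort couples only the fatigue latent to band powers (a
    ramp, so a time-on-task effect is expected in the held-out trace); the
    stress cohort couples only the (flat within task) stress latent, so no
    time effect is expected.
    """
    channels = channels or FRONTAL[:3]
    subjects = []
    for si in range(n_subjects):
        sseed = seed * 1000 + si
        if biometric == "fatigue":
            prof = default_profile(sseed, effects=dict(FATIGUE_EFFECTS))
            fsid = "Pf2"
        else:
            prof = default_profile(sseed, effects=dict(STRESS_EFFECTS),
                                   **STRESS_HRV)
            fsid = "Ps4"
        spec = FEATURE_SETS[fsid]
        windows = []
        recs = {}
        for task in ("breath_count", "nback3", "nback1"):
            rec = _eeg_with_task(prof, task, channels)
            rec = _append_ecg(rec, prof)
            recs[task] = rec
            if task == "nback1":
                continue
            ws = ef.training_windows(rec, biometric, task)
            if spec.source != "EEG_committee":
                beats = BeatSeries(rec.meta["beat_times"])
                feats = cardiac_window_features(
                    beats, [(w.start, w.end) for w in ws], spec.ecg_mode,
                    recording_span=(0, TASK_SECONDS))
                for w, f in zip(ws, feats):
                    w.cardiac = f
            windows += ws
        committee = train_committee(windows, spec)
        lo, hi = loo_bounds(windows, spec)
        trace = predict_trace(committee, recs["nback1"])
        subjects.append(SubjectRegression(
            subject=f"S{si}", low_bound=lo, high_bound=hi,
            intermediate_score=float(np.nanmean(trace.values)), trace=trace))
    return subjects


def permutation_null_calibration(n_sessions: int = 200, n_trials: int = 100,
                                 w: int = 10, n_iter: int = 3000,
                                 seed: int = 0) -> float:
    """Type-I rate of the permutation test under null behavior."""
    sig = 0
    for s in range(n_sessions):
        prof = default_profile(seed * 100000 + s)
        lat = generate_latents("threat_detection", 330, prof)
        trials = synthesize_behavior(lat, prof, n_trials, null_mode=True)
        at = lat.at(trials["onset"].to_numpy() + 1.0)
        bio = at["fatigue"] + 0.1 * at["stress"]
        res = permutation_test(bio, trials["rt"].to_numpy(), w=w,
                               n_iter=n_iter, seed=seed + s)
        sig += res.significant
    return sig / n_sessions


def permutation_power_curve(n_seeds: int = 50, n_trials: int = 200,
                            n_iter: int = 3000, seed: int = 0
                            ) -> dict[int, float]:
    """Detection rate vs smoothing window for behavior linked at r ~ 0.5."""
    hits = {w: 0 for w in range(1, 11)}
    for s in range(n_seeds):
        prof = default_profile(seed * 100000 + 50000 + s)
        lat = generate_latents("threat_detection", 660, prof)
        trials = synthesize_behavior(lat, prof, n_trials)
        bio = lat.at(trials["onset"].to_numpy() + 1.0)["fatigue"]
        rt = trials["rt"].to_numpy()
        for w in hits:
            res = permutation_test(bio, rt, w=w, n_iter=n_iter,
                                   seed=seed + 997 * w + s)
            hits[w] += res.significant
    return {w: h / n_seeds for w, h in hits.items()}
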