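"""Readers and writers for recordings, feature tables, models and results.

The canonical on-disk recording format is a CSV of time + one column per
channel, with a JSON sidecar carrying the sampling rate, channel roles,
event markers and any ground truth.  EDF files are additionally readable
(channel roles inferred from labels).  All text output is UTF-8,
comma-separated, with times in seconds at 6 decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_features import FeatureWindow
from .models import BiometricTrace, CommitteeModel, ElectrodeModel, FEATURE_SETS
from .recording import Recording


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV plus a JSON sidecar of events/ground truth."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.insert(0, "time", np.round(rec.times, 6))
    df.to_csv(path, index=False, float_format="%.6f")
    side = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "channel_roles": rec.channel_roles,
        "events": [[float(t), lab] for t, lab in rec.events],
    }
    for key in ("beat_times", "blink_times", "rejected_channels",
                "rejected_ics", "bad_channel", "task"):
        if key in rec.meta:
            v = rec.meta[key]
            side[key] = v.tolist() if isinstance(v, np.ndarray) else v
    lat = rec.meta.get("latents")
    if lat is not None:
        side["latents"] = {
            "times": lat.times.tolist(), "fatigue": lat.fatigue.tolist(),
            "stress": lat.stress.tolist(),
            "attention": lat.attention.tolist(),
            "mw_events": list(lat.mw_events), "task": lat.task,
        }
    _sidecar_path(path).write_text(json.dumps(side, sort_keys=True))
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from CSV (+sidecar) or EDF.

    For CSV the sidecar supplies fs/roles/events when present; otherwise
    fs is inferred from the time column and roles from channel labels.
    For EDF the header supplies fs and labels; labels containing ECG/EKG
    or EOG set those roles, everything else is EEG.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "EDF":
        return _read_edf(path)
    if fmt != "CSV":
        raise ValueError(f"unknown recording format {fmt!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' header column")
    side_path = _sidecar_path(path)
    side = json.loads(side_path.read_text()) if side_path.exists() else {}
    names = [c for c in df.columns if c != "time"]
    t = df["time"].to_numpy(float)
    fs = side.get("fs") or (1.0 / np.median(np.diff(t)))
    roles = side.get("channel_roles") or [_role_from_label(n) for n in names]
    events = [(float(a), b) for a, b in side.get("events", [])]
    meta = {}
    for key in ("beat_times", "blink_times", "rejected_channels",
                "rejected_ics", "bad_channel", "task"):
        if key in side:
            meta[key] = (np.asarray(side[key])
                         if key == "beat_times" else side[key])
    if "latents" in side:
        from .synthetic import LatentStateTraject

        L = side["latents"]
        meta["latents"] = LatentStateTraject(
            np.asarray(L["times"]), np.asarray(L["fatigue"]),
            np.asarray(L["stress"]), np.asarray(L["attention"]),
            list(L["mw_events"]), task=L.get("task", ""))
    return Recording(data=df[names].to_numpy(float).T, fs=float(fs),
                     channel_names=names, channel_roles=roles,
                     events=events, meta=meta)


def _role_from_label(label: str) -> str:
    u = label.upper()
    if "ECG" in u or "EKG" in u:
        return "ECG"
    if "EOG" in u:
        return "EOG"
    return "EEG"


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    return Recording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                     channel_names=list(names),
                     channel_roles=[_role_from_label(n) for n in names])


# ---------------------------------------------------------------------------
# Feature tables, models, traces
# ---------------------------------------------------------------------------

def windows_to_frame(windows: list[FeatureWindow]) -> pd.DataFrame:
    """Long table: one row per window x channel, band-power columns."""
    rows = []
    for w in windows:
        for ci, ch in enumerate(w.channel_names):
            row = {"start": w.start, "end": w.end, "channel": ch,
                   "label": w.label, "task": w.task, "subject": w.subject}
            for bi, b in enumerate(w.band_names):
                row[b] = w.powers[ci, bi]
            rows.append(row)
    return pd.DataFrame(rows)


def write_committee(model: CommitteeModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "feature_set": model.spec.id,
        "biometric": model.spec.biometric,
        "members": [
            {
                "channel": m.channel,
                "coef": m.coef.tolist(),
                "feature_mean": m.feature_mean.tolist(),
                "feature_sd": m.feature_sd.tolist(),
                "converged": m.converged,
            }
            for m in model.members
        ],
    }
    path.write_text(json.dumps(doc, sort_keys=True, indent=1))
    return path


def read_committee(path: str | Path) -> CommitteeModel:
    doc = json.loads(Path(path).read_text())
    spec = FEATURE_SETS[doc["feature_set"]]
    members = [
        ElectrodeModel(channel=m["channel"], coef=np.asarray(m["coef"]),
                       feature_mean=np.asarray(m["feature_mean"]),
                       feature_sd=np.asarray(m["feature_sd"]),
                       converged=m["converged"], feature_set=spec.id)
        for m in doc["members"]
    ]
    return CommitteeModel(spec=spec, members=members)


def write_trace(trace: BiometricTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time": trace.times, "value": trace.values}).to_csv(
        path, index=False, float_format="%.6f")
    return path
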