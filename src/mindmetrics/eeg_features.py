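"""Windowed EEG band-power features with task-based labels.

Training features come from 10 s non-overlapping bins (fatigue, stress) or
6 s event-locked windows around mind-wandering button presses (attention);
test-time features come from sliding windows at a 1 s stride.  Band power
is the contribution of the DFT bins inside a band to the window's
mean-square signal power, so a pure tone of amplitude A contributes A^2/2
to its band and the band powers over a partition of [0, Nyquist) sum to
the window variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import EEG_BANDS, BandTable
from .recording import Recording

#: Window lengths in seconds per biometric.
WINDOW_LENGTHS = {"fatigue": 10.0, "stress": 10.0, "attention": 6.0}
TEST_STRIDE = 1.0
#: Event-locked attention windows: [e-8, e-2] inattentive, [e+2, e+8] attentive.
ATTENTION_PRE = (8.0, 2.0)
ATTENTION_POST = (2.0, 8.0)
MIN_MW_EVENTS = 3


@dataclass
class FeatureWindow:
    """One time window's per-channel band powers plus an optional label."""

    start: float
    end: float
    powers: np.ndarray          # channels x bands
    label: str = "unlabeled"    # low | high | unlabeled
    task: str = ""
    subject: str = ""
    channel_names: tuple[str, ...] = ()
    band_names: tuple[str, ...] = ()
    cardiac: np.ndarray | None = None   # optional HRV feature vector

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if np.any(self.powers < 0):
            raise ValueError("band powers must be non-negative")

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


def band_power(segment: np.ndarray, fs: float, band: tuple[float, float],
               *, taper: str = "hann") -> float:
    """Mean-square power of ``segment`` carried by DFT bins lo <= f < hi.

    With the default Hann taper the window is power-normalized (divided by
    the mean squared taper) so that broadband power levels match the
    rectangular case; ``taper='rect'`` gives the exact Parseval partition.
    """
    lo, hi = band
    if hi > (fs / 2) * (1 + 1e-6):
        raise ValueError(f"band [{lo}, {hi}) exceeds Nyquist {fs / 2}")
    x = np.asarray(segment, float)
    n = x.size
    if n < fs:
        raise ValueError("segment must be at least 1 s long")
    if taper == "hann":
        w = np.hanning(n)
        x = x * w
        norm = np.mean(w ** 2)
    elif taper == "rect":
        norm = 1.0
    else:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.fft.rfft(x)
    # one-sided mean-square contribution per bin
    p = (np.abs(spec) ** 2) / n**2
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (f >= lo) & (f < hi)
    return float(p[mask].sum() / norm)


def window_powers(rec: Recording, start: float, end: float,
                  bands: BandTable = EEG_BANDS, *, taper: str = "hann",
                  channel_indices: np.ndarray | None = None) -> np.ndarray:
    """Channels x bands power matrix for one time window."""
    i0, i1 = int(round(start * rec.fs)), int(round(end * rec.fs))
    if channel_indices is None:
        channel_indices = rec.indices("EEG")
    seg = rec.data[channel_indices, i0:i1]
    out = np.empty((len(channel_indices), len(bands)))
    for ci in range(seg.shape[0]):
        for bi, band in enumerate(bands):
            out[ci, bi] = band_power(seg[ci], rec.fs, (band.lo, band.hi),
                                     taper=taper)
    return out


def _make_window(rec: Recording, start: float, end: float, label: str,
                 task: str, subject: str, bands: BandTable,
                 taper: str) -> FeatureWindow:
    idx = _retained(rec)
    return FeatureWindow(
        start=start, end=end,
        powers=window_powers(rec, start, end, bands, taper=taper,
                             channel_indices=idx),
        label=label, task=task, subject=subject,
        channel_names=tuple(rec.channel_names[i] for i in idx),
        band_names=bands.names,
    )


def _retained(rec: Recording) -> np.ndarray:
    bad = set(rec.meta.get("rejected_channels", []))
    return np.array([i for i in rec.indices("EEG")
                     if rec.channel_names[i] not in bad], dtype=int)


def training_windows(rec: Recording, biometric: str, task: str, *,
                     bands: BandTable = EEG_BANDS, taper: str = "hann",
                     subject: str = "") -> list[FeatureWindow]:
    """Labeled 10 s non-overlapping bins for fatigue or stress training.

    Breath-count data is the low class for both biometrics.  For fatigue
    only the latter half of the 3-back task is used (labeled high; the
    first half is discarded because fatigue builds gradually); for stress
    the whole 3-back task is the high class (stress rises with load on a
    fast time scale).  A trailing partial window is dropped.
    """
    if biometric not in ("fatigue", "stress"):
        raise ValueError("training_windows handles fatigue and stress only")
    if task not in ("breath_count", "nback3", "nback1"):
        raise ValueError(f"unexpected training task {task!r}")
    dur = rec.duration
    if dur < 20:
        raise ValueError("task segment too short (< 20 s)")
    wlen = WINDOW_LENGTHS[biometric]
    if task == "breath_count":
        t0, label = 0.0, "low"
    elif task == "nback1":
        t0, label = 0.0, "unlabeled"
    elif biometric == "fatigue":
        t0, label = dur / 2, "high"   # latter half only
    else:
        t0, label = 0.0, "high"
    starts = np.arange(t0, dur - wlen + 1e-9, wlen)
    return [_make_window(rec, s, s + wlen, label, task, subject, bands, taper)
            for s in starts]


def attention_windows(rec: Recording, mw_events: list[float] | None = None, *,
                      bands: BandTable = EEG_BANDS, taper: str = "hann",
                      subject: str = "") -> list[FeatureWindow]:
    """Event-locked 6 s attention training windows around button presses.

    Per event e: [e-8, e-2] is inattentive, [e+2, e+8] attentive.  An
    attentive window overlapping any other event's inattentive window is
    relabeled inattentive (the press evidently did not restore sustained
    attention).  Windows clipped by the recording edges are dropped.
    Subjects with fewer than three usable events are excluded: an empty
    list is returned and ``meta['attention_excluded']`` is set.
    """
    if mw_events is None:
        mw_events = rec.event_times("mw_event")
    dur = rec.duration
    events = [e for e in mw_events
              if e - ATTENTION_PRE[0] >= 0 and e + ATTENTION_POST[1] <= dur]
    if len(events) < MIN_MW_EVENTS:
        rec.meta["attention_excluded"] = True
        return []
    inatt = [(e - ATTENTION_PRE[0], e - ATTENTION_PRE[1]) for e in events]
    att = [(e + ATTENTION_POST[0], e + ATTENTION_POST[1]) for e in events]
    windows: list[FeatureWindow] = []
    for s, t in inatt:
        windows.append(_make_window(rec, s, t, "low", "breath_count",
                                    subject, bands, taper))
    for k, (s, t) in enumerate(att):
        overlaps = any(s < ie and t > is_ for j, (is_, ie) in enumerate(inatt)
                       if j != k)
        label = "low" if overlaps else "high"
        windows.append(_make_window(rec, s, t, label, "breath_count",
                                    subject, bands, taper))
    windows.sort(key=lambda w: w.start)
    return windows


def test_windows(rec: Recording, biometric: str, *,
                 bands: BandTable = EEG_BANDS, taper: str = "hann",
                 stride: float = TEST_STRIDE,
                 subject: str = "") -> list[FeatureWindow]:
    """Unlabeled sliding windows (10 s fatigue/stress, 6 s attention, 1 s
    stride) whose timestamp is the window center."""
    wlen = WINDOW_LENGTHS[biometric]
    dur = rec.duration
    if dur < wlen:
        raise ValueError(f"recording shorter than the {wlen} s test window")
    starts = np.arange(0.0, dur - wlen + 1e-9, stride)
    return [_make_window(rec, s, s + wlen, "unlabeled",
                         rec.meta.get("task", ""), subject, bands, taper)
            for s in starts]
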