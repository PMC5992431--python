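"""Synthetic EEG/ECG sessions with known latent mental states.

The generator emulates the calibration-and-novel-task study design the
analysis pipeline assumes: a relaxing breath-count task (low fatigue, low
stress, intermittent mind-wandering), visual N-back recall at moderate
(1-back) and heavy (3-back) load, and a threat-detection task with
per-trial accuracy and reaction time.  Ground-truth latents, beat times
and injected-artifact locations are always exported in ``Recording.meta``
so parameter-recovery tests can close the loop.

EEG channels are sums of band-limited Gaussian-noise carriers (one per
spectral band) whose instantaneous amplitude follows
``baseline * (1 + effect * latent)`` per a signed region/band direction
table, on top of a 1/f background.  ECG is a QRS-like template train whose
RR intervals carry LF (~0.1 Hz) and HF (~0.3 Hz) modulation with the LF/HF
balance tied to the stress latent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .bands import EEG_BANDS, BandTable
from .recording import CHANNEL_GROUPS, EEG_CHANNELS, GROUP_OF_CHANNEL, Recording

TASK_KINDS = ("breath_count", "nback1", "nback3", "threat_detection")

#: Study-length task durations in seconds (breath-count 30 min, N-back 21 min).
FULL_TASK_DURATIONS = {
    "breath_count": 1800.0,
    "nback1": 1260.0,
    "nback3": 1260.0,
    "threat_detection": 1800.0,
}

#: Scaled-down durations used by default in tests and synthetic pipeline runs.
SCALED_TASK_DURATIONS = {
    "breath_count": 300.0,
    "nback1": 300.0,
    "nback3": 300.0,
    "threat_detection": 330.0,
}

#: Signed band-power effect directions: (biometric, band, region) -> multiplier.
#: Region "all" applies to every channel.  Directions follow the consistent
#: per-channel findings for fatigue and stress committees and the classic
#: mind-wandering signature (theta/delta up, alpha/beta down).
DEFAULT_EFFECTS: dict[tuple[str, str, str], float] = {
    # fatigue: frontal gamma up, fronto-central alpha down
    ("fatigue", "gamma", "frontal"): 0.6,
    ("fatigue", "alpha", "fronto-central"): -0.4,
    # stress: theta up pre-frontally/centrally/centro-parietally, frontal gamma
    # up; fronto-central delta, frontal beta and widespread alpha down
    ("stress", "theta", "pre-frontal"): 0.5,
    ("stress", "theta", "central"): 0.5,
    ("stress", "theta", "centro-parietal"): 0.5,
    ("stress", "gamma", "frontal"): 0.4,
    ("stress", "delta", "fronto-central"): -0.3,
    ("stress", "beta", "frontal"): -0.3,
    ("stress", "alpha", "pre-frontal"): -0.4,
    ("stress", "alpha", "fronto-central"): -0.4,
    ("stress", "alpha", "central"): -0.4,
    ("stress", "alpha", "centro-parietal"): -0.4,
    # mind-wandering (attention == 0): theta/delta up, alpha/beta down
    ("mind_wandering", "theta", "all"): 0.4,
    ("mind_wandering", "delta", "all"): 0.4,
    ("mind_wandering", "alpha", "all"): -0.4,
    ("mind_wandering", "beta", "all"): -0.4,
}

#: Baseline carrier RMS amplitude per band (arbitrary microvolt-like units,
#: roughly 1/f across band centers).
DEFAULT_BAND_AMPS = {
    "delta": 4.0,
    "theta": 3.0,
    "alpha": 3.0,
    "beta": 1.5,
    "gamma": 0.8,
    "high_gamma": 0.5,
}


def _rng(seed: int, *tags) -> np.random.Generator:
    """Independent deterministic stream keyed by seed plus string/int tags."""
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            keys.append(zlib.crc32(t.encode()) & 0x7FFFFFFF)
        else:
            keys.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(keys)


@dataclass
class BehaviorLink:
    """Coefficients linking latents to novel-task behavior.

    Accuracy: ``correct ~ Bernoulli(sigmoid(b0 + b . latents))``.
    Reaction time: ``rt = r0 + r . latents + N(0, rt_noise)`` truncated
    to (0, 2] s.  Latent order is (fatigue, stress, mind_wandering).
    """

    b0: float = 1.2
    b: tuple[float, float, float] = (-1.5, -0.8, -0.8)
    r0: float = 0.70
    r: tuple[float, float, float] = (0.35, 0.20, 0.15)
    rt_noise: float = 0.12


@dataclass
class SubjectProfile:
    """Per-subject generative parameters; same seed => identical recordings."""

    seed: int
    band_amps: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPS))
    effects: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    pink_amp: float = 2.0
    amp_jitter: float = 0.1           # per-channel baseline variability (frac)
    # ECG / HRV
    rr_mean: float = 0.9              # s
    lf_base: float = 0.012            # s, LF RR modulation at zero stress
    lf_gain: float = 0.045            # s per unit stress
    hf_base: float = 0.050            # s, HF RR modulation at zero stress
    hf_gain: float = 0.040            # s per unit stress (subtracted)
    rr_jitter: float = 0.004          # s, per-beat white jitter
    ecg_noise: float = 0.02           # waveform additive noise RMS
    # latent dynamics
    stress_levels: dict[str, float] = field(default_factory=lambda: {
        "breath_count": 0.10, "nback1": 0.50, "nback3": 0.90,
        "threat_detection": 0.50,
    })
    fatigue_caps: dict[str, float] = field(default_factory=lambda: {
        "breath_count": 0.15, "nback1": 0.60, "nback3": 1.00,
        "threat_detection": 0.80,
    })
    mw_bout_mean: float = 20.0        # s, mean mind-wandering bout
    attentive_run_mean: float = 60.0  # s, mean attentive run
    behavior: BehaviorLink = field(default_factory=BehaviorLink)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.band_amps.values()):
            raise ValueError("baseline band amplitudes must be > 0")
        if not (0.5 <= self.rr_mean <= 1.5):
            raise ValueError("rr_mean must lie in [0.5, 1.5] s")

    def with_(self, **kw) -> "SubjectProfile":
        return replace(self, **kw)


def default_profile(seed: int = 0, **overrides) -> SubjectProfile:
    return SubjectProfile(seed=seed, **overrides)


@dataclass
class LatentStateTraject:
    """Ground-truth latent states on a regular time grid.

    ``fatigue`` and ``stress`` are in [0, 1]; ``attention`` is binary per
    sample (0 during mind-wandering bouts); ``mw_events`` are the button
    presses that terminate mind-wandering bouts.
    """

    times: np.ndarray
    fatigue: np.ndarray
    stress: np.ndarray
    attention: np.ndarray
    mw_events: list[float]
    task: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for arr in (self.fatigue, self.stress):
            if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
                raise ValueError("latents must lie in [0, 1]")
        if not np.all(np.isin(self.attention, (0, 1))):
            raise ValueError("attention must be binary")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def at(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """Latents sampled at arbitrary times (attention: previous-value)."""
        t = np.asarray(t, float)
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1,
                      0, len(self.times) - 1)
        return {
            "fatigue": np.interp(t, self.times, self.fatigue),
            "stress": np.interp(t, self.times, self.stress),
            "attention": self.attention[idx].astype(float),
        }


def generate_latents(task_kind: str, duration: float,
                     profile: SubjectProfile, *,
                     tag: str = "") -> LatentStateTraject:
    """Latent fatigue/stress/attention trajectories for one task.

    Fatigue ramps linearly from 0 to a task-specific cap over time on task;
    stress steps to a load-dependent level at task onset (ordering
    breath_count < nback1 < nback3 by construction); attention alternates
    between attentive runs and mind-wandering bouts only during
    breath-count, with a button press at the end of each bout.
    """
    if task_kind not in TASK_KINDS:
        raise ValueError(f"unknown task_kind {task_kind!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    name = f"{task_kind}:{tag}" if tag else task_kind
    dt = 0.1
    times = np.arange(0.0, duration + dt / 2, dt)
    fatigue = np.clip(
        profile.fatigue_caps[task_kind] * times / duration, 0.0, 1.0)
    level = profile.stress_levels[task_kind]
    if task_kind == "threat_detection":
        rng = _rng(profile.seed, "latents", name)
        phase = rng.uniform(0, 2 * np.pi)
        stress = np.clip(
            level + 0.25 * np.sin(2 * np.pi * times / (duration / 2) + phase),
            0.02, 0.98)
    else:
        stress = np.full_like(times, level)
    attention = np.ones_like(times)
    mw_events: list[float] = []
    if task_kind == "breath_count":
        rng = _rng(profile.seed, "latents", name)
        t = rng.exponential(profile.attentive_run_mean)  # first attentive run
        while t < duration:
            bout = 4.0 + rng.exponential(max(profile.mw_bout_mean - 4.0, 1.0))
            end = min(t + bout, duration)
            attention[(times >= t) & (times < end)] = 0.0
            if end < duration:
                mw_events.append(float(end))
            t = end + rng.exponential(profile.attentive_run_mean)
    return LatentStateTraject(times, fatigue, stress, attention,
                              mw_events, task=name)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, min(hi, 0.999 * fs / 2)],
                        btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y ** 2))
    return y / max(rms, 1e-12)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f (power) noise via spectral shaping.

    Normalized by the *expected* RMS of the shaped spectrum, not the
    realized one: the realized total is dominated by a handful of
    ultra-low-frequency bins, and dividing by it would imprint a random
    per-recording gain on every band.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0)
    f[0] = f[1]
    w = 1.0 / np.sqrt(f)        # power ~ 1/f
    spec *= w
    mult = np.full(w.size, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    expected_ms = float((mult * w ** 2).sum()) / n
    y = np.fft.irfft(spec, n)
    return y / np.sqrt(expected_ms)


def synthesize_eeg(latents: LatentStateTraject, profile: SubjectProfile,
                   n_channels: int = 29, fs: float = 500.0, *,
                   channels: list[str] | None = None,
                   bands: BandTable = EEG_BANDS,
                   line_noise_amp: float = 0.0,
                   blink_rate: float = 0.0,
                   bad_channel: str | None = None) -> Recording:
    """Multichannel EEG whose band powers track the latent states.

    Each channel sums one band-limited noise carrier per spectral band,
    amplitude-modulated as ``baseline * (1 + sum(effect * latent))`` using
    the profile's signed (biometric, band, region) table, plus a 1/f
    background.  Optional artifacts: a 60 Hz line tone, blink-like frontal
    transients, and one designated high-power "bad" channel.
    """
    if channels is None:
        if n_channels < 2:
            raise ValueError("need at least 2 channels")
        channels = list(EEG_CHANNELS[:n_channels])
    max_hi = max(b.hi for b in bands)
    if fs < 2 * max_hi:
        raise ValueError(
            f"fs={fs} too low for band up to {max_hi} Hz (need >= {2 * max_hi})")
    n = int(round(latents.duration * fs))
    t = np.arange(n) / fs
    lat = latents.at(t)
    latent_series = {
        "fatigue": lat["fatigue"],
        "stress": lat["stress"],
        "mind_wandering": 1.0 - lat["attention"],
    }
    data = np.zeros((len(channels), n))
    for ci, ch in enumerate(channels):
        grp = GROUP_OF_CHANNEL.get(ch, "all")
        rng = _rng(profile.seed, "eeg", latents.task, ch)
        # baseline amplitudes are a stable subject trait: jitter is keyed by
        # channel and band only, never by task, so tasks differ only through
        # the latents (and noise realizations)
        amp_rng = _rng(profile.seed, "amps", ch)
        x = profile.pink_amp * _pink_noise(rng, n)
        for band in bands:
            base = profile.band_amps.get(band.name, 1.0)
            base = base * (1.0 + profile.amp_jitter * amp_rng.standard_normal())
            mod = np.ones(n)
            for bio, series in latent_series.items():
                for g in (grp, "all"):
                    eff = profile.effects.get((bio, band.name, g), 0.0)
                    if eff:
                        mod = mod + eff * series
            carrier = _bandpass_noise(rng, n, fs, band.lo, band.hi)
            x = x + carrier * base * np.clip(mod, 0.05, None)
        data[ci] = x

    meta: dict = {"latents": latents, "task": latents.task}
    if line_noise_amp > 0:
        rng = _rng(profile.seed, "line", latents.task)
        data += line_noise_amp * np.sin(
            2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        meta["line_noise_amp"] = line_noise_amp
    blink_times: list[float] = []
    if blink_rate > 0:
        rng = _rng(profile.seed, "blinks", latents.task)
        n_blinks = rng.poisson(blink_rate * latents.duration)
        blink_times = sorted(rng.uniform(1.0, latents.duration - 1.0,
                                         size=n_blinks).tolist())
        wave = _blink_train(t, blink_times)
        gains = {"pre-frontal": 1.0, "frontal": 0.4}
        for ci, ch in enumerate(channels):
            g = gains.get(GROUP_OF_CHANNEL.get(ch, ""), 0.03)
            data[ci] += 30.0 * g * wave
        meta["blink_times"] = blink_times
    if bad_channel is not None:
        bi = channels.index(bad_channel)
        rng = _rng(profile.seed, "bad", latents.task)
        data[bi] += 20.0 * np.std(data[bi]) * rng.standard_normal(n)
        meta["bad_channel"] = bad_channel

    events = [(e, "mw_event") for e in latents.mw_events]
    return Recording(data=data, fs=fs, channel_names=list(channels),
                     channel_roles=["EEG"] * len(channels),
                     events=events, meta=meta)


def _blink_train(t: np.ndarray, blink_times: list[float]) -> np.ndarray:
    wave = np.zeros_like(t)
    for bt in blink_times:
        wave += np.exp(-0.5 * ((t - bt) / 0.1) ** 2)
    return wave


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def _qrs_template(fs: float, width: float = 0.012) -> np.ndarray:
    """Mexican-hat spike resembling a QRS complex (unit peak)."""
    half = int(round(0.06 * fs))
    tt = np.arange(-half, half + 1) / fs
    return (1 - (tt / width) ** 2) * np.exp(-0.5 * (tt / width) ** 2)


def synthesize_ecg(latents: LatentStateTraject, profile: SubjectProfile,
                   fs: float = 500.0) -> Recording:
    """Single-lead ECG with stress-modulated RR-interval dynamics.

    RR(t) = rr_mean + a_LF(t) sin(2*pi*0.1 t + phi) + a_HF(t) sin(2*pi*0.3 t
    + psi) + jitter, with a_LF increasing and a_HF decreasing in the stress
    latent.  True beat times are stored in ``meta['beat_times']``.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz for QRS morphology")
    rng = _rng(profile.seed, "ecg", latents.task)
    phi, psi = rng.uniform(0, 2 * np.pi, size=2)
    duration = latents.duration
    beats = []
    tb = 0.3
    while tb < duration:
        beats.append(tb)
        s = float(latents.at(np.array([tb]))["stress"][0])
        a_lf = profile.lf_base + profile.lf_gain * s
        a_hf = max(profile.hf_base - profile.hf_gain * s, 0.0)
        rr = (profile.rr_mean
              + a_lf * np.sin(2 * np.pi * 0.1 * tb + phi)
              + a_hf * np.sin(2 * np.pi * 0.3 * tb + psi)
              + profile.rr_jitter * rng.standard_normal())
        tb += float(np.clip(rr, 0.3, 2.0))
    beat_times = np.array(beats)

    n = int(round(duration * fs))
    x = profile.ecg_noise * rng.standard_normal(n)
    tmpl = _qrs_template(fs)
    half = (len(tmpl) - 1) // 2
    for bt in beat_times:
        i = int(round(bt * fs))
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        x[lo:hi] += tmpl[half - (i - lo): half + (hi - i)]
    meta = {"latents": latents, "task": latents.task,
            "beat_times": beat_times, "rr_true": np.diff(beat_times)}
    return Recording(data=x[None, :], fs=fs, channel_names=["ECG"],
                     channel_roles=["ECG"], meta=meta)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def synthesize_behavior(latents: LatentStateTraject, profile: SubjectProfile,
                        n_trials: int, *, null_mode: bool = False,
                        threat_type: str = "person", block: str = "test",
                        start: float = 5.0, spacing: float = 3.0,
                        trial_duration: float = 2.0,
                        link: BehaviorLink | None = None) -> pd.DataFrame:
    """Per-trial threat-detection behavior linked to (or independent of) latents.

    Returns a trial table with columns onset, duration, correct, rt,
    threat_type, block.  In null mode the link coefficients are zeroed, so
    behavior is independent of the latents by construction.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    link = link or profile.behavior
    onsets = start + np.arange(n_trials) * spacing
    if onsets[-1] + trial_duration > latents.duration + 1e-9:
        raise ValueError("trials exceed the latent trajectory span")
    rng = _rng(profile.seed, "behavior", latents.task, threat_type, block)
    lat = latents.at(onsets + trial_duration / 2)
    lvec = np.stack([lat["fatigue"], lat["stress"], 1.0 - lat["attention"]])
    b = np.zeros(3) if null_mode else np.asarray(link.b)
    r = np.zeros(3) if null_mode else np.asarray(link.r)
    p = 1.0 / (1.0 + np.exp(-(link.b0 + b @ lvec)))
    correct = (rng.uniform(size=n_trials) < p).astype(int)
    rt = link.r0 + r @ lvec + link.rt_noise * rng.standard_normal(n_trials)
    rt = np.clip(rt, 1e-3, trial_duration)
    return pd.DataFrame({
        "onset": onsets,
        "duration": trial_duration,
        "correct": correct,
        "rt": rt,
        "threat_type": threat_type,
        "block": block,
    })


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def make_session(profile: SubjectProfile, task_kind: str,
                 duration: float | None = None, fs: float = 500.0,
                 n_channels: int = 29, *,
                 tag: str = "",
                 channels: list[str] | None = None,
                 with_eog: bool = True,
                 line_noise_amp: float = 0.0, blink_rate: float = 0.1,
                 bad_channel: str | None = None) -> Recording:
    """One task's combined EEG + EOG + ECG recording with event markers.

    EOG leads carry the blink train plus slow noise and serve as nuisance
    channels for artifact ranking; the ECG lead doubles as both the cardiac
    signal and a nuisance channel.  Ground truth (latents, beat times,
    blink times) is merged into ``meta``.
    """
    if duration is None:
        duration = SCALED_TASK_DURATIONS[task_kind]
    latents = generate_latents(task_kind, duration, profile, tag=tag)
    eeg = synthesize_eeg(latents, profile, n_channels=n_channels, fs=fs,
                         channels=channels, line_noise_amp=line_noise_amp,
                         blink_rate=blink_rate, bad_channel=bad_channel)
    ecg = synthesize_ecg(latents, profile, fs=fs)
    n = min(eeg.n_samples, ecg.n_samples)
    data = [eeg.data[:, :n]]
    names = list(eeg.channel_names)
    roles = list(eeg.channel_roles)
    if with_eog:
        rng = _rng(profile.seed, "eog", latents.task)
        t = np.arange(n) / fs
        blink = _blink_train(t, eeg.meta.get("blink_times", []))
        for lead in ("EOG1", "EOG2"):
            noise = signal.sosfiltfilt(
                signal.butter(2, 8.0, btype="low", fs=fs, output="sos"),
                rng.standard_normal(n))
            data.append((60.0 * blink + 5.0 * noise)[None, :])
            names.append(lead)
            roles.append("EOG")
    data.append(ecg.data[:, :n])
    names.append("ECG")
    roles.append("ECG")
    meta = dict(eeg.meta)
    meta.update({k: ecg.meta[k] for k in ("beat_times", "rr_true")})
    events = [(0.0, f"{task_kind}_start")] + list(eeg.events) \
        + [(n / fs, f"{task_kind}_end")]
    return Recording(data=np.vstack(data), fs=fs, channel_names=names,
                     channel_roles=roles, events=sorted(events), meta=meta)
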