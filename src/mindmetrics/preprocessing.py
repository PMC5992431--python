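"""Artifact-removal pipeline for raw EEG/ECG recordings.

Stages, in order: basic filtering (60 Hz band-stop, 0.1 Hz high-pass, DC
removal, average re-reference of the EEG channels), single-pass rejection
of channels with outlying broadband spectral power, ICA-based artifact
removal (components ranked by correlation with nuisance leads, then
iteratively retained on the noise list only while their removal improves a
signal-quality index), spherical-spline interpolation of rejected channels
and moving-average drift correction.

The signal-quality index is a pluggable contract: any callable mapping a
Recording to a scalar where *lower is better*.  The default proxy scores
non-physiological spectral power (59-61 Hz plus everything above 100 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal

from .recording import Recording

logger = logging.getLogger(__name__)

#: An IC stays on the noise list only if removing it changes the quality
#: index by no more than this (a decrease means a quality increase).
SQI_THRESHOLD = -0.001
#: At least this fraction of ICs must survive the rejection loop.
MIN_IC_KEEP_FRACTION = 0.25
#: Moving-average drift-correction windows, in samples.
EEG_DETREND_WINDOW = 1000
ECG_DETREND_WINDOW = 50


# ---------------------------------------------------------------------------
# Basic filtering
# ---------------------------------------------------------------------------

def basic_filters(rec: Recording) -> Recording:
    """Band-stop 59-61 Hz, high-pass 0.1 Hz, DC removal, average re-reference.

    Both filters are applied spectrally (zero-phase by construction): the
    59-61 Hz bins are nulled and frequencies below 0.1 Hz are rolled off
    with a raised cosine from 0.05 Hz.  A time-domain IIR high-pass with a
    0.1 Hz corner at these sampling rates is numerically fragile (poles at
    the unit circle); the spectral form is exact and transient-free.  The
    average reference is the instantaneous mean of the retained EEG
    channels only; ECG/EOG/AUX channels are filtered but never enter the
    reference.
    """
    if rec.fs <= 122:
        raise ValueError("fs must exceed 122 Hz for the 59-61 Hz band-stop")
    out = rec.copy()
    n = out.n_samples
    f = np.fft.rfftfreq(n, 1.0 / rec.fs)
    gain = np.ones_like(f)
    gain[(f >= 59.0) & (f <= 61.0)] = 0.0               # line-noise notch
    lo, hi = 0.05, 0.1                                  # high-pass roll-off
    gain[f < lo] = 0.0
    ramp = (f >= lo) & (f < hi)
    gain[ramp] = 0.5 * (1 - np.cos(np.pi * (f[ramp] - lo) / (hi - lo)))
    x = np.fft.irfft(np.fft.rfft(out.data, axis=1) * gain, n, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    eeg = out.indices("EEG")
    if eeg.size:
        ref = x[eeg].mean(axis=0)
        x[eeg] -= ref
    out.data = x
    return out


# ---------------------------------------------------------------------------
# Channel rejection
# ---------------------------------------------------------------------------

def _normalized_log_powers(rec: Recording, idx: np.ndarray,
                           lo: float = 1.0, hi: float = 250.0) -> np.ndarray:
    """Per-channel broadband power, median-normalized then log-transformed."""
    hi = min(hi, rec.fs / 2)
    f, p = signal.periodogram(rec.data[idx], fs=rec.fs, axis=1)
    mask = (f >= lo) & (f <= hi)
    tot = p[:, mask].sum(axis=1)
    med = np.median(tot)
    return np.log10(tot / max(med, 1e-300) + 1e-300)


def reject_channels(rec: Recording) -> tuple[Recording, list[str]]:
    """Flag EEG channels whose normalized 1-250 Hz power exceeds mean + 3 SD.

    Single pass; flagged channels are recorded in ``meta['rejected_channels']``
    and excluded from later averaging/ICA but not dropped from the array.
    """
    eeg = rec.indices("EEG")
    if eeg.size < 4:
        raise ValueError("need at least 4 EEG channels for outlier rejection")
    z = _normalized_log_powers(rec, eeg)
    thresh = z.mean() + 3 * z.std()
    bad = [rec.channel_names[eeg[i]] for i in np.where(z > thresh)[0]]
    if len(bad) == eeg.size:
        raise RuntimeError("channel rejection removed every EEG channel")
    out = rec.copy()
    out.meta["rejected_channels"] = bad
    return out, bad


def retained_eeg_indices(rec: Recording) -> np.ndarray:
    bad = set(rec.meta.get("rejected_channels", []))
    return np.array([i for i in rec.indices("EEG")
                     if rec.channel_names[i] not in bad], dtype=int)


# ---------------------------------------------------------------------------
# ICA decomposition and artifact rejection
# ---------------------------------------------------------------------------

@dataclass
class ICDecomposition:
    """Linear unmixing of the retained EEG channels.

    ``mixing @ sources`` reconstructs the decomposed data (plus the stored
    per-channel mean).  ``noise_rank`` orders components by nuisance
    correlation, worst first; ``rejected`` is the final noise set.
    """

    mixing: np.ndarray            # channels x components
    sources: np.ndarray           # components x samples
    channel_indices: np.ndarray   # rows of the parent Recording decomposed
    mean: np.ndarray              # per-channel mean removed before ICA
    noise_rank: list[int] = field(default_factory=list)
    rank_scores: list[float] = field(default_factory=list)
    rejected: set[int] = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self, exclude: set[int] | None = None) -> np.ndarray:
        """Back-project sources to channel space, optionally excluding ICs."""
        keep = np.array([i for i in range(self.n_components)
                         if not exclude or i not in exclude], dtype=int)
        out = self.mixing[:, keep] @ self.sources[keep]
        return out + self.mean[:, None]


def decompose(rec: Recording, n_components: int | None = None,
              seed: int = 0) -> ICDecomposition:
    """FastICA of the retained EEG channels.

    One component per retained channel, capped at the numerical rank of
    the data: average re-referencing leaves the EEG rank-deficient by one,
    and whitening a zero-variance direction makes the unmixing matrix
    blow up (and its pseudo-inverse collapse to zero).
    """
    from sklearn.decomposition import FastICA

    idx = retained_eeg_indices(rec)
    x = rec.data[idx]
    mean = x.mean(axis=1)
    centered = x - mean[:, None]
    ev = np.linalg.eigvalsh(centered @ centered.T)
    rank = int(np.sum(ev > max(ev.max(), 1e-300) * 1e-10))
    n_components = min(n_components or idx.size, rank)
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=500, tol=1e-4)
    sources = ica.fit_transform(centered.T).T
    return ICDecomposition(mixing=ica.mixing_, sources=sources,
                           channel_indices=idx, mean=mean)


def rank_noise_components(ics: ICDecomposition,
                          nuisance: Recording | np.ndarray) -> ICDecomposition:
    """Rank ICs by descending max |Pearson r| against any nuisance channel.

    Zero-variance components rank below every finite-correlation component.
    """
    nu = nuisance.data if isinstance(nuisance, Recording) else np.asarray(nuisance)
    if nu.ndim == 1:
        nu = nu[None, :]
    if nu.shape[0] == 0:
        raise ValueError("need at least one nuisance channel")
    n = min(nu.shape[1], ics.sources.shape[1])
    scores = []
    for k in range(ics.n_components):
        s = ics.sources[k, :n]
        if s.std() == 0:
            scores.append(-1.0)
            continue
        r = max(abs(np.corrcoef(s, nu[j, :n])[0, 1])
                for j in range(nu.shape[0]) if nu[j, :n].std() > 0)
        scores.append(float(r))
    order = sorted(range(ics.n_components), key=lambda k: -scores[k])
    ics.noise_rank = order
    ics.rank_scores = [scores[k] for k in order]
    return ics


def iterative_ic_rejection(
    ics: ICDecomposition,
    quality_index: Callable[[np.ndarray], float],
    *,
    threshold: float = SQI_THRESHOLD,
    min_keep_fraction: float = MIN_IC_KEEP_FRACTION,
) -> ICDecomposition:
    """Greedy noise-component selection under a quality index.

    Components are visited in ``noise_rank`` order.  Each is tentatively
    added to the noise list; if the quality index of the reconstruction
    without the current noise set changes by more than ``threshold``
    relative to the previous state (i.e. quality did not improve), it is
    taken back off the list.  The loop stops once every component has been
    tried or only ``min_keep_fraction`` of the components remain unrejected.

    ``quality_index`` receives the reconstructed channels x samples array;
    lower scores mean better quality.
    """
    if not ics.noise_rank:
        raise ValueError("noise_rank must be populated (run rank_noise_components)")
    n = ics.n_components
    max_reject = n - int(np.ceil(min_keep_fraction * n))
    rejected: set[int] = set()
    current = quality_index(ics.reconstruct(exclude=rejected))
    if not np.isfinite(current):
        raise RuntimeError("quality index returned a non-finite baseline score")
    for comp in ics.noise_rank:
        if len(rejected) >= max_reject:
            break
        trial = rejected | {comp}
        score = quality_index(ics.reconstruct(exclude=trial))
        if not np.isfinite(score):
            raise RuntimeError(f"quality index non-finite when removing IC {comp}")
        if score - current <= threshold:
            rejected = trial
            current = score
    ics.rejected = rejected
    return ics


def default_quality_index(fs: float) -> Callable[[np.ndarray], float]:
    """Default SQI proxy: summed non-physiological spectral power.

    Scores the 59-61 Hz line band plus all power above 100 Hz (when
    resolvable); lower is better, matching the convention that a change
    below -0.001 marks a quality increase.
    """

    def sqi(data: np.ndarray) -> float:
        f, p = signal.periodogram(data, fs=fs, axis=1)
        mask = ((f >= 59.0) & (f <= 61.0)) | (f > 100.0)
        denom = p.sum() + 1e-300
        return float(p[:, mask].sum() / denom)

    return sqi


def apply_ic_rejection(rec: Recording, ics: ICDecomposition) -> Recording:
    """Back-project the retained (non-noise) components into the recording."""
    out = rec.copy()
    out.data[ics.channel_indices] = ics.reconstruct(exclude=ics.rejected)
    out.meta["rejected_ics"] = sorted(ics.rejected)
    return out


# ---------------------------------------------------------------------------
# Interpolation and drift correction
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window in samples)."""
    n = x.shape[-1]
    half = window // 2
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1),
                  axis=-1)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def interpolate_and_detrend(rec: Recording,
                            rejected: list[str] | None = None) -> Recording:
    """Spherical-spline interpolation of rejected channels, then drift removal.

    Rejected EEG channels are rebuilt from the retained ones via
    spherical-spline interpolation on the standard 10-20 montage; with
    fewer than 3 retained neighbors the fallback is inverse-distance
    weighting (logged).  Every channel then has its centered moving average
    subtracted: window 1000 samples for EEG/EOG/AUX, 50 samples for ECG.
    """
    out = rec.copy()
    if rejected is None:
        rejected = rec.meta.get("rejected_channels", [])
    if rejected:
        retained = retained_eeg_indices(rec)
        if retained.size >= 3:
            out.data = _spline_interpolate(out, rejected)
        else:
            logger.warning("fewer than 3 retained EEG channels; "
                           "using inverse-distance interpolation")
            out.data = _idw_interpolate(out, rejected)
        out.meta["interpolated_channels"] = list(rejected)
    for i, role in enumerate(out.channel_roles):
        window = ECG_DETREND_WINDOW if role == "ECG" else EEG_DETREND_WINDOW
        out.data[i] = out.data[i] - _moving_average(out.data[i], window)
    return out


def _montage_positions(names: list[str]) -> dict[str, np.ndarray]:
    import mne

    montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    return {n: pos[n] for n in names if n in pos}


def _spline_interpolate(rec: Recording, rejected: list[str]) -> np.ndarray:
    import mne

    eeg = rec.indices("EEG")
    names = [rec.channel_names[i] for i in eeg]
    info = mne.create_info(names, rec.fs, ch_types="eeg", verbose="error")
    raw = mne.io.RawArray(rec.data[eeg] * 1e-6, info, verbose="error")
    raw.set_montage("standard_1020", on_missing="raise", verbose="error")
    raw.info["bads"] = [b for b in rejected if b in names]
    raw.interpolate_bads(reset_bads=True, verbose="error")
    data = rec.data.copy()
    data[eeg] = raw.get_data() * 1e6
    return data


def _idw_interpolate(rec: Recording, rejected: list[str]) -> np.ndarray:
    eeg = rec.indices("EEG")
    names = [rec.channel_names[i] for i in eeg]
    pos = _montage_positions(names)
    good = [n for n in names if n not in rejected and n in pos]
    data = rec.data.copy()
    for b in rejected:
        if b not in pos or not good:
            continue
        d = np.array([np.linalg.norm(pos[b] - pos[g]) for g in good])
        w = 1.0 / np.maximum(d, 1e-6) ** 2
        w /= w.sum()
        bi = rec.channel_names.index(b)
        gi = [rec.channel_names.index(g) for g in good]
        data[bi] = w @ data[gi]
    return data


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess(rec: Recording, *,
               quality_index: Callable[[np.ndarray], float] | None = None,
               ica_seed: int = 0, run_ica: bool = True) -> Recording:
    """Run the full artifact-removal chain on one recording.

    Returns a cleaned Recording whose ``meta`` holds the report: rejected
    channels, rejected ICs, and the quality-index proxy used.
    """
    out = basic_filters(rec)
    out, bad = reject_channels(out)
    if run_ica:
        nuisance_idx = np.concatenate([out.indices("EOG"), out.indices("ECG"),
                                       out.indices("AUX")])
        if nuisance_idx.size:
            ics = decompose(out, seed=ica_seed)
            ics = rank_noise_components(ics, out.data[nuisance_idx])
            qi = quality_index or default_quality_index(out.fs)
            ics = iterative_ic_rejection(ics, qi)
            out = apply_ic_rejection(out, ics)
        else:
            logger.info("no nuisance channels; skipping IC rejection")
    out = interpolate_and_detrend(out, bad)
    if not np.all(np.isfinite(out.data)):
        raise RuntimeError("non-finite values after preprocessing")
    return out
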