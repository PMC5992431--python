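"""ECG R-peak detection and HRV spectral stress features.

The RR-interval (tachogram) spectrum indexes autonomic balance: power at
and below ~0.08 Hz reflects sympathetic influence, 0.15-0.4 Hz
parasympathetic.  Two feature modes are provided: integrated power in the
physiological VLF/LF/HF bands, and 0.1 Hz bins spanning 0.01-0.4 Hz.

Because VLF power (0.01 Hz) is unresolvable inside a 10 s training bin,
per-bin cardiac features are computed from a longer centered HRV context
window (default 120 s, clipped at the recording edges) and assigned to the
bin's timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import HRV_BANDS
from .recording import Recording

#: Physiological RR-interval gate after cleaning, in seconds.
RR_MIN, RR_MAX = 0.3, 2.0
#: HRV resampling rate for spectral analysis (Hz).
HRV_RESAMPLE_FS = 4.0
#: Default HRV context window per feature bin (s).
DEFAULT_CONTEXT = 120.0
#: 0.1 Hz bin edges of the binned spectral mode.
PS1_EDGES = (0.01, 0.1, 0.2, 0.3, 0.4)


@dataclass
class BeatSeries:
    """Strictly increasing R-peak times and the RR intervals between them."""

    peak_times: np.ndarray
    flagged_gaps: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def rr(self) -> np.ndarray:
        return np.diff(self.peak_times)

    def in_window(self, start: float, end: float) -> "BeatSeries":
        m = (self.peak_times >= start) & (self.peak_times <= end)
        return BeatSeries(self.peak_times[m], self.flagged_gaps)


class UnusableSignalError(RuntimeError):
    """Raised when an ECG trace yields too few credible beats."""


def detect_r_peaks(ecg: np.ndarray, fs: float) -> BeatSeries:
    """Detect QRS complexes with a band-pass + squared-derivative detector.

    The trace is band-passed to 5-30 Hz, differentiated and squared, then
    smoothed over 120 ms; peaks above an adaptive threshold (40% of the
    90th percentile of the envelope) separated by at least 300 ms are kept
    and refined to the band-passed signal's local extremum.  Intervals
    below the physiological gate are merged; intervals above it are kept
    but flagged as gaps.
    """
    x = np.asarray(ecg, float)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    sos = sps.butter(3, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    env = np.convolve(np.gradient(bp) ** 2,
                      np.ones(int(0.12 * fs)) / int(0.12 * fs), mode="same")
    thresh = 0.4 * np.percentile(env, 90)
    if thresh <= 0 or env.max() <= 0:
        raise UnusableSignalError("flat or powerless ECG trace")
    peaks, _ = sps.find_peaks(env, height=thresh, distance=int(0.3 * fs))
    # refine to the sharpest deflection of the band-passed signal
    half = int(0.05 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half, x.size)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    times = np.unique(np.asarray(refined)) / fs
    # merge sub-physiological intervals (keep the first beat of the pair)
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= RR_MIN:
            keep.append(i)
    times = times[keep]
    if times.size < 5:
        raise UnusableSignalError(
            f"only {times.size} beats detected; signal unusable")
    rr = np.diff(times)
    gaps = [(float(times[i]), float(times[i + 1]))
            for i in np.where(rr > RR_MAX)[0]]
    return BeatSeries(times, flagged_gaps=gaps)


@dataclass
class HrvSpectrum:
    freqs: np.ndarray
    power: np.ndarray           # mean-square per bin of the tachogram (s^2)
    total_power: float          # variance of the interpolated RR series

    def band_power(self, lo: float, hi: float) -> float:
        m = (self.freqs >= lo) & (self.freqs < hi)
        return float(self.power[m].sum())

    def argmax_freq(self, lo: float = 0.01, hi: float = 0.5) -> float:
        m = (self.freqs >= lo) & (self.freqs < hi)
        return float(self.freqs[m][np.argmax(self.power[m])])


def hrv_spectrum(beats: BeatSeries, window: tuple[float, float] | None = None
                 ) -> HrvSpectrum:
    """Periodogram of the RR tachogram over a time window.

    The RR series (value RR[i] at the time of the bounding later peak) is
    resampled with a cubic spline onto a uniform 4 Hz grid spanning the
    window (splines avoid the sinc^2 low-pass bias of linear
    interpolation, which would depress HF power), linearly detrended, and
    Fourier transformed; bin powers sum to the detrended series'
    mean-square (Parseval).
    """
    from scipy.interpolate import CubicSpline

    if window is not None:
        beats = beats.in_window(*window)
    t = beats.peak_times
    if t.size < 8:
        raise ValueError("need at least 8 beats in the window")
    rr = np.diff(t)
    rt = t[1:]
    grid = np.arange(rt[0], rt[-1], 1.0 / HRV_RESAMPLE_FS)
    if grid.size < 16:
        raise ValueError("window too short for HRV spectral analysis")
    x = CubicSpline(rt, rr)(grid)
    x = sps.detrend(x, type="linear")
    n = x.size
    spec = np.fft.rfft(x)
    p = (np.abs(spec) ** 2) / n**2
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    f = np.fft.rfftfreq(n, 1.0 / HRV_RESAMPLE_FS)
    return HrvSpectrum(freqs=f, power=p, total_power=float(np.mean(x ** 2)))


def hrv_band_features(spectrum: HrvSpectrum, mode: str = "Ps2_bands"
                      ) -> np.ndarray:
    """HRV feature vector: 3 physiological bands or 4 x 0.1 Hz bins.

    ``Ps2_bands``: integrated power in VLF (0.01-0.04), LF (0.04-0.15) and
    HF (0.15-0.4) Hz.  ``Ps1_bins``: integrated power in [0.01,0.1),
    [0.1,0.2), [0.2,0.3), [0.3,0.4].
    """
    if spectrum.freqs[-1] < 0.4:
        raise ValueError("spectrum must cover 0.01-0.4 Hz")
    if mode == "Ps2_bands":
        return np.array([spectrum.band_power(b.lo, b.hi) for b in HRV_BANDS])
    if mode == "Ps1_bins":
        out = []
        for lo, hi in zip(PS1_EDGES[:-1], PS1_EDGES[1:]):
            if hi == PS1_EDGES[-1]:        # last bin closed at 0.4
                m = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
                out.append(float(spectrum.power[m].sum()))
            else:
                out.append(spectrum.band_power(lo, hi))
        return np.array(out)
    raise ValueError(f"unknown mode {mode!r}")


def lf_hf_ratio(spectrum: HrvSpectrum) -> float:
    lf = spectrum.band_power(0.04, 0.15)
    hf = spectrum.band_power(0.15, 0.40)
    return lf / max(hf, 1e-12)


def cardiac_window_features(beats: BeatSeries,
                            windows: list[tuple[float, float]],
                            mode: str = "Ps2_bands", *,
                            context: float = DEFAULT_CONTEXT,
                            recording_span: tuple[float, float] | None = None
                            ) -> list[np.ndarray | None]:
    """Per-bin HRV features from a longer centered context window.

    Each feature bin receives the band features of the HRV spectrum
    computed over ``context`` seconds centered on the bin (clipped to the
    recording span).  Bins whose context holds fewer than 8 beats yield
    ``None`` and should be dropped downstream.
    """
    if any(windows[i][0] > windows[i + 1][0] for i in range(len(windows) - 1)):
        raise ValueError("windows must be sorted by start time")
    if recording_span is None:
        recording_span = (float(beats.peak_times[0]),
                          float(beats.peak_times[-1]))
    lo_all, hi_all = recording_span
    out: list[np.ndarray | None] = []
    for (s, e) in windows:
        c = 0.5 * (s + e)
        # keep the context at full length near the edges by sliding it
        # inside the recording (constant spectral resolution along the
        # trace); it only shrinks when the recording itself is shorter
        if hi_all - lo_all <= context:
            lo, hi = lo_all, hi_all
        else:
            lo = min(max(c - context / 2, lo_all), hi_all - context)
            hi = lo + context
        try:
            spec = hrv_spectrum(beats, (lo, hi))
            out.append(hrv_band_features(spec, mode))
        except ValueError:
            out.append(None)
    return out
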