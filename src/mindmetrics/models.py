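"""Per-electrode binomial-logit GLM committees for the three biometrics.

Nine feature sets are defined (two for fatigue, four for stress, three for
attention).  For EEG-based sets one GLM is fitted per retained electrode
and the committee prediction is the mean of the member sigmoids; sets
based on ECG alone have a single member.  Fits use iteratively reweighted
least squares with a small ridge penalty on the slopes so that separable
training sets still yield finite coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .eeg_features import FeatureWindow, test_windows
from .cardiac_features import BeatSeries, cardiac_window_features, detect_r_peaks
from .recording import Recording

logger = logging.getLogger(__name__)

EPS_POWER = 1e-12
DEFAULT_RIDGE = 1e-4

ALL_BANDS = ("delta", "theta", "alpha", "beta", "gamma", "high_gamma")


@dataclass(frozen=True)
class FeatureSetSpec:
    """Definition of one biometric feature set."""

    id: str
    biometric: str                       # fatigue | stress | attention
    source: str                          # EEG_committee | ECG_only | EEG_plus_ECG
    eeg_bands: tuple[str, ...] = ()
    ratio: tuple[str, str] | None = None  # e.g. ("theta", "beta")
    ecg_mode: str | None = None          # Ps1_bins | Ps2_bands
    window: float = 10.0


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    "Pf1": FeatureSetSpec("Pf1", "fatigue", "EEG_committee",
                          eeg_bands=("theta", "alpha")),
    "Pf2": FeatureSetSpec("Pf2", "fatigue", "EEG_committee",
                          eeg_bands=ALL_BANDS),
    "Ps1": FeatureSetSpec("Ps1", "stress", "ECG_only", ecg_mode="Ps1_bins"),
    "Ps2": FeatureSetSpec("Ps2", "stress", "ECG_only", ecg_mode="Ps2_bands"),
    "Ps3": FeatureSetSpec("Ps3", "stress", "EEG_committee",
                          eeg_bands=ALL_BANDS),
    "Ps4": FeatureSetSpec("Ps4", "stress", "EEG_plus_ECG",
                          eeg_bands=ALL_BANDS, ecg_mode="Ps2_bands"),
    "Pa1": FeatureSetSpec("Pa1", "attention", "EEG_committee",
                          ratio=("theta", "beta"), window=6.0),
    "Pa2": FeatureSetSpec("Pa2", "attention", "EEG_committee",
                          eeg_bands=ALL_BANDS, window=6.0),
    "Pa3": FeatureSetSpec("Pa3", "attention", "EEG_committee",
                          eeg_bands=("delta", "theta", "alpha", "beta"),
                          window=6.0),
}


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def _eeg_features(w: FeatureWindow, spec: FeatureSetSpec,
                  channel: str) -> np.ndarray:
    ci = w.channel_names.index(channel)
    if spec.ratio is not None:
        num = w.powers[ci, w.band_names.index(spec.ratio[0])]
        den = w.powers[ci, w.band_names.index(spec.ratio[1])]
        if den <= EPS_POWER:
            logger.warning("near-zero %s power in ratio feature; guarding",
                           spec.ratio[1])
        return np.array([num / max(den, EPS_POWER)])
    bidx = [w.band_names.index(b) for b in spec.eeg_bands]
    return w.powers[ci, bidx]


def assemble_design(windows: list[FeatureWindow], spec: FeatureSetSpec,
                    channel: str | None = None, *, transform: str = "log"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and 0/1 labels for one electrode (or the ECG model).

    Labels map low/inattentive -> 0 and high/attentive -> 1.  Feature
    columns follow the set definition (band powers, theta/beta ratio, HRV
    band powers, or EEG + HRV concatenated); rows with missing cardiac
    features are dropped.  ``transform='log'`` applies log10(x + eps) to
    power-type features (the default used for fitting); ``'raw'`` leaves
    them untouched.
    """
    labeled = [w for w in windows if w.label in ("low", "high")]
    rows, ys = [], []
    for w in labeled:
        feats = []
        if spec.source in ("EEG_committee", "EEG_plus_ECG"):
            if channel is None:
                raise ValueError("channel required for EEG-based sets")
            feats.append(_eeg_features(w, spec, channel))
        if spec.source in ("ECG_only", "EEG_plus_ECG"):
            if w.cardiac is None:
                continue
            feats.append(np.asarray(w.cardiac, float))
        rows.append(np.concatenate(feats))
        ys.append(1.0 if w.label == "high" else 0.0)
    if not rows:
        raise ValueError("no labeled windows with complete features")
    X = np.vstack(rows)
    y = np.asarray(ys)
    if y.min() == y.max():
        raise ValueError("need both classes in the training windows")
    if transform == "log":
        X = np.log10(np.maximum(X, 0.0) + EPS_POWER)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    return X, y


# ---------------------------------------------------------------------------
# GLM fitting (ridge-penalized IRLS)
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeModel:
    """One electrode's logistic model on standardized features."""

    channel: str
    coef: np.ndarray              # [intercept, slopes...]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    pvalues: np.ndarray | None = None
    converged: bool = True
    feature_set: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.feature_mean) / self.feature_sd
        eta = self.coef[0] + Z @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def fit_glm(X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE, *,
            max_iter: int = 100, tol: float = 1e-8,
            channel: str = "", standardize: bool = True) -> ElectrodeModel:
    """Binomial-logit GLM via IRLS with a ridge penalty on the slopes.

    Coefficients maximize the binomial log-likelihood minus
    (ridge/2)*||slopes||^2; the intercept is unpenalized.  Convergence:
    max |delta coef| < 1e-8 within 100 iterations, else the model is
    flagged non-converged.  Wald p-values come from the inverse of the
    penalized information matrix.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more rows ({n}) than features ({d})")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = np.zeros(d), np.ones(d)
    Z = np.column_stack([np.ones(n), (X - mu) / sd])
    R = np.diag(np.concatenate([[0.0], np.full(d, ridge)]))
    b = np.zeros(d + 1)
    converged = False
    for _ in range(max_iter):
        eta = Z @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = Z.T @ (y - p) - R @ b
        info = (Z * w[:, None]).T @ Z + R
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        b = b + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not np.all(np.isfinite(b)):
        raise ConvergenceError("non-finite coefficients")
    eta = Z @ b
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1 - p), 1e-10, None)
    info = (Z * w[:, None]).T @ Z + R
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        zstat = np.divide(b, se, out=np.zeros_like(b), where=se > 0)
        pvals = 2 * stats.norm.sf(np.abs(zstat))
    except np.linalg.LinAlgError:
        pvals = None
    if not converged:
        logger.warning("IRLS did not converge for channel %r", channel)
    return ElectrodeModel(channel=channel, coef=b, feature_mean=mu,
                          feature_sd=sd, pvalues=pvals, converged=converged)


# ---------------------------------------------------------------------------
# Committee
# ---------------------------------------------------------------------------

@dataclass
class CommitteeModel:
    """Mean-aggregated set of per-electrode GLMs for one feature set."""

    spec: FeatureSetSpec
    members: list[ElectrodeModel]

    def predict_window(self, w: FeatureWindow, *, transform: str = "log"
                       ) -> float:
        vals = []
        for m in self.members:
            feats = []
            if self.spec.source in ("EEG_committee", "EEG_plus_ECG"):
                feats.append(_eeg_features(w, self.spec, m.channel))
            if self.spec.source in ("ECG_only", "EEG_plus_ECG"):
                if w.cardiac is None:
                    return np.nan
                feats.append(np.asarray(w.cardiac, float))
            x = np.concatenate(feats)
            if transform == "log":
                x = np.log10(np.maximum(x, 0.0) + EPS_POWER)
            vals.append(float(m.predict(x)[0]))
        return float(np.mean(vals))


@dataclass
class BiometricTrace:
    """Committee predictions in [0, 1] on a 1 s-stride timeline."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must align")

    def mean_in(self, start: float, end: float) -> float:
        m = (self.times >= start) & (self.times <= end)
        if not m.any():
            return np.nan
        return float(np.nanmean(self.values[m]))


def train_committee(windows: list[FeatureWindow], spec: FeatureSetSpec, *,
                    ridge: float = DEFAULT_RIDGE, transform: str = "log"
                    ) -> CommitteeModel:
    """Fit one GLM per retained electrode (single model for ECG-only sets).

    Electrodes whose fit does not converge are dropped from the committee
    with a warning; if every member fails the committee cannot be built.
    """
    if spec.source == "ECG_only":
        channels: list[str | None] = [None]
    else:
        channels = list(windows[0].channel_names)
    members = []
    for ch in channels:
        try:
            X, y = assemble_design(windows, spec, ch, transform=transform)
            m = fit_glm(X, y, ridge, channel=ch or "ECG")
        except (ValueError, ConvergenceError) as exc:
            logger.warning("dropping electrode %r from %s committee: %s",
                           ch, spec.id, exc)
            continue
        if not m.converged:
            logger.warning("dropping non-converged electrode %r from %s",
                           ch, spec.id)
            continue
        m.feature_set = spec.id
        members.append(m)
    if not members:
        raise RuntimeError(f"all members failed for feature set {spec.id}")
    return CommitteeModel(spec=spec, members=members)


def predict_trace(model: CommitteeModel, rec: Recording, *,
                  beats: BeatSeries | None = None, transform: str = "log",
                  hrv_context: float = 120.0) -> BiometricTrace:
    """Sliding-window committee predictions over a recording (1 s stride)."""
    spec = model.spec
    windows = test_windows(rec, spec.biometric)
    if spec.source in ("ECG_only", "EEG_plus_ECG"):
        if beats is None:
            ecg_idx = rec.indices("ECG")
            if ecg_idx.size == 0:
                raise ValueError("cardiac model requires an ECG channel")
            beats = detect_r_peaks(rec.data[ecg_idx[0]], rec.fs)
        feats = cardiac_window_features(
            beats, [(w.start, w.end) for w in windows],
            spec.ecg_mode, context=hrv_context,
            recording_span=(0.0, rec.duration))
        for w, f in zip(windows, feats):
            w.cardiac = f
    times = np.array([w.center for w in windows])
    vals = np.array([model.predict_window(w, transform=transform)
                     for w in windows])
    return BiometricTrace(times=times, values=vals)


# ---------------------------------------------------------------------------
# Feature consistency across subjects
# ---------------------------------------------------------------------------

def feature_consistency(subject_models: list[dict[str, ElectrodeModel]],
                        band_names: tuple[str, ...] = ALL_BANDS, *,
                        alpha: float = 0.05, min_fraction: float = 0.5
                        ) -> list[dict]:
    """(channel, band) coefficients consistently significant across subjects.

    Emits a row when a coefficient is Wald-significant at ``alpha`` with
    the same sign in strictly more than ``min_fraction`` of subjects.
    """
    if len(subject_models) < 2:
        raise ValueError("need at least 2 subjects")
    channels = sorted({ch for models in subject_models for ch in models})
    rows = []
    n_subj = len(subject_models)
    for ch in channels:
        for bi, band in enumerate(band_names):
            pos = neg = 0
            for models in subject_models:
                m = models.get(ch)
                if m is None or m.pvalues is None:
                    continue
                coef, p = m.coef[1 + bi], m.pvalues[1 + bi]
                if p < alpha:
                    if coef > 0:
                        pos += 1
                    elif coef < 0:
                        neg += 1
            for direction, count in (("+", pos), ("-", neg)):
                if count / n_subj > min_fraction:
                    rows.append({"channel": ch, "band": band,
                                 "direction": direction,
                                 "fraction_of_subjects": count / n_subj})
    return rows
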