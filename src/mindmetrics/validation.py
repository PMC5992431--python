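"""Level-1 and level-2 validation of the biometric committees.

Level 1: class-balanced k-fold cross-validation of discrete
classification, evaluated per channel and averaged across channels and
folds per subject (k = 10 for fatigue/stress, 3 for attention).

Level 2: leave-one-out scores on the training tasks give per-subject low
and high bounds, and predictions on a held-out moderate-load task (1-back)
check that the learned mapping is continuous: the intermediate task should
score strictly between the bounds (paired t-tests across subjects), and a
repeated-measures ANOVA over time bins probes for a time-on-task effect
(expected for fatigue, not for stress).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eeg_features import FeatureWindow
from .models import (BiometricTrace, CommitteeModel, FeatureSetSpec,
                     assemble_design, fit_glm, DEFAULT_RIDGE)

#: Cross-validation folds per biometric.
K_FOLDS = {"fatigue": 10, "stress": 10, "attention": 3}


# ---------------------------------------------------------------------------
# Balanced partitions and k-fold CV
# ---------------------------------------------------------------------------

def balanced_partitions(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign rows to k folds with equal per-class counts in every fold.

    Surplus rows (per class, beyond the largest multiple of k shared by
    both classes) are discarded at random with the given seed and marked
    -1.  Raises if the smaller class has fewer than k rows.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    counts = {c: int((y == c).sum()) for c in classes}
    m = min(counts.values()) // k
    if m == 0:
        raise ValueError(
            f"class too small for {k} folds: need >= {k} rows per class, "
            f"have {counts}")
    rng = np.random.default_rng(seed)
    folds = np.full(y.shape[0], -1, dtype=int)
    for c in classes:
        idx = rng.permutation(np.where(y == c)[0])[: m * k]
        folds[idx] = np.repeat(np.arange(k), m)
    return folds


@dataclass
class CVResult:
    biometric: str
    feature_set: str
    channels: list[str]
    per_channel_fold_accuracies: np.ndarray   # channels x k
    subject_accuracy: float
    n_windows: int = 0


def kfold_cv(windows: list[FeatureWindow], spec: FeatureSetSpec,
             k: int | None = None, seed: int = 0, *,
             ridge: float = DEFAULT_RIDGE, transform: str = "log"
             ) -> CVResult:
    """Balanced k-fold CV of one feature set, channel by channel.

    Every channel is trained and scored independently (threshold 0.5);
    the subject-level accuracy is the mean over channels and folds.
    """
    k = k or K_FOLDS[spec.biometric]
    if spec.source == "ECG_only":
        channels: list[str | None] = [None]
        names = ["ECG"]
    else:
        channels = list(windows[0].channel_names)
        names = list(channels)
    designs = [assemble_design(windows, spec, ch, transform=transform)
               for ch in channels]
    y0 = designs[0][1]
    folds = balanced_partitions(y0, k, seed)
    acc = np.zeros((len(channels), k))
    for ci, (X, y) in enumerate(designs):
        if not np.array_equal(y, y0):
            raise RuntimeError("inconsistent label vectors across channels")
        for j in range(k):
            train, test = folds != j, folds == j
            train &= folds >= 0
            model = fit_glm(X[train], y[train], ridge, standardize=True)
            pred = (model.predict(X[test]) >= 0.5).astype(float)
            acc[ci, j] = float(np.mean(pred == y[test]))
    return CVResult(biometric=spec.biometric, feature_set=spec.id,
                    channels=names, per_channel_fold_accuracies=acc,
                    subject_accuracy=float(acc.mean()),
                    n_windows=int((folds >= 0).sum()))


# ---------------------------------------------------------------------------
# Leave-one-out bounds
# ---------------------------------------------------------------------------

def loo_bounds(windows: list[FeatureWindow], spec: FeatureSetSpec, *,
               ridge: float = DEFAULT_RIDGE, transform: str = "log"
               ) -> tuple[float, float]:
    """Committee LOO mean scores of the low- and high-class windows.

    Each labeled window is scored by a committee trained on all other
    labeled windows; the means over the low and high classes bound the
    biometric's range on the training tasks.
    """
    if spec.source == "ECG_only":
        channels: list[str | None] = [None]
    else:
        channels = list(windows[0].channel_names)
    designs = [assemble_design(windows, spec, ch, transform=transform)
               for ch in channels]
    y = designs[0][1]
    n = y.size
    if min((y == 0).sum(), (y == 1).sum()) < 10:
        raise ValueError("need at least 10 windows per class for LOO bounds")
    scores = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        member_scores = []
        for X, _ in designs:
            m = fit_glm(X[mask], y[mask], ridge, standardize=True)
            member_scores.append(float(m.predict(X[i:i + 1])[0]))
        scores[i] = float(np.mean(member_scores))
        mask[i] = True
    return float(scores[y == 0].mean()), float(scores[y == 1].mean())


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def paired_t_test(a: np.ndarray, b: np.ndarray, tails: str = "two-sided"
                  ) -> tuple[float, float]:
    """Paired-sample t-test; tails in {'two-sided', 'greater', 'less'}.

    'greater' tests mean(a - b) > 0.  Zero-variance differences are
    degenerate: (0, 1) when the difference is identically zero, else
    (signed inf, nan).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("missing values not allowed")
    d = a - b
    if np.allclose(d.std(), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0 if tails == "two-sided" else 0.5
        return float(np.sign(d.mean()) * np.inf), float("nan")
    res = stats.ttest_rel(a, b, alternative=tails)
    return float(res.statistic), float(res.pvalue)


def repeated_measures_anova(matrix: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA over time bins (subjects x bins)."""
    from statsmodels.stats.anova import AnovaRM

    matrix = np.asarray(matrix, float)
    n_subj, n_bins = matrix.shape
    if n_subj < 2 or n_bins < 2:
        raise ValueError("need >= 2 subjects and >= 2 time bins")
    # degenerate: no variation across time bins at all (identical columns)
    scale = max(np.abs(matrix).max(), 1.0)
    if np.var(matrix.mean(axis=0)) < (1e-12 * scale) ** 2:
        return 0.0, 1.0
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_bins),
        "time": np.tile(np.arange(n_bins), n_subj),
        "value": matrix.ravel(),
    })
    res = AnovaRM(long, depvar="value", subject="subject",
                  within=["time"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


# ---------------------------------------------------------------------------
# Intermediate (1-back) regression test
# ---------------------------------------------------------------------------

@dataclass
class SubjectRegression:
    subject: str
    low_bound: float
    high_bound: float
    intermediate_score: float
    trace: BiometricTrace | None = None


@dataclass
class RegressionReport:
    biometric: str
    feature_set: str
    low_bound: float                  # mean across subjects
    high_bound: float
    intermediate_score: float
    t_low: tuple[float, float]        # intermediate > low bound
    t_high: tuple[float, float]       # high bound > intermediate
    time_effect: tuple[float, float]  # RM-ANOVA (F, p) over trace time bins
    per_subject: list[SubjectRegression] = field(default_factory=list)
    tails: str = "greater"


def intermediate_score(model: CommitteeModel, intermediate_rec, **kw) -> float:
    """Mean committee trace value on a held-out task recording."""
    from .models import predict_trace

    trace = predict_trace(model, intermediate_rec, **kw)
    return float(np.nanmean(trace.values))


def intermediate_regression_test(per_subject: list[SubjectRegression], *,
                                 biometric: str = "", feature_set: str = "",
                                 tails: str = "greater", n_time_bins: int = 5
                                 ) -> RegressionReport:
    """Cohort-level check that the held-out task scores between the bounds.

    Two paired t-tests across subjects (default one-tailed, directional):
    intermediate vs low bound, and high bound vs intermediate; both are
    expected significant at 0.025 (correcting for two comparisons) when
    the learned mapping is continuous.  Traces, when present, are averaged
    into ``n_time_bins`` equal bins per subject and fed to a one-way
    repeated-measures ANOVA for a time-on-task effect.
    """
    if not per_subject:
        raise ValueError("no subjects")
    low = np.array([s.low_bound for s in per_subject])
    high = np.array([s.high_bound for s in per_subject])
    mid = np.array([s.intermediate_score for s in per_subject])
    if len(per_subject) >= 3:
        t_low = paired_t_test(mid, low, tails=tails)
        t_high = paired_t_test(high, mid, tails=tails)
    else:
        t_low = t_high = (float("nan"), float("nan"))
    time_effect = (float("nan"), float("nan"))
    traces = [s.trace for s in per_subject if s.trace is not None]
    if len(traces) >= 2:
        mat = np.vstack([_binned(tr, n_time_bins) for tr in traces])
        time_effect = repeated_measures_anova(mat)
    return RegressionReport(
        biometric=biometric, feature_set=feature_set,
        low_bound=float(low.mean()), high_bound=float(high.mean()),
        intermediate_score=float(mid.mean()),
        t_low=t_low, t_high=t_high, time_effect=time_effect,
        per_subject=list(per_subject), tails=tails)


def _binned(trace: BiometricTrace, n_bins: int) -> np.ndarray:
    edges = np.linspace(trace.times[0], trace.times[-1] + 1e-9, n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        m = (trace.times >= edges[i]) & (trace.times < edges[i + 1])
        out[i] = np.nanmean(trace.values[m]) if m.any() else np.nan
    return out
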