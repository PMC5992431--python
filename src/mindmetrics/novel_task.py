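"""Level-3 validation: biometric-behavior correlation on a novel task.

Biometric traces are averaged over the temporal extent of each
threat-detection trial; performance (per-trial accuracy and reaction time)
is smoothed with trailing moving averages of 1-10 trials; the Pearson
correlation of the aligned series is tested against a permutation null
built by shuffling the raw per-trial performance 3,000 times and
re-applying the same smoothing.  A subject counts as 1 if the correlation
is significant for both threat types (collected on separate days), 0.5
for exactly one, 0 for neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import BiometricTrace

N_PERMUTATIONS = 3000
ALPHA = 0.05
MIN_TRIALS = 20
MAX_WINDOW = 10


def trial_biometric_means(trace: BiometricTrace, trials: pd.DataFrame
                          ) -> np.ndarray:
    """Mean trace value over each trial's [onset, onset + duration] span.

    Trials outside the trace span yield NaN (flagged missing; exclude
    downstream).  At the 1 s trace stride a 2 s trial averages at least
    two samples.
    """
    out = np.full(len(trials), np.nan)
    t0, t1 = trace.times[0], trace.times[-1]
    for i, (onset, dur) in enumerate(zip(trials["onset"], trials["duration"])):
        if onset < t0 - 1e-9 or onset + dur > t1 + 1e-9:
            continue
        out[i] = trace.mean_in(onset, onset + dur)
    return out


def moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Trailing moving average over trial order; length n - w + 1."""
    x = np.asarray(x, float)
    if not (1 <= w <= x.size):
        raise ValueError(f"window {w} invalid for {x.size} trials")
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


def moving_average_performance(trials: pd.DataFrame, w: int
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Trailing w-trial moving averages of accuracy and reaction time."""
    if not (1 <= w <= MAX_WINDOW):
        raise ValueError("window must be between 1 and 10 trials")
    if w > len(trials):
        raise ValueError("window exceeds the number of trials")
    return (moving_average(trials["correct"].to_numpy(float), w),
            moving_average(trials["rt"].to_numpy(float), w))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PermutationResult:
    window: int
    metric: str
    r_observed: float
    null: np.ndarray
    p: float
    significant: bool
    degenerate: bool = False


def permutation_test(biometric: np.ndarray, performance: np.ndarray, w: int,
                     n_iter: int = N_PERMUTATIONS, seed: int = 0, *,
                     metric: str = "", method: str = "pearson"
                     ) -> PermutationResult:
    """Permutation test of the smoothed biometric-performance correlation.

    ``biometric`` and ``performance`` are raw per-trial values.  Both are
    smoothed with the same trailing w-trial moving average; each null
    iteration shuffles the raw performance across trials before
    re-smoothing, so the null respects the serial correlation the
    smoothing induces.  Two-sided p with +1 smoothing:
    p = (1 + #{|r_null| >= |r_obs|}) / (n_iter + 1).
    """
    b = np.asarray(biometric, float)
    perf = np.asarray(performance, float)
    ok = np.isfinite(b) & np.isfinite(perf)
    b, perf = b[ok], perf[ok]
    n = b.size
    if n < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} trials after exclusions")
    if method == "spearman":
        b = stats.rankdata(b)
        perf_ranked = stats.rankdata(perf)
    else:
        perf_ranked = perf
    bs = moving_average(b, w)
    r_obs = _pearson(bs, moving_average(perf_ranked, w))
    if not np.isfinite(r_obs):
        return PermutationResult(w, metric, np.nan,
                                 np.full(n_iter, np.nan), 1.0,
                                 significant=False, degenerate=True)
    rng = np.random.default_rng(seed)
    # vectorized null: shuffle raw performance, re-smooth, correlate
    perm = np.array([rng.permutation(perf_ranked) for _ in range(n_iter)])
    if method == "spearman":
        perm = stats.rankdata(perm, axis=1)
    c = np.concatenate([np.zeros((n_iter, 1)), np.cumsum(perm, axis=1)],
                       axis=1)
    sm = (c[:, w:] - c[:, :-w]) / w
    bz = (bs - bs.mean())
    bnorm = np.sqrt((bz ** 2).sum())
    sz = sm - sm.mean(axis=1, keepdims=True)
    snorm = np.sqrt((sz ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null = (sz @ bz) / (snorm * bnorm)
    null = np.where(np.isfinite(null), null, 0.0)
    p = (1.0 + np.sum(np.abs(null) >= abs(r_obs))) / (n_iter + 1.0)
    return PermutationResult(window=w, metric=metric, r_observed=r_obs,
                             null=null, p=float(p),
                             significant=bool(p < ALPHA))


def evaluate_trace_against_trials(trace: BiometricTrace, trials: pd.DataFrame,
                                  windows: range = range(1, MAX_WINDOW + 1),
                                  n_iter: int = N_PERMUTATIONS, seed: int = 0
                                  ) -> list[PermutationResult]:
    """Permutation tests for both metrics over all smoothing windows."""
    bio = trial_biometric_means(trace, trials)
    out = []
    for metric, col in (("accuracy", "correct"), ("rt", "rt")):
        perf = trials[col].to_numpy(float)
        for w in windows:
            out.append(permutation_test(
                bio, perf, w, n_iter=n_iter,
                seed=seed + 1000 * w + (0 if metric == "accuracy" else 1),
                metric=metric))
    return out


def subject_significance(results_by_threat_type: dict[str, bool]) -> float:
    """0.5-subject counting rule over the two threat types.

    1 if the correlation is significant for both threat types, 0.5 for
    exactly one, 0 for neither.  Both types must be present.
    """
    expected = {"person", "object"}
    if set(results_by_threat_type) != expected:
        raise ValueError(f"need results for both threat types {expected}")
    n_sig = sum(bool(v) for v in results_by_threat_type.values())
    return {0: 0.0, 1: 0.5, 2: 1.0}[n_sig]


def proportion_significant_curve(per_subject: list[dict[str, dict[int, bool]]]
                                 ) -> dict[int, float]:
    """Proportion-of-subjects curve per smoothing window.

    ``per_subject`` maps, for each subject, threat type -> {window ->
    significant}.  Subjects missing a threat type are excluded.
    """
    curve: dict[int, float] = {}
    for w in range(1, MAX_WINDOW + 1):
        scores = []
        for subj in per_subject:
            if set(subj) != {"person", "object"}:
                continue
            scores.append(subject_significance(
                {tt: subj[tt].get(w, False) for tt in subj}))
        curve[w] = float(np.mean(scores)) if scores else np.nan
    return curve
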