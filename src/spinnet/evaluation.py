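"""Predictive-performance metrics and risk-group stratification.

Conventions: a *higher* predicted score always means *higher* risk (shorter
expected survival or higher disease probability).  Concordance is Harrell's
C over censoring-admissible pairs with prediction ties counted 0.5; AUC is
the midrank Mann-Whitney statistic.  Risk stratification sorts the test set
by predicted score, splits it into five nearly equal groups (remainder to
the highest-risk groups) and compares observed per-group disease ratios to
the ideal ratios obtained by packing all true cases into the highest-risk
groups first; MSPE is the mean squared difference across the five groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ranksums
from sklearn.metrics import roc_auc_score

from .errors import SpinError

N_GROUPS = 5


def concordance_index(prediction, time, event) -> float:
    """Harrell's C-index of a risk prediction against censored survival.

    A pair ``(i, j)`` with ``t_i < t_j`` is admissible when the earlier
    sample had the event; it is concordant when that sample also has the
    higher predicted risk.  Prediction ties contribute 0.5.
    """
    prediction = np.asarray(prediction, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=int).ravel()
    if not (prediction.shape == time.shape == event.shape):
        raise SpinError("prediction, time and event must have equal length")
    # admissible[i, j]: sample i failed strictly before sample j's time
    admissible = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_adm = admissible.sum()
    if n_adm == 0:
        raise SpinError("no comparable pair (need an event before another time)")
    concordant = (prediction[:, None] > prediction[None, :]) & admissible
    tied = (prediction[:, None] == prediction[None, :]) & admissible
    return float((concordant.sum() + 0.5 * tied.sum()) / n_adm)


def auc(score, label) -> float:
    """ROC AUC (midrank ties) of a risk score against a binary label."""
    score = np.asarray(score, dtype=float).ravel()
    label = np.asarray(label, dtype=int).ravel()
    if score.shape != label.shape:
        raise SpinError("score and label must have equal length")
    if len(set(label.tolist())) < 2:
        raise SpinError("AUC needs both classes present")
    return float(roc_auc_score(label, score))


def group_sizes(n: int, k: int = N_GROUPS) -> list[int]:
    """Split ``n`` into ``k`` nearly equal sizes, remainder to the first groups."""
    base, extra = divmod(n, k)
    return [base + 1 if i < extra else base for i in range(k)]


def stratify_five_groups(score) -> np.ndarray:
    """Assign each sample to one of five risk groups (0 = highest risk).

    Samples are sorted by predicted score descending (ties keep original
    order); with ``n = 5k + m`` the first ``m`` groups take ``k + 1``
    samples.
    """
    score = np.asarray(score, dtype=float).ravel()
    n = len(score)
    if n < N_GROUPS:
        raise SpinError(f"need at least {N_GROUPS} samples, got {n}")
    order = np.argsort(-score, kind="stable")
    sizes = group_sizes(n)
    groups = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        groups[order[start : start + size]] = g
        start += size
    return groups


def disease_ratios(groups, label) -> np.ndarray:
    """Observed fraction of true cases in each predicted-risk group."""
    groups = np.asarray(groups, dtype=int).ravel()
    label = np.asarray(label, dtype=int).ravel()
    if groups.shape != label.shape:
        raise SpinError("groups and label must have equal length")
    out = np.empty(N_GROUPS)
    for g in range(N_GROUPS):
        members = label[groups == g]
        if len(members) == 0:
            raise SpinError(f"group {g} is empty")
        out[g] = members.mean()
    return out


def ideal_disease_ratios(label, sizes=None) -> np.ndarray:
    """Best-achievable per-group disease ratios for the given case count.

    Groups are filled in risk order with all true cases first, then
    controls: a group is all-cases (ratio 1) until cases run out, the group
    where they run out gets the remainder, later groups get 0.
    """
    label = np.asarray(label, dtype=int).ravel()
    if sizes is None:
        sizes = group_sizes(len(label))
    sizes = list(map(int, sizes))
    if sum(sizes) != len(label):
        raise SpinError("group sizes must sum to the number of samples")
    cases = int(label.sum())
    out = np.empty(len(sizes))
    for g, size in enumerate(sizes):
        if size == 0:
            raise SpinError(f"group {g} is empty")
        take = min(cases, size)
        out[g] = take / size
        cases -= take
    return out


def mspe(observed, ideal) -> float:
    """Mean squared prediction error between observed and ideal ratios."""
    observed = np.asarray(observed, dtype=float).ravel()
    ideal = np.asarray(ideal, dtype=float).ravel()
    if observed.shape != ideal.shape:
        raise SpinError("ratio vectors must have equal length")
    return float(np.mean((observed - ideal) ** 2))


@dataclass
class StratificationResult:
    """Five-group risk stratification summary."""

    sizes: list[int]
    observed: np.ndarray
    ideal: np.ndarray
    mspe: float


def stratification_result(score, label) -> StratificationResult:
    """Full stratification: groups, observed/ideal ratios and MSPE."""
    groups = stratify_five_groups(score)
    sizes = group_sizes(len(np.asarray(score).ravel()))
    observed = disease_ratios(groups, label)
    ideal = ideal_disease_ratios(label, sizes)
    return StratificationResult(sizes, observed, ideal, mspe(observed, ideal))


def compare_repeats(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between repeat-level metrics."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if len(a) < 3 or len(b) < 3:
        raise SpinError("need at least 3 repeats per model")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all metric values identical; p-value is 1", stacklevel=2)
        return 1.0
    return float(ranksums(a, b).pvalue)
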