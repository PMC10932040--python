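"""Ranking and classification metrics for virtual-screening evaluation.

ROC AUC is computed from the ranked list by the cumulative-count rule

    AUC = 1 / (n (N - n)) * sum_i A_i (I_i - I_{i-1})

where A_i and I_i are the cumulative numbers of actives and inactives
at rank position i (descending score). Score ties are handled by
mid-rank averaging, which makes the statistic identical to the
normalized Mann-Whitney U. The enrichment factor at fraction X,

    EF_X = (# actives ranked <= floor(X N)) / (n X),

is reported alongside its ceiling EFmax = min(n, floor(X N)) / (n X)
and the normalized ratio EF/EFmax, which is comparable across tasks
with different active fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EF_FRACTIONS = (0.001, 0.005)


class UndefinedMetricError(ValueError):
    """A metric whose denominator is empty (e.g. AUC with one class)."""


@dataclass
class RankedTask:
    """Scores and binary labels for one task, sorted on demand.

    For enrichment, ties straddling the window boundary are resolved
    pessimistically (actives ranked after inactives at equal score), so
    reported enrichment is conservative.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")

    @property
    def n(self) -> int:
        return int(self.labels.sum())

    @property
    def N(self) -> int:
        return int(self.labels.size)

    def active_ranks_pessimistic(self) -> np.ndarray:
        """1-based ranks of actives after a descending sort, actives last in ties."""
        # lexsort keys: primary -scores asc == scores desc; secondary puts
        # inactives (labels==0) before actives at equal score
        order = np.lexsort((self.labels, -self.scores))
        ranked_labels = self.labels[order]
        return np.flatnonzero(ranked_labels == 1) + 1


def roc_auc(task: RankedTask) -> float:
    """Rank-formula ROC AUC with mid-rank tie handling.

    Walks the descending-score list in tie groups; a group with ``a``
    actives and ``b`` inactives contributes A_before * b concordant
    pairs plus a*b/2 for the within-group ties — the cumulative-count
    rectangle rule generalized to tied scores.
    """
    n, N = task.n, task.N
    if n == 0 or n == N:
        raise UndefinedMetricError(
            f"AUC undefined: {n} actives out of {N} compounds (need 0 < n < N)"
        )
    order = np.argsort(-task.scores, kind="stable")
    scores = task.scores[order]
    labels = task.labels[order]
    total = 0.0
    a_before = 0
    i = 0
    while i < N:
        j = i
        while j < N and scores[j] == scores[i]:
            j += 1
        a = int(labels[i:j].sum())
        b = (j - i) - a
        total += a_before * b + 0.5 * a * b
        a_before += a
        i = j
    return total / (n * (N - n))


def enrichment_factor(task: RankedTask, X: float) -> float:
    """EF_X: actives found in the top floor(X*N) over the expected n*X."""
    if not 0 < X <= 1:
        raise ValueError(f"X must be in (0, 1], got {X}")
    n, N = task.n, task.N
    if n == 0:
        raise UndefinedMetricError("EF undefined with zero actives")
    window = math.floor(X * N)
    if window == 0:
        return 0.0
    hits = int((task.active_ranks_pessimistic() <= window).sum())
    return hits / (n * X)


def ef_max(n: int, N: int, X: float) -> float:
    """Ceiling of EF_X given n actives among N compounds.

    The most actives the top floor(X*N) window can hold is
    min(n, floor(X*N)); dividing that recovered fraction by X gives the
    maximum enrichment (1/X when the window cannot hold all actives).
    """
    if n <= 0:
        raise UndefinedMetricError("EFmax undefined with zero actives")
    if not 0 < X <= 1:
        raise ValueError(f"X must be in (0, 1], got {X}")
    window = math.floor(X * N)
    if window == 0:
        raise UndefinedMetricError(f"top-{X} window of {N} compounds holds no compound")
    return min(n, window) / n / X


def tp_fraction_at(task: RankedTask, X: float) -> float:
    """Fraction of all actives recovered in the top X; equals EF_X * X."""
    if task.n == 0:
        raise UndefinedMetricError("undefined with zero actives")
    window = math.floor(X * task.N)
    return int((task.active_ranks_pessimistic() <= window).sum()) / task.n


def confusion_metrics(
    predictions: np.ndarray, labels: np.ndarray
) -> dict[str, float | None]:
    """Accuracy, precision, recall and F1 from binary predictions.

    Metrics whose denominator is zero are reported as None, not 0.
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != y.shape:
        raise ValueError("shape mismatch")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision and recall and precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is None or recall is None:
        f1 = None
    else:
        f1 = 0.0
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


@dataclass
class TaskReport:
    """Per-task metric bundle."""

    task_id: str
    n: int
    N: int
    auc: float | None
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    ef_at: dict[float, float] = field(default_factory=dict)
    efmax_at: dict[float, float] = field(default_factory=dict)
    ef_ratio_at: dict[float, float] = field(default_factory=dict)
    tp_fraction_at: dict[float, float] = field(default_factory=dict)


def evaluate_task(
    task_id: str,
    scores: np.ndarray,
    labels: np.ndarray,
    ef_fractions: Sequence[float] = DEFAULT_EF_FRACTIONS,
    threshold: float = 0.5,
) -> TaskReport:
    """Compute the full metric bundle for one task's ranked predictions.

    Degenerate tasks (no actives, or no inactives for AUC) get None for
    the affected metrics instead of raising.
    """
    task = RankedTask(scores=scores, labels=labels)
    try:
        auc = roc_auc(task)
    except UndefinedMetricError:
        auc = None
    report = TaskReport(task_id=task_id, n=task.n, N=task.N, auc=auc)
    cm = confusion_metrics((task.scores >= threshold).astype(int), task.labels)
    report.accuracy, report.precision = cm["accuracy"], cm["precision"]
    report.recall, report.f1 = cm["recall"], cm["f1"]
    for X in ef_fractions:
        try:
            ef = enrichment_factor(task, X)
            emax = ef_max(task.n, task.N, X)
        except UndefinedMetricError:
            continue
        report.ef_at[X] = ef
        report.efmax_at[X] = emax
        report.ef_ratio_at[X] = ef / emax if emax > 0 else None
        report.tp_fraction_at[X] = tp_fraction_at(task, X)
    return report


def evaluate_tasks(
    scores: np.ndarray,
    labels: np.ndarray,
    task_ids: Sequence[str],
    mask: np.ndarray | None = None,
    ef_fractions: Sequence[float] = DEFAULT_EF_FRACTIONS,
) -> list[TaskReport]:
    """Per-task reports for a (compounds x tasks) score/label pair.

    Rows where the model produced no score for a task (NaN, e.g.
    single-task baselines) or the mask excludes the cell are skipped.
    """
    reports = []
    for t, task_id in enumerate(task_ids):
        s = scores[:, t]
        y = labels[:, t]
        keep = ~np.isnan(s)
        if mask is not None:
            keep &= mask[:, t].astype(bool)
        if keep.sum() == 0:
            continue
        reports.append(evaluate_task(task_id, s[keep], y[keep], ef_fractions))
    return reports


def reports_to_frame(reports: Sequence[TaskReport]) -> pd.DataFrame:
    """Flatten TaskReports to one row per task (EF columns per fraction)."""
    rows = []
    for r in reports:
        row = {
            "task_id": r.task_id, "n_actives": r.n, "n_total": r.N, "auc": r.auc,
            "accuracy": r.accuracy, "precision": r.precision,
            "recall": r.recall, "f1": r.f1,
        }
        for X, v in r.ef_at.items():
            row[f"ef_{X}"] = v
            row[f"efmax_{X}"] = r.efmax_at[X]
            row[f"ef_ratio_{X}"] = r.ef_ratio_at[X]
            row[f"tp_fraction_{X}"] = r.tp_fraction_at[X]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_reports(
    reports: Sequence[TaskReport], groups: dict[str, str] | None = None
) -> dict:
    """Mean/median AUC and EF ratios, optionally per kinase group."""
    df = reports_to_frame(reports)
    numeric = df.select_dtypes("number").drop(columns=["n_actives", "n_total"], errors="ignore")
    out = {
        "n_tasks": len(df),
        "mean": {k: float(v) for k, v in numeric.mean(numeric_only=True).items()},
        "median": {k: float(v) for k, v in numeric.median(numeric_only=True).items()},
    }
    if groups:
        df["group"] = df["task_id"].map(groups).fillna("unassigned")
        out["per_group"] = {
            g: {k: float(v) for k, v in sub.mean(numeric_only=True).items()
                if k in ("auc",) or k.startswith("ef_ratio")}
            for g, sub in df.groupby("group")
        }
    return out


def compare_models(
    per_task_scores_a: Sequence[float],
    per_task_scores_b: Sequence[float],
    test: str = "mann_whitney",
) -> dict:
    """Two-sided comparison of two per-task metric vectors.

    ``mann_whitney`` is the distribution-free default; ``t_test`` is the
    two-sample t-test used for the multi-task random-forest comparison.
    Direction is the sign of mean(a) - mean(b).
    """
    a = np.asarray(per_task_scores_a, dtype=float)
    b = np.asarray(per_task_scores_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 tasks per side")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic = float(res.statistic)
    elif test == "t_test":
        res = stats.ttest_ind(a, b)
        statistic = float(res.statistic)
    else:
        raise ValueError(f"unknown test {test!r}")
    diff = float(a.mean() - b.mean())
    return {
        "test": test,
        "statistic": statistic,
        "p_value": float(res.pvalue),
        "direction": int(np.sign(diff)),
        "mean_difference": diff,
    }
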