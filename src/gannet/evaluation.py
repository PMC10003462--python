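"""Classification metrics and the repeated-training stability protocol.

Metrics: accuracy at the 0.5 probability threshold (ties classified as
case), support-weighted F1 over both classes, and AUC as the rank statistic
(ties credited 0.5). The stability protocol reruns a seedable pipeline n
times (100 in the study design), reports per-metric means with empirical
percentile 95% intervals, and flags the best iteration by test AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

__all__ = ["MetricsReport", "IterationSummary", "compute_metrics", "repeat_runs",
           "brier_score"]


@dataclass
class MetricsReport:
    accuracy: float
    weighted_f1: float
    auc: float
    n_samples: int
    threshold: float = 0.5
    train_accuracy: float = float("nan")  # optional, for pipeline summaries


def compute_metrics(probabilities, labels) -> MetricsReport:
    """Accuracy, weighted F1 and AUC of predicted case probabilities."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    pred = (p >= 0.5).astype(int)
    accuracy = float(np.mean(pred == y))
    wf1 = float(f1_score(y, pred, average="weighted", zero_division=0))
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels "
                         f"(accuracy={accuracy:.3f}, weighted_f1={wf1:.3f})")
    auc = float(roc_auc_score(y, p))
    return MetricsReport(accuracy=accuracy, weighted_f1=wf1, auc=auc,
                         n_samples=len(y))


def brier_score(probabilities, labels) -> float:
    """Mean squared error of the probability forecast."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    return float(np.mean((p - y) ** 2))


@dataclass
class IterationSummary:
    """Across-iteration means, percentile 95% CIs, and the best iteration."""

    n_iterations: int
    n_failures: int
    mean: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    best_iteration: int           # index (0-based) among successful runs
    best_test_auc: float
    per_iteration: pd.DataFrame


def repeat_runs(pipeline, n: int = 100, base_seed: int = 0) -> IterationSummary:
    """Run ``pipeline(seed)`` for seeds base_seed..base_seed+n-1.

    ``pipeline`` must return a mapping with at least ``test_auc``; typical
    keys are train_acc/test_acc/test_f1/test_auc. Crashed runs are recorded
    as failures and excluded from the summary. CIs are the empirical 2.5th
    and 97.5th percentiles.
    """
    rows = []
    failures = 0
    for i in range(n):
        seed = base_seed + i
        try:
            metrics = pipeline(seed)
        except Exception:  # noqa: BLE001 - any run crash counts as a failure
            failures += 1
            continue
        row = {"iteration": i, "seed": seed}
        row.update({k: float(v) for k, v in metrics.items()})
        rows.append(row)
    if not rows:
        raise RuntimeError(f"all {n} runs failed")
    table = pd.DataFrame(rows)
    metric_cols = [c for c in table.columns if c not in ("iteration", "seed")]
    mean = {c: float(table[c].mean()) for c in metric_cols}
    ci95 = {c: (float(np.percentile(table[c], 2.5)),
                float(np.percentile(table[c], 97.5))) for c in metric_cols}
    best_pos = int(table["test_auc"].idxmax())
    return IterationSummary(
        n_iterations=len(rows),
        n_failures=failures,
        mean=mean,
        ci95=ci95,
        best_iteration=int(table.loc[best_pos, "iteration"]),
        best_test_auc=float(table["test_auc"].max()),
        per_iteration=table,
    )
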