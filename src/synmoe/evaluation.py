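"""Metric suite, cross-validation aggregation, score-consistency analysis,
and candidate-screening rules.

Regression tasks report RMSE, Spearman rank correlation and R²;
classification tasks report accuracy, precision, recall, F1, AUROC and
AUPR.  Screening mirrors the post-hoc candidate triage: count how many of
the five predicted synergy scores exceed a threshold (the *support*), keep
combinations whose predicted synergy probability or whose full score set
clears a bar, and drop pairs whose predicted adverse-interaction
probability is high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .data_model import REGRESSION_TASKS

PREDICTION_COLUMNS = tuple(f"pred_{t}" for t in REGRESSION_TASKS)


@dataclass
class EvaluationReport:
    """Metric values keyed task -> metric.

    For a single fold, values are floats; after :func:`aggregate_cv`, each
    value is a dict with mean / variance / ci95_halfwidth across folds.
    """

    per_task: dict[str, dict[str, object]]
    n_samples: int | None = None

    def task_names(self) -> tuple[str, ...]:
        return tuple(self.per_task)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def regression_metrics(actual, predicted, printed_denominator: bool = False,
                       ) -> dict[str, float]:
    """RMSE, Spearman (average ranks under ties) and R².

    The default R² is the standard coefficient of determination,
    1 - Σ(Y_i - y_i)² / Σ(Y_i - Ȳ)².  ``printed_denominator=True`` switches
    the denominator to Σ(y_i - Ȳ)² (predictions against the actual mean),
    provided for exact-formula comparison only.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError(f"length mismatch: {actual.shape} vs {predicted.shape}")
    if actual.size < 2:
        raise ValueError("need at least 2 points")
    if not (np.all(np.isfinite(actual)) and np.all(np.isfinite(predicted))):
        raise ValueError("non-finite values in inputs")
    rmse = float(np.sqrt(np.mean((actual - predicted) ** 2)))
    sse = float(np.sum((actual - predicted) ** 2))
    if printed_denominator:
        sst = float(np.sum((predicted - actual.mean()) ** 2))
    else:
        sst = float(np.sum((actual - actual.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("zero variance in the R^2 denominator")
    spearman = float(stats.spearmanr(actual, predicted).statistic)
    return {"rmse": rmse, "spearman": spearman, "r2": 1.0 - sse / sst}


def classification_metrics(labels, probs, cutoff: float = 0.5) -> dict[str, float]:
    """Threshold metrics at `cutoff` plus ranking metrics.

    AUROC equals the probability that a random positive outranks a random
    negative, with half credit for ties; AUPR is the area under the
    precision-recall step curve.  Both require both classes present.
    """
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC/AUPR undefined: only one class present")
    pred = (probs >= cutoff).astype(int)
    return {
        "accuracy": float(skm.accuracy_score(labels, pred)),
        "precision": float(skm.precision_score(labels, pred, zero_division=0)),
        "recall": float(skm.recall_score(labels, pred, zero_division=0)),
        "f1": float(skm.f1_score(labels, pred, zero_division=0)),
        "auroc": float(skm.roc_auc_score(labels, probs)),
        "aupr": float(skm.average_precision_score(labels, probs)),
    }


def aggregate_cv(per_fold_reports: list[EvaluationReport]) -> EvaluationReport:
    """Mean, sample variance and 95% CI half-width per metric across folds."""
    if len(per_fold_reports) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    rosters = {r.task_names() for r in per_fold_reports}
    if len(rosters) > 1:
        raise ValueError(f"fold reports have mismatched task rosters: {rosters}")
    k = len(per_fold_reports)
    tcrit = float(stats.t.ppf(0.975, k - 1))
    out: dict[str, dict[str, object]] = {}
    for task in per_fold_reports[0].per_task:
        out[task] = {}
        for metric in per_fold_reports[0].per_task[task]:
            vals = np.array([r.per_task[task][metric] for r in per_fold_reports],
                            dtype=float)
            var = float(vals.var(ddof=1))
            out[task][metric] = {
                "mean": float(vals.mean()),
                "variance": var,
                "ci95_halfwidth": tcrit * np.sqrt(var / k),
            }
    return EvaluationReport(per_task=out, n_samples=None)


# --------------------------------------------------------------------------
# consistency analysis & screening
# --------------------------------------------------------------------------

def count_support(scores: dict[str, float], threshold: float = 5.0) -> int:
    """Number of the five synergy scores strictly exceeding the threshold."""
    missing = [t for t in REGRESSION_TASKS if t not in scores]
    if missing:
        raise KeyError(f"missing score(s): {missing}")
    vals = np.array([scores[t] for t in REGRESSION_TASKS], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite synergy score")
    return int(np.sum(vals > threshold))


def pairwise_score_correlation(scores_by_task: dict[str, np.ndarray],
                               subset_mask=None) -> pd.DataFrame:
    """Pearson correlation between every pair of synergy scores over an
    optional sample subset (e.g. the predicted-synergistic samples)."""
    tasks = list(scores_by_task)
    arrays = [np.asarray(scores_by_task[t], dtype=float) for t in tasks]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("score vectors differ in length")
    if subset_mask is not None:
        mask = np.asarray(subset_mask, dtype=bool)
        if mask.size != n:
            raise ValueError("mask length mismatch")
        if mask.sum() < 2:
            raise ValueError("subset too small for correlation")
        arrays = [a[mask] for a in arrays]
    for t, a in zip(tasks, arrays):
        if np.ptp(a) == 0:
            raise ValueError(f"zero variance in task {t!r} over the subset")
    mat = np.corrcoef(np.stack(arrays))
    return pd.DataFrame(mat, index=tasks, columns=tasks)


@dataclass(frozen=True)
class ScreenRule:
    """One screening rule.

    kinds: ``support_count`` (support >= min_support), ``prob_threshold``
    (synergy probability > threshold), ``all_scores_threshold`` (all five
    predicted scores > threshold), ``ddi_exclude`` (drop rows whose adverse
    DDI probability > threshold).
    """

    kind: str
    threshold: float = 5.0
    min_support: int = 0

    def __post_init__(self):
        if self.kind not in ("support_count", "prob_threshold",
                             "all_scores_threshold", "ddi_exclude"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("rule threshold must be finite")


def screen_candidates(predictions: pd.DataFrame, rules: list[ScreenRule],
                      support_threshold: float = 5.0) -> pd.DataFrame:
    """Apply screening rules conjunctively, preserving the input row order.

    Expects the five ``pred_<task>`` columns plus ``synergy_prob`` and (for
    ddi_exclude) ``ddi_prob``.  The surviving rows carry a ``support``
    column: how many predicted scores strictly exceed `support_threshold`.
    """
    missing = [c for c in PREDICTION_COLUMNS if c not in predictions.columns]
    if missing:
        raise KeyError(f"predictions table missing column(s): {missing}")
    df = predictions.copy()
    score_mat = df[list(PREDICTION_COLUMNS)].to_numpy(dtype=float)
    df["support"] = (score_mat > support_threshold).sum(axis=1)
    keep = np.ones(len(df), dtype=bool)
    for rule in rules:
        if rule.kind == "support_count":
            keep &= (score_mat > rule.threshold).sum(axis=1) >= rule.min_support
        elif rule.kind == "prob_threshold":
            if "synergy_prob" not in df.columns:
                raise KeyError("rule needs a 'synergy_prob' column")
            keep &= df["synergy_prob"].to_numpy(dtype=float) > rule.threshold
        elif rule.kind == "all_scores_threshold":
            keep &= (score_mat > rule.threshold).all(axis=1)
        elif rule.kind == "ddi_exclude":
            if "ddi_prob" not in df.columns:
                raise KeyError("rule needs a 'ddi_prob' column")
            keep &= df["ddi_prob"].to_numpy(dtype=float) <= rule.threshold
    return df.loc[keep]


# --------------------------------------------------------------------------
# model evaluation glue
# --------------------------------------------------------------------------

def predictions_frame(model, samples, store) -> pd.DataFrame:
    """Order-averaged predictions for a sample list as a flat table."""
    from .training import predict_symmetrized

    bundles = predict_symmetrized(model, samples, store)
    rows = []
    for s, b in zip(samples, bundles):
        row = {"drug_x": s.drug_x, "drug_y": s.drug_y, "cell_line": s.cell_line}
        for t, v in b.regression.items():
            row[f"pred_{t}"] = v
            row[f"actual_{t}"] = s.scores[t]
        if "synergy" in b.classification:
            row["synergy_prob"] = b.classification["synergy"][1]
        if "ddi" in b.classification:
            row["ddi_prob"] = b.classification["ddi"][1]
        row["synergy_label"] = s.synergy_label
        row["ddi_label"] = s.ddi_label
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_model(model, dataset, indices) -> EvaluationReport:
    """Per-task metrics on the indexed subset, with order-averaged predictions."""
    samples = [dataset.samples[i] for i in indices]
    df = predictions_frame(model, samples, dataset.store)
    per_task: dict[str, dict[str, object]] = {}
    for task in model.config.tasks:
        if task.kind == "regression":
            per_task[task.name] = regression_metrics(
                df[f"actual_{task.name}"], df[f"pred_{task.name}"])
        else:
            labels = df["synergy_label" if task.name == "synergy" else "ddi_label"]
            probs = df["synergy_prob" if task.name == "synergy" else "ddi_prob"]
            per_task[task.name] = classification_metrics(labels, probs)
    return EvaluationReport(per_task=per_task, n_samples=len(samples))
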