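"""Evaluation metrics: ROC-AUC (Mann-Whitney), pooled AUC, threshold metrics.

Pooled AUC is the AUC of the concatenation of all folds' (label, score)
pairs, which differs in general from the mean of per-fold AUCs; both are
reported. Ties in scores receive half credit (Mann-Whitney convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .records import ValidationError


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as half credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pooled_auc(per_fold_predictions: Sequence[tuple[Sequence[int], Sequence[float]]]) -> float:
    """AUC of all folds' predictions concatenated into one set."""
    if len(per_fold_predictions) == 0:
        raise ValidationError("need at least one fold")
    labels = np.concatenate([np.asarray(l, dtype=int) for l, _ in per_fold_predictions])
    scores = np.concatenate([np.asarray(s, dtype=float) for _, s in per_fold_predictions])
    return roc_auc(labels, scores)


def threshold_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> dict:
    """Accuracy, recall, specificity and confusion counts at a threshold.

    Predicted positive means score >= threshold. Confusion counts are
    reported in the fixed order (TN, FP, FN, TP). Recall is None when no
    positives exist; specificity is None when no negatives exist.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / n if n else None,
        "recall": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "confusion": (tn, fp, fn, tp),
    }


def summarize_folds(per_fold: Sequence[dict]) -> dict:
    """Mean +/- sample SD per metric over folds, with mean+/-SD interval.

    Metrics missing (None) in a fold are dropped from that metric's mean.
    """
    out: dict[str, dict] = {}
    keys = {k for fold in per_fold for k, v in fold.items() if isinstance(v, (int, float))}
    for key in sorted(keys):
        vals = np.array([f[key] for f in per_fold if f.get(key) is not None], dtype=float)
        if vals.size == 0:
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[key] = {
            "mean": mean,
            "sd": sd,
            "interval": (mean - sd, mean + sd),
            "interval_method": "mean±sd",
            "n_folds": int(vals.size),
        }
    return out


@dataclass
class EvalReport:
    """Per-fold and pooled classification metrics for one experiment."""

    per_fold: list[dict]
    mean_metrics: dict
    pooled_auc: float
    roc_points: list[tuple[float, float, float]]
    predictions: list[dict] = field(default_factory=list)
    fold_details: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "config": self.config,
            "per_fold": self.per_fold,
            "mean_metrics": self.mean_metrics,
            "pooled_auc": self.pooled_auc,
            "roc_points": self.roc_points,
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def confusion_text(self) -> str:
        """Fixed text layout of per-fold confusion matrices for diffable logs."""
        lines = []
        for fold in self.per_fold:
            tn, fp, fn, tp = fold["confusion"]
            lines.append(f"fold {fold['fold']}:  TN={tn:3d} FP={fp:3d}")
            lines.append(f"         FN={fn:3d} TP={tp:3d}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def roc_curve_points(
    labels: Sequence[int], scores: Sequence[float]
) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) points at every distinct score."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    points = [(0.0, 0.0, float("inf"))]
    for t in np.unique(s)[::-1]:
        pred = s >= t
        tpr = float(np.sum(pred & (y == 1)) / n_pos)
        fpr = float(np.sum(pred & (y == 0)) / n_neg)
        points.append((fpr, tpr, float(t)))
    return points


def build_report(
    predictions: list[dict],
    threshold: float = 0.5,
    fold_details: list[dict] | None = None,
    config: dict | None = None,
) -> EvalReport:
    """Assemble an EvalReport from per-record prediction rows.

    Each row needs keys: record_id, patient_id, fold, label (0/1), score.
    """
    folds = sorted({p["fold"] for p in predictions})
    per_fold = []
    by_fold = []
    for f in folds:
        rows = [p for p in predictions if p["fold"] == f]
        y = [p["label"] for p in rows]
        s = [p["score"] for p in rows]
        entry = {"fold": f, **threshold_metrics(y, s, threshold)}
        try:
            entry["auc"] = roc_auc(y, s)
        except ValidationError:
            entry["auc"] = None
        per_fold.append(entry)
        by_fold.append((y, s))
    all_y = [p["label"] for p in predictions]
    all_s = [p["score"] for p in predictions]
    return EvalReport(
        per_fold=per_fold,
        mean_metrics=summarize_folds(per_fold),
        pooled_auc=pooled_auc(by_fold),
        roc_points=roc_curve_points(all_y, all_s),
        predictions=predictions,
        fold_details=fold_details or [],
        config=config or {},
    )
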