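"""Classification metrics and the repeated random-split evaluation protocol.

AUC follows the Mann–Whitney convention: the probability that a random
positive outscores a random negative, with ties credited one half.  The
multiclass headline metric is the micro-averaged AUC — one-vs-rest
binarized labels and scores are flattened into a single binary problem —
because macro averaging over-weights minority dose categories in the
imbalanced regimes typical of toxicity data.  The protocol draws
``n_repeats`` independent Monte-Carlo train/test splits (not folds),
trains each model from scratch, and reports per-run and aggregated
metrics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .data import LabeledDataset, random_split

logger = logging.getLogger(__name__)

__all__ = [
    "confusion_counts",
    "binary_metrics",
    "roc_auc",
    "micro_auc_multiclass",
    "EvaluationReport",
    "repeated_evaluation",
]


def confusion_counts(labels: np.ndarray,
                     predictions: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) from binary labels and binary hard predictions."""
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    for arr, name in ((y, "labels"), (yhat, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    return tp, tn, fp, fn


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0.0", stacklevel=3)
        return 0.0
    return num / den


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (equals the pair-counting estimator)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined when only one class is present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def binary_metrics(labels: np.ndarray, probabilities: np.ndarray,
                   threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, AUC, sensitivity, specificity and precision at a threshold."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float).ravel()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    tp, tn, fp, fn = confusion_counts(y, (p >= threshold).astype(int))
    n = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / n,
        "auc": roc_auc(y, p),
        "sensitivity": _safe_ratio(tp, tp + fn, "sensitivity"),
        "specificity": _safe_ratio(tn, tn + fp, "specificity"),
        "precision": _safe_ratio(tp, tp + fp, "precision"),
    }


def micro_auc_multiclass(labels_onehot: np.ndarray,
                         probabilities: np.ndarray) -> float:
    """Micro-averaged multiclass AUC.

    Both the one-hot label matrix and the probability matrix are
    flattened (column-major) into length ``n*C`` vectors and scored as a
    single binary ranking problem.
    """
    y = np.asarray(labels_onehot)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("label and probability matrices must share a shape")
    return roc_auc(y.ravel(order="F"), p.ravel(order="F"))


def multiclass_metrics(labels: np.ndarray,
                       probabilities: np.ndarray) -> dict[str, float]:
    """Accuracy and micro-averaged AUC for a categorical model."""
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(probabilities, dtype=float)
    onehot = np.eye(p.shape[1])[y]
    return {
        "accuracy": float(np.mean(p.argmax(axis=1) == y)),
        "auc": micro_auc_multiclass(onehot, p),
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Per-run metrics plus their mean/SD aggregate over repeated splits."""

    per_run: tuple[dict, ...]
    protocol: dict

    @property
    def n_repeats(self) -> int:
        return len(self.per_run)

    @property
    def aggregate(self) -> dict[str, dict[str, float]]:
        keys = self.per_run[0].keys()
        out = {}
        for k in keys:
            vals = np.array([run[k] for run in self.per_run], dtype=float)
            out[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(
            {"protocol": self.protocol, "per_run": list(self.per_run),
             "aggregate": self.aggregate},
            indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(blob + "\n")
        return blob

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(list(self.per_run)).to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"{self.n_repeats}-repeat evaluation "
                 f"(test_size={self.protocol.get('test_size')}, "
                 f"master_seed={self.protocol.get('master_seed')})"]
        for metric, agg in self.aggregate.items():
            lines.append(f"  {metric:<12} {agg['mean']:.4f} +/- {agg['sd']:.4f}")
        return "\n".join(lines)


def repeated_evaluation(
    dataset: LabeledDataset,
    model_factory: Callable[[LabeledDataset, int], Callable[[LabeledDataset], np.ndarray]],
    n_repeats: int = 10,
    test_size: float | int = 0.2,
    master_seed: int = 0,
) -> EvaluationReport:
    """Monte-Carlo repeated-split evaluation.

    Each repeat ``i`` draws a fresh random split with seed
    ``master_seed + i``, calls ``model_factory(train, seed)`` to obtain a
    scorer ``test -> probability matrix``, and evaluates it on the held
    out test set.  Failed repeats are recorded and the report is marked
    partial when fewer than ``n_repeats`` succeed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    runs: list[dict] = []
    failures: list[dict] = []
    for i in range(n_repeats):
        seed = master_seed + i
        try:
            train, test = random_split(dataset, test_size, seed)
            scorer = model_factory(train, seed)
            proba = np.asarray(scorer(test), dtype=float)
            if dataset.n_classes == 2:
                run = binary_metrics(test.labels, proba[:, 0])
            else:
                run = multiclass_metrics(test.labels, proba)
            runs.append(run)
        except Exception as exc:  # recorded, not fatal, per protocol contract
            logger.error("repeat %d failed: %s", i, exc)
            failures.append({"repeat": i, "error": str(exc)})
    if not runs:
        raise RuntimeError(f"all {n_repeats} repeats failed: {failures}")
    protocol = {
        "n_repeats": n_repeats,
        "test_size": test_size,
        "master_seed": master_seed,
        "partial": bool(failures),
        "failures": failures,
    }
    return EvaluationReport(per_run=tuple(runs), protocol=protocol)
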