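"""Confusion-matrix accounting: OA, AA, expected agreement and Cohen's kappa.

Conventions: rows of the confusion matrix are ground truth, columns are
predictions; ``OA`` and ``AA`` are percentages, ``p_e`` (the chance-agreement
term) and ``kappa`` live on the [0, 1] / [-1, 1] scales:

    OA    = sum_i TP_i / N * 100
    AA    = (1/k) sum_i TP_i / n_i * 100
    p_e   = sum_i n_i * m_i / N^2
    kappa = (OA/100 - p_e) / (1 - p_e)

with ``n_i`` the truth row sums, ``m_i`` the prediction column sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "compute_metrics", "metrics_from_confusion", "aggregate_runs"]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) int, rows = truth, cols = prediction

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def n_true(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def m_pred(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    per_class_accuracy: list[float]  # percent
    oa: float                        # percent
    aa: float                        # percent
    p_e: float
    kappa: float
    confusion: ConfusionMatrix
    group_index: int | None = None


def confusion_matrix(truth: np.ndarray, pred: np.ndarray, k: int) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.size == 0:
        raise ValueError("empty label vectors")
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    for name, arr in (("truth", truth), ("prediction", pred)):
        if arr.min() < 1 or arr.max() > k:
            raise ValueError(f"{name} labels must lie in 1..{k}")
    counts = np.bincount((truth - 1) * k + (pred - 1), minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts=counts)


def metrics_from_confusion(cm: ConfusionMatrix,
                           group_index: int | None = None) -> MetricsReport:
    n_i = cm.n_true
    if (n_i == 0).any():
        missing = np.nonzero(n_i == 0)[0] + 1
        raise ValueError(f"AA undefined: no truth pixels for class(es) {missing.tolist()}")
    tp = cm.tp
    n = cm.total
    per_class = tp / n_i * 100.0
    oa = tp.sum() / n * 100.0
    aa = per_class.mean()
    p_e = float((n_i.astype(float) * cm.m_pred).sum()) / n ** 2
    kappa = (oa / 100.0 - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return MetricsReport(per_class_accuracy=[float(v) for v in per_class],
                         oa=float(oa), aa=float(aa), p_e=p_e, kappa=float(kappa),
                         confusion=cm, group_index=group_index)


def compute_metrics(truth: np.ndarray, pred: np.ndarray, k: int,
                    group_index: int | None = None) -> MetricsReport:
    return metrics_from_confusion(confusion_matrix(truth, pred, k), group_index)


def aggregate_runs(reports: list[MetricsReport]) -> dict:
    """Mean +/- population-std summary across repetition groups."""
    if not reports:
        raise ValueError("need at least one report")
    ks = {r.confusion.k for r in reports}
    if len(ks) != 1:
        raise ValueError(f"reports mix class counts: {sorted(ks)}")
    k = ks.pop()

    def stat(values: np.ndarray) -> dict:
        mean, std = float(np.mean(values)), float(np.std(values))
        return {"mean": mean, "std": std,
                "formatted": f"{mean:.2f} ± {std:.2f}"}

    per_class = np.array([r.per_class_accuracy for r in reports])
    return {
        "n_runs": len(reports),
        "oa": stat(np.array([r.oa for r in reports])),
        "aa": stat(np.array([r.aa for r in reports])),
        "kappa": stat(np.array([r.kappa for r in reports])),
        "per_class": [stat(per_class[:, i]) for i in range(k)],
    }
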