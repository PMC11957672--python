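"""Confusion-matrix metrics, per-protein confidence intervals, curve sweeps.

Per-residue predictions are scored per ligand class and on the derived
binary binding/non-binding task with MCC, precision, recall, accuracy and
F1. Aggregate numbers are reported the way the field expects for this
task: the metric is computed per protein, then averaged, with a symmetric
95 % confidence interval (1.96 standard errors, normal assumption).
Degenerate confusion tables return 0 rather than an error (an MCC or F1
denominator of zero means no information, not a failure); proteins where a
class has neither observed nor predicted positives are by default excluded
from that class's aggregation because the metric is undefined there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CLASSES
from .prediction import to_binary

Z_95 = 1.96

METRIC_NAMES = ("mcc", "precision", "recall", "accuracy", "f1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class MetricSet:
    mcc: float
    precision: float
    recall: float
    accuracy: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(calls: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Confusion counts for aligned binary arrays of any shape."""
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have identical shape")
    return ConfusionCounts(
        tp=int(np.sum(calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        tn=int(np.sum(~calls & ~labels)),
        fn=int(np.sum(~calls & labels)),
    )


def confusion_per_class(
    calls: np.ndarray, labels: np.ndarray
) -> dict[str, ConfusionCounts]:
    """Per-ligand-class counts plus the binary (any-class) reduction."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    out = {cls: confusion(calls[:, k], labels[:, k]) for k, cls in enumerate(CLASSES)}
    out["binary"] = confusion(calls.any(axis=1), labels.any(axis=1))
    return out


def metrics(counts: ConfusionCounts) -> MetricSet:
    """MCC, precision, recall, accuracy, F1 from one confusion table.

    Every zero denominator yields 0 for that metric, keeping all metrics
    total functions of the counts.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom > 0 else 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    accuracy = (tp + tn) / counts.total if counts.total > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MetricSet(float(mcc), precision, recall, accuracy, f1)


def per_protein_ci(values) -> tuple[float, float, int]:
    """(mean, 95 % CI half-width, n) over per-protein metric values.

    Half-width = 1.96 · SD / √n with the sample (ddof=1) SD. With a single
    protein the half-width is undefined and reported as 0.
    """
    values = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    n = len(values)
    if n == 0:
        return float("nan"), 0.0, 0
    mean = float(values.mean())
    if n == 1:
        warnings.warn("single protein: CI half-width undefined, reporting 0")
        return mean, 0.0, 1
    half = float(Z_95 * values.std(ddof=1) / np.sqrt(n))
    return mean, half, n


def metric_defined(counts: ConfusionCounts) -> bool:
    """A per-protein class metric is undefined when the protein has
    neither observed nor predicted positives for that class."""
    return (counts.tp + counts.fn > 0) or (counts.fp > 0)


def aggregate_per_protein(
    per_protein_counts: list[dict[str, ConfusionCounts]],
    undefined: str = "exclude",
) -> pd.DataFrame:
    """Mean ± 95 % CI of every metric, per class and binary.

    ``undefined='exclude'`` drops proteins where a class metric is
    undefined (default); ``'zero'`` keeps them with metric value 0.
    Returns a tidy frame with columns (task, metric, mean, ci95, n).
    """
    if undefined not in ("exclude", "zero"):
        raise ValueError("undefined must be 'exclude' or 'zero'")
    rows = []
    for task in (*CLASSES, "binary"):
        per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
        for counts in per_protein_counts:
            cc = counts[task]
            if undefined == "exclude" and not metric_defined(cc):
                continue
            ms = metrics(cc)
            for m in METRIC_NAMES:
                per_metric[m].append(getattr(ms, m))
        for m in METRIC_NAMES:
            mean, half, n = per_protein_ci(per_metric[m])
            rows.append(
                {"task": task, "metric": m, "mean": mean, "ci95": half, "n": n}
            )
    return pd.DataFrame(rows)


def pr_roc_sweep(
    probs: np.ndarray, labels: np.ndarray, thresholds=None
) -> pd.DataFrame:
    """Binary-task precision/recall and TPR/FPR across decision thresholds.

    ``probs`` is L×3; the binary score is the per-residue reliability
    (max class probability) and the binary label is any-class binding.
    """
    if thresholds is None:
        thresholds = np.linspace(0.05, 0.95, 19)
    labels_bin = np.asarray(labels).any(axis=1).astype(int)
    rows = []
    for t in thresholds:
        calls, _ = to_binary(probs, float(t))
        cc = confusion(calls, labels_bin)
        ms = metrics(cc)
        fpr = cc.fp / (cc.fp + cc.tn) if cc.fp + cc.tn > 0 else 0.0
        rows.append(
            {
                "threshold": float(t),
                "precision": ms.precision,
                "recall": ms.recall,
                "tpr": ms.recall,
                "fpr": fpr,
            }
        )
    return pd.DataFrame(rows)


def reliability_table(
    probs: np.ndarray, labels: np.ndarray, thresholds=None
) -> pd.DataFrame:
    """Coverage and precision of high-reliability predictions.

    For each reliability cutoff t: coverage is the fraction of observed
    binding residues whose score exceeds t; precision is the fraction of
    residues scoring above t that are truly binding.
    """
    if thresholds is None:
        thresholds = np.arange(0.5, 1.0, 0.05)
    probs = np.asarray(probs)
    labels_bin = np.asarray(labels).any(axis=1).astype(bool)
    score = probs.max(axis=1)
    n_binding = int(labels_bin.sum())
    rows = []
    for t in thresholds:
        above = score > t
        n_above = int(above.sum())
        coverage = (
            float(np.sum(above & labels_bin)) / n_binding if n_binding else 0.0
        )
        precision = float(np.sum(above & labels_bin)) / n_above if n_above else 0.0
        rows.append(
            {
                "threshold": float(t),
                "coverage": coverage,
                "precision": precision,
                "n_above": n_above,
            }
        )
    return pd.DataFrame(rows)


def plddt_correlation(plddt: np.ndarray, probs: np.ndarray) -> float:
    """Pearson r between structure confidence and predicted binding.

    ``probs`` may be L×3 (reduced to the per-residue maximum) or a length-L
    vector. A constant input has undefined correlation: returns NaN with a
    warning.
    """
    plddt = np.asarray(plddt, dtype=float)
    probs = np.asarray(probs, dtype=float)
    score = probs.max(axis=1) if probs.ndim == 2 else probs
    if len(score) != len(plddt):
        raise ValueError("pLDDT and probability vectors differ in length")
    if np.ptp(plddt) == 0 or np.ptp(score) == 0:
        warnings.warn("constant input: Pearson correlation undefined")
        return float("nan")
    return float(stats.pearsonr(plddt, score).statistic)
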