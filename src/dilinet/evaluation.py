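"""Metric panel, top-k positive-likelihood-ratio analysis, and label/call
agreement measures.

Undefined quantities (zero-denominator LR+, single-class AUC, kappa with
perfect expected agreement) are carried as None and serialize as JSON null —
never silently reported as 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class EvaluationReport:
    n_pos: int
    n_neg: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    mcc: float | None
    f1: float | None
    ppv: float | None
    lr_plus: float | None
    lr_plus_infinite: bool
    average_precision: float | None
    auc_roc: float | None

    def __post_init__(self) -> None:
        assert self.tp + self.fn == self.n_pos
        assert self.tn + self.fp == self.n_neg

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    def to_row(self) -> dict:
        return asdict(self)


def _confusion(labels: np.ndarray, calls: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((labels == 1) & (calls == 1)))
    fp = int(np.sum((labels == 0) & (calls == 1)))
    tn = int(np.sum((labels == 0) & (calls == 0)))
    fn = int(np.sum((labels == 1) & (calls == 0)))
    return tp, fp, tn, fn


def report_from_counts(
    tp: int, fp: int, tn: int, fn: int, probs: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> EvaluationReport:
    """Build the metric panel from confusion counts (plus optional ranking
    metrics when probabilities are supplied)."""
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else None
    spec = tn / n_neg if n_neg else None
    ba = (sens + spec) / 2 if sens is not None and spec is not None else None
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else None
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else None
    ppv = tp / (tp + fp) if (tp + fp) else None
    lr_inf = False
    if sens is None or spec is None:
        lr = None
    elif spec < 1.0:
        lr = sens / (1.0 - spec)
    else:
        lr = None
        lr_inf = sens > 0
    auc = ap = None
    if probs is not None and labels is not None and n_pos and n_neg:
        auc = float(roc_auc_score(labels, probs))
        ap = float(average_precision_score(labels, probs))
    return EvaluationReport(
        n_pos=n_pos,
        n_neg=n_neg,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=ba,
        mcc=mcc,
        f1=f1,
        ppv=ppv,
        lr_plus=lr,
        lr_plus_infinite=lr_inf,
        average_precision=ap,
        auc_roc=auc,
    )


def binary_report(
    labels, calls, probs=None
) -> EvaluationReport:
    """Full metric panel for binary calls (and optional probabilities)."""
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    if not set(np.unique(labels)) <= {0, 1} or not set(np.unique(calls)) <= {0, 1}:
        raise ValueError("labels and calls must be binary")
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != labels.shape:
            raise ValueError("probs must align with labels")
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("probs must be in [0, 1]")
    tp, fp, tn, fn = _confusion(labels, calls)
    return report_from_counts(tp, fp, tn, fn, probs=probs, labels=labels)


def lr_plus_at_topk(probs, labels, k: int) -> dict:
    """Metric panel treating the k highest-probability compounds as positive
    calls.  Probability ties break by stable input order (earlier row wins).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(probs)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    order = sorted(range(n), key=lambda i: (-probs[i], i))
    calls = np.zeros(n, dtype=int)
    calls[order[:k]] = 1
    rep = binary_report(labels, calls, probs)
    return {
        "k": k,
        "tp": rep.tp,
        "fp": rep.fp,
        "lr_plus": rep.lr_plus,
        "lr_plus_infinite": rep.lr_plus_infinite,
        "ppv": rep.ppv,
        "report": rep,
    }


def lr_plus_curve(probs, labels) -> list[dict]:
    """LR+/PPV profile over k = 1..n for the low-false-positive-rate plot."""
    return [
        {kk: v for kk, v in lr_plus_at_topk(probs, labels, k).items() if kk != "report"}
        for k in range(1, len(probs) + 1)
    ]


def jaccard_calls(calls_a, calls_b) -> float:
    """|a AND b| / |a OR b| over binary call vectors; both all-zero -> 1."""
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    union = int(np.sum((a == 1) | (b == 1)))
    if union == 0:
        warnings.warn("both call vectors are all-negative; Jaccard defined as 1")
        return 1.0
    return float(np.sum((a == 1) & (b == 1)) / union)


def kappa(labels_a, labels_b) -> float | None:
    """Cohen's kappa; None when expected agreement is perfect (undefined)."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty label vectors")
    cats = sorted(set(a) | set(b))
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    p_e = sum(
        (a.count(c) / n) * (b.count(c) / n) for c in cats
    )
    if math.isclose(p_e, 1.0):
        return None
    return (p_o - p_e) / (1.0 - p_e)


def auc_mann_whitney(labels, probs) -> float | None:
    """AUC-ROC via the Mann-Whitney U identity (independent oracle)."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))


__all__ = [
    "EvaluationReport",
    "binary_report",
    "report_from_counts",
    "lr_plus_at_topk",
    "lr_plus_curve",
    "jaccard_calls",
    "kappa",
    "auc_mann_whitney",
]
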