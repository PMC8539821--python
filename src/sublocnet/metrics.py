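"""Multi-label ranking metrics and per-label binary metrics.

The three ranking metrics operate on an n x L ground-truth binary matrix y
and a same-shaped score matrix s in [0, 1]:

* ranking loss — per protein, the fraction of (true, false) label pairs the
  scores order incorrectly, ``s_true <= s_false`` counting as a violation
  (ties count against the classifier), averaged over proteins.  Denominator
  per protein: ``k (L - k)`` with k the number of positive labels.
* coverage — per protein, the worst (largest) 1-based rank over its true
  labels, where the rank of label j is ``|{k : s_k >= s_j}|`` (ties counted
  inclusively), averaged over proteins.  Some libraries report rank − 1; pass
  ``zero_based=True`` to match them.
* label-ranking average precision — per protein, the mean over true labels j
  of (number of true labels ranked at or above j) / (rank of j), averaged
  over proteins.

Per-label binary metrics (F1, MCC, AUC) follow their textbook definitions.
Metrics that are mathematically undefined for a degenerate input (e.g. a
label column with no positives) return ``None`` — an explicit marker, never
an imputed 0 — and are excluded from macro-averages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from sublocnet.errors import ValidationError

__all__ = [
    "ranking_loss",
    "coverage",
    "average_precision",
    "binary_confusion",
    "f1_score",
    "mcc",
    "auc",
    "evaluate_all",
    "EvaluationReport",
]


def _check_pair(y, s) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    s = np.asarray(s, dtype=np.float64)
    if y.ndim == 1:
        y = y[None, :]
        s = s[None, :]
    if y.shape != s.shape:
        raise ValidationError(f"shape mismatch: labels {y.shape} vs scores {s.shape}")
    if y.ndim != 2:
        raise ValidationError(f"expected 2-D matrices, got ndim={y.ndim}")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("label matrix must be binary")
    if not np.all(np.isfinite(s)):
        raise ValidationError("non-finite scores")
    return y.astype(np.int64), s


def ranking_loss(y, s) -> float:
    """Mean fraction of (true, false) label pairs with s_true <= s_false."""
    y, s = _check_pair(y, s)
    n, L = y.shape
    k = y.sum(axis=1)
    if np.any(k == 0) or np.any(k == L):
        raise ValidationError(
            "ranking loss undefined for all-positive or all-negative rows"
        )
    # violations: pairs (true j, false l) with s_j <= s_l
    per_row = np.empty(n)
    for i in range(n):
        pos = s[i, y[i] == 1]
        neg = s[i, y[i] == 0]
        viol = np.sum(pos[:, None] <= neg[None, :])
        per_row[i] = viol / (len(pos) * len(neg))
    return float(per_row.mean())


def _ranks(s_row: np.ndarray) -> np.ndarray:
    """1-based inclusive rank of each label: |{k: s_k >= s_j}|."""
    return (s_row[None, :] >= s_row[:, None]).sum(axis=1)


def coverage(y, s, zero_based: bool = False) -> float:
    """Mean worst-case 1-based rank needed to cover every true label."""
    y, s = _check_pair(y, s)
    if np.any(y.sum(axis=1) == 0):
        raise ValidationError("coverage undefined for rows with no positive label")
    per_row = []
    for yi, si in zip(y, s):
        ranks = _ranks(si)
        per_row.append(ranks[yi == 1].max())
    value = float(np.mean(per_row))
    return value - 1.0 if zero_based else value


def average_precision(y, s) -> float:
    """Label-ranking average precision, ties counted inclusively."""
    y, s = _check_pair(y, s)
    if np.any(y.sum(axis=1) == 0):
        raise ValidationError("average precision undefined for rows with no positive label")
    per_row = []
    for yi, si in zip(y, s):
        ranks = _ranks(si)
        true_idx = np.flatnonzero(yi == 1)
        terms = []
        for j in true_idx:
            above = si >= si[j]
            terms.append(np.sum(above & (yi == 1)) / ranks[j])
        per_row.append(np.mean(terms))
    return float(np.mean(per_row))


def binary_confusion(y, y_hat_bin) -> dict[str, int]:
    """Confusion counts {tp, tn, fp, fn} of two equal-length binary vectors."""
    y = np.asarray(y)
    p = np.asarray(y_hat_bin)
    if y.shape != p.shape or y.ndim != 1:
        raise ValidationError(f"expected equal-length vectors, got {y.shape} vs {p.shape}")
    if not np.isin(y, (0, 1)).all() or not np.isin(p, (0, 1)).all():
        raise ValidationError("confusion inputs must be binary")
    y = y.astype(bool)
    p = p.astype(bool)
    return {
        "tp": int(np.sum(y & p)),
        "tn": int(np.sum(~y & ~p)),
        "fp": int(np.sum(~y & p)),
        "fn": int(np.sum(y & ~p)),
    }


def f1_score(conf: dict[str, int]) -> float | None:
    """F1 = 2 PPV TPR / (PPV + TPR); None when precision or recall is undefined."""
    tp, fp, fn = conf["tp"], conf["fp"], conf["fn"]
    if tp + fp == 0 or tp + fn == 0:
        return None
    if tp == 0:
        return 0.0
    ppv = tp / (tp + fp)
    tpr = tp / (tp + fn)
    return 2 * ppv * tpr / (ppv + tpr)


def mcc(conf: dict[str, int]) -> float | None:
    """Matthews correlation coefficient; None when any marginal sum is zero."""
    tp, tn, fp, fn = conf["tp"], conf["tn"], conf["fp"], conf["fn"]
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auc(y, s) -> float | None:
    """Rank-based ROC AUC: P(score of random positive > random negative), ties 1/2.

    Returns None for single-class input (the curve is undefined).
    """
    y = np.asarray(y)
    s = np.asarray(s, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValidationError(f"expected equal-length vectors, got {y.shape} vs {s.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary")
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    wins = np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :])
    return float(wins / (len(pos) * len(neg)))


@dataclass
class EvaluationReport:
    """Per-label and multi-label metrics of one score matrix."""

    n: int
    n_labels: int
    threshold: float
    per_label: list[dict[str, float | None]]
    macro_f1: float | None
    macro_mcc: float | None
    macro_auc: float | None
    ranking_loss: float
    coverage: float
    average_precision: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "n_labels": self.n_labels,
                "threshold": self.threshold,
                "per_label": self.per_label,
                "macro_f1": self.macro_f1,
                "macro_mcc": self.macro_mcc,
                "macro_auc": self.macro_auc,
                "ranking_loss": self.ranking_loss,
                "coverage": self.coverage,
                "average_precision": self.average_precision,
            },
            indent=2,
        )


def _macro(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def evaluate_all(y, s, threshold: float = 0.5) -> EvaluationReport:
    """Full report: per-label F1/MCC/AUC (scores binarized at ``threshold``),
    their macro-averages over defined labels, and RL/Cov/AP on raw scores."""
    y, s = _check_pair(y, s)
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    n, L = y.shape
    s_bin = (s >= threshold).astype(np.int64)
    per_label: list[dict[str, float | None]] = []
    for j in range(L):
        conf = binary_confusion(y[:, j], s_bin[:, j])
        per_label.append(
            {
                "f1": f1_score(conf),
                "mcc": mcc(conf),
                "auc": auc(y[:, j], s[:, j]),
            }
        )
    return EvaluationReport(
        n=n,
        n_labels=L,
        threshold=threshold,
        per_label=per_label,
        macro_f1=_macro([d["f1"] for d in per_label]),
        macro_mcc=_macro([d["mcc"] for d in per_label]),
        macro_auc=_macro([d["auc"] for d in per_label]),
        ranking_loss=ranking_loss(y, s),
        coverage=coverage(y, s),
        average_precision=average_precision(y, s),
    )
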