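"""Retrieval metrics: precision / recall / F-measure, truncated average
precision (AP@k, mAP@k) and the area under the precision-recall curve
obtained by sweeping the association threshold."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "precision_recall_f",
    "average_precision_at_k",
    "map_at_k",
    "auc_pr",
]


def precision_recall_f(predicted: Iterable, gold: Iterable) -> tuple[float, float, float]:
    """P = |correct|/|predicted|, R = |correct|/|gold|, F = 2PR/(P+R).

    An empty prediction has precision 0; F is 0 when P + R is 0.
    """
    predicted, gold = set(predicted), set(gold)
    correct = len(predicted & gold)
    p = correct / len(predicted) if predicted else 0.0
    r = correct / len(gold) if gold else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def average_precision_at_k(ranked: Sequence, relevant: Iterable, k: int = 10) -> float:
    """Truncated AP: mean of precision-at-rank over the relevant items found
    in the top k, normalized by min(|relevant|, k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    relevant = set(relevant)
    if not relevant:
        return 0.0
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list must be duplicate-free")
    hits = 0
    total = 0.0
    for rank, item in enumerate(ranked[:k], start=1):
        if item in relevant:
            hits += 1
            total += hits / rank
    return total / min(len(relevant), k)


def map_at_k(results: Iterable[tuple[Sequence, Iterable]], k: int = 10) -> float:
    """Mean AP@k over (ranked list, relevant set) pairs."""
    aps = [average_precision_at_k(ranked, relevant, k) for ranked, relevant in results]
    if not aps:
        raise ValueError("no queries")
    return float(np.mean(aps))


def auc_pr(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a (recall, precision) curve from a threshold
    sweep, clipped to [0, 1]."""
    if len(points) < 2:
        raise ValueError("need at least two (recall, precision) points")
    pts = sorted(points)
    recall = np.array([r for r, _ in pts], dtype=float)
    precision = np.clip([p for _, p in pts], 0.0, 1.0)
    area = float(np.trapezoid(precision, recall))
    return float(min(max(area, 0.0), 1.0))
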