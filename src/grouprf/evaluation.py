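"""Ranking and selection quality metrics against a known relevant set.

For a selection S and a set of truly relevant groups: precision = TP/|S|
(defined as 1 for an empty selection -- no false discoveries) and
recall = TP/(number of relevant groups).  A full ranking is scored by the
area under its precision-recall curve (AUPR), traced by selecting growing
top-k prefixes; AUPR is 1 when all relevant groups sit at the top and
near R/g for a random ranking of g groups with R relevant.  rec-1 and
prec-1 are the theoretical bounds: the best recall at precision 1 and the
best precision at recall 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def precision_recall(selected, truth) -> tuple[float, float]:
    """Precision and recall of a selected group set against the truth.

    An empty selection has precision 1 by convention (it makes no false
    discovery), so conservative selectors are not penalized.
    """
    truth = set(truth)
    if not truth:
        raise ValueError("the set of relevant groups must be non-empty")
    selected = list(selected)
    tp = sum(1 for g in selected if g in truth)
    precision = tp / len(selected) if selected else 1.0
    recall = tp / len(truth)
    return precision, recall


def _prefix_curve(ranking: Sequence, truth) -> tuple[np.ndarray, np.ndarray]:
    truth = set(truth)
    if not truth:
        raise ValueError("the set of relevant groups must be non-empty")
    hits = np.array([g in truth for g in ranking], dtype=float)
    tp = np.cumsum(hits)
    k = np.arange(1, len(ranking) + 1)
    return tp / k, tp / len(truth)  # precision_k, recall_k


def aupr(ranking: Sequence, truth) -> float:
    """Area under the precision-recall curve of a complete ranking.

    Precision/recall are evaluated at every top-k prefix.  Recall rises by
    1/R exactly when a relevant group enters the prefix, and that step is
    credited the precision of the prefix *strictly before* the entering
    group (1 by convention for a relevant group at rank 1), i.e. a
    left-continuous step integral.  A relevant group thus never inflates
    the precision credited to its own recall gain: a perfect ranking
    scores exactly 1 and a random ranking scores R/g in expectation,
    rather than carrying the upward small-sample bias of trapezoidal or
    average-precision estimates.
    """
    truth = set(truth)
    if not truth:
        raise ValueError("the set of relevant groups must be non-empty")
    hits = np.array([g in truth for g in ranking], dtype=bool)
    tp_before = np.concatenate(([0], np.cumsum(hits)[:-1]))
    pos = np.arange(len(ranking))
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_before = np.where(pos > 0, tp_before / np.maximum(pos, 1), 1.0)
    return float(np.sum(prec_before[hits]) / len(truth))


def rec1_prec1(ranking: Sequence, truth) -> tuple[float, float]:
    """Best recall at precision 1 and best precision at recall 1.

    rec-1 is the recall of the longest ranking prefix containing no
    irrelevant group (the ideal conservative selector); prec-1 is the
    highest precision among prefixes that capture every relevant group
    (the ideal exhaustive selector).
    """
    precision, recall = _prefix_curve(ranking, truth)
    clean = precision == 1.0
    rec1 = float(recall[clean].max()) if clean.any() else 0.0
    full = recall == 1.0
    prec1 = float(precision[full].max()) if full.any() else 0.0
    return rec1, prec1


def misclassification_rate(y_true, y_pred) -> float:
    """Percent disagreement between two label vectors (0-100)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be one-dimensional and equal-length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return float(100.0 * np.mean(y_true != y_pred))
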