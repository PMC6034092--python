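"""Aggregation of per-feature importances into per-group scores and ranking.

Three aggregation functions are supported for a group G of #G features:

* ``sum`` -- total impurity reduction attributed to the group,
  :math:`I_{sum}(G) = \\sum_{j \\in G} I(x_j)`;
* ``avg`` -- :math:`I_{sum}/\\#G`, insensitive to group size;
* ``max`` -- the best single feature, :math:`\\max_{j \\in G} I(x_j)`.

The sum is biased toward large groups (they simply receive more splits,
especially at K = 1); the average removes that bias but dilutes groups in
which only a few features matter; the max assumes one feature can speak
for its group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .partition import FeaturePartition

AGGREGATIONS = ("sum", "avg", "max")


class GroupScoreTable:
    """Per-group aggregated importances with ranks (1 = highest score).

    Stored as a DataFrame with columns ``group_id, size, score, rank,
    aggregation``, ordered by rank.  Ties are broken by the partition's
    group order so the ranking (on which all permutation procedures
    condition) is reproducible.
    """

    def __init__(self, frame: pd.DataFrame, aggregation: str):
        self.frame = frame.reset_index(drop=True)
        self.aggregation = aggregation

    @property
    def ranking(self) -> list[str]:
        """Group ids from rank 1 down."""
        return self.frame["group_id"].tolist()

    @property
    def scores(self) -> np.ndarray:
        """Observed scores in rank order (non-increasing)."""
        return self.frame["score"].to_numpy()

    @property
    def n_groups(self) -> int:
        return len(self.frame)

    def score_of(self, group_id: str) -> float:
        return float(self.frame.set_index("group_id").loc[group_id, "score"])

    def save(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        top = ", ".join(self.frame["group_id"].head(3))
        return f"GroupScoreTable({self.n_groups} groups, {self.aggregation}; top: {top}...)"


def group_scores(
    importances: np.ndarray, partition: FeaturePartition, method: str
) -> np.ndarray:
    """Aggregate per-feature importances; returns scores aligned with
    ``partition.group_ids`` (unranked). Unassigned features are ignored."""
    if method not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {method!r}; expected one of {AGGREGATIONS}")
    imp = np.asarray(importances, dtype=float)
    if imp.shape != (partition.n_features,):
        raise ValueError(
            f"importance length {imp.shape} does not match partition "
            f"({partition.n_features} features)"
        )
    mask = partition.assigned_mask
    idx = partition.assignment[mask]
    vals = imp[mask]
    g = partition.n_groups
    if method == "max":
        out = np.full(g, -np.inf)
        np.maximum.at(out, idx, vals)
        return out
    sums = np.bincount(idx, weights=vals, minlength=g)
    if method == "avg":
        return sums / partition.sizes
    return sums


def rank_groups(scores: np.ndarray, group_ids) -> np.ndarray:
    """Order group positions by descending score, stable in listed order.

    Returns the permutation of ``range(len(scores))`` that sorts groups
    from rank 1 down; equal scores keep the ``group_ids`` listing order.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(group_ids):
        raise ValueError("one score per group required")
    return np.argsort(-scores, kind="stable")


def aggregate(
    importances: np.ndarray, partition: FeaturePartition, method: str
) -> GroupScoreTable:
    """Aggregate and rank: the main entry point of this module."""
    scores = group_scores(importances, partition, method)
    order = rank_groups(scores, partition.group_ids)
    frame = pd.DataFrame(
        {
            "group_id": [partition.group_ids[i] for i in order],
            "size": partition.sizes[order],
            "score": scores[order],
            "rank": np.arange(1, partition.n_groups + 1),
            "aggregation": method,
        }
    )
    return GroupScoreTable(frame, method)
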