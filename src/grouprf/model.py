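"""Model/Results facade over the forest, aggregation and selection layers.

Typical session::

    model = GroupImportanceRF(X, y, partition, aggregation="avg")
    res = model.fit(n_trees=1000, k="sqrt", seed=0)
    print(res.summary())
    sel = res.select(method="cer", alpha=0.05, n_permutations=1000, seed=1)
    print(sel.summary())

The results object carries the fitted forest, the unnormalized per-feature
MDI importances, and the ranked per-group score table; ``select`` runs one
of the permutation procedures against that ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forest import ForestConfig, fit_forest, mdi_importance, predict
from .groups import AGGREGATIONS, GroupScoreTable, aggregate
from .partition import FeaturePartition
from .selection import (
    PermutationProtocol,
    SelectionResult,
    run_method,
    tail_permutation_scores,
)


class GroupImportanceRF:
    """Group-level Random Forests importance model.

    Parameters
    ----------
    X : array-like, shape (n, p)
        Feature matrix (e.g. in-mask voxel intensities per subject).
    y : array-like of {0,1}
        Binary outcome.
    partition : FeaturePartition
        Disjoint feature groups (e.g. atlas regions).
    aggregation : {"sum", "avg", "max"}
        How per-feature importances are pooled per group.
    """

    def __init__(self, X, y, partition: FeaturePartition, aggregation: str = "avg"):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must equal the number of samples")
        if self.X.shape[1] != partition.n_features:
            raise ValueError(
                f"partition covers {partition.n_features} features, X has {self.X.shape[1]}"
            )
        if aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        self.partition = partition
        self.aggregation = aggregation

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        partition: FeaturePartition,
        label_col: str = "label",
        aggregation: str = "avg",
    ) -> "GroupImportanceRF":
        """Build from a DataFrame holding the features plus a label column."""
        if label_col not in frame.columns:
            raise ValueError(f"label column {label_col!r} not found")
        y = frame[label_col].to_numpy()
        X = frame.drop(columns=[label_col]).to_numpy(dtype=np.float64)
        return cls(X, y, partition, aggregation)

    def fit(
        self,
        n_trees: int = 1000,
        k: int | str = "sqrt",
        bootstrap: bool = True,
        seed: int | None = None,
    ) -> "GroupImportanceResults":
        config = ForestConfig(n_trees=n_trees, k=k, bootstrap=bootstrap, seed=seed)
        forest = fit_forest(self.X, self.y, config)
        importances = mdi_importance(forest)
        table = aggregate(importances, self.partition, self.aggregation)
        return GroupImportanceResults(self, forest, importances, table)


class GroupImportanceResults:
    """Fitted forest + per-feature importances + ranked group scores."""

    def __init__(self, model, forest, importances, group_scores: GroupScoreTable):
        self.model = model
        self.forest = forest
        self.importances = importances
        self.group_scores = group_scores

    @property
    def ranking(self) -> list[str]:
        return self.group_scores.ranking

    def predict(self, X) -> np.ndarray:
        return predict(self.forest, X)

    def training_error(self) -> float:
        """Resubstitution misclassification rate in percent."""
        from .evaluation import misclassification_rate

        return misclassification_rate(self.model.y, self.predict(self.model.X))

    def select(
        self,
        method: str = "cer",
        alpha: float = 0.05,
        n_permutations: int = 1000,
        seed: int | None = None,
        rule: str = "first_crossing",
        full_curve: bool = False,
        early_abort: bool = False,
        forest_config: ForestConfig | None = None,
    ) -> SelectionResult:
        """Run one permutation procedure against the fitted ranking.

        ``forest_config`` defaults to the configuration of the fitted
        forest (each repetition refits with a derived seed).
        """
        protocol = PermutationProtocol(
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed,
            forest=forest_config or self.forest.config,
            aggregation=self.model.aggregation,
            rule=rule,
            full_curve=full_curve,
            early_abort=early_abort,
        )
        return run_method(
            method, self.model.X, self.model.y, self.model.partition, self.group_scores, protocol
        )

    def select_many(self, methods=("cer", "cerr", "efdr"), **kw) -> dict[str, SelectionResult]:
        """Run several tail-permutation procedures sharing the refits."""
        protocol = PermutationProtocol(
            n_permutations=kw.get("n_permutations", 1000),
            alpha=kw.get("alpha", 0.05),
            seed=kw.get("seed"),
            forest=kw.get("forest_config") or self.forest.config,
            aggregation=self.model.aggregation,
            rule=kw.get("rule", "first_crossing"),
            full_curve=kw.get("full_curve", False),
            early_abort=kw.get("early_abort", False),
        )
        out = {}
        tail = [m for m in methods if m != "mprobes"]
        if tail:
            out.update(
                tail_permutation_scores(
                    self.model.X,
                    self.model.y,
                    self.model.partition,
                    self.group_scores,
                    protocol,
                    tail,
                )
            )
        if "mprobes" in methods:
            out["mprobes"] = run_method(
                "mprobes",
                self.model.X,
                self.model.y,
                self.model.partition,
                self.group_scores,
                protocol,
            )
        return out

    def summary(self) -> str:
        f = self.forest.config
        head = (
            f"Group importance (Random Forests MDI, {self.model.aggregation} aggregation)\n"
            f"n={self.model.X.shape[0]} samples, p={self.model.X.shape[1]} features, "
            f"{self.model.partition.n_groups} groups "
            f"({self.model.partition.n_unassigned} unassigned features)\n"
            f"T={f.n_trees} trees, K={f.k}, bootstrap={f.bootstrap}, seed={f.seed}\n"
            f"total importance (mean impurity reduction per tree): "
            f"{float(np.sum(self.importances)):.4f}\n"
        )
        return head + self.group_scores.frame.to_string(index=False)
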