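"""Random Forests fitting and Mean Decrease of Impurity (MDI) importances.

The per-feature importance of feature :math:`x_i` in a tree T is

.. math::

    I(x_i, T) = \\sum_{N \\in T : v(N) = x_i} \\frac{n(N)}{n} \\Delta I(N),

where the sum runs over interior nodes splitting on :math:`x_i`, ``n(N)``
is the number of training examples reaching node N, ``n`` the size of the
sample the tree was grown from, and

.. math::

    \\Delta I(N) = I(N) - \\frac{n(N_l)}{n(N)} I(N_l) - \\frac{n(N_r)}{n(N)} I(N_r)

is the Gini impurity reduction at N.  The forest score is the unweighted
mean of :math:`I(x_i, T)` over the T trees and is deliberately kept
*unnormalized*: summed over all features it equals the mean total impurity
reduction of a tree, so group sums retain a physical meaning.

Tree growing is delegated to scikit-learn (fully grown trees, Gini
criterion, K candidate features per split, optional bootstrap); the
unnormalized MDI is read back from the stored node statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier


@dataclass
class ForestConfig:
    """Random Forests hyper-parameters.

    Parameters
    ----------
    n_trees : int
        Number of trees T.
    k : int or {"sqrt", "all"}
        Number of candidate features examined at each split.  ``"sqrt"``
        resolves to ``round(sqrt(p))`` (at least 1); ``"all"`` to ``p``.
    bootstrap : bool
        Grow each tree on a bootstrap sample of size n (the standard
        setting) or on the original sample (useful for exact test cases).
    seed : int or None
        Seed for bootstrap and split-candidate randomness.
    """

    n_trees: int = 1000
    k: int | str = "sqrt"
    bootstrap: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.k, str):
            if self.k not in ("sqrt", "all"):
                raise ValueError("symbolic k must be 'sqrt' or 'all'")
        elif self.k < 1:
            raise ValueError("k must be >= 1")

    def resolve_k(self, p: int) -> int:
        if self.k == "sqrt":
            return max(1, round(np.sqrt(p)))
        if self.k == "all":
            return p
        if self.k > p:
            raise ValueError(f"k={self.k} exceeds number of features p={p}")
        return int(self.k)

    def replace(self, **kw) -> "ForestConfig":
        d = {"n_trees": self.n_trees, "k": self.k, "bootstrap": self.bootstrap, "seed": self.seed}
        d.update(kw)
        return ForestConfig(**d)


@dataclass
class FittedForest:
    """A fitted ensemble plus the training-set size it was grown on."""

    estimator: RandomForestClassifier
    config: ForestConfig
    n_samples: int
    n_features: int

    @property
    def trees(self):
        return self.estimator.estimators_


def gini_impurity(class_counts) -> float:
    """Gini impurity ``1 - p0^2 - p1^2`` of a node with the given class counts."""
    c = np.asarray(class_counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("node has no examples")
    p = c / total
    return float(1.0 - np.sum(p**2))


def fit_forest(X, y, config: ForestConfig) -> FittedForest:
    """Grow a Random Forests classifier.

    Trees are grown to purity (no depth or leaf-size limit, minimum split
    size 2) with the Gini criterion.  Identical ``(X, y, config)`` yield
    identical forests.

    Raises
    ------
    ValueError
        If fewer than two samples, a single class, non-{0,1} labels, or
        non-finite feature values are given.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x features matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("labels must be coded {0, 1}")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.resolve_k(p),
        bootstrap=config.bootstrap,
        n_jobs=1,
        random_state=_as_random_state(config.seed),
    )
    clf.fit(X, y.astype(np.int64))
    return FittedForest(clf, config, n, p)


def mdi_importance(forest: FittedForest) -> np.ndarray:
    """Unnormalized MDI importance of every feature, averaged over trees.

    Per tree, each interior node N splitting on feature i contributes
    ``(n(N)/n) * dI(N)``; with bootstrap on, ``n(N)`` counts the (repeated)
    bootstrap examples reaching N and ``n`` is the bootstrap sample size.
    A feature used in no split has importance exactly 0.  No rescaling to
    unit sum is applied.
    """
    imp = np.zeros(forest.n_features)
    for tree in forest.trees:
        imp += tree.tree_.compute_feature_importances(normalize=False)
    return imp / forest.config.n_trees


def per_tree_importance(forest: FittedForest) -> np.ndarray:
    """Unnormalized MDI per tree, shape ``(T, p)`` (diagnostic surface)."""
    return np.vstack(
        [t.tree_.compute_feature_importances(normalize=False) for t in forest.trees]
    )


def predict(forest: FittedForest, X) -> np.ndarray:
    """Majority vote over the trees' leaf predictions.

    Fully grown trees have pure leaves, so scikit-learn's probability
    averaging equals vote counting; ties on an even number of trees go to
    class 0.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, expected {forest.n_features}"
        )
    proba = forest.estimator.predict_proba(X)
    # argmax breaks the 0.5/0.5 tie toward the first (lower) class
    return forest.estimator.classes_[np.argmax(proba, axis=1)].astype(np.int64)


def _as_random_state(seed: int | None):
    if seed is None:
        return None
    return int(np.uint64(seed) % np.uint64(2**31))
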