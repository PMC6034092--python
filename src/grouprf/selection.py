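"""Permutation-based statistical scores for a group-importance ranking.

Starting from groups ordered by importance (s_1 >= ... >= s_G), four
procedures convert the raw scores into FWER/FDR-style quantities in [0,1]:

* **CER** (conditional error rate, a FWER control): at rank i, features of
  groups ranked i..G are row-permuted (one shared permutation vector, so
  their joint distribution survives and only the link to the labels is
  broken), the forest is refit, and CER_i is the fraction of P repetitions
  in which the best permuted tail-group score reaches the observed s_i.
* **CER^r**: same permutation scheme, but the event is "group g_i is
  ranked i-th or better among all G groups on the permuted data" -- a less
  conservative, rank-based variant.
* **eFDR**: same scheme; per repetition the false-positive count V_i is
  the longest prefix on which the descending permuted tail scores dominate
  the observed scores s_i, s_{i+1}, ...; eFDR_i is the mean of
  V_i / (V_i + i - 1) (0/0 defined as 0).
* **mProbes** (FWER): every group gets a probe copy whose rows are
  shuffled with its own permutation vector; one forest is fit on the
  doubled matrix per repetition and a group fails a repetition when any
  probe group scores at least as high as it does.

Groups are selected at level alpha by taking the ranking prefix before
the first score >= alpha (default), or every rank up to the last score
below alpha (``max_rank``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forest import ForestConfig, fit_forest, mdi_importance
from .groups import GroupScoreTable, group_scores, rank_groups
from .partition import FeaturePartition

METHODS = ("cer", "cerr", "efdr", "mprobes")
RULES = ("first_crossing", "max_rank")


@dataclass
class PermutationProtocol:
    """Shared settings of the four permutation procedures.

    Parameters
    ----------
    n_permutations : int
        Number of repetitions P; statistical scores have 1/P granularity,
        so P must exceed 1/alpha for any selection to be possible.
    alpha : float
        Risk level for selection (default 0.05).
    seed : int
        Master seed; each (rank, repetition) derives its own stream, so
        runs are reproducible and order-independent.
    forest : ForestConfig
        Forest refit at every repetition.
    aggregation : {"sum", "avg", "max"}
        Aggregation used to recompute group scores on permuted data; must
        match the observed ranking's aggregation.
    rule : {"first_crossing", "max_rank"}
        Selection rule at level alpha.
    full_curve : bool
        Evaluate every rank (for score-vs-rank curves) instead of stopping
        after the first rank whose score reaches alpha.
    early_abort : bool
        Stop a rank's repetitions as soon as the accumulated failure mass
        already guarantees a score >= alpha.  The selection decision is
        unchanged; the reported score at the crossing rank is then based
        on the repetitions actually run (and still >= alpha).
    permutations : sequence, optional
        Explicit permutation vectors overriding the random draws -- one
        row permutation per repetition for the tail procedures, one
        sequence of per-group permutations per repetition for mProbes.
        Used for exhaustive enumeration on tiny instances.
    max_ranks : int, optional
        Evaluate at most this many top ranks (with ``full_curve``, bounds
        the curve length; deeper ranks are left unevaluated).
    """

    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    forest: ForestConfig = field(default_factory=ForestConfig)
    aggregation: str = "avg"
    rule: str = "first_crossing"
    full_curve: bool = False
    early_abort: bool = False
    max_ranks: int | None = None
    permutations: Sequence | None = None

    def __post_init__(self):
        if self.permutations is not None:
            self.n_permutations = len(self.permutations)
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")


@dataclass
class SelectionResult:
    """Outcome of one selection procedure on one ranking."""

    method: str
    ranking: list[str]
    observed_scores: np.ndarray
    stat_scores: np.ndarray  # NaN at ranks never evaluated
    selected: list[str]
    alpha: float
    rule: str
    n_permutations: int
    reps_used: np.ndarray
    aggregation: str

    @property
    def ranks_evaluated(self) -> int:
        return int(np.sum(~np.isnan(self.stat_scores)))

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "group_id": self.ranking,
                "observed_score": self.observed_scores,
                "stat_score": self.stat_scores,
                "method": self.method,
                "selected": [g in sel for g in self.ranking],
            }
        )

    def save(self, path, metadata_path=None, **extra_metadata) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if metadata_path is not None:
            import json

            meta = {
                "method": self.method,
                "alpha": self.alpha,
                "rule": self.rule,
                "n_permutations": self.n_permutations,
                "aggregation": self.aggregation,
                **extra_metadata,
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2, default=str)

    def summary(self) -> str:
        lines = [
            f"{self.method}: {self.n_selected} group(s) selected at alpha={self.alpha} "
            f"({self.rule}, P={self.n_permutations}, {self.aggregation})",
        ]
        frame = self.to_frame()
        shown = frame[~np.isnan(self.stat_scores)]
        lines.append(shown.to_string(index=False))
        return "\n".join(lines)


def select_at_threshold(
    stat_scores: np.ndarray, alpha: float, rule: str = "first_crossing"
) -> int:
    """Number of top-ranked groups selected at level alpha.

    ``first_crossing`` keeps the longest prefix in which every score is
    below alpha; ``max_rank`` keeps every rank up to the last score below
    alpha.  NaN (unevaluated) scores never select.
    """
    s = np.asarray(stat_scores, dtype=float)
    below = np.zeros(s.size, dtype=bool)
    ok = ~np.isnan(s)
    below[ok] = s[ok] < alpha
    if rule == "first_crossing":
        r = int(np.argmin(below)) if not below.all() else below.size
        return r
    if rule == "max_rank":
        hits = np.flatnonzero(below)
        return int(hits[-1]) + 1 if hits.size else 0
    raise ValueError(f"rule must be one of {RULES}")


def efdr_false_positive_count(permuted_tail_scores, observed_tail_scores) -> int:
    """False-positive count V at a rank, from one permutation repetition.

    With the permuted tail scores sorted descending as s^p_(1) >= s^p_(2)
    >= ..., V is the largest k such that s^p_(j) >= s_obs_(j) for every
    j <= k -- the number of permuted groups that, rank for rank, dominate
    the observed scores.  V = 0 when even the best permuted score falls
    short.
    """
    sp = np.sort(np.asarray(permuted_tail_scores, dtype=float))[::-1]
    so = np.asarray(observed_tail_scores, dtype=float)
    if sp.shape != so.shape:
        raise ValueError("permuted and observed tails must have equal length")
    dominated = sp >= so
    return int(np.argmin(dominated)) if not dominated.all() else int(dominated.size)


def permute_tail_groups(
    X: np.ndarray,
    partition: FeaturePartition,
    ranking_order: Sequence[int],
    i: int,
    perm: np.ndarray,
) -> np.ndarray:
    """Row-permute every feature of the groups ranked i..G.

    One shared permutation vector ``perm`` is applied to all permuted
    columns so their joint distribution is preserved; only the link to the
    labels (and to the intact head groups) is destroyed.  Unassigned
    features are permuted with the tail -- they are never declared
    relevant.  Groups ranked 1..i-1 and the labels are untouched.
    """
    G = len(ranking_order)
    if not 1 <= i <= G:
        raise ValueError(f"rank i={i} outside 1..{G}")
    cols = _tail_columns(partition, ranking_order, i)
    out = X.copy()
    out[:, cols] = X[np.asarray(perm)][:, cols]
    return out


def _tail_columns(partition, ranking_order, i) -> np.ndarray:
    tail = np.zeros(partition.n_groups + 1, dtype=bool)
    tail[list(ranking_order[i - 1 :])] = True
    tail[-1] = True  # sentinel for unassigned (-1) via fancy index below
    return np.flatnonzero(tail[partition.assignment])


def repetition_rng(seed, rank: int, rep: int) -> np.random.Generator:
    """The random stream of one (rank, repetition) cell.

    Part of the reproducibility contract: every repetition derives its
    permutation vector(s) and then its forest seed (via
    :func:`derive_forest_seed`) from this generator, so runs can be
    reproduced, resumed or parallelized without changing results.
    mProbes repetitions use rank 0.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rank, rep)))


def derive_forest_seed(rng) -> int:
    """Forest seed for one repetition, drawn after its permutation(s)."""
    return int(rng.integers(0, 2**31))


def tail_permutation_scores(
    X,
    y,
    partition: FeaturePartition,
    table: GroupScoreTable,
    protocol: PermutationProtocol,
    methods: Sequence[str] = ("cer",),
) -> dict[str, SelectionResult]:
    """Run CER / CER^r / eFDR in one pass, sharing the permuted refits.

    All three condition on the same tail-permutation scheme, so requesting
    several methods costs the same G x P forest fits as one.  Ranks are
    evaluated from the top; a method stops after the first rank whose
    score reaches alpha unless ``protocol.full_curve``.
    """
    bad = [m for m in methods if m not in ("cer", "cerr", "efdr")]
    if bad:
        raise ValueError(f"unknown tail-permutation methods: {bad}")
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if table.aggregation != protocol.aggregation:
        raise ValueError(
            f"table aggregation {table.aggregation!r} != protocol {protocol.aggregation!r}"
        )
    gid_index = {g: j for j, g in enumerate(partition.group_ids)}
    order = np.array([gid_index[g] for g in table.ranking])
    s_obs = table.scores
    G = order.size
    P = protocol.n_permutations
    last_rank = G if protocol.max_ranks is None else min(G, protocol.max_ranks)

    scores = {m: np.full(G, np.nan) for m in methods}
    reps_used = {m: np.zeros(G, dtype=int) for m in methods}
    active = set(methods)

    for i in range(1, last_rank + 1):
        here = set(methods) if protocol.full_curve else set(active)
        if not here:
            break
        cols = _tail_columns(partition, order, i)
        acc = {m: 0.0 for m in here}
        reps_done = 0
        for rep in range(P):
            rng = repetition_rng(protocol.seed, i, rep)
            if protocol.permutations is not None:
                perm = np.asarray(protocol.permutations[rep])
            else:
                perm = rng.permutation(n)
            cfg = protocol.forest.replace(seed=derive_forest_seed(rng))
            Xp = X.copy()
            Xp[:, cols] = X[perm][:, cols]
            sp = group_scores(mdi_importance(fit_forest(Xp, y, cfg)), partition, protocol.aggregation)
            reps_done += 1
            if "cer" in here:
                acc["cer"] += float(np.max(sp[order[i - 1 :]]) >= s_obs[i - 1])
            if "cerr" in here:
                perm_order = rank_groups(sp, partition.group_ids)
                rank_of = int(np.flatnonzero(perm_order == order[i - 1])[0]) + 1
                acc["cerr"] += float(rank_of <= i)
            if "efdr" in here:
                V = efdr_false_positive_count(sp[order[i - 1 :]], s_obs[i - 1 :])
                denom = V + i - 1
                acc["efdr"] += V / denom if denom > 0 else 0.0
            if (
                protocol.early_abort
                and not protocol.full_curve
                and all(acc[m] >= protocol.alpha * P - 1e-12 for m in here)
            ):
                break
        for m in here:
            scores[m][i - 1] = acc[m] / reps_done
            reps_used[m][i - 1] = reps_done
        for m in list(active & here):
            if scores[m][i - 1] >= protocol.alpha:
                active.discard(m)

    out = {}
    for m in methods:
        r = select_at_threshold(scores[m], protocol.alpha, protocol.rule)
        out[m] = SelectionResult(
            method=m,
            ranking=list(table.ranking),
            observed_scores=s_obs.copy(),
            stat_scores=scores[m],
            selected=list(table.ranking[:r]),
            alpha=protocol.alpha,
            rule=protocol.rule,
            n_permutations=P,
            reps_used=reps_used[m],
            aggregation=protocol.aggregation,
        )
    return out


def cer(X, y, partition, table, protocol) -> SelectionResult:
    """Conditional error rate (FWER control) for each top rank."""
    return tail_permutation_scores(X, y, partition, table, protocol, ("cer",))["cer"]


def cer_rank(X, y, partition, table, protocol) -> SelectionResult:
    """Rank-based CER variant (less conservative than CER)."""
    return tail_permutation_scores(X, y, partition, table, protocol, ("cerr",))["cerr"]


def efdr(X, y, partition, table, protocol) -> SelectionResult:
    """Permutation estimate of the false discovery rate at each rank."""
    return tail_permutation_scores(X, y, partition, table, protocol, ("efdr",))["efdr"]


def mprobes(X, y, partition: FeaturePartition, table: GroupScoreTable, protocol) -> SelectionResult:
    """FWER estimation with random probe groups.

    Each repetition doubles the matrix with one probe copy per group, each
    probe shuffled by its own row-permutation vector (shared inside the
    group, so within-group correlation survives).  One forest per
    repetition scores all groups at once, which makes mProbes a factor G
    cheaper than the tail-permutation procedures.  Real-group scores are
    recomputed on the augmented run, since adding probes changes the
    competition for splits.
    """
    X = np.asarray(X, dtype=np.float64)
    if table.aggregation != protocol.aggregation:
        raise ValueError(
            f"table aggregation {table.aggregation!r} != protocol {protocol.aggregation!r}"
        )
    n, p = X.shape
    G = partition.n_groups
    P = protocol.n_permutations
    group_cols = [partition.indices(j) for j in range(G)]
    sizes = partition.sizes
    offsets = p + np.concatenate(([0], np.cumsum(sizes)))
    p_aug = int(offsets[-1])

    aug_assignment = np.concatenate(
        [partition.assignment, G + np.repeat(np.arange(G), sizes)]
    )
    aug_partition = FeaturePartition(
        list(partition.group_ids) + [f"probe::{g}" for g in partition.group_ids],
        aug_assignment,
    )

    fails = np.zeros(G)
    reps_done = 0
    for rep in range(P):
        rng = repetition_rng(protocol.seed, 0, rep)
        if protocol.permutations is not None:
            perms = [np.asarray(v) for v in protocol.permutations[rep]]
        else:
            perms = [rng.permutation(n) for _ in range(G)]
        cfg = protocol.forest.replace(seed=derive_forest_seed(rng))
        X_aug = np.empty((n, p_aug))
        X_aug[:, :p] = X
        for j in range(G):
            X_aug[:, offsets[j] : offsets[j + 1]] = X[perms[j]][:, group_cols[j]]
        sp = group_scores(
            mdi_importance(fit_forest(X_aug, y, cfg)), aug_partition, protocol.aggregation
        )
        real, probe = sp[:G], sp[G:]
        fails += probe.max() >= real
        reps_done += 1
        if protocol.early_abort and np.all(fails >= protocol.alpha * P - 1e-12):
            break

    per_group = fails / reps_done
    gid_index = {g: j for j, g in enumerate(partition.group_ids)}
    stat = np.array([per_group[gid_index[g]] for g in table.ranking])
    r = select_at_threshold(stat, protocol.alpha, protocol.rule)
    return SelectionResult(
        method="mprobes",
        ranking=list(table.ranking),
        observed_scores=table.scores.copy(),
        stat_scores=stat,
        selected=list(table.ranking[:r]),
        alpha=protocol.alpha,
        rule=protocol.rule,
        n_permutations=P,
        reps_used=np.full(G, reps_done),
        aggregation=protocol.aggregation,
    )


def run_method(method: str, X, y, partition, table, protocol) -> SelectionResult:
    """Dispatch by method name ("cer", "cerr", "efdr", "mprobes")."""
    if method == "mprobes":
        return mprobes(X, y, partition, table, protocol)
    if method in ("cer", "cerr", "efdr"):
        return tail_permutation_scores(X, y, partition, table, protocol, (method,))[method]
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
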