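"""Reproducible end-to-end runs: ranking, selection, benchmark grids.

Every run writes its tables together with a metadata sidecar holding all
seeds and parameters, so an interrupted benchmark can be re-run and yield
the identical final table (per-dataset seeds derive from the cell and the
dataset index, never from global state).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, io
from .model import GroupImportanceRF
from .partition import FeaturePartition
from .synthetic import SyntheticSpec, generate


def run_rank(
    X,
    y,
    partition: FeaturePartition,
    aggregation: str = "avg",
    n_trees: int = 1000,
    k="sqrt",
    bootstrap: bool = True,
    seed: int | None = None,
    out_dir=None,
):
    """Fit, aggregate and rank; optionally persist table + metadata."""
    res = GroupImportanceRF(X, y, partition, aggregation).fit(
        n_trees=n_trees, k=k, bootstrap=bootstrap, seed=seed
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        res.group_scores.save(out_dir / "group_scores.tsv")
        io.write_metadata(
            out_dir / "rank_metadata.json",
            aggregation=aggregation,
            n_trees=n_trees,
            k=k,
            bootstrap=bootstrap,
            seed=seed,
            n_samples=int(np.asarray(X).shape[0]),
            n_features=int(np.asarray(X).shape[1]),
            n_groups=partition.n_groups,
        )
    return res


@dataclass
class BenchmarkCell:
    """One cell of a benchmark grid on the synthetic linear problem."""

    method: str = "cer"
    aggregation: str = "avg"
    R: int = 5
    n: int = 100
    p: int = 500
    g: int = 50
    k: int | str = "sqrt"
    n_trees: int = 1000
    n_permutations: int = 1000
    alpha: float = 0.05
    rule: str = "first_crossing"
    early_abort: bool = False


def run_benchmark_cell(
    cell: BenchmarkCell, n_datasets: int, seed: int = 0
) -> pd.DataFrame:
    """Generate ``n_datasets`` datasets for one cell; rank, select, score.

    Returns one row per dataset with the selection-quality metrics
    (relevant/irrelevant groups selected, precision, recall, AUPR).
    Dataset seeds derive from ``(seed, dataset index)``, so a re-run (or a
    resumed run) reproduces the table exactly.
    """
    rows = []
    for d in range(n_datasets):
        ds_seed, fit_seed, sel_seed = _dataset_seeds(seed, d)
        X, y, truth = generate(
            SyntheticSpec(p=cell.p, g=cell.g, R=cell.R, n=cell.n, seed=ds_seed)
        )
        res = GroupImportanceRF(X, y, truth.partition, cell.aggregation).fit(
            n_trees=cell.n_trees, k=cell.k, seed=fit_seed
        )
        sel = res.select(
            method=cell.method,
            alpha=cell.alpha,
            n_permutations=cell.n_permutations,
            seed=sel_seed,
            rule=cell.rule,
            early_abort=cell.early_abort,
        )
        truth_set = set(truth.relevant_groups)
        precision, recall = evaluation.precision_recall(sel.selected, truth_set)
        n_rel = sum(1 for g in sel.selected if g in truth_set)
        rows.append(
            {
                "dataset": d,
                "method": cell.method,
                "aggregation": cell.aggregation,
                "R": cell.R,
                "n": cell.n,
                "n_selected": sel.n_selected,
                "n_relevant_selected": n_rel,
                "n_irrelevant_selected": sel.n_selected - n_rel,
                "n_features_selected": int(
                    sum(truth.partition.sizes[truth.partition.group_ids.index(g)] for g in sel.selected)
                ),
                "precision": precision,
                "recall": recall,
                "aupr": evaluation.aupr(res.ranking, truth_set),
            }
        )
    return pd.DataFrame(rows)


def _dataset_seeds(seed: int, index: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence(seed, spawn_key=(index,))
    a, b, c = (int(s) for s in ss.generate_state(3) % 2**31)
    return a, b, c


def replicate_selection_study(
    n_datasets: int = 5,
    R: int = 5,
    n: int = 100,
    p: int = 500,
    g: int = 50,
    n_trees: int = 150,
    k="sqrt",
    n_permutations: int = 100,
    alpha: float = 0.05,
    aggregation: str = "avg",
    methods=("cer", "efdr", "mprobes"),
    rule: str = "first_crossing",
    early_abort: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Selection-quality replication on the synthetic linear benchmark.

    For each generated dataset, ranks groups once, then runs the requested
    selection procedures (the tail-permutation ones share their permuted
    refits) and counts relevant/irrelevant groups selected at level alpha.
    Returns one row per (dataset, method).
    """
    from .selection import PermutationProtocol, mprobes, tail_permutation_scores

    rows = []
    tail_methods = tuple(m for m in methods if m in ("cer", "cerr", "efdr"))
    for d in range(n_datasets):
        ds_seed, fit_seed, sel_seed = _dataset_seeds(seed, d)
        X, y, truth = generate(SyntheticSpec(p=p, g=g, R=R, n=n, seed=ds_seed))
        res = GroupImportanceRF(X, y, truth.partition, aggregation).fit(
            n_trees=n_trees, k=k, seed=fit_seed
        )
        protocol = PermutationProtocol(
            n_permutations=n_permutations,
            alpha=alpha,
            seed=sel_seed,
            forest=res.forest.config,
            aggregation=aggregation,
            rule=rule,
            early_abort=early_abort,
        )
        out = {}
        if tail_methods:
            out.update(
                tail_permutation_scores(
                    X, y, truth.partition, res.group_scores, protocol, tail_methods
                )
            )
        if "mprobes" in methods:
            out["mprobes"] = mprobes(X, y, truth.partition, res.group_scores, protocol)
        rel = set(truth.relevant_groups)
        for m, sel in out.items():
            n_rel = sum(1 for gid in sel.selected if gid in rel)
            rows.append(
                {
                    "dataset": d,
                    "method": m,
                    "n_selected": sel.n_selected,
                    "n_relevant_selected": n_rel,
                    "n_irrelevant_selected": sel.n_selected - n_rel,
                }
            )
    return pd.DataFrame(rows)


def aggregation_ordering_study(
    n_datasets: int = 5,
    R: int = 5,
    n: int = 100,
    p: int = 500,
    g: int = 50,
    n_trees: int = 300,
    k: int | str = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranking quality of avg vs sum aggregation from the same forests.

    At K = 1 every feature is equally likely to be picked for a split, so
    the summed group importance tracks group size; the average removes the
    size bias and ranks relevant groups higher.  Returns per-dataset AUPRs
    of both aggregations and the Spearman correlation of each group score
    with group size.
    """
    from scipy.stats import spearmanr

    from .forest import ForestConfig, fit_forest, mdi_importance
    from .groups import aggregate, group_scores

    rows = []
    for d in range(n_datasets):
        ds_seed, fit_seed, _ = _dataset_seeds(seed, d)
        X, y, truth = generate(SyntheticSpec(p=p, g=g, R=R, n=n, seed=ds_seed))
        forest = fit_forest(X, y, ForestConfig(n_trees=n_trees, k=k, seed=fit_seed))
        imp = mdi_importance(forest)
        part = truth.partition
        rel = set(truth.relevant_groups)
        row = {"dataset": d}
        for method in ("avg", "sum"):
            table = aggregate(imp, part, method)
            row[f"aupr_{method}"] = evaluation.aupr(table.ranking, rel)
            row[f"size_corr_{method}"] = float(
                spearmanr(group_scores(imp, part, method), part.sizes).statistic
            )
        rows.append(row)
    return pd.DataFrame(rows)


def null_fwer_study(
    n_replicates: int = 20,
    n: int = 100,
    p: int = 500,
    g: int = 20,
    n_trees: int = 100,
    n_permutations: int = 100,
    alpha: float = 0.05,
    aggregation: str = "avg",
    methods=("cer", "mprobes"),
    seed: int = 0,
) -> pd.DataFrame:
    """FWER under the global null (labels independent of every feature).

    Generates pure-noise datasets (R = 0) and records, per replicate, how
    many groups each procedure selects; a FWER-controlling procedure at
    alpha = 0.05 should select anything at all in only a small fraction of
    replicates.
    """
    from .selection import PermutationProtocol, mprobes, tail_permutation_scores

    rows = []
    tail_methods = tuple(m for m in methods if m in ("cer", "cerr", "efdr"))
    for r in range(n_replicates):
        ds_seed, fit_seed, sel_seed = _dataset_seeds(seed, r)
        X, y, truth = generate(SyntheticSpec(p=p, g=g, R=0, n=n, seed=ds_seed))
        res = GroupImportanceRF(X, y, truth.partition, aggregation).fit(
            n_trees=n_trees, k="sqrt", seed=fit_seed
        )
        protocol = PermutationProtocol(
            n_permutations=n_permutations,
            alpha=alpha,
            seed=sel_seed,
            forest=res.forest.config,
            aggregation=aggregation,
            early_abort=True,
        )
        out = {}
        if tail_methods:
            out.update(
                tail_permutation_scores(
                    X, y, truth.partition, res.group_scores, protocol, tail_methods
                )
            )
        if "mprobes" in methods:
            out["mprobes"] = mprobes(X, y, truth.partition, res.group_scores, protocol)
        for m, sel in out.items():
            rows.append({"replicate": r, "method": m, "n_selected": sel.n_selected})
    return pd.DataFrame(rows)


def run_benchmark(
    cells, n_datasets: int, seed: int = 0, out_dir=None
) -> pd.DataFrame:
    """Run a grid of cells; returns per-dataset rows plus one mean row per cell."""
    frames = []
    for c, cell in enumerate(cells):
        per = run_benchmark_cell(cell, n_datasets, seed=seed + c)
        mean = per.drop(columns=["dataset"]).select_dtypes("number").mean().to_dict()
        mean_row = {**per.iloc[0][["method", "aggregation"]].to_dict(), **mean, "dataset": "mean"}
        frames.append(pd.concat([per, pd.DataFrame([mean_row])], ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_dir / "benchmark.tsv", sep="\t", index=False)
        io.write_metadata(
            out_dir / "benchmark_metadata.json",
            seed=seed,
            n_datasets=n_datasets,
            cells=[vars(c) for c in cells],
        )
    return out
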