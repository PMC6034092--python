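import numpy as np
import pytest

from grouprf.forest import ForestConfig
from grouprf.groups import aggregate
from grouprf.model import GroupImportanceRF
from grouprf.partition import FeaturePartition
from grouprf.selection import (
    PermutationProtocol,
    cer,
    cer_rank,
    efdr,
    efdr_false_positive_count,
    mprobes,
    permute_tail_groups,
    select_at_threshold,
    tail_permutation_scores,
)


def small_protocol(**kw):
    defaults = dict(
        n_permutations=20,
        alpha=0.05,
        seed=0,
        forest=ForestConfig(n_trees=10, k="sqrt", bootstrap=True, seed=0),
        aggregation="avg",
    )
    defaults.update(kw)
    return PermutationProtocol(**defaults)


class TestSelectAtThreshold:
    def test_first_crossing(self):
        assert select_at_threshold([0.01, 0.02, 0.3, 0.04], 0.05, "first_crossing") == 2

    def test_max_rank(self):
        assert select_at_threshold([0.01, 0.02, 0.3, 0.04], 0.05, "max_rank") == 4

    def test_alpha_zero_selects_nothing(self):
        for rule in ("first_crossing", "max_rank"):
            assert select_at_threshold([0.01, 0.02], 0.0, rule) == 0

    def test_nan_blocks_selection(self):
        assert select_at_threshold([0.01, np.nan, 0.01], 0.05, "first_crossing") == 1

    def test_all_below(self):
        assert select_at_threshold([0.0, 0.0], 0.05, "first_crossing") == 2


class TestPermuteTailGroups:
    def test_identity_permutation_leaves_matrix_unchanged(self, three_group_partition, rng):
        X = rng.normal(size=(4, 6))
        out = permute_tail_groups(X, three_group_partition, [0, 1, 2], 1, np.arange(4))
        np.testing.assert_array_equal(out, X)

    def test_rank_bounds(self, three_group_partition, rng):
        X = rng.normal(size=(4, 6))
        with pytest.raises(ValueError):
            permute_tail_groups(X, three_group_partition, [0, 1, 2], 4, np.arange(4))
        with pytest.raises(ValueError):
            permute_tail_groups(X, three_group_partition, [0, 1, 2], 0, np.arange(4))

    def test_last_rank_permutes_only_last_group_and_unassigned(
        self, three_group_partition, rng
    ):
        X = rng.normal(size=(4, 6))
        perm = np.array([2, 3, 0, 1])
        out = permute_tail_groups(X, three_group_partition, [0, 1, 2], 3, perm)
        np.testing.assert_array_equal(out[:, :4], X[:, :4])  # groups A, B intact
        np.testing.assert_array_equal(out[:, 4:], X[perm][:, 4:])  # C + unassigned

    def test_matches_row_shuffle_oracle_and_preserves_tail_correlation(
        self, three_group_partition, rng
    ):
        """All tail columns receive the SAME row shuffle, so the joint rows
        of the tail block are exactly the original rows, reordered."""
        X = rng.normal(size=(4, 6))
        ranking = [2, 0, 1]  # C ranked first; tail at i=2 is groups A, B
        perm = np.array([1, 3, 2, 0])
        out = permute_tail_groups(X, three_group_partition, ranking, 2, perm)
        tail_cols = [0, 1, 2, 3, 5]  # A, B and the unassigned feature
        oracle = X.copy()
        oracle[:, tail_cols] = X[perm][:, tail_cols]
        np.testing.assert_array_equal(out, oracle)
        # within-tail correlation structure preserved exactly (same rows)
        np.testing.assert_allclose(
            np.corrcoef(out[:, tail_cols], rowvar=False),
            np.corrcoef(X[:, tail_cols], rowvar=False),
            atol=1e-12,
        )
        np.testing.assert_array_equal(out[:, 4], X[:, 4])  # head group intact


class TestEfdrFalsePositiveCount:
    def test_spec_example(self):
        # observed ordered scores (5,4,3,2); at rank i=2 the observed tail
        # is (4,3,2); permuted tail (4.5, 1.0, 0.5): k=1 holds, k=2 fails
        assert efdr_false_positive_count([4.5, 1.0, 0.5], [4.0, 3.0, 2.0]) == 1

    def test_zero_when_nothing_dominates(self):
        assert efdr_false_positive_count([0.0, 0.0], [0.1, 0.05]) == 0

    def test_full_domination(self):
        assert efdr_false_positive_count([9.0, 8.0], [1.0, 2.0]) == 2

    def test_unsorted_input_is_sorted_internally(self):
        assert efdr_false_positive_count([1.0, 4.5, 0.5], [4.0, 3.0, 2.0]) == 1


@pytest.fixture(scope="module")
def fitted_tiny():
    from grouprf.synthetic import SyntheticSpec, generate

    X, y, truth = generate(SyntheticSpec(p=30, g=3, R=1, n=30, seed=5))
    res = GroupImportanceRF(X, y, truth.partition, "avg").fit(n_trees=10, seed=1)
    return X, y, truth.partition, res.group_scores


class TestScoreProperties:
    def test_scores_in_unit_interval_and_multiples_of_inv_p(self, fitted_tiny):
        X, y, part, table = fitted_tiny
        proto = small_protocol(full_curve=True)
        results = tail_permutation_scores(X, y, part, table, proto, ("cer", "cerr"))
        results["mprobes"] = mprobes(X, y, part, table, small_protocol())
        for m, res in results.items():
            s = res.stat_scores[~np.isnan(res.stat_scores)]
            assert ((0 <= s) & (s <= 1)).all()
            np.testing.assert_allclose(s * proto.n_permutations, np.round(s * 20), atol=1e-9)

    def test_efdr_in_unit_interval(self, fitted_tiny):
        X, y, part, table = fitted_tiny
        res = efdr(X, y, part, table, small_protocol(full_curve=True))
        s = res.stat_scores
        assert ((0 <= s) & (s <= 1)).all()

    def test_deterministic_given_seed(self, fitted_tiny):
        X, y, part, table = fitted_tiny
        a = cer(X, y, part, table, small_protocol(seed=9))
        b = cer(X, y, part, table, small_protocol(seed=9))
        np.testing.assert_array_equal(a.stat_scores, b.stat_scores)
        assert a.selected == b.selected

    def test_shared_pass_equals_individual_runs(self, fitted_tiny):
        """cer/cerr/efdr computed together (sharing refits) equal the
        separately computed results -- seeds derive from (rank, rep)."""
        X, y, part, table = fitted_tiny
        shared = tail_permutation_scores(
            X, y, part, table, small_protocol(full_curve=True), ("cer", "cerr", "efdr")
        )
        np.testing.assert_array_equal(
            shared["cer"].stat_scores,
            cer(X, y, part, table, small_protocol(full_curve=True)).stat_scores,
        )
        np.testing.assert_array_equal(
            shared["efdr"].stat_scores,
            efdr(X, y, part, table, small_protocol(full_curve=True)).stat_scores,
        )

    def test_first_crossing_stops_early(self, fitted_tiny):
        X, y, part, table = fitted_tiny
        res = cer(X, y, part, table, small_protocol())
        evaluated = ~np.isnan(res.stat_scores)
        # evaluated ranks form a prefix; all but possibly the last are < alpha
        k = res.ranks_evaluated
        assert evaluated[:k].all() and not evaluated[k:].any()
        assert res.selected == res.ranking[: len(res.selected)]

    def test_low_resolution_estimator_only_selects_exact_zeros(self, fitted_tiny):
        """With P <= 1/alpha the estimator's resolution is 1/P >= alpha, so
        only ranks whose permutations NEVER dominate (score exactly 0) can
        be selected."""
        X, y, part, table = fitted_tiny
        res = cer(X, y, part, table, small_protocol(n_permutations=10, alpha=0.05))
        for g in res.selected:
            assert res.stat_scores[res.ranking.index(g)] == 0.0

    def test_zero_observed_score_gives_cer_one(self):
        """A group whose observed score is 0 can always be matched by the
        non-negative permuted scores."""
        X = np.random.default_rng(3).normal(size=(12, 4))
        y = np.array([0, 1] * 6)
        X[:, 2] = 0.0  # group C constant -> importance exactly 0
        X[:, 3] = 0.0
        part = FeaturePartition(["A", "B", "C"], [0, 1, 2, 2])
        res_fit = GroupImportanceRF(X, y, part, "avg").fit(
            n_trees=5, k="all", bootstrap=False, seed=0
        )
        assert res_fit.group_scores.frame.set_index("group_id").loc["C", "score"] == 0
        proto = small_protocol(
            n_permutations=5,
            forest=ForestConfig(n_trees=5, k="all", bootstrap=False, seed=0),
            full_curve=True,
        )
        res = cer(X, y, part, res_fit.group_scores, proto)
        assert res.stat_scores[res.ranking.index("C")] == 1.0

    def test_single_group_cer_rank_is_one(self):
        """With G=1, rank(g_1) <= 1 always, so CER^r_1 = 1: no selection."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(14, 3))
        y = rng.integers(0, 2, 14)
        y[:7] = 0
        y[7:] = 1
        part = FeaturePartition(["only"], [0, 0, 0])
        table = aggregate(np.array([0.1, 0.2, 0.3]), part, "avg")
        res = cer_rank(X, y, part, table, small_protocol(n_permutations=6))
        assert res.stat_scores[0] == 1.0
        assert res.selected == []

    def test_mprobes_scores_and_metadata(self, fitted_tiny, tmp_path):
        X, y, part, table = fitted_tiny
        res = mprobes(X, y, part, table, small_protocol())
        assert res.method == "mprobes"
        assert res.ranks_evaluated == part.n_groups
        frame = res.to_frame()
        assert frame["rank"].tolist() == [1, 2, 3]
        res.save(tmp_path / "sel.tsv", metadata_path=tmp_path / "meta.json", seed=0)
        assert (tmp_path / "meta.json").exists()

    def test_aggregation_mismatch_rejected(self, fitted_tiny):
        X, y, part, table = fitted_tiny
        with pytest.raises(ValueError, match="aggregation"):
            cer(X, y, part, table, small_protocol(aggregation="max"))

    def test_early_abort_preserves_selection(self, fitted_tiny):
        X, y, part, table = fitted_tiny
        full = cer(X, y, part, table, small_protocol(seed=4))
        aborted = cer(X, y, part, table, small_protocol(seed=4, early_abort=True))
        assert full.selected == aborted.selected
        # the crossing-rank score under abort is still a valid failure rate
        k = aborted.ranks_evaluated - 1
        if not np.isnan(aborted.stat_scores[k]) and aborted.stat_scores[k] >= 0.05:
            assert aborted.stat_scores[k] >= aborted.alpha
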