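import numpy as np
import pandas as pd
import pytest

from hrvcohort.selection import (
    ForestParams,
    SurvivalForest,
    fit_survival_forest,
    logrank_statistic,
    rank_by_hits,
    select_top_union,
)
from hrvcohort.synthetic import CohortGenParams, gen_cohort
from oracles import logrank_naive


class TestLiteratureRanking:
    def test_descending_by_hits(self):
        table = pd.DataFrame(
            {"marker": ["sdnn", "lf", "dc"], "hit_count": [500, 300, 10]}
        )
        assert rank_by_hits(table, 2) == ["sdnn", "lf"]

    def test_tie_broken_lexicographically(self):
        table = pd.DataFrame({"marker": ["b", "a"], "hit_count": [5, 5]})
        assert rank_by_hits(table, 1) == ["a"]

    def test_full_ranking_is_permutation(self):
        table = pd.DataFrame(
            {"marker": list("edcba"), "hit_count": [1, 5, 3, 2, 4]}
        )
        assert sorted(rank_by_hits(table)) == sorted(table["marker"])

    def test_duplicates_rejected(self):
        table = pd.DataFrame({"marker": ["a", "a"], "hit_count": [1, 2]})
        with pytest.raises(ValueError, match="duplicate"):
            rank_by_hits(table, 1)


class TestLogrank:
    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            t = rng.exponential(size=n).round(2)  # induce some ties
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n).astype(bool)
            if e.sum() == 0:
                continue
            assert logrank_statistic(t, e, g) == pytest.approx(
                logrank_naive(t, e, g), abs=1e-10
            )

    def test_zero_when_one_group_empty(self):
        assert logrank_statistic([1, 2, 3], [1, 1, 0], [False] * 3) == 0.0

    def test_chi_square_matches_scikit_survival(self, rng):
        # independent library cross-check: the squared standardized
        # statistic is the log-rank chi-square
        from sksurv.compare import compare_survival

        n = 80
        t = rng.exponential(size=n).round(2)
        e = rng.integers(0, 2, n)
        e[:10] = 1
        g = rng.integers(0, 2, n)
        y = np.array([(bool(ei), ti) for ei, ti in zip(e, t)],
                     dtype=[("event", "?"), ("time", "<f8")])
        chisq, _ = compare_survival(y, g)
        z = logrank_statistic(t, e, g.astype(bool))
        assert z ** 2 == pytest.approx(chisq, abs=1e-8)


class TestForest:
    def _toy(self):
        # binary column perfectly separating early deaths from late censorings
        X = pd.DataFrame(
            {
                "flag": [1, 1, 1, 1, 0, 0, 0, 0],
                "noise": [0.1, 0.9, 0.4, 0.3, 0.8, 0.2, 0.6, 0.5],
            }
        )
        time = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        event = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        return X, time, event

    def test_separating_column_splits_root(self):
        # grow a single tree on the full sample (no bootstrap) so the
        # log-rank-maximal split is checkable by hand
        X, t, e = self._toy()
        model = SurvivalForest(
            X, t, e,
            params=ForestParams(n_trees=1, min_node_size=2,
                                min_node_deaths=1, seed=0),
        )
        root = model._grow(np.arange(len(t)), 0, np.random.default_rng(0))
        assert model.feature_names[root.var] == "flag"

    def test_same_seed_identical_forest(self):
        X, t, e = self._toy()
        params = ForestParams(n_trees=5, min_node_size=2, min_node_deaths=1, seed=7)
        a = fit_survival_forest(X, t, e, params=params)
        b = fit_survival_forest(X, t, e, params=params)

        def describe(node):
            if node.is_leaf:
                return ("leaf", node.n)
            return (node.var, node.value, describe(node.left), describe(node.right))

        assert [describe(tr) for tr in a.trees] == [describe(tr) for tr in b.trees]
        assert all((x == y).all() for x, y in zip(a.in_bag, b.in_bag))

    def test_bootstrap_in_bag_size_with_repeats(self):
        X, t, e = self._toy()
        res = fit_survival_forest(
            X, t, e, params=ForestParams(n_trees=10, seed=3)
        )
        for bag in res.in_bag:
            assert len(bag) == len(t)
        assert any(len(np.unique(bag)) < len(t) for bag in res.in_bag)

    def test_zero_events_refused(self):
        X, t, e = self._toy()
        with pytest.raises(ValueError, match="event"):
            SurvivalForest(X, t, np.zeros_like(e))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        n = 60
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t = rng.exponential(np.exp(-X["a"]))
        e = rng.integers(0, 2, n)
        e[0] = 1
        params = ForestParams(n_trees=10, min_node_size=5, min_node_deaths=1, seed=9)
        res1 = fit_survival_forest(X, t, e, params=params)
        X2 = X.copy()
        X2["a"] = np.exp(X2["a"])  # strictly monotone transform
        res2 = fit_survival_forest(X2, t, e, params=params)

        def structure(node):
            if node.is_leaf:
                return ("leaf", node.n, node.n_events)
            return (node.var, structure(node.left), structure(node.right))

        assert [structure(tr) for tr in res1.trees] == [
            structure(tr) for tr in res2.trees
        ]
        pd.testing.assert_series_equal(
            res1.minimal_depth_importance(), res2.minimal_depth_importance()
        )


class TestMinimalDepth:
    def test_root_splitter_has_depth_zero(self):
        X = pd.DataFrame({"flag": [1, 1, 1, 1, 0, 0, 0, 0], "z": np.zeros(8)})
        t = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = fit_survival_forest(
            X, t, e, params=ForestParams(n_trees=5, min_node_size=2,
                                         min_node_deaths=1, seed=1)
        )
        imp = res.minimal_depth_importance()
        assert imp["flag"] == 0.0
        # the constant column is never split: worst possible depth
        assert imp["z"] > imp["flag"]

    def test_hazard_driver_ranked_above_noise(self):
        p = CohortGenParams(
            n_subjects=300, healthy_fraction=0.0,
            marker_dists={"driver": ((0, 1), (0, 1)), "noise1": ((0, 1), (0, 1)),
                          "noise2": ((0, 1), (0, 1))},
            log_hr_per_sd={"driver": 1.0}, weibull_scale=20.0, seed=77,
        )
        b = gen_cohort(p)
        X = b.markers[["driver", "noise1", "noise2"]].copy()
        X["age"] = b.covariates["age"]
        X["sex"] = b.covariates["sex"]
        res = fit_survival_forest(
            X, b.covariates["time_all_cause"], b.covariates["event_all_cause"],
            params=ForestParams(n_trees=100, seed=1), forced=("age", "sex"),
        )
        ranking = res.ranking(exclude_forced=True)
        assert ranking[0] == "driver"


class TestUnion:
    def test_disjoint_lists_give_twenty(self):
        lit = [f"l{i}" for i in range(10)]
        forest = [f"f{i}" for i in range(10)]
        assert len(select_top_union(lit, forest, 10)) == 20

    def test_identical_lists_give_ten(self):
        lst = [f"m{i}" for i in range(10)]
        sel = select_top_union(lst, lst, 10)
        assert len(sel) == 10
        assert all(src == "both" for src in sel.values())

    def test_single_overlap_gives_nineteen(self):
        lit = [f"l{i}" for i in range(10)]
        forest = ["l0"] + [f"f{i}" for i in range(9)]
        sel = select_top_union(lit, forest, 10)
        assert len(sel) == 19
        assert sel["l0"] == "both"

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            select_top_union(["a"], ["b"], 2)
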