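"""Dual-track marker selection.

Two rankings are combined: (1) a literature ranking of markers by
cardiovascular publication hit counts (supplied as a table; the search
itself is an external, non-reproducible step), and (2) a data-driven ranking
from a random survival forest predicting cardiac death, with age and sex as
forced covariates and mean minimal depth as the importance metric (the
shallower a marker's first split, the more important it is). The selected
set is the union of the top k (default 10) markers of each ranking.

The forest grows binary survival trees on bootstrap samples; at each node a
random subset of markers (plus the forced covariates) is screened, and the
split maximising the standardized two-sample log-rank statistic over a
deterministic grid of candidate cut points is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForestParams",
    "TreeNode",
    "SurvivalForest",
    "SurvivalForestResults",
    "logrank_statistic",
    "rank_by_hits",
    "fit_survival_forest",
    "minimal_depth_importance",
    "select_top_union",
]


def logrank_statistic(time, event, group) -> float:
    """Standardized two-sample log-rank statistic.

    ``group`` is a boolean membership vector; returns (O1 - E1) / sqrt(V)
    where O1/E1 are observed/expected events in group 1 and V the
    hypergeometric variance, summed over distinct event times. Zero when the
    variance vanishes (no events, or one group empty).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    group = np.asarray(group, dtype=float)
    n = len(time)
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], group[order]
    ut, inv = np.unique(t, return_inverse=True)
    n_at = np.bincount(inv).astype(float)
    d = np.bincount(inv, weights=e)
    d1 = np.bincount(inv, weights=e * g)
    n1_at = np.bincount(inv, weights=g)
    # risk sets: subjects with time >= ut[k]
    Y = n - np.concatenate(([0.0], np.cumsum(n_at)[:-1]))
    Y1 = np.sum(g) - np.concatenate(([0.0], np.cumsum(n1_at)[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = Y1 * d / Y
        var = (Y1 / Y) * (1.0 - Y1 / Y) * d * (Y - d) / np.where(Y > 1, Y - 1, 1.0)
    var = np.where(Y > 1, var, 0.0)
    keep = d > 0
    num = float(np.sum((d1 - expected)[keep]))
    V = float(np.sum(var[keep]))
    if V <= 0:
        return 0.0
    return num / math.sqrt(V)


@dataclass
class ForestParams:
    """Random-survival-forest hyperparameters.

    ``mtry`` defaults to ceil(sqrt(#markers)); candidate split values per
    screened variable are its node-level quantiles at ``n_split_candidates``
    evenly spaced probabilities (deterministic given the data and seed).
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_deaths: int = 3
    min_node_size: int = 15
    n_split_candidates: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_trees", "min_node_deaths", "min_node_size", "n_split_candidates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.mtry is not None and self.mtry <= 0:
            raise ValueError("mtry must be a positive integer")


@dataclass
class TreeNode:
    depth: int
    n: int
    n_events: int
    var: int | None = None  # split variable index; None for a leaf
    value: float | None = None  # split threshold (left: x <= value)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None


class SurvivalForest:
    """Random survival forest model (log-rank splitting).

    Parameters
    ----------
    X : array or DataFrame, subjects x variables. All variables are split
        candidates; ``forced`` names variables added to every node's
        candidate set in addition to the ``mtry`` sampled ones (used for the
        age/sex adjustment).
    time, event : survival outcome (event=1 observed, 0 censored).
    """

    def __init__(self, X, time, event, feature_names=None, forced=(), params=None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        if np.isnan(self.X).any():
            raise ValueError("X must not contain missing values")
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if self.event.sum() < 1:
            raise ValueError("survival forest needs at least one event")
        n, p = self.X.shape
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{j}" for j in range(p)]
        )
        self.forced_idx = [self.feature_names.index(f) for f in forced]
        self.params = params or ForestParams()
        free = [j for j in range(p) if j not in self.forced_idx]
        self._free_idx = np.asarray(free, dtype=int)
        self._mtry = self.params.mtry or max(1, math.ceil(math.sqrt(len(free))))

    # -- tree growing -------------------------------------------------------

    def _best_split(self, idx: np.ndarray, cand_vars: np.ndarray, rng):
        t, e = self.time[idx], self.event[idx]
        best = (0.0, None, None)
        probs = np.linspace(0.0, 1.0, self.params.n_split_candidates + 2)[1:-1]
        for j in cand_vars:
            xv = self.X[idx, j]
            if xv.max() == xv.min():
                continue  # constant column: never selected
            cuts = np.unique(np.quantile(xv, probs))
            for c in cuts:
                left = xv <= c
                nl = int(left.sum())
                if nl == 0 or nl == len(idx):
                    continue
                stat = abs(logrank_statistic(t, e, left))
                if stat > best[0] + 1e-12:
                    best = (stat, int(j), float(c))
        return best

    def _grow(self, idx: np.ndarray, depth: int, rng) -> TreeNode:
        node = TreeNode(depth=depth, n=len(idx), n_events=int(self.event[idx].sum()))
        if (
            node.n < self.params.min_node_size
            or node.n_events < self.params.min_node_deaths
        ):
            return node
        n_free = min(self._mtry, len(self._free_idx))
        sampled = rng.choice(self._free_idx, size=n_free, replace=False)
        cand = np.concatenate([sampled, np.asarray(self.forced_idx, dtype=int)])
        stat, var, value = self._best_split(idx, cand, rng)
        if var is None or stat == 0.0:
            return node
        left_mask = self.X[idx, var] <= value
        node.var, node.value = var, value
        node.left = self._grow(idx[left_mask], depth + 1, rng)
        node.right = self._grow(idx[~left_mask], depth + 1, rng)
        return node

    def fit(self) -> "SurvivalForestResults":
        rng = np.random.default_rng(self.params.seed)
        n = len(self.time)
        trees, in_bag = [], []
        for _ in range(self.params.n_trees):
            bag = rng.integers(0, n, size=n)
            trees.append(self._grow(np.asarray(bag), 0, rng))
            in_bag.append(bag)
        return SurvivalForestResults(self, trees, in_bag)


def _tree_min_depths(root: TreeNode, p: int) -> tuple[np.ndarray, int]:
    """Per-variable minimal split depth in one tree, and max terminal depth."""
    depths = np.full(p, np.inf)
    max_depth = 0
    stack = [root]
    while stack:
        node = stack.pop()
        max_depth = max(max_depth, node.depth)
        if not node.is_leaf:
            depths[node.var] = min(depths[node.var], node.depth)
            stack.extend([node.left, node.right])
    return depths, max_depth


class SurvivalForestResults:
    """Fitted forest: trees, in-bag indices, and minimal-depth importances."""

    def __init__(self, model: SurvivalForest, trees, in_bag):
        self.model = model
        self.trees = trees
        self.in_bag = in_bag

    def minimal_depth_importance(self) -> pd.Series:
        """Mean minimal depth per variable (ascending = most important).

        Variables never split in a tree are assigned that tree's maximal
        terminal depth (the worst observable depth), penalising absence.
        """
        p = self.model.X.shape[1]
        total = np.zeros(p)
        for tree in self.trees:
            depths, max_depth = _tree_min_depths(tree, p)
            depths = np.where(np.isfinite(depths), depths, float(max_depth))
            total += depths
        mean_depth = total / len(self.trees)
        return pd.Series(mean_depth, index=self.model.feature_names).sort_values(
            kind="mergesort"
        )

    def ranking(self, exclude_forced: bool = True) -> list[str]:
        imp = self.minimal_depth_importance()
        if exclude_forced:
            forced = {self.model.feature_names[j] for j in self.model.forced_idx}
            imp = imp[~imp.index.isin(forced)]
        return list(imp.index)

    def summary(self) -> pd.DataFrame:
        imp = self.minimal_depth_importance()
        return pd.DataFrame(
            {
                "variable": imp.index,
                "mean_minimal_depth": imp.to_numpy(),
                "rank": np.arange(1, len(imp) + 1),
            }
        ).reset_index(drop=True)


def fit_survival_forest(
    X, time, event, params: ForestParams | None = None,
    feature_names=None, forced=(),
) -> SurvivalForestResults:
    """Convenience wrapper: build and fit a :class:`SurvivalForest`."""
    return SurvivalForest(
        X, time, event, feature_names=feature_names, forced=forced,
        params=params or ForestParams(),
    ).fit()


def minimal_depth_importance(results: SurvivalForestResults) -> pd.Series:
    return results.minimal_depth_importance()


def rank_by_hits(table: pd.DataFrame, k: int | None = None) -> list[str]:
    """Top-k markers by literature hit count, descending.

    Ties are broken by marker-name lexicographic order so the ranking is
    deterministic. Duplicate marker names are a validation error.
    """
    if table["marker"].duplicated().any():
        dupes = table.loc[table["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"duplicate marker names in literature table: {dupes}")
    if (table["hit_count"] < 0).any():
        raise ValueError("hit counts must be non-negative")
    ordered = table.sort_values(
        ["hit_count", "marker"], ascending=[False, True], kind="mergesort"
    )["marker"].tolist()
    if k is None:
        return ordered
    if k > len(ordered):
        raise ValueError(f"k={k} exceeds the number of markers ({len(ordered)})")
    return ordered[:k]


def select_top_union(
    lit_ranks: list[str], forest_ranks: list[str], k: int = 10
) -> dict[str, str]:
    """Union of the two top-k lists; source is 'literature', 'forest' or 'both'."""
    if k > len(lit_ranks) or k > len(forest_ranks):
        raise ValueError("k exceeds the length of a ranking")
    top_lit = set(lit_ranks[:k])
    top_forest = set(forest_ranks[:k])
    out = {}
    for m in sorted(top_lit | top_forest):
        if m in top_lit and m in top_forest:
            out[m] = "both"
        elif m in top_lit:
            out[m] = "literature"
        else:
            out[m] = "forest"
    return out
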