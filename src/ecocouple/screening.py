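"""Driver screening: collinearity filter x importance filter, intersected.

Candidate drivers of the coupling coordination degree are screened twice
and only the intersection survives:

* **Collinearity** — the variance inflation factor VIF_j = 1/(1 - R²_j),
  with R²_j from regressing driver j on all other drivers (OLS with
  intercept). Drivers with VIF above a cutoff (default 6) are excluded,
  one-shot by default; a greedy-iterative mode (drop the worst, recompute)
  is available.
* **Importance** — a bagged ensemble of regression trees (default 500)
  predicts CCD from the drivers; each driver's %IncMSE is the mean
  relative increase in out-of-bag squared error across trees when that
  driver's values are permuted among the tree's out-of-bag rows. A
  per-driver p-value comes from a response-permutation null (refit on a
  shuffled response, recompute importances); drivers with p below alpha
  pass.

The bagging/out-of-bag bookkeeping is implemented here (bootstrap indices
are drawn explicitly so each tree's out-of-bag rows are known exactly);
the trees themselves are scikit-learn decision trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["ScreeningReport", "BaggedForest", "vif", "vif_filter",
           "permutation_importance", "importance_filter", "intersect_screen",
           "screen_drivers"]


@dataclass
class ScreeningReport:
    """Outcome of one region/year screening run."""

    vif: dict[str, float]
    importance: dict[str, float]          # driver -> %IncMSE
    importance_p: dict[str, float]        # driver -> permutation p-value
    vif_pass: list[str]
    importance_pass: list[str]
    selected: list[str]
    n_rows: int = 0
    warnings: list[str] = field(default_factory=list)


def _predictor_matrix(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    X = table.loc[:, list(predictors)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in predictor columns")
    return X


def vif(table: pd.DataFrame, predictors: Sequence[str] | None = None) -> dict[str, float]:
    """Variance inflation factor per predictor.

    Exact linear dependence yields +inf (flagged downstream, not an
    exception); a constant column is a degenerate predictor and raises.
    """
    predictors = list(predictors if predictors is not None else table.columns)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = _predictor_matrix(table, predictors)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more rows than predictors")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"constant predictor(s): {bad}")
    out: dict[str, float] = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(predictors):
        y = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(table: pd.DataFrame, predictors: Sequence[str] | None = None,
               threshold: float = 6.0, mode: str = "one-shot") -> tuple[list[str], dict[str, float]]:
    """Drivers surviving the VIF cutoff, with their VIFs.

    ``one-shot`` (default) drops every driver whose VIF exceeds the
    threshold in a single pass; ``iterative`` repeatedly drops the single
    worst driver and recomputes until all survivors pass.
    """
    predictors = list(predictors if predictors is not None else table.columns)
    if mode == "one-shot":
        scores = vif(table, predictors)
        keep = [p for p in predictors if scores[p] <= threshold]
        return keep, scores
    keep = list(predictors)
    scores = vif(table, keep)
    while len(keep) >= 2:
        scores = vif(table, keep)
        worst = max(keep, key=lambda p: scores[p])
        if scores[worst] <= threshold:
            break
        keep.remove(worst)
    return keep, scores


class BaggedForest:
    """Bagged regression trees with explicit bootstrap/out-of-bag indices.

    A plain random-forest regressor (feature subsampling per split via
    ``max_features``), except that the bootstrap is drawn here so the
    out-of-bag rows of every tree are available for the permutation
    importance computation.
    """

    def __init__(self, n_trees: int = 500, max_features: float | str = 1 / 3,
                 min_samples_leaf: int = 5, seed: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_indices_: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        rng = np.random.default_rng(self.seed)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        n = X32.shape[0]
        self.trees_, self.oob_indices_ = [], []
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeRegressor(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X32[boot], y[boot], check_input=False)
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
        return self

    def oob_prediction(self, X: np.ndarray) -> np.ndarray:
        """Mean over-trees OOB prediction per row (NaN if never OOB)."""
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        n = X32.shape[0]
        tot = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_indices_):
            tot[oob] += tree.predict(X32[oob], check_input=False)
            cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


def permutation_importance(forest: BaggedForest, X: np.ndarray, y: np.ndarray,
                           seed: int = 0) -> np.ndarray:
    """%IncMSE per feature: mean relative OOB-MSE increase under permutation.

    For each tree and feature, the feature's values are shuffled among the
    tree's out-of-bag rows and the OOB squared error recomputed; the score
    is the across-tree mean of 100 * (mse_permuted - mse_oob) / mse_oob.
    A constant feature scores exactly 0 (permutation is a no-op).
    """
    rng = np.random.default_rng(seed)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    k = X32.shape[1]
    inc = np.zeros((len(forest.trees_), k))
    constant = X32.std(axis=0) == 0
    for t, (tree, oob) in enumerate(zip(forest.trees_, forest.oob_indices_)):
        if oob.size == 0:
            continue
        Xo, yo = X32[oob], y[oob]
        base_mse = float(np.mean((yo - tree.predict(Xo, check_input=False)) ** 2))
        if base_mse == 0:
            continue
        for j in range(k):
            if constant[j]:
                continue
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(oob.size), j]
            perm_mse = float(np.mean((yo - tree.predict(Xp, check_input=False)) ** 2))
            inc[t, j] = 100.0 * (perm_mse - base_mse) / base_mse
    return inc.mean(axis=0)


def importance_filter(table: pd.DataFrame, response: str = "CCD",
                      predictors: Sequence[str] | None = None,
                      n_trees: int = 500, n_permutations: int = 100,
                      alpha: float = 0.05, seed: int = 0,
                      ) -> tuple[list[str], dict[str, float], dict[str, float]]:
    """Drivers whose permutation importance beats a response-permutation null.

    Returns (passing drivers, %IncMSE per driver, p-value per driver).
    The p-value for driver j is the fraction of null refits — the forest
    refit after shuffling the response — whose importance for j reaches
    the observed one, with the +1 continuity correction.
    """
    predictors = list(predictors if predictors is not None else
                      [c for c in table.columns if c != response])
    X = _predictor_matrix(table, predictors)
    y = table[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if X.shape[0] < 100:
        raise ValueError("importance filter needs at least 100 rows")
    if 1.0 / (n_permutations + 1) >= alpha:
        raise ValueError(
            f"n_permutations={n_permutations} cannot resolve alpha={alpha}: "
            f"the smallest attainable p-value is 1/{n_permutations + 1}")
    rng = np.random.default_rng(seed)
    forest = BaggedForest(n_trees=n_trees, seed=int(rng.integers(2**31 - 1))).fit(X, y)
    obs = permutation_importance(forest, X, y, seed=int(rng.integers(2**31 - 1)))
    exceed = np.zeros(len(predictors))
    for _ in range(n_permutations):
        yp = y[rng.permutation(y.size)]
        f0 = BaggedForest(n_trees=n_trees, seed=int(rng.integers(2**31 - 1))).fit(X, yp)
        null = permutation_importance(f0, X, yp, seed=int(rng.integers(2**31 - 1)))
        exceed += null >= obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    passing = [p for p, pv in zip(predictors, pvals) if pv < alpha]
    return passing, dict(zip(predictors, obs)), dict(zip(predictors, pvals))


def intersect_screen(vif_pass: Sequence[str], importance_pass: Sequence[str],
                     order: Sequence[str] | None = None) -> list[str]:
    """Set intersection in stable original column order."""
    common = set(vif_pass) & set(importance_pass)
    order = list(order if order is not None else vif_pass)
    return [p for p in order if p in common]


def screen_drivers(table: pd.DataFrame, response: str = "CCD",
                   predictors: Sequence[str] | None = None,
                   vif_threshold: float = 6.0, vif_mode: str = "one-shot",
                   n_trees: int = 500, n_permutations: int = 100,
                   alpha: float = 0.05, seed: int = 0) -> ScreeningReport:
    """Full screening for one table: VIF filter ∩ importance filter."""
    predictors = list(predictors if predictors is not None else
                      [c for c in table.columns
                       if c != response and pd.api.types.is_numeric_dtype(table[c])])
    warnings: list[str] = []
    v_pass, v_scores = vif_filter(table, predictors, vif_threshold, vif_mode)
    if not v_pass:
        warnings.append("all drivers excluded by the VIF filter")
    i_pass, scores, pvals = importance_filter(
        table, response, predictors, n_trees, n_permutations, alpha, seed)
    selected = intersect_screen(v_pass, i_pass, order=predictors)
    if not selected:
        warnings.append("empty selection: VIF and importance filters are disjoint")
    return ScreeningReport(v_scores, scores, pvals, v_pass, i_pass, selected,
                           n_rows=len(table), warnings=warnings)
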