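"""Boosted regression trees for presence/background data, from first principles.

This is stagewise gradient boosting of shallow regression trees on the
Bernoulli (binomial deviance) loss, the formulation used throughout the
species-distribution-modelling literature:

* the model score F(x) is additive in log-odds: F = F0 + lr * sum_m T_m(x),
  with F0 the empirical log-odds of presence;
* each boosting step fits a small regression tree to the pseudo-residuals
  y_i - p_i on a random bag of the training rows (sampled without
  replacement), splits chosen greedily to maximise squared-error reduction;
* terminal-node values are one-step Newton estimates
  sum(y - p) / sum(p (1 - p)) over the in-bag rows in the leaf;
* predicted probability is logistic(F).

Hyperparameters mirror the gbm/dismo vocabulary: ``tree_complexity`` is the
number of splits per tree, ``learning_rate`` the shrinkage, ``bag_fraction``
the subsample fraction, ``step_size`` the tree-count increment used during
cross-validated selection of the ensemble size.  Relative influence of a
predictor is its share of total split improvement, normalised to 100%;
partial dependence is the mean predicted probability with one predictor
forced across a grid of values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    EmptyInputError,
    UndefinedStatisticError,
)
from .occurrence_processing import FeatureTable
from .raster_io import CATEGORICAL, EnvStack, RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "BoostedTreesModel",
    "CVSelection",
    "fit_brt",
    "predict_brt",
    "cv_select_trees",
    "relative_influence",
    "partial_dependence",
    "model_to_json",
    "model_from_json",
]

_EPS_IMPROVEMENT = 1e-12
_NEWTON_CLAMP = 10.0  # guards separable leaves


@dataclass(frozen=True)
class FitConfig:
    """Boosting hyperparameters (defaults follow the study configuration)."""

    tree_complexity: int = 4
    learning_rate: float = 0.005
    bag_fraction: float = 0.75
    step_size: int = 10
    n_folds: int = 10
    max_trees: int = 10_000
    min_obs_in_node: int = 10
    patience: int = 5  # CV checkpoints without improvement before stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_size < 1:
            raise ConfigurationError("step_size must be >= 1")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if not 0 < self.bag_fraction <= 1:
            raise ConfigurationError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ConfigurationError("tree_complexity must be >= 1")


class _Node:
    """One tree node; interior nodes carry a split, leaves a terminal value."""

    __slots__ = ("col", "threshold", "left_codes", "right_codes", "left", "right",
                 "improvement", "n_left", "n_right", "value")

    def __init__(self) -> None:
        self.col = -1            # -1 marks a leaf
        self.threshold = math.nan
        self.left_codes = None   # np.ndarray of codes routed left (categorical)
        self.right_codes = None
        self.left = None
        self.right = None
        self.improvement = 0.0
        self.n_left = 0
        self.n_right = 0
        self.value = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.col < 0


@dataclass
class BoostedTreesModel:
    """A fitted additive sequence of depth-limited regression trees."""

    feature_names: list[str]
    kinds: dict[str, str]
    initial_score: float
    trees: list[_Node]
    learning_rate: float
    tree_complexity: int
    bag_fraction: float
    n_trees_used: int
    config: FitConfig | None = None
    unseen_code_count: int = 0  # cumulative over predictions, logged

    def __post_init__(self) -> None:
        if self.n_trees_used > len(self.trees):
            raise ConfigurationError("n_trees_used exceeds number of fitted trees")

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        score = np.full(len(X), self.initial_score, dtype=float)
        unseen = [0]
        for tree in self.trees[: self.n_trees_used]:
            out = np.empty(len(X), dtype=float)
            _tree_predict(tree, X, np.arange(len(X)), out, unseen)
            score += self.learning_rate * out
        if unseen[0]:
            self.unseen_code_count += unseen[0]
            logger.warning("prediction routed %d unseen categorical codes", unseen[0])
        return score

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.raw_scores(X))


# -- tree fitting --------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _best_continuous_split(x: np.ndarray, r: np.ndarray, min_obs: int):
    """(improvement, threshold) of the best squared-error split, or None."""
    n = len(x)
    if n < 2 * min_obs:
        return None
    order = np.argsort(x, kind="stable")
    xs, rs = x[order], r[order]
    cs = np.cumsum(rs)
    S = cs[-1]
    nl = np.arange(1, n)          # left size after splitting at position i
    valid = xs[:-1] != xs[1:]
    valid &= (nl >= min_obs) & (n - nl >= min_obs)
    if not valid.any():
        return None
    csl = cs[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        imp = csl**2 / nl + (S - csl) ** 2 / (n - nl) - S**2 / n
    imp[~valid] = -np.inf
    i = int(np.argmax(imp))       # first max -> lowest threshold on ties
    if imp[i] <= _EPS_IMPROVEMENT:
        return None
    return float(imp[i]), float((xs[i] + xs[i + 1]) / 2.0)


def _best_categorical_split(x: np.ndarray, r: np.ndarray, min_obs: int):
    """(improvement, left_codes, right_codes) or None.

    Exhaustive subset search for <= 10 observed codes; otherwise codes are
    ordered by in-node mean residual and split like an ordered variable.
    """
    codes, inverse = np.unique(x, return_inverse=True)
    k = len(codes)
    if k < 2:
        return None
    sums = np.bincount(inverse, weights=r, minlength=k)
    counts = np.bincount(inverse, minlength=k)
    S, n = sums.sum(), counts.sum()
    base = S**2 / n

    best = None
    if k <= 10:
        # fix code 0 on the right to halve the subset enumeration
        idx = np.arange(1, k)
        for size in range(1, k):
            for combo in combinations(idx, size):
                sel = np.array(combo)
                nl = counts[sel].sum()
                if nl < min_obs or n - nl < min_obs:
                    continue
                sl = sums[sel].sum()
                imp = sl**2 / nl + (S - sl) ** 2 / (n - nl) - base
                if best is None or imp > best[0] + _EPS_IMPROVEMENT:
                    best = (float(imp), codes[sel])
    else:
        order = np.argsort(sums / np.maximum(counts, 1), kind="stable")
        csum = np.cumsum(sums[order])
        ccnt = np.cumsum(counts[order])
        for i in range(k - 1):
            nl = ccnt[i]
            if nl < min_obs or n - nl < min_obs:
                continue
            imp = csum[i] ** 2 / nl + (S - csum[i]) ** 2 / (n - nl) - base
            if best is None or imp > best[0] + _EPS_IMPROVEMENT:
                best = (float(imp), codes[order[: i + 1]])
    if best is None or best[0] <= _EPS_IMPROVEMENT:
        return None
    imp, left = best
    right = np.setdiff1d(codes, left)
    return imp, np.sort(left), right


def _leaf_best_split(X: np.ndarray, r: np.ndarray, rows: np.ndarray,
                     cat_cols: np.ndarray, min_obs: int):
    """Best split over all predictors for the rows in a leaf, or None.

    Ties are broken toward the lower predictor index (and, within a
    continuous predictor, the lower threshold) for determinism.
    """
    best = None
    rr = r[rows]
    for j in range(X.shape[1]):
        xj = X[rows, j]
        if cat_cols[j]:
            res = _best_categorical_split(xj, rr, min_obs)
            if res is not None and (best is None or res[0] > best[0] + _EPS_IMPROVEMENT):
                best = (res[0], j, ("cat", res[1], res[2]))
        else:
            res = _best_continuous_split(xj, rr, min_obs)
            if res is not None and (best is None or res[0] > best[0] + _EPS_IMPROVEMENT):
                best = (res[0], j, ("num", res[1]))
    return best


def _fit_tree(X: np.ndarray, r: np.ndarray, w: np.ndarray, bag: np.ndarray,
              cat_cols: np.ndarray, n_splits: int, min_obs: int) -> _Node:
    """Fit one regression tree on the bag rows by best-first leaf expansion."""
    root = _Node()
    leaves: list[tuple[_Node, np.ndarray]] = [(root, bag)]
    pending = {id(root): _leaf_best_split(X, r, bag, cat_cols, min_obs)}

    for _ in range(n_splits):
        # pick the splittable leaf with the largest improvement (first on ties)
        pick = None
        for node, rows in leaves:
            cand = pending[id(node)]
            if cand is not None and (pick is None or cand[0] > pick[1][0] + _EPS_IMPROVEMENT):
                pick = (node, cand, rows)
        if pick is None:
            break
        node, (imp, j, split), rows = pick
        xj = X[rows, j]
        if split[0] == "num":
            node.threshold = split[1]
            go_left = xj <= node.threshold
        else:
            node.left_codes = split[1]
            node.right_codes = split[2]
            go_left = np.isin(xj, node.left_codes)
        node.col = j
        node.improvement = imp
        left_rows, right_rows = rows[go_left], rows[~go_left]
        node.n_left, node.n_right = len(left_rows), len(right_rows)
        node.left, node.right = _Node(), _Node()
        leaves.remove((node, rows))
        del pending[id(node)]
        for child, child_rows in ((node.left, left_rows), (node.right, right_rows)):
            leaves.append((child, child_rows))
            pending[id(child)] = _leaf_best_split(X, r, child_rows, cat_cols, min_obs)

    for node, rows in leaves:
        num = r[rows].sum()
        den = w[rows].sum()
        val = num / den if den > 1e-10 else 0.0
        node.value = float(np.clip(val, -_NEWTON_CLAMP, _NEWTON_CLAMP))
    return root


def _tree_predict(node: _Node, X: np.ndarray, idx: np.ndarray, out: np.ndarray,
                  unseen: list[int]) -> None:
    if node.is_leaf:
        out[idx] = node.value
        return
    xv = X[idx, node.col]
    if node.left_codes is None:
        go_left = xv <= node.threshold
    else:
        in_left = np.isin(xv, node.left_codes)
        in_right = np.isin(xv, node.right_codes)
        novel = ~in_left & ~in_right
        n_novel = int(novel.sum())
        if n_novel:
            unseen[0] += n_novel
        # unseen codes follow the child with more training weight
        go_left = in_left | (novel & (node.n_left >= node.n_right))
    _tree_predict(node.left, X, idx[go_left], out, unseen)
    _tree_predict(node.right, X, idx[~go_left], out, unseen)


# -- boosting ------------------------------------------------------------------

def _encode(data: FeatureTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = data.frame.to_numpy(dtype=float)
    y = np.asarray(data.labels, dtype=float)
    cat_cols = np.array(
        [data.kinds.get(name) == CATEGORICAL for name in data.frame.columns]
    )
    return X, y, cat_cols


class _Booster:
    """Incremental boosting engine shared by fit_brt and cv_select_trees."""

    def __init__(self, X: np.ndarray, y: np.ndarray, cat_cols: np.ndarray,
                 config: FitConfig, rng: np.random.Generator,
                 X_holdout: np.ndarray | None = None) -> None:
        if config.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        pbar = y.mean()
        if pbar <= 0 or pbar >= 1:
            raise DegenerateFitError("training data holds a single class")
        self.X, self.y, self.cat_cols = X, y, cat_cols
        self.config = config
        self.rng = rng
        self.initial_score = math.log(pbar / (1.0 - pbar))
        self.score = np.full(len(y), self.initial_score)
        self.trees: list[_Node] = []
        self.X_holdout = X_holdout
        self.holdout_score = (
            np.full(len(X_holdout), self.initial_score) if X_holdout is not None else None
        )
        self._bag_size = max(2, int(round(config.bag_fraction * len(y))))
        self._unseen = [0]

    def grow(self, n_trees: int) -> None:
        cfg = self.config
        n = len(self.y)
        all_idx = np.arange(n)
        for _ in range(n_trees):
            p = _sigmoid(self.score)
            r = self.y - p
            w = p * (1.0 - p)
            if self._bag_size < n:
                bag = self.rng.choice(n, size=self._bag_size, replace=False)
            else:
                bag = all_idx
            tree = _fit_tree(self.X, r, w, bag, self.cat_cols,
                             cfg.tree_complexity, cfg.min_obs_in_node)
            out = np.empty(n)
            _tree_predict(tree, self.X, all_idx, out, self._unseen)
            self.score += cfg.learning_rate * out
            if self.holdout_score is not None:
                hout = np.empty(len(self.X_holdout))
                _tree_predict(tree, self.X_holdout, np.arange(len(self.X_holdout)),
                              hout, self._unseen)
                self.holdout_score += cfg.learning_rate * hout
            self.trees.append(tree)

    def to_model(self, feature_names: list[str], kinds: dict[str, str],
                 n_trees_used: int | None = None) -> BoostedTreesModel:
        n_used = len(self.trees) if n_trees_used is None else n_trees_used
        return BoostedTreesModel(
            feature_names=list(feature_names),
            kinds=dict(kinds),
            initial_score=self.initial_score,
            trees=list(self.trees),
            learning_rate=self.config.learning_rate,
            tree_complexity=self.config.tree_complexity,
            bag_fraction=self.config.bag_fraction,
            n_trees_used=n_used,
            config=self.config,
        )


def fit_brt(data: FeatureTable, config: FitConfig, n_trees: int) -> BoostedTreesModel:
    """Fit a boosted-trees model with a fixed number of trees."""
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    X, y, cat_cols = _encode(data)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    booster = _Booster(X, y, cat_cols, config, rng)
    booster.grow(n_trees)
    return booster.to_model(data.predictors, data.kinds)


def predict_brt(model: BoostedTreesModel, rows: FeatureTable | pd.DataFrame | EnvStack):
    """Predicted presence probability per row, or a suitability raster.

    Raster input returns a RasterGrid with the stack's joint nodata mask.
    """
    if isinstance(rows, EnvStack):
        missing = [n for n in model.feature_names if n not in rows]
        if missing:
            raise ConfigurationError(f"stack is missing model predictors {missing}")
        cells = rows.valid_cells()
        X = rows.cell_values(cells, model.feature_names)
        probs = model.predict_proba(X)
        values = np.zeros((rows.header.nrows, rows.header.ncols))
        values[cells[:, 0], cells[:, 1]] = probs
        return RasterGrid(header=rows.header, values=values, mask=rows.joint_mask.copy())
    frame = rows.frame if isinstance(rows, FeatureTable) else rows
    missing = [n for n in model.feature_names if n not in frame.columns]
    if missing:
        raise ConfigurationError(f"rows are missing model predictors {missing}")
    X = frame[model.feature_names].to_numpy(dtype=float)
    return model.predict_proba(X)


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance -2/n * sum(y log p + (1-y) log(1-p))."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class CVSelection:
    """Result of cross-validated ensemble-size selection."""

    n_trees_optimal: int
    deviance_curve: list[tuple[int, float]]  # (tree count, mean held-out deviance)
    cv_auc: float
    fold_aucs: list[float] = field(default_factory=list)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per row; stratified by label, assigned by seeded permutation."""
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold


def cv_select_trees(data: FeatureTable, config: FitConfig) -> CVSelection:
    """Select the ensemble size by stagewise k-fold cross-validation.

    Fold models grow in increments of ``step_size`` while the mean held-out
    Bernoulli deviance is tracked; growth stops when the deviance has not
    improved for ``patience`` checkpoints or ``max_trees`` is reached.  The
    returned optimum is the checkpoint minimising held-out deviance (always a
    multiple of step_size) and ``cv_auc`` the mean held-out AUC there.
    """
    from .ensemble_evaluation import auc  # local import avoids a cycle

    if len(data) < 2 * config.n_folds:
        raise EmptyInputError(f"need at least {2 * config.n_folds} rows for {config.n_folds}-fold CV")
    X, y, cat_cols = _encode(data)
    ss = np.random.SeedSequence(config.seed)
    fold_ss, *boost_ss = ss.spawn(config.n_folds + 1)
    fold_rng = np.random.default_rng(fold_ss)

    for attempt in range(5):
        fold = _stratified_folds(y, config.n_folds, fold_rng)
        ok = all(
            len(np.unique(y[fold != f])) == 2 for f in range(config.n_folds)
        )
        if ok:
            break
    else:
        raise DegenerateFitError("could not stratify folds with both classes in training")

    boosters = []
    holdout_idx = []
    for f in range(config.n_folds):
        tr, ho = fold != f, fold == f
        boosters.append(
            _Booster(X[tr], y[tr], cat_cols, config,
                     np.random.default_rng(boost_ss[f]), X_holdout=X[ho])
        )
        holdout_idx.append(np.nonzero(ho)[0])

    curve: list[tuple[int, float]] = []
    snapshots: list[list[np.ndarray]] = []
    best_i = 0
    t = 0
    while t < config.max_trees:
        step = min(config.step_size, config.max_trees - t)
        for b in boosters:
            b.grow(step)
        t += step
        pooled = np.empty(len(y))
        snap = []
        for f, b in enumerate(boosters):
            pooled[holdout_idx[f]] = _sigmoid(b.holdout_score)
            snap.append(b.holdout_score.copy())
        dev = bernoulli_deviance(y, pooled)
        curve.append((t, dev))
        snapshots.append(snap)
        if dev < curve[best_i][1]:
            best_i = len(curve) - 1
        elif len(curve) - 1 - best_i >= config.patience:
            break

    n_opt = curve[best_i][0]
    fold_aucs = []
    for f in range(config.n_folds):
        yo = y[holdout_idx[f]]
        if len(np.unique(yo)) < 2:
            logger.warning("fold %d held-out set has a single class; AUC skipped", f)
            continue
        fold_aucs.append(auc(_sigmoid(snapshots[best_i][f]), yo.astype(int)))
    if not fold_aucs:
        raise DegenerateFitError("no fold had both classes held out")
    return CVSelection(
        n_trees_optimal=n_opt,
        deviance_curve=curve,
        cv_auc=float(np.mean(fold_aucs)),
        fold_aucs=fold_aucs,
    )


# -- interpretation ------------------------------------------------------------

def _collect_improvements(node: _Node, acc: np.ndarray) -> None:
    if node.is_leaf:
        return
    acc[node.col] += node.improvement
    _collect_improvements(node.left, acc)
    _collect_improvements(node.right, acc)


def relative_influence(model: BoostedTreesModel) -> dict[str, float]:
    """Percentage of total split improvement per predictor (sums to 100)."""
    acc = np.zeros(len(model.feature_names))
    for tree in model.trees[: model.n_trees_used]:
        _collect_improvements(tree, acc)
    total = acc.sum()
    if total <= 0:
        raise UndefinedStatisticError("model contains no splits; relative influence undefined")
    pct = acc / total * 100.0
    return {name: float(v) for name, v in zip(model.feature_names, pct)}


def partial_dependence(
    model: BoostedTreesModel, predictor: str, data: FeatureTable, n_points: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal effect curve of one predictor on the probability scale.

    Continuous predictors are evaluated on an ``n_points`` quantile grid of
    the data; categorical predictors on their observed codes.  For each grid
    value v the predictor column is forced to v over all rows and predictions
    are averaged.
    """
    if predictor not in model.feature_names:
        raise ConfigurationError(f"predictor {predictor!r} not in model schema")
    if len(data) == 0:
        raise EmptyInputError("partial dependence needs at least one data row")
    col = data.frame[predictor].to_numpy(dtype=float)
    if model.kinds.get(predictor) == CATEGORICAL:
        grid = np.unique(col)
    else:
        qs = np.linspace(0.0, 1.0, max(2, n_points))
        grid = np.unique(np.quantile(col, qs))
    X = data.frame[model.feature_names].to_numpy(dtype=float)
    j = model.feature_names.index(predictor)
    mean_resp = np.empty(len(grid))
    for i, v in enumerate(grid):
        Xi = X.copy()
        Xi[:, j] = v
        mean_resp[i] = model.predict_proba(Xi).mean()
    return grid, mean_resp


# -- serialization -------------------------------------------------------------

def _node_to_dict(node: _Node, names: list[str]) -> dict:
    if node.is_leaf:
        return {"value": node.value}
    d = {
        "predictor": names[node.col],
        "improvement": node.improvement,
        "n_left": node.n_left,
        "n_right": node.n_right,
        "left": _node_to_dict(node.left, names),
        "right": _node_to_dict(node.right, names),
    }
    if node.left_codes is None:
        d["threshold"] = node.threshold
    else:
        d["left_codes"] = [float(c) for c in node.left_codes]
        d["right_codes"] = [float(c) for c in node.right_codes]
    return d


def _node_from_dict(d: dict, name_to_col: dict[str, int]) -> _Node:
    node = _Node()
    if "predictor" not in d:
        node.value = float(d["value"])
        return node
    node.col = name_to_col[d["predictor"]]
    node.improvement = float(d["improvement"])
    node.n_left = int(d["n_left"])
    node.n_right = int(d["n_right"])
    if "threshold" in d:
        node.threshold = float(d["threshold"])
    else:
        node.left_codes = np.array(d["left_codes"], dtype=float)
        node.right_codes = np.array(d["right_codes"], dtype=float)
    node.left = _node_from_dict(d["left"], name_to_col)
    node.right = _node_from_dict(d["right"], name_to_col)
    return node


def model_to_json(model: BoostedTreesModel) -> str:
    payload = {
        "feature_names": model.feature_names,
        "kinds": model.kinds,
        "initial_score": model.initial_score,
        "learning_rate": model.learning_rate,
        "tree_complexity": model.tree_complexity,
        "bag_fraction": model.bag_fraction,
        "n_trees_used": model.n_trees_used,
        "trees": [_node_to_dict(t, model.feature_names) for t in model.trees],
    }
    return json.dumps(payload)


def model_from_json(text: str) -> BoostedTreesModel:
    d = json.loads(text)
    name_to_col = {n: i for i, n in enumerate(d["feature_names"])}
    return BoostedTreesModel(
        feature_names=list(d["feature_names"]),
        kinds=dict(d["kinds"]),
        initial_score=float(d["initial_score"]),
        trees=[_node_from_dict(t, name_to_col) for t in d["trees"]],
        learning_rate=float(d["learning_rate"]),
        tree_complexity=int(d["tree_complexity"]),
        bag_fraction=float(d["bag_fraction"]),
        n_trees_used=int(d["n_trees_used"]),
    )
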