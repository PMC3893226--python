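"""Stochastic gradient-boosted regression trees with cross-validated
tree-number selection, relative influence, partial dependence, and
replicate ensembles.

The booster is the classic stagewise algorithm: at each stage a shallow CART
regression tree (grown best-first to a fixed number of terminal nodes) is fit
to the pointwise gradient of the deviance on a random ``bag_fraction``
subsample, its terminal-node values are replaced by one Newton step for the
family, and the fitted function moves by ``learning_rate`` times the tree.
Trees are added in blocks of ``step_size`` while the k-fold cross-validated
predictive deviance keeps improving; the selected model size is the argmin of
the CV deviance trace.  Families: ``bernoulli`` (occurrence), ``poisson``
(counts per equal-area bin), ``gaussian`` (fallback).

Single trees are fit with :class:`sklearn.tree.DecisionTreeRegressor`; the
boosting loop, Newton leaf updates, CV stopping rule, influence and
partial-dependence calculations live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class BRTConfig:
    """Boosting settings (defaults follow common working-guide practice)."""

    learning_rate: float = 0.005
    tree_complexity: int = 5       # terminal nodes - 1 (number of splits)
    bag_fraction: float = 0.5
    n_folds: int = 10
    step_size: int = 50            # trees added per CV evaluation block
    max_trees: int = 10000
    family: str = "bernoulli"
    seed: int = 0
    patience: int = 3              # CV blocks without a new minimum before stopping

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.family not in ("bernoulli", "poisson", "gaussian"):
            raise ValueError(f"unknown family '{self.family}'")


# ---------------------------------------------------------------------------
# family helpers

def _intercept(y: np.ndarray, family: str) -> float:
    if family == "bernoulli":
        p = np.clip(y.mean(), _EPS, 1 - _EPS)
        return float(np.log(p / (1 - p)))
    if family == "poisson":
        return float(np.log(max(y.mean(), _EPS)))
    return float(y.mean())


def _mean_value(F: np.ndarray, family: str) -> np.ndarray:
    if family == "bernoulli":
        return 1.0 / (1.0 + np.exp(-F))
    if family == "poisson":
        return np.exp(np.clip(F, -30, 30))
    return F


def _gradient(y: np.ndarray, F: np.ndarray, family: str) -> np.ndarray:
    return y - _mean_value(F, family)  # identical form for all three families


def _deviance(y: np.ndarray, F: np.ndarray, family: str) -> float:
    mu = _mean_value(F, family)
    if family == "bernoulli":
        p = np.clip(mu, _EPS, 1 - _EPS)
        return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    if family == "poisson":
        mu = np.maximum(mu, _EPS)
        term = np.where(y > 0, y * np.log(np.maximum(y, _EPS) / mu), 0.0)
        return float(2.0 * np.mean(term - (y - mu)))
    return float(np.mean((y - mu) ** 2))


def _newton_leaf_values(tree: DecisionTreeRegressor, X: np.ndarray, y: np.ndarray,
                        F: np.ndarray, family: str) -> np.ndarray:
    """Per-leaf Newton-step values indexed by sklearn node id."""
    leaves = tree.apply(X)
    n_nodes = tree.tree_.node_count
    values = np.zeros(n_nodes)
    mu = _mean_value(F, family)
    resid = y - mu
    if family == "bernoulli":
        hess = np.maximum(mu * (1 - mu), _EPS)
    elif family == "poisson":
        hess = np.maximum(mu, _EPS)
    else:
        hess = np.ones_like(mu)
    num = np.bincount(leaves, weights=resid, minlength=n_nodes)
    den = np.bincount(leaves, weights=hess, minlength=n_nodes)
    nz = den > 0
    values[nz] = num[nz] / den[nz]
    return np.clip(values, -4.0, 4.0)


class _Booster:
    """Incrementally growable boosted-tree model on a fixed training set."""

    def __init__(self, X: np.ndarray, y: np.ndarray, config: BRTConfig,
                 rng: np.random.Generator) -> None:
        self.X, self.y, self.config, self.rng = X, y, config, rng
        self.f0 = _intercept(y, config.family)
        self.F = np.full(len(y), self.f0)
        self.trees: list[DecisionTreeRegressor] = []
        self.leaf_values: list[np.ndarray] = []
        self.train_deviance: list[float] = [_deviance(y, self.F, config.family)]

    def grow(self, n_new: int) -> None:
        cfg = self.config
        n = len(self.y)
        n_bag = max(2, int(round(cfg.bag_fraction * n)))
        for _ in range(n_new):
            bag = self.rng.choice(n, size=n_bag, replace=False)
            grad = _gradient(self.y, self.F, cfg.family)
            tree = DecisionTreeRegressor(
                max_leaf_nodes=cfg.tree_complexity + 1,
                random_state=int(self.rng.integers(2**31)))
            tree.fit(self.X[bag], grad[bag])
            vals = _newton_leaf_values(tree, self.X[bag], self.y[bag], self.F[bag],
                                       cfg.family)
            self.trees.append(tree)
            self.leaf_values.append(vals)
            self.F += cfg.learning_rate * vals[tree.apply(self.X)]
            self.train_deviance.append(_deviance(self.y, self.F, cfg.family))

    def raw_predict(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        F = np.full(len(X), self.f0)
        use = self.trees if n_trees is None else self.trees[:n_trees]
        for tree, vals in zip(use, self.leaf_values[:len(use)]):
            F += self.config.learning_rate * vals[tree.apply(X)]
        return F


@dataclass
class BRTModel:
    """A fitted boosted-tree model with its CV tree-selection traces."""

    config: BRTConfig
    feature_names: list[str]
    f0: float
    trees: list = field(repr=False, default_factory=list)
    leaf_values: list = field(repr=False, default_factory=list)
    optimal_n_trees: int = 0
    train_deviance: list[float] = field(default_factory=list)
    cv_steps: list[int] = field(default_factory=list)
    cv_deviance: list[float] = field(default_factory=list)
    degenerate: bool = False
    feature_means: np.ndarray | None = None
    feature_mins: np.ndarray | None = None
    feature_maxs: np.ndarray | None = None
    cached_influence: dict | None = None  # set on deserialised models


@dataclass
class PartialDependenceCurve:
    predictor: str
    grid: np.ndarray
    response: np.ndarray


@dataclass
class BRTEnsemble:
    models: list[BRTModel]
    train_indices: list[np.ndarray]
    holdout_indices: list[np.ndarray]
    config: BRTConfig


def _as_matrix(features: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    if np.isnan(X).all(axis=0).any():
        bad = [n for n, a in zip(names, np.isnan(X).all(axis=0)) if a]
        raise ValueError(f"all-nodata feature column(s): {bad}")
    return X, names


def fit_brt(features: pd.DataFrame, response: np.ndarray, config: BRTConfig) -> BRTModel:
    """Fit one boosted-tree model with CV selection of the tree count.

    K-fold boosters are grown in lockstep blocks of ``config.step_size``
    trees; the block loop stops once the mean holdout deviance has not set a
    new minimum for ``config.patience`` consecutive blocks (or at
    ``max_trees``).  The returned model is refit on all rows with the argmin
    tree count.  A model whose CV deviance never improves on the intercept is
    flagged degenerate and keeps zero trees (prediction = base rate).
    """
    X, names = _as_matrix(features)
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError("response length does not match feature rows")
    if config.family == "poisson" and np.any(y < 0):
        raise ValueError("poisson response must be non-negative")
    if config.family == "bernoulli" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("bernoulli response must be 0/1")
    rng = np.random.default_rng(config.seed)
    model = BRTModel(config=config, feature_names=names, f0=_intercept(y, config.family),
                     feature_means=np.nanmean(X, axis=0),
                     feature_mins=np.nanmin(X, axis=0), feature_maxs=np.nanmax(X, axis=0))
    if len(np.unique(y)) < 2:
        warnings.warn("constant response: returning intercept-only (degenerate) model")
        model.degenerate = True
        model.train_deviance = [_deviance(y, np.full(len(y), model.f0), config.family)]
        return model

    # --- k-fold CV in lockstep blocks
    n = len(y)
    order = rng.permutation(n)
    folds = np.array_split(order, config.n_folds)
    fold_boosters = []
    for k, hold in enumerate(folds):
        tr = np.setdiff1d(order, hold, assume_unique=False)
        fold_boosters.append((
            _Booster(X[tr], y[tr], config, np.random.default_rng(config.seed * 1009 + k + 1)),
            tr, hold))
    cv_steps = [0]
    cv_dev = [float(np.mean([_deviance(y[h], np.full(len(h), b.f0), config.family)
                             for b, _, h in fold_boosters]))]
    best, since_best = cv_dev[0], 0
    n_trees = 0
    while n_trees < config.max_trees and since_best < config.patience:
        block = min(config.step_size, config.max_trees - n_trees)
        for b, _, _ in fold_boosters:
            b.grow(block)
        n_trees += block
        dev = float(np.mean([_deviance(y[h], b.raw_predict(X[h]), config.family)
                             for b, _, h in fold_boosters]))
        cv_steps.append(n_trees)
        cv_dev.append(dev)
        if dev < best - 1e-12:
            best, since_best = dev, 0
        else:
            since_best += 1
    model.cv_steps, model.cv_deviance = cv_steps, cv_dev
    optimal = cv_steps[int(np.argmin(cv_dev))]
    if optimal == 0:
        warnings.warn("CV deviance never improved on the intercept: degenerate model "
                      "(no better than random)")
        model.degenerate = True
        model.train_deviance = [_deviance(y, np.full(n, model.f0), config.family)]
        return model

    # --- final fit on all rows at the selected size
    final = _Booster(X, y, config, np.random.default_rng(config.seed * 1009))
    final.grow(optimal)
    model.trees = final.trees
    model.leaf_values = final.leaf_values
    model.f0 = final.f0
    model.optimal_n_trees = optimal
    model.train_deviance = final.train_deviance
    return model


def _model_matrix(model: BRTModel, features: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    return features[model.feature_names].to_numpy(dtype=float)


def raw_predict(model: BRTModel, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
    n_use = model.optimal_n_trees if n_trees is None else n_trees
    F = np.full(len(X), model.f0)
    for tree, vals in zip(model.trees[:n_use], model.leaf_values[:n_use]):
        F += model.config.learning_rate * vals[tree.apply(X)]
    return F


def predict_brt(model: BRTModel, features: pd.DataFrame) -> np.ndarray:
    """Predictions on the response scale (probability / expected count)."""
    X = _model_matrix(model, features)
    return _mean_value(raw_predict(model, X), model.config.family)


def relative_influence(model: BRTModel) -> pd.Series:
    """Per-predictor percentage of total split improvement, summing to 100.

    Each split's contribution is its squared-error improvement on the
    stage's gradient (sklearn's weighted impurity decrease), summed over all
    trees up to the selected tree count.
    """
    totals = np.zeros(len(model.feature_names))
    if model.degenerate or not model.trees:
        warnings.warn("degenerate model: all-zero relative influence")
        return pd.Series(totals, index=model.feature_names)
    if model.cached_influence is not None:
        return pd.Series(model.cached_influence).reindex(model.feature_names).fillna(0.0
                                                                                     ).sort_values(ascending=False)
    for tree in model.trees[:model.optimal_n_trees]:
        totals += tree.tree_.compute_feature_importances(normalize=False)
    s = totals.sum()
    if s > 0:
        totals = totals / s * 100.0
    return pd.Series(totals, index=model.feature_names).sort_values(ascending=False)


def partial_dependence(model: BRTModel, predictor: str,
                       n_points: int = 100) -> PartialDependenceCurve:
    """Response over one predictor's training range, others held at their means."""
    if predictor not in model.feature_names:
        raise ValueError(f"unknown predictor '{predictor}'")
    j = model.feature_names.index(predictor)
    grid = np.linspace(model.feature_mins[j], model.feature_maxs[j], n_points)
    X = np.tile(model.feature_means, (n_points, 1))
    X[:, j] = grid
    resp = _mean_value(raw_predict(model, X), model.config.family)
    return PartialDependenceCurve(predictor=predictor, grid=grid, response=resp)


def fit_ensemble(features: pd.DataFrame, response: np.ndarray, config: BRTConfig,
                 n_replicates: int = 10, train_fraction: float = 0.5) -> BRTEnsemble:
    """Replicate models on independent random train/holdout splits.

    Each replicate trains on a different random ``train_fraction`` of the
    rows (the rest retained as that replicate's holdout); per-replicate seeds
    derive from the master seed so any member is independently reproducible.
    """
    n = len(features)
    if n < int(np.ceil(2 / train_fraction)):
        raise ValueError("too few rows for the requested train fraction")
    y = np.asarray(response, dtype=float)
    master = np.random.SeedSequence(config.seed)
    models, train_idx, hold_idx = [], [], []
    for rep, child in enumerate(master.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        tr, ho = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        rep_cfg = replace(config, seed=rep_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            m = fit_brt(features.iloc[tr], y[tr], rep_cfg)
        if m.degenerate:
            logger.warning("ensemble replicate %d is degenerate", rep)
        models.append(m)
        train_idx.append(tr)
        hold_idx.append(ho)
    return BRTEnsemble(models=models, train_indices=train_idx,
                       holdout_indices=hold_idx, config=config)


def predict_ensemble(ensemble: BRTEnsemble, features: pd.DataFrame) -> np.ndarray:
    """Arithmetic mean of member predictions on the response scale."""
    preds = np.stack([predict_brt(m, features) for m in ensemble.models])
    return preds.mean(axis=0)


class _FrozenTree:
    """A deserialised regression tree supporting only ``apply``.

    Stores the CART split arrays (child pointers, split feature, threshold)
    so a saved model predicts without sklearn object unpickling.
    """

    def __init__(self, left, right, feature, threshold) -> None:
        self.left = np.asarray(left, dtype=int)
        self.right = np.asarray(right, dtype=int)
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)

    def apply(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=int)
        active = self.left[node] != -1
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.left[node] != -1
        return node


def model_to_dict(model: BRTModel) -> dict:
    """Serializable representation of a fitted model (documented JSON schema)."""
    trees = []
    for tree, vals in zip(model.trees[:model.optimal_n_trees],
                          model.leaf_values[:model.optimal_n_trees]):
        t = tree.tree_ if hasattr(tree, "tree_") else tree
        trees.append({
            "left": np.asarray(t.children_left if hasattr(t, "children_left") else t.left).tolist(),
            "right": np.asarray(t.children_right if hasattr(t, "children_right") else t.right).tolist(),
            "feature": np.asarray(t.feature).tolist(),
            "threshold": np.asarray(t.threshold).tolist(),
            "leaf_values": np.asarray(vals).tolist(),
        })
    cfg = model.config
    return {
        "schema": "reefscape-brt-model/1",
        "config": {k: getattr(cfg, k) for k in (
            "learning_rate", "tree_complexity", "bag_fraction", "n_folds", "step_size",
            "max_trees", "family", "seed", "patience")},
        "feature_names": model.feature_names,
        "f0": model.f0,
        "optimal_n_trees": model.optimal_n_trees,
        "degenerate": model.degenerate,
        "relative_influence": (relative_influence(model).to_dict()
                               if model.trees else {}),
        "cv_steps": model.cv_steps,
        "cv_deviance": model.cv_deviance,
        "feature_means": np.asarray(model.feature_means).tolist(),
        "feature_mins": np.asarray(model.feature_mins).tolist(),
        "feature_maxs": np.asarray(model.feature_maxs).tolist(),
        "trees": trees,
    }


def model_from_dict(d: dict) -> BRTModel:
    cfg = BRTConfig(**d["config"])
    model = BRTModel(
        config=cfg, feature_names=list(d["feature_names"]), f0=float(d["f0"]),
        optimal_n_trees=int(d["optimal_n_trees"]), degenerate=bool(d["degenerate"]),
        cv_steps=list(d.get("cv_steps", [])), cv_deviance=list(d.get("cv_deviance", [])),
        feature_means=np.asarray(d["feature_means"]),
        feature_mins=np.asarray(d["feature_mins"]),
        feature_maxs=np.asarray(d["feature_maxs"]),
        cached_influence=d.get("relative_influence") or None)
    for t in d["trees"]:
        model.trees.append(_FrozenTree(t["left"], t["right"], t["feature"], t["threshold"]))
        model.leaf_values.append(np.asarray(t["leaf_values"], dtype=float))
    return model


def predict_ensemble_raster(ensemble: BRTEnsemble, stack) -> np.ndarray:
    """Cell-wise ensemble-mean prediction over a predictor stack."""
    names = ensemble.models[0].feature_names
    missing = [nm for nm in names if nm not in stack.layers]
    if missing:
        raise ValueError(f"stack lacks layer(s): {missing}")
    shape = next(iter(stack.layers.values())).shape
    for nm in names:
        if stack.layers[nm].shape != shape:
            raise ValueError(f"layer '{nm}' shape mismatch")
    cols = np.column_stack([stack.layers[nm].ravel() for nm in names])
    valid = np.isfinite(cols).all(axis=1)
    out = np.full(cols.shape[0], np.nan)
    if valid.any():
        df = pd.DataFrame(cols[valid], columns=names)
        out[valid] = predict_ensemble(ensemble, df)
    return out.reshape(shape)
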