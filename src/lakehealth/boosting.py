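"""Gradient-boosted regression trees with Gaussian loss, written from first
principles.

The model is the classic stagewise additive expansion

    F_m(x) = F_0 + nu * sum_{t=1..m} h_t(x),

where ``F_0`` is the training-response mean, ``nu`` the learning rate, and
each base learner ``h_t`` is a small regression tree fitted to the current
residuals (the negative gradient of squared-error loss) on a subsampled
"bag" of the training rows.  Trees are grown *best-first*: the split with
the largest squared-error improvement anywhere on the frontier is taken
next, and a tree with interaction depth ``d`` contains exactly ``d`` splits
(or fewer if no further split reduces error).  This is the convention under
which an interaction depth of 5 bounds the order of modeled interactions at
five, rather than producing a 31-leaf symmetric tree.

The iteration count is selected by k-fold cross-validation: each fold's
model tracks held-out squared error per iteration, the fold-averaged curve
is minimized, and the final model — refit on all rows — is read off at that
iteration.

Variable importance follows Friedman's relative influence: the sum of
squared-error improvements of every split made on a predictor, accumulated
over the ensemble and normalized to percentages.  Partial dependence is
computed by the exact data-average definition: the target predictor(s) are
overwritten with a grid value in every training row and the model
predictions are averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "GBMConfig",
    "RegressionTree",
    "BoostedModel",
    "fit_tree",
    "fit_gbm",
    "relative_influence",
    "partial_dependence",
]


@dataclass
class GBMConfig:
    """Hyperparameters of the boosted ensemble.

    Defaults are the survey analysis settings: 1500 Gaussian-loss
    iterations, 5 splits per tree, learning rate 0.005, 5-fold CV, and the
    customary subsampling defaults (half-row bagging, minimum terminal node
    size of 10).
    """

    n_trees: int = 1500
    interaction_depth: int = 5
    learning_rate: float = 0.005
    cv_folds: int = 5
    loss: str = "gaussian"
    bag_fraction: float = 0.5
    min_node_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ConfigurationError("learning_rate must be in (0, 1]")
        if self.interaction_depth < 1:
            raise ConfigurationError("interaction_depth must be >= 1")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ConfigurationError("bag_fraction must be in (0, 1]")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.min_node_size < 1:
            raise ConfigurationError("min_node_size must be >= 1")
        if self.loss != "gaussian":
            raise ConfigurationError("only the gaussian loss is supported")

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "interaction_depth": self.interaction_depth,
            "learning_rate": self.learning_rate,
            "cv_folds": self.cv_folds,
            "loss": self.loss,
            "bag_fraction": self.bag_fraction,
            "min_node_size": self.min_node_size,
            "seed": self.seed,
        }


@dataclass
class RegressionTree:
    """A small regression tree stored as flat node arrays.

    ``feature[i] == -1`` marks a leaf; ``value`` holds leaf predictions
    (means of the bagged residuals reaching the node) and ``improvement``
    the squared-error reduction achieved by each internal node's split.
    """

    feature: np.ndarray    # int, -1 for leaves
    threshold: np.ndarray  # float, NaN for leaves
    left: np.ndarray       # int child index, -1 for leaves
    right: np.ndarray
    value: np.ndarray      # float leaf prediction (defined for all nodes)
    improvement: np.ndarray  # float, 0 for leaves

    @property
    def n_splits(self) -> int:
        return int(np.sum(self.feature >= 0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the tree on a (n, p) matrix, vectorized per node."""
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, rows = stack.pop()
            if self.feature[node] < 0 or rows.size == 0:
                out[rows] = self.value[node]
                continue
            go_left = X[rows, self.feature[node]] <= self.threshold[node]
            stack.append((int(self.left[node]), rows[go_left]))
            stack.append((int(self.right[node]), rows[~go_left]))
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "improvement": self.improvement.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=int),
            right=np.asarray(d["right"], dtype=int),
            value=np.asarray(d["value"], dtype=float),
            improvement=np.asarray(d["improvement"], dtype=float),
        )


def _best_split(X: np.ndarray, r: np.ndarray, rows: np.ndarray,
                min_node: int) -> tuple[int, float, float, np.ndarray, np.ndarray] | None:
    """Exhaustive best split of ``rows`` on any variable.

    Candidates are midpoints between consecutive distinct sorted values.
    Improvement is the decrease in total within-node squared error,
        SSE(parent) - SSE(left) - SSE(right)
      = S_l^2/n_l + S_r^2/n_r - S^2/n,
    with S the residual sums.  Ties break toward the lowest variable index,
    then the lowest threshold (guaranteed by strict-greater comparison and
    first-argmax, respectively).
    """
    n = rows.size
    if n < 2 * min_node:
        return None
    best = None
    best_imp = 0.0
    total = float(r[rows].sum())
    base = total * total / n
    for j in range(X.shape[1]):
        x = X[rows, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        rs = r[rows[order]]
        cum = np.cumsum(rs)
        # split after position i (1-based count of left rows)
        counts = np.arange(1, n)
        valid = (xs[1:] > xs[:-1]) & (counts >= min_node) & (n - counts >= min_node)
        if not valid.any():
            continue
        s_left = cum[:-1]
        imp = np.where(
            valid,
            s_left * s_left / counts + (total - s_left) ** 2 / (n - counts) - base,
            -np.inf,
        )
        k = int(np.argmax(imp))
        if imp[k] > best_imp + 1e-12 * max(1.0, abs(best_imp)):
            best_imp = float(imp[k])
            thr = 0.5 * (xs[k] + xs[k + 1])
            best = (j, thr, best_imp, rows[order[: k + 1]], rows[order[k + 1:]])
    return best


def fit_tree(X: np.ndarray, r: np.ndarray, depth: int, min_node: int,
             rows: np.ndarray | None = None) -> RegressionTree:
    """Grow a best-first regression tree on residuals ``r``.

    ``rows`` restricts fitting to a bagged subset.  Growth stops after
    ``depth`` splits or when no candidate split reduces squared error while
    keeping ``min_node`` rows in each child.  Constant residuals yield a
    single-leaf tree predicting their mean.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    if rows is None:
        rows = np.arange(X.shape[0])
    if rows.size == 0:
        raise ValidationError("cannot fit a tree on zero rows")

    feature = [-1]
    threshold = [np.nan]
    left = [-1]
    right = [-1]
    value = [float(r[rows].mean())]
    improvement = [0.0]

    # frontier: node_index -> (rows, cached best split or None)
    frontier: dict[int, tuple[np.ndarray, tuple | None]] = {
        0: (rows, _best_split(X, r, rows, min_node))
    }
    for _ in range(depth):
        # pick frontier node with the largest improvement
        best_node = -1
        best_split = None
        for node, (_, cand) in frontier.items():
            if cand is not None and (best_split is None or cand[2] > best_split[2]):
                best_node, best_split = node, cand
        if best_split is None:
            break
        j, thr, imp, rows_l, rows_r = best_split
        del frontier[best_node]
        li = len(feature)
        ri = li + 1
        feature[best_node] = j
        threshold[best_node] = thr
        left[best_node] = li
        right[best_node] = ri
        improvement[best_node] = imp
        for child_rows in (rows_l, rows_r):
            feature.append(-1)
            threshold.append(np.nan)
            left.append(-1)
            right.append(-1)
            value.append(float(r[child_rows].mean()))
            improvement.append(0.0)
        frontier[li] = (rows_l, _best_split(X, r, rows_l, min_node))
        frontier[ri] = (rows_r, _best_split(X, r, rows_r, min_node))

    return RegressionTree(
        feature=np.asarray(feature, dtype=int),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=int),
        right=np.asarray(right, dtype=int),
        value=np.asarray(value, dtype=float),
        improvement=np.asarray(improvement, dtype=float),
    )


@dataclass
class BoostedModel:
    """A fitted gradient-boosted ensemble.

    ``predict`` truncates at the CV-selected ``best_iteration`` by default;
    pass ``iterations`` explicitly to inspect other points on the path.
    """

    init: float
    trees: list[RegressionTree]
    config: GBMConfig
    feature_names: list[str]
    best_iteration: int
    train_curve: np.ndarray            # mean squared error per iteration
    cv_curve: np.ndarray | None = None  # fold-averaged held-out MSE

    def predict(self, X, iterations: int | None = None) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        m = self.best_iteration if iterations is None else iterations
        if not 0 <= m <= len(self.trees):
            raise ValidationError(f"iterations must be in [0, {len(self.trees)}]")
        out = np.full(X.shape[0], self.init)
        nu = self.config.learning_rate
        for tree in self.trees[:m]:
            out += nu * tree.predict(X)
        return out

    def to_dict(self) -> dict:
        return {
            "init": self.init,
            "config": self.config.to_dict(),
            "feature_names": list(self.feature_names),
            "best_iteration": self.best_iteration,
            "train_curve": self.train_curve.tolist(),
            "cv_curve": None if self.cv_curve is None else self.cv_curve.tolist(),
            "trees": [t.to_dict() for t in self.trees],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedModel":
        return cls(
            init=float(d["init"]),
            trees=[RegressionTree.from_dict(t) for t in d["trees"]],
            config=GBMConfig(**d["config"]),
            feature_names=list(d["feature_names"]),
            best_iteration=int(d["best_iteration"]),
            train_curve=np.asarray(d["train_curve"], dtype=float),
            cv_curve=(None if d["cv_curve"] is None
                      else np.asarray(d["cv_curve"], dtype=float)),
        )

    @classmethod
    def from_json(cls, path) -> "BoostedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_matrix(X, feature_names: Sequence[str]) -> np.ndarray:
    """Accept a DataFrame (reordered by name) or a plain array."""
    if hasattr(X, "loc") and hasattr(X, "columns"):
        missing = [c for c in feature_names if c not in X.columns]
        if missing:
            raise ConfigurationError(f"missing predictor columns: {missing}")
        return X.loc[:, list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValidationError(
            f"expected a 2-D matrix with {len(feature_names)} columns")
    return X


def _boost(X: np.ndarray, y: np.ndarray, config: GBMConfig,
           rng: np.random.Generator,
           X_val: np.ndarray | None = None,
           y_val: np.ndarray | None = None):
    """Run the boosting iterations; returns (init, trees, train_mse, val_mse)."""
    n = X.shape[0]
    init = float(y.mean())
    pred = np.full(n, init)
    trees: list[RegressionTree] = []
    train_mse = np.empty(config.n_trees)
    val_mse = None
    if X_val is not None:
        pred_val = np.full(X_val.shape[0], init)
        val_mse = np.empty(config.n_trees)
    n_bag = max(1, int(round(config.bag_fraction * n)))
    for m in range(config.n_trees):
        resid = y - pred
        if config.bag_fraction < 1.0:
            bag = rng.choice(n, size=n_bag, replace=False)
        else:
            bag = np.arange(n)
        tree = fit_tree(X, resid, config.interaction_depth,
                        config.min_node_size, rows=bag)
        trees.append(tree)
        pred += config.learning_rate * tree.predict(X)
        train_mse[m] = float(np.mean((y - pred) ** 2))
        if X_val is not None:
            pred_val += config.learning_rate * tree.predict(X_val)
            val_mse[m] = float(np.mean((y_val - pred_val) ** 2))
    return init, trees, train_mse, val_mse


def fit_gbm(X, y, config: GBMConfig | None = None,
            feature_names: Sequence[str] | None = None) -> BoostedModel:
    """Fit the boosted ensemble with cross-validated iteration selection.

    The CV folds are a seeded random partition of the rows; each fold's
    model is trained under the same configuration and scored on its
    held-out fold at every iteration.  ``best_iteration`` minimizes the
    fold-averaged held-out MSE, and the returned model is refit on all rows
    and truncated there for prediction.

    All randomness (fold assignment, per-iteration bagging in each fold and
    in the final fit) derives from ``config.seed`` through spawned
    ``numpy.random.SeedSequence`` substreams, so a fit is reproducible
    bit-for-bit.
    """
    if config is None:
        config = GBMConfig()
    if hasattr(X, "columns") and feature_names is None:
        feature_names = [str(c) for c in X.columns]
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(np.asarray(X).shape[1])]
    Xm = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if np.isnan(Xm).any():
        raise ValidationError("predictor matrix contains missing values")
    if y.shape[0] != Xm.shape[0]:
        raise ValidationError("X and y have different numbers of rows")
    n = Xm.shape[0]
    if n < config.cv_folds:
        raise ConfigurationError("need at least cv_folds rows")

    # substreams: [fold assignment, final fit, fold 0, fold 1, ...]
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + config.cv_folds)
    fold_rng = np.random.default_rng(children[0])
    fold_of = fold_rng.permuted(np.arange(n) % config.cv_folds)

    cv_sse = np.zeros(config.n_trees)
    cv_n = 0
    for k in range(config.cv_folds):
        held = fold_of == k
        if held.sum() == 0 or (~held).sum() < 2 * config.min_node_size:
            continue
        rng_k = np.random.default_rng(children[2 + k])
        _, _, _, val_mse = _boost(Xm[~held], y[~held], config, rng_k,
                                  X_val=Xm[held], y_val=y[held])
        cv_sse += val_mse * held.sum()
        cv_n += held.sum()
    cv_curve = cv_sse / cv_n
    best_iteration = int(np.argmin(cv_curve)) + 1

    rng_final = np.random.default_rng(children[1])
    init, trees, train_mse, _ = _boost(Xm, y, config, rng_final)
    return BoostedModel(
        init=init,
        trees=trees,
        config=config,
        feature_names=list(feature_names),
        best_iteration=best_iteration,
        train_curve=train_mse,
        cv_curve=cv_curve,
    )


def relative_influence(model: BoostedModel, up_to: int | None = None):
    """Friedman relative influence per predictor, in percent.

    Sums the squared-error improvement of every split on each variable over
    trees ``1..up_to`` (default: the CV-selected iteration) and normalizes
    the sums to 100.  A model with no splits returns all zeros.
    """
    import pandas as pd

    m = model.best_iteration if up_to is None else up_to
    raw = np.zeros(len(model.feature_names))
    for tree in model.trees[:m]:
        internal = tree.feature >= 0
        np.add.at(raw, tree.feature[internal], tree.improvement[internal])
    total = raw.sum()
    if total > 0:
        pct = 100.0 * raw / total
    else:
        pct = raw  # all-zero: a no-split model has no attributable variance
    return pd.Series(pct, index=list(model.feature_names),
                     name="relative_influence").sort_values(ascending=False)


def partial_dependence(model: BoostedModel, X, variables: Sequence[str],
                       grid: Sequence[np.ndarray] | np.ndarray | None = None,
                       grid_size: int = 50, iterations: int | None = None):
    """Exact partial dependence over one or two predictors.

    For each grid point the named variable(s) are overwritten in every row
    of ``X`` and the model predictions averaged — the data-average
    definition itself, with no tree-traversal shortcuts.  Returns a
    DataFrame with the grid column(s) and a ``partial_dependence`` column.
    """
    import pandas as pd

    variables = list(variables)
    if len(variables) not in (1, 2):
        raise ConfigurationError("partial dependence takes 1 or 2 variables")
    for v in variables:
        if v not in model.feature_names:
            raise ConfigurationError(f"variable {v!r} not in the model")
    Xm = _as_matrix(X, model.feature_names)
    cols = [model.feature_names.index(v) for v in variables]
    if grid is None:
        grids = [np.linspace(Xm[:, c].min(), Xm[:, c].max(), grid_size)
                 for c in cols]
    elif len(variables) == 1 and not isinstance(grid, (list, tuple)):
        grids = [np.asarray(grid, dtype=float)]
    else:
        grids = [np.asarray(g, dtype=float) for g in grid]
    if len(grids) != len(variables):
        raise ConfigurationError("one grid per variable is required")

    if len(variables) == 1:
        points = grids[0][:, None]
    else:
        a, b = np.meshgrid(grids[0], grids[1], indexing="ij")
        points = np.column_stack([a.ravel(), b.ravel()])

    work = Xm.copy()
    pd_vals = np.empty(points.shape[0])
    for i, pt in enumerate(points):
        for c, val in zip(cols, pt):
            work[:, c] = val
        pd_vals[i] = float(np.mean(model.predict(work, iterations=iterations)))
    out = {v: points[:, k] for k, v in enumerate(variables)}
    out["partial_dependence"] = pd_vals
    return pd.DataFrame(out)
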