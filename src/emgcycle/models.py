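"""Linear (ridge) and non-linear (random forest) regressors.

Ridge regression operates on z-scores of both inputs and output with no
intercept; the weights solve the penalised normal equations

    (X'X + lambda I) beta = X'y.

The shrinkage parameter is selected by averaging 10-fold cross-validated
R-squared over every integer lambda in 1..100 across the available
datasets, smoothing the curve with a centred moving average, and taking
the argmax (ties broken toward the smaller, more parsimonious lambda).

The forest is a bagged ensemble of 100 regression trees, each grown on a
bootstrap sample of the training rows with 12 (one third of 36) candidate
variables per split.  Rows absent from a tree's bootstrap sample form its
out-of-bag (OOB) set — roughly a third of the data — which provides
unbiased performance estimates and permutation variable importance
without a held-out set.  Individual trees are fitted with
scikit-learn's ``DecisionTreeRegressor``; bagging, OOB aggregation and
importance are implemented here so bootstrap membership is explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve
from sklearn.tree import DecisionTreeRegressor

from .evaluation import r_squared

log = logging.getLogger(__name__)


@dataclass
class StandardScaler:
    """Column-wise z-scoring with training-set statistics only.

    Zero-variance columns are flagged and dropped at transform time so a
    constant feature can never produce infinities downstream.
    """

    mean_: np.ndarray = None
    std_: np.ndarray = None
    keep_: np.ndarray = None

    def fit(self, x: np.ndarray) -> "StandardScaler":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate scaling")
        self.mean_ = x.mean(axis=0)
        self.std_ = x.std(axis=0, ddof=0)
        self.keep_ = self.std_ > 0
        if not np.all(self.keep_):
            log.warning("dropping %d zero-variance column(s)", int(np.sum(~self.keep_)))
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.mean_) / np.where(self.keep_, self.std_, 1.0)
        return z[:, self.keep_]

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        if not np.all(self.keep_):
            raise ValueError("cannot invert a transform that dropped columns")
        return np.atleast_2d(z) * self.std_ + self.mean_


@dataclass
class RidgeModel:
    """Weights in standardized space plus the shrinkage used to fit them."""

    weights: np.ndarray
    lam: float

    def predict(self, x_z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x_z) @ self.weights


def ridge_fit(x_z: np.ndarray, y_z: np.ndarray, lam: float) -> RidgeModel:
    """Solve (X'X + lambda I) beta = X'y on z-scored data (no intercept)."""
    if lam < 0:
        raise ValueError("shrinkage must be non-negative")
    x_z = np.atleast_2d(np.asarray(x_z, dtype=float))
    y_z = np.asarray(y_z, dtype=float)
    if x_z.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    g = x_z.T @ x_z + lam * np.eye(x_z.shape[1])
    if lam == 0 and np.linalg.matrix_rank(g) < g.shape[0]:
        raise np.linalg.LinAlgError(
            "X'X is singular at lambda=0 (collinear inputs); use lambda > 0"
        )
    beta = solve(g, x_z.T @ y_z, assume_a="pos" if lam > 0 else "gen")
    return RidgeModel(weights=beta, lam=float(lam))


def _fold_indices(n: int, k: int, rng: np.random.Generator, contiguous: bool = False) -> list[np.ndarray]:
    if k > n:
        raise ValueError("more folds than rows")
    idx = np.arange(n) if contiguous else rng.permutation(n)
    return [fold for fold in np.array_split(idx, k)]


def select_shrinkage(
    datasets: list[tuple[np.ndarray, np.ndarray]],
    lam_grid: np.ndarray | None = None,
    folds: int = 10,
    smooth_window: int = 9,
    seed: int = 0,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Pick the shrinkage maximising the smoothed mean CV R-squared.

    For every lambda on the grid (integers 1..100 by default) and every
    dataset, a ``folds``-fold cross-validated mean R-squared is computed —
    z-scoring is fit on the training part of each fold only.  Curves are
    averaged across datasets, smoothed with a centred moving average of
    width ``smooth_window``, and the argmax is returned (ties toward the
    smaller lambda) together with the raw and smoothed curves.
    """
    if lam_grid is None:
        lam_grid = np.arange(1, 101)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty shrinkage grid")
    if not datasets:
        raise ValueError("need at least one dataset")

    curves = np.zeros((len(datasets), lam_grid.size))
    p = datasets[0][0].shape[1]
    eye = np.eye(p)
    for d_i, (x, y) in enumerate(datasets):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # fold assignment depends only on (n, seed): identical datasets get
        # identical folds, so duplicating a dataset cannot move the optimum
        folds_idx = _fold_indices(len(y), folds, np.random.default_rng(seed))
        r2 = np.zeros((folds, lam_grid.size))
        for f_i, val in enumerate(folds_idx):
            train = np.setdiff1d(np.arange(len(y)), val)
            xs, ys = StandardScaler(), StandardScaler()
            x_tr = xs.fit_transform(x[train])
            y_tr = ys.fit_transform(y[train, None])[:, 0]
            x_val = xs.transform(x[val])
            y_val = ys.transform(y[val, None])[:, 0]
            # Gram matrices once per fold; each lambda is a cheap p x p solve
            g = x_tr.T @ x_tr
            b = x_tr.T @ y_tr
            for l_i, lam in enumerate(lam_grid):
                beta = solve(g + lam * eye[: g.shape[0], : g.shape[0]], b, assume_a="pos")
                r2[f_i, l_i] = r_squared(y_val, x_val @ beta)
        curves[d_i] = r2.mean(axis=0)

    raw = curves.mean(axis=0)
    smoothed = (
        pd.Series(raw).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    best = int(np.argmax(smoothed))  # np.argmax returns the first (smallest lambda) tie
    return int(lam_grid[best]), raw, smoothed


@dataclass
class ForestModel:
    """Bagged regression forest with explicit bootstrap bookkeeping."""

    trees: list = field(default_factory=list)
    bootstrap_idx: list = field(default_factory=list)
    n_trees: int = 100
    mtry: int = 12
    seed: int = 0
    x_train: np.ndarray = None
    y_train: np.ndarray = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.mean([t.predict(x) for t in self.trees], axis=0)

    def oob_mask(self) -> np.ndarray:
        """(n_trees, n_rows) boolean: True where a row is OOB for a tree."""
        n = len(self.y_train)
        mask = np.ones((len(self.trees), n), dtype=bool)
        for t_i, idx in enumerate(self.bootstrap_idx):
            mask[t_i, idx] = False
        return mask

    def oob_predictions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-row OOB prediction (mean over trees not trained on the row).

        Returns (predictions, valid) where ``valid`` marks rows that were
        OOB for at least one tree; the rest are excluded with a warning.
        """
        mask = self.oob_mask()
        preds = np.stack([t.predict(self.x_train) for t in self.trees])
        counts = mask.sum(axis=0)
        valid = counts > 0
        if not np.all(valid):
            log.warning("%d row(s) appear in every bootstrap sample; excluded from OOB",
                        int(np.sum(~valid)))
        num = (preds * mask).sum(axis=0)
        out = np.full(len(valid), np.nan)
        out[valid] = num[valid] / counts[valid]
        return out, valid

    def oob_fraction(self) -> float:
        """Mean per-tree fraction of rows left out of the bootstrap (~1/e)."""
        return float(self.oob_mask().mean())


def forest_fit(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    mtry: int | None = None,
    seed: int = 0,
) -> ForestModel:
    """Grow a bagged forest: bootstrap per tree, ``mtry`` variables per split."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("need at least 10 rows to grow a forest")
    if mtry is None:
        mtry = max(p // 3, 1)
    if mtry > p:
        raise ValueError("mtry cannot exceed the number of variables")
    rng = np.random.default_rng(seed)
    model = ForestModel(n_trees=n_trees, mtry=mtry, seed=seed, x_train=x, y_train=y)
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(x[idx], y[idx])
        model.trees.append(tree)
        model.bootstrap_idx.append(idx)
    return model


def forest_oob_r2(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    mtry: int | None = None,
    n_seeds: int = 10,
    seed: int = 0,
) -> tuple[float, list[float], list[ForestModel]]:
    """OOB R-squared averaged over ``n_seeds`` independently seeded forests."""
    per_seed, forests = [], []
    for s in range(n_seeds):
        model = forest_fit(x, y, n_trees=n_trees, mtry=mtry, seed=seed + s)
        preds, valid = model.oob_predictions()
        per_seed.append(r_squared(np.asarray(y)[valid], preds[valid]))
        forests.append(model)
    return float(np.mean(per_seed)), per_seed, forests


def permutation_importance(
    model: ForestModel, seed: int = 0, normalize: bool = False
) -> np.ndarray:
    """Increase in OOB mean squared error after permuting each variable.

    For every tree, each column is shuffled within the tree's OOB rows and
    the rise in OOB MSE over the unpermuted baseline is recorded; the
    importance of a variable is the average rise across trees.  With
    ``normalize=True`` the importances are scaled to sum to one, so 1/p is
    the reference line for "all variables equally important".
    """
    rng = np.random.default_rng(seed)
    x, y = model.x_train, model.y_train
    n, p = x.shape
    mask = model.oob_mask()
    deltas = np.zeros((len(model.trees), p))
    for t_i, tree in enumerate(model.trees):
        oob = np.flatnonzero(mask[t_i])
        if oob.size == 0:
            continue
        x_oob, y_oob = x[oob], y[oob]
        base_mse = float(np.mean((tree.predict(x_oob) - y_oob) ** 2))
        # one stacked predict per tree: p permuted copies of the OOB block
        stacked = np.tile(x_oob, (p, 1))
        m = oob.size
        for j in range(p):
            stacked[j * m : (j + 1) * m, j] = x_oob[rng.permutation(m), j]
        pred = tree.predict(stacked).reshape(p, m)
        deltas[t_i] = np.mean((pred - y_oob) ** 2, axis=1) - base_mse
    imp = deltas.mean(axis=0)
    if normalize:
        total = np.sum(np.abs(imp))
        if total > 0:
            imp = np.abs(imp) / total
    return imp


def averaged_permutation_importance(forests: list[ForestModel], seed: int = 0) -> np.ndarray:
    """Mean raw permutation importance across a list of fitted forests."""
    return np.mean([permutation_importance(f, seed=seed + i) for i, f in enumerate(forests)], axis=0)
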