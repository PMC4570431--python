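"""Model assessment: rank correlation, R-squared, cross-validation and
the distribution summaries used to compare variable weights/importances.

R-squared follows the classical definition

    R2 = 1 - sum (y - yhat)^2 / sum (y - mean(y))^2

(1 for a perfect regressor, 0 for the naive mean predictor, negative for
worse-than-mean predictions).  Spearman's coefficient is the Pearson
correlation of average ranks, which coincides with the classical
1 - 6*sum(d^2)/(n(n^2-1)) closed form whenever there are no ties.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination; 0 (with a warning) for constant y."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        log.warning("constant target: R^2 defined as 0")
        return 0.0
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN (flagged with a warning) when either input is constant,
    where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant input: Spearman correlation undefined")
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = x.size
    if np.unique(x).size == n and np.unique(y).size == n:
        # tie-free: the classical closed form is exact (+/-1 on monotone data)
        return float(1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1)))
    return float(np.corrcoef(rx, ry)[0, 1])


def kfold_cv(
    x: np.ndarray,
    y: np.ndarray,
    model: str = "ridge",
    lam: float = 32.0,
    n_trees: int = 100,
    k: int = 10,
    seed: int = 0,
    contiguous: bool = False,
) -> tuple[float, list[float]]:
    """Mean k-fold cross-validated R-squared for a ridge or forest model.

    Folds partition the rows (random by default, time-contiguous behind a
    flag).  Scaling is fit on each training split only; ridge models
    z-score both inputs and output, forests use raw targets (trees are
    invariant to monotone input transforms, so inputs are left raw too).
    This fold assignment is independent of any folds used to choose the
    ridge shrinkage.
    """
    from .models import StandardScaler, forest_fit, ridge_fit, _fold_indices

    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    folds = _fold_indices(len(y), k, rng, contiguous=contiguous)
    per_fold = []
    for val in folds:
        train = np.setdiff1d(np.arange(len(y)), val)
        if model == "ridge":
            xs, ys = StandardScaler(), StandardScaler()
            x_tr = xs.fit_transform(x[train])
            y_tr = ys.fit_transform(y[train, None])[:, 0]
            fit = ridge_fit(x_tr, y_tr, lam)
            pred_z = fit.predict(xs.transform(x[val]))
            pred = pred_z * ys.std_[0] + ys.mean_[0]
        elif model == "forest":
            fit = forest_fit(x[train], y[train], n_trees=n_trees,
                             seed=int(rng.integers(0, 2**31 - 1)))
            pred = fit.predict(x[val])
        else:
            raise ValueError("model must be 'ridge' or 'forest'")
        per_fold.append(r_squared(y[val], pred))
    return float(np.mean(per_fold)), per_fold


def summarize_distribution(values: np.ndarray, q_step: float = 0.2) -> dict:
    """Quantile segments and mean-vs-zero significance per variable.

    ``values`` has one row per dataset and one column per variable; for
    each variable the 0, 0.2, ..., 1 quantiles are reported along with a
    two-sided one-sample t-test of mean different from zero (p < 0.05
    flag).  Degenerate zero-variance samples with a non-zero mean are
    flagged significant by convention (warned).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    probs = np.arange(0.0, 1.0 + 1e-9, q_step)
    quantiles = np.quantile(values, probs, axis=0).T
    significant = np.zeros(p, dtype=bool)
    pvals = np.full(p, np.nan)
    if n >= 3:
        for j in range(p):
            col = values[:, j]
            if np.ptp(col) == 0:
                if col[0] != 0:
                    log.warning("zero-variance variable with non-zero mean: flagged significant")
                    significant[j] = True
                    pvals[j] = 0.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.ttest_1samp(col, 0.0)
            pvals[j] = res.pvalue
            significant[j] = res.pvalue < 0.05
    return {"quantiles": quantiles, "probs": probs, "p_values": pvals,
            "significant": significant}


def paired_model_comparison(r2_a: np.ndarray, r2_b: np.ndarray) -> float:
    """Two-sided paired t-test p-value on per-dataset R-squared differences.

    Identical vectors give p = 1; a constant non-zero difference (zero
    variance) gives p = 0 with a warning, since the t statistic diverges.
    """
    a = np.asarray(r2_a, dtype=float)
    b = np.asarray(r2_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 1.0
        log.warning("constant non-zero difference: p reported as 0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)
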