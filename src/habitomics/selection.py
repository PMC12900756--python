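"""Feature-selection cascade: z-score, univariate filter, correlation pruning,
LASSO-penalized logistic regression.

Stage order is fixed (ICC filtering happens upstream in :mod:`features`):
training statistics drive every decision and test rows are only transformed.
The univariate stage gates each feature through a per-class Shapiro-Wilk
normality check (Welch t-test if both classes look normal, Mann-Whitney U
otherwise); correlation pruning walks features by ascending univariate p and
drops any later feature correlated |r| > 0.9 with a kept one; the LASSO
penalty is chosen by ten-fold cross-validated binomial deviance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold


@dataclass
class SelectionResult:
    """Everything the cascade decided, for provenance and reuse."""

    zscore_mean: dict[str, float]
    zscore_sd: dict[str, float]
    univariate: pd.DataFrame  # index feature; columns test, p, kept
    pruned_pairs: list[tuple[str, str, float]]  # (kept, dropped, |r|)
    lasso_lambda: float
    lasso_path: pd.DataFrame  # lambda, mean_deviance, sd_deviance, n_nonzero
    selected: dict[str, float]  # feature -> coefficient
    intercept: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "zscore_mean": self.zscore_mean,
            "zscore_sd": self.zscore_sd,
            "univariate": self.univariate.reset_index().to_dict(orient="list"),
            "pruned_pairs": self.pruned_pairs,
            "lasso_lambda": self.lasso_lambda,
            "lasso_path": self.lasso_path.to_dict(orient="list"),
            "selected": self.selected,
            "intercept": self.intercept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


# --------------------------------------------------------------------------
# Z-score standardization
# --------------------------------------------------------------------------

def zscore_fit_apply(
    train_table: pd.DataFrame,
    *other_tables: pd.DataFrame,
) -> tuple[list[pd.DataFrame], pd.Series, pd.Series]:
    """Standardize with training mean/SD (population SD, ddof=0).

    Returns ([train_z, *others_z], mean, sd).  Zero-SD training columns are
    dropped from every table with a warning.
    """
    mu = train_table.mean(axis=0)
    sd = train_table.std(axis=0, ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        warnings.warn(
            f"dropping {len(dead)} constant training feature(s)", stacklevel=2
        )
    keep = sd.index[sd > 0]
    out = [(t[keep] - mu[keep]) / sd[keep] for t in (train_table, *other_tables)]
    return out, mu[keep], sd[keep]


# --------------------------------------------------------------------------
# Univariate filter
# --------------------------------------------------------------------------

def _feature_test(x0: np.ndarray, x1: np.ndarray, alpha_norm: float) -> tuple[str, float]:
    normal = True
    for x in (x0, x1):
        if len(x) < 3 or np.ptp(x) == 0:
            normal = False
            break
        if stats.shapiro(x).pvalue < alpha_norm:
            normal = False
            break
    if normal:
        return "t", float(stats.ttest_ind(x0, x1, equal_var=False).pvalue)
    if np.ptp(np.concatenate([x0, x1])) == 0:
        return "MWU", 1.0
    res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method="asymptotic")
    return "MWU", float(res.pvalue)


def univariate_filter(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-sample test, normality-gated t vs Mann-Whitney U.

    Returns a frame (index = feature) with columns ``test``, ``p``, ``kept``
    (p < alpha).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rows = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        t, p = _feature_test(x[y == 0], x[y == 1], alpha_norm)
        rows.append((col, t, p, p < alpha))
    return pd.DataFrame(rows, columns=["feature", "test", "p", "kept"]).set_index(
        "feature"
    )


# --------------------------------------------------------------------------
# Correlation pruning
# --------------------------------------------------------------------------

def correlation_prune(
    table: pd.DataFrame,
    survivors: list[str],
    p_values: pd.Series,
    r_threshold: float = 0.9,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy prune ordered by ascending univariate p.

    A later feature is dropped when |Pearson r| with an already-kept feature
    exceeds ``r_threshold``; the final set is pairwise |r| <= threshold.
    """
    if not survivors:
        raise ValueError("need at least one surviving feature")
    order = sorted(survivors, key=lambda c: (p_values[c], survivors.index(c)))
    X = table[order].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(order)):
        clash = next(
            (i for i in kept_idx if abs(corr[i, j]) > r_threshold), None
        )
        if clash is None:
            kept_idx.append(j)
        else:
            dropped.append((order[clash], order[j], float(abs(corr[clash, j]))))
    return [order[i] for i in kept_idx], dropped


# --------------------------------------------------------------------------
# LASSO selection
# --------------------------------------------------------------------------

def _lambda_grid(n: int) -> np.ndarray:
    return np.logspace(-3.5, 0.5, 40)


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    one_se: bool = False,
) -> tuple[float, pd.DataFrame, dict[str, float], float]:
    """L1-penalized logistic regression with stratified CV over a lambda grid.

    ``lambda`` follows the mean-deviance convention (penalty per sample);
    internally C = 1 / (n * lambda).  Returns (chosen lambda, path frame,
    {feature: coefficient} for nonzero features, intercept).  An empty
    selection is allowed and flagged via a warning.
    """
    y = np.asarray(labels)
    X = table.to_numpy(dtype=float)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        n_folds = max(2, int(counts.min()))
    grid = np.sort(np.asarray(lambda_grid if lambda_grid is not None else _lambda_grid(n)))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((len(grid), n_folds))
    for f, (tr, te) in enumerate(cv.split(X, y)):
        for i, lam in enumerate(grid):
            model = LogisticRegression(
                penalty="l1", C=1.0 / (n * lam), solver="liblinear", max_iter=2000,
                random_state=seed,
            )
            model.fit(X[tr], y[tr])
            p = model.predict_proba(X[te])[:, 1]
            dev[i, f] = 2.0 * log_loss(y[te], p, labels=classes)
    mean_dev = dev.mean(axis=1)
    sd_dev = dev.std(axis=1, ddof=1)
    best = int(np.argmin(mean_dev))
    if one_se:
        limit = mean_dev[best] + sd_dev[best] / np.sqrt(n_folds)
        best = int(max(i for i in range(len(grid)) if mean_dev[i] <= limit))
    lam = float(grid[best])
    final = LogisticRegression(
        penalty="l1", C=1.0 / (n * lam), solver="liblinear", max_iter=2000,
        random_state=seed,
    ).fit(X, y)
    coefs = final.coef_.ravel()
    selected = {
        c: float(w) for c, w in zip(table.columns, coefs) if w != 0.0
    }
    path = pd.DataFrame(
        {"lambda": grid, "mean_deviance": mean_dev, "sd_deviance": sd_dev}
    )
    if not selected:
        warnings.warn("LASSO selected no features at the optimal lambda", stacklevel=2)
    return lam, path, selected, float(final.intercept_[0])


# --------------------------------------------------------------------------
# Full cascade
# --------------------------------------------------------------------------

def select_features(
    train_table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    test_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
    r_threshold: float = 0.9,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[SelectionResult, pd.DataFrame, pd.DataFrame | None]:
    """Run z-score -> univariate -> correlation -> LASSO on training rows.

    Returns (result, train_selected_z, test_selected_z); the returned tables
    are standardized and restricted to the selected features.
    """
    tables, mu, sd = zscore_fit_apply(
        train_table, *( [test_table] if test_table is not None else [] )
    )
    train_z = tables[0]
    test_z = tables[1] if test_table is not None else None

    uni = univariate_filter(train_z, labels, alpha=alpha)
    survivors = uni.index[uni["kept"]].tolist()
    if not survivors:
        # fall back to the least-insignificant features so the cascade can
        # still produce a model on weak data; flagged for the report
        warnings.warn("no univariate survivors; keeping 10 smallest-p features",
                      stacklevel=2)
        survivors = uni["p"].nsmallest(min(10, len(uni))).index.tolist()
    pruned, dropped_pairs = correlation_prune(
        train_z, survivors, uni["p"], r_threshold=r_threshold
    )
    lam, path, selected, intercept = lasso_select(
        train_z[pruned], labels, n_folds=n_folds, seed=seed
    )
    if not selected:
        # degenerate but allowed: keep the single best-p pruned feature
        selected = {pruned[0]: 0.0}
    result = SelectionResult(
        zscore_mean={c: float(mu[c]) for c in train_z.columns},
        zscore_sd={c: float(sd[c]) for c in train_z.columns},
        univariate=uni,
        pruned_pairs=dropped_pairs,
        lasso_lambda=lam,
        lasso_path=path,
        selected=selected,
        intercept=intercept,
    )
    cols = list(selected)
    return result, train_z[cols], (test_z[cols] if test_z is not None else None)
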