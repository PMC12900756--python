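"""Evaluation statistics: ROC/AUC with DeLong inference, threshold metrics,
calibration, decision-curve analysis, additive attributions, baseline tables.

AUC is the Mann-Whitney pair-counting statistic (ties count one half); its
variance, confidence intervals, and paired model comparisons use DeLong's
placement-value covariance.  Decision curves report net benefit
``TP/n - (FP/n) * p_t / (1 - p_t)`` against treat-all/treat-none references.
Attributions are Shapley values: telescoping marginal contributions averaged
over sampled feature permutations (exactly additive by construction), with
LightGBM's native tree-path attribution available for tree models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# AUC and DeLong machinery
# --------------------------------------------------------------------------

def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y == 1, y == 0


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney statistic; tied pairs count one half."""
    pos, neg = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)  # midranks
    m = int(pos.sum())
    n = int(neg.sum())
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos, neg = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    sp, sn = s[pos], s[neg]
    m, n = len(sp), len(sn)
    all_ranks = stats.rankdata(np.concatenate([sp, sn]))
    rp = stats.rankdata(sp)
    rn = stats.rankdata(sn)
    v10 = (all_ranks[:m] - rp) / n
    v01 = 1.0 - (all_ranks[m:] - rn) / m
    return v10, v01, float(v10.mean())


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    v10, v01, _ = _placements(scores, labels)
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return float(s10 / len(v10) + s01 / len(v01))


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """(AUC, lower, upper): normal-approximation CI truncated to [0, 1]."""
    auc = roc_auc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0:
        warnings.warn("degenerate DeLong variance; CI collapses to the point",
                      stacklevel=2)
        return auc, auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-sided paired DeLong comparison of two AUCs on the same patients."""
    a10, a01, auc_a = _placements(scores_a, labels)
    b10, b01, auc_b = _placements(scores_b, labels)
    m, n = len(a10), len(a01)
    if m > 1:
        cov10 = np.cov(np.stack([a10, b10]), ddof=1)
    else:
        cov10 = np.zeros((2, 2))
    if n > 1:
        cov01 = np.cov(np.stack([a01, b01]), ddof=1)
    else:
        cov01 = np.zeros((2, 2))
    var = (
        cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]
    ) / m + (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# --------------------------------------------------------------------------
# Threshold metrics
# --------------------------------------------------------------------------

def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on these scores."""
    pos, neg = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    cand = np.unique(s)
    best_t, best_j = cand[0], -np.inf
    for t in cand:
        pred = s >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & neg).sum() / neg.sum()
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def threshold_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/PPV/NPV from the 2x2 table at a threshold."""
    pos, neg = _check_two_class(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    fp = int((pred & neg).sum())
    tn = int((~pred & neg).sum())
    n = tp + fn + fp + tn
    return {
        "threshold": float(threshold),
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if (tp + fp) else np.nan,
        "npv": tn / (tn + fn) if (tn + fn) else np.nan,
    }


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def calibration_curve(
    probabilities: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> tuple[pd.DataFrame, float]:
    """Equal-frequency calibration bins plus the Brier score."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_bins > len(p):
        warnings.warn("fewer samples than bins; reducing bin count", stacklevel=2)
        n_bins = max(1, len(p))
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(p[sel].mean()),
                "observed_fraction": float(y[sel].mean()),
                "n": int(sel.sum()),
            }
        )
    brier = float(np.mean((p - y) ** 2))
    return pd.DataFrame(rows), brier


# --------------------------------------------------------------------------
# Decision curve analysis
# --------------------------------------------------------------------------

def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit of the model, treat-all and treat-none per threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = len(y)
    prev = y.mean()
    rows = []
    for t in thresholds:
        w = t / (1.0 - t)
        pred = p >= t
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        rows.append(
            {
                "threshold": float(t),
                "net_benefit": float(tp - fp * w),
                "treat_all": float(prev - (1 - prev) * w),
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Additive attributions (Shapley values)
# --------------------------------------------------------------------------

def attribution_summary(
    model,
    feature_table: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 16,
    seed: int = 0,
    method: str = "permutation",
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Per-sample additive attributions and the global importance ranking.

    ``method='permutation'`` averages telescoping marginal contributions over
    sampled feature permutations against the background distribution; each
    sample's attributions plus the base value sum exactly to the model output.
    ``method='tree'`` uses LightGBM's native tree-path attribution (log-odds
    scale).  Returns (attribution matrix, mean-|attribution| ranking, base).
    """
    if len(background) == 0:
        raise ValueError("background set must be nonempty")
    X = feature_table.to_numpy(dtype=float)
    B = background[feature_table.columns].to_numpy(dtype=float)
    cols = list(feature_table.columns)

    if method == "tree":
        booster = getattr(model, "estimator", model)
        contrib = booster.predict(X, pred_contrib=True)
        phi = contrib[:, :-1]
        base = float(contrib[0, -1])
    elif method == "permutation":
        if callable(model):
            f = model
        else:
            f = lambda A: model.predict_probability(pd.DataFrame(A, columns=cols))
        n, m = X.shape
        b = len(B)
        rng = np.random.default_rng(seed)
        base = float(np.mean(f(B)))
        phi = np.zeros((n, m))
        for _ in range(n_permutations):
            perm = rng.permutation(m)
            for i in range(n):
                # stack of background copies with progressively replaced columns
                T = np.repeat(B[None, :, :], m + 1, axis=0)
                for t, j in enumerate(perm, start=1):
                    T[t:, :, j] = X[i, j]
                evals = np.asarray(f(T.reshape(-1, m))).reshape(m + 1, b).mean(axis=1)
                phi[i, perm] += np.diff(evals)
        phi /= n_permutations
    else:
        raise ValueError(f"unknown attribution method: {method}")

    attr = pd.DataFrame(phi, index=feature_table.index, columns=cols)
    ranking = attr.abs().mean(axis=0).sort_values(ascending=False)
    return attr, ranking, base


# --------------------------------------------------------------------------
# Baseline comparisons
# --------------------------------------------------------------------------

def baseline_comparison(
    clinical_table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    categorical_max_levels: int = 5,
) -> pd.DataFrame:
    """Per-variable two-group test: normality-gated t/MWU for continuous
    variables, chi-square (Fisher exact when any expected cell < 5) for
    categorical ones.  Returns a frame with the test used and two-sided p."""
    y = np.asarray(labels).astype(int)
    rows = []
    for col in clinical_table.columns:
        x = clinical_table[col]
        levels = x.dropna().unique()
        categorical = (not np.issubdtype(np.asarray(levels).dtype, np.number)) or (
            len(levels) <= categorical_max_levels
        )
        if categorical:
            tab = pd.crosstab(x, y)
            tab = tab.loc[tab.sum(axis=1) > 0]
            if tab.shape[0] < 2:
                warnings.warn(f"variable {col} has a single level; skipped",
                              stacklevel=2)
                continue
            chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy())
            if (expected < 5).any() and tab.shape == (2, 2):
                _, p = stats.fisher_exact(tab.to_numpy())
                test = "fisher"
            else:
                test = "chi2"
        else:
            x0 = x[y == 0].to_numpy(dtype=float)
            x1 = x[y == 1].to_numpy(dtype=float)
            if len(x0) < 2 or len(x1) < 2:
                raise ValueError(f"need >=2 per group for {col}")
            if np.ptp(np.concatenate([x0, x1])) == 0:
                test, p = "t", 1.0
            else:
                test, p = _gated_two_sample(x0, x1)
        rows.append({"variable": col, "test": test, "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")


def _gated_two_sample(x0: np.ndarray, x1: np.ndarray, alpha_norm: float = 0.05):
    normal = all(
        len(x) >= 3 and np.ptp(x) > 0 and stats.shapiro(x).pvalue >= alpha_norm
        for x in (x0, x1)
    )
    if normal:
        return "t", stats.ttest_ind(x0, x1, equal_var=False).pvalue
    return "MWU", stats.mannwhitneyu(x0, x1, alternative="two-sided").pvalue
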