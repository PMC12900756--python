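"""Clinical predictor screening, per-region classifiers, and the nomogram.

Region signatures are modeled with five algorithms (LR, SVM, RF, ExtraTrees,
LightGBM) tuned by five-fold cross-validated AUC; the per-region "radscore"
is the tuned model's predicted probability of high grade.  Clinical
covariates are screened by univariate-then-multivariate logistic regression
(odds ratios with 95% CIs), and the combined nomogram is a logistic fit of
grade on the independent clinical predictor(s) plus the intratumoral, 2-mm
peritumoral, and integrated-habitat radscores, with a 0-100 points mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lightgbm import LGBMClassifier
from scipy.special import expit
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

ALGORITHM_ORDER = ("LR", "SVM", "RF", "ExtraTrees", "LightGBM")

DEFAULT_GRIDS: dict[str, dict] = {
    "LR": {"C": [0.1, 1.0, 10.0]},
    "SVM": {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
    "RF": {"n_estimators": [100, 300], "max_depth": [3, None]},
    "ExtraTrees": {"n_estimators": [100, 300], "max_depth": [3, None]},
    "LightGBM": {"n_estimators": [100, 300], "max_depth": [3, -1]},
}


@dataclass(frozen=True)
class RegionModelSpec:
    """One region-model recipe: algorithm, grid, CV folds, seed."""

    region: str
    algorithm: str
    grid: dict | None = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHM_ORDER:
            raise ValueError(f"algorithm must be one of {ALGORITHM_ORDER}")


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if algorithm == "SVM":
        # probability=True is Platt scaling fitted on internal CV folds
        return SVC(probability=True, random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "ExtraTrees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1)
    if algorithm == "LightGBM":
        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, min_child_samples=5
        )
    raise ValueError(algorithm)


@dataclass
class TrainedModel:
    """A fitted region model; radscore = predicted probability of high grade."""

    spec: RegionModelSpec
    estimator: object
    feature_names: list[str]
    best_params: dict
    cv_auc: float

    def predict_probability(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]

    # alias used by attribution tooling
    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]


def train_region_model(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    spec: RegionModelSpec,
) -> TrainedModel:
    """Grid-search the algorithm's small hyperparameter grid by CV AUC."""
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    y = np.asarray(labels)
    grid = spec.grid if spec.grid is not None else DEFAULT_GRIDS[spec.algorithm]
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_estimator(spec.algorithm, spec.seed),
        param_grid=grid,
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(features.to_numpy(dtype=float), y)
    return TrainedModel(
        spec=spec,
        estimator=search.best_estimator_,
        feature_names=list(features.columns),
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
    )


def train_all_algorithms(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    region: str,
    cv_folds: int = 5,
    seed: int = 0,
) -> dict[str, TrainedModel]:
    return {
        algo: train_region_model(
            features, labels, RegionModelSpec(region, algo, cv_folds=cv_folds, seed=seed)
        )
        for algo in ALGORITHM_ORDER
    }


def select_best_algorithm(
    models: dict[str, TrainedModel],
    evaluation_scores: dict[str, float] | None = None,
    policy: str = "cv",
) -> tuple[str, TrainedModel]:
    """Pick the region's algorithm.

    ``policy='cv'`` (default) maximizes cross-validated training AUC.
    ``policy='paper_faithful'`` maximizes the supplied test-set AUCs and emits
    a selection-bias warning, since test labels inform the choice.  Ties break
    by the fixed algorithm order LR < SVM < RF < ExtraTrees < LightGBM.
    """
    if not models:
        raise ValueError("no candidate models")
    if policy == "paper_faithful":
        if evaluation_scores is None:
            raise ValueError("paper_faithful policy needs test-set scores")
        warnings.warn(
            "algorithm chosen by test-set AUC: estimates are optimistically biased",
            stacklevel=2,
        )
        scores = evaluation_scores
    elif policy == "cv":
        scores = {a: m.cv_auc for a, m in models.items()}
    else:
        raise ValueError(f"unknown policy: {policy}")
    ordered = [a for a in ALGORITHM_ORDER if a in models]
    best = max(ordered, key=lambda a: scores[a])  # max is stable: first wins ties
    return best, models[best]


# --------------------------------------------------------------------------
# Clinical screening
# --------------------------------------------------------------------------

def _logit_fit(X: pd.DataFrame, y: np.ndarray):
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.bse)):
                raise np.linalg.LinAlgError
            return res, False
        except Exception:
            # perfect separation or singular fit: ridge-penalized fallback
            res = sm.Logit(y, Xc).fit_regularized(
                disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
            )
            return res, True


def screen_clinical(
    clinical_table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    entry_alpha: float = 0.05,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Univariate then multivariate logistic screening of covariates.

    Returns (independent predictors, OR table).  Covariates with univariate
    p < ``entry_alpha`` enter one multivariate fit; those with multivariate
    p < ``alpha`` are the independent predictors.
    """
    y = np.asarray(labels)
    if clinical_table.shape[1] == 0:
        raise ValueError("no covariates")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rows = []
    for col in clinical_table.columns:
        res, flagged = _logit_fit(clinical_table[[col]], y)
        coef = res.params[col]
        try:
            se = res.bse[col]
            p = res.pvalues[col]
        except Exception:
            se, p = np.nan, np.nan
        lo, hi = np.exp(coef - 1.96 * se), np.exp(coef + 1.96 * se)
        rows.append(
            {
                "covariate": col, "stage": "univariate", "OR": float(np.exp(coef)),
                "ci_low": float(lo), "ci_high": float(hi), "p": float(p),
                "penalized": flagged,
            }
        )
    table = pd.DataFrame(rows).set_index("covariate")
    entered = table.index[table["p"] < entry_alpha].tolist()
    independent: list[str] = []
    if entered:
        res, flagged = _logit_fit(clinical_table[entered], y)
        for col in entered:
            coef = res.params[col]
            try:
                se = res.bse[col]
                p = res.pvalues[col]
            except Exception:
                se, p = np.nan, np.nan
            table.loc[f"{col} (multivariate)"] = {
                "stage": "multivariate", "OR": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.96 * se)),
                "ci_high": float(np.exp(coef + 1.96 * se)),
                "p": float(p), "penalized": flagged,
            }
            if np.isfinite(p) and p < alpha:
                independent.append(col)
    return independent, table


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """OR of a 2x2 table {a, b; c, d} = (a d)/(b c)."""
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


# --------------------------------------------------------------------------
# Nomogram
# --------------------------------------------------------------------------

@dataclass
class NomogramModel:
    """Logistic fusion of clinical predictor(s) and region radscores.

    ``points`` maps each input linearly to 0-100 relative to the largest
    coefficient-times-range contribution, the conventional nomogram scale.
    """

    input_names: list[str]
    coefficients: np.ndarray
    intercept: float
    input_ranges: dict[str, tuple[float, float]]
    ridge_stabilized: bool = False

    def linear_predictor(self, inputs: pd.DataFrame) -> np.ndarray:
        X = inputs[self.input_names].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients

    def predict_probability(self, inputs: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(inputs))

    def points_table(self) -> pd.DataFrame:
        spans = {}
        for name, beta in zip(self.input_names, self.coefficients):
            lo, hi = self.input_ranges[name]
            spans[name] = abs(beta * (hi - lo))
        top = max(spans.values()) if spans else 1.0
        top = top if top > 0 else 1.0
        rows = []
        for name, beta in zip(self.input_names, self.coefficients):
            lo, hi = self.input_ranges[name]
            rows.append(
                {
                    "input": name,
                    "coefficient": float(beta),
                    "range_low": lo,
                    "range_high": hi,
                    "points_per_unit": float(100.0 * abs(beta) / top),
                    "max_points": float(100.0 * spans[name] / top),
                }
            )
        return pd.DataFrame(rows).set_index("input")


def build_nomogram(
    inputs_train: pd.DataFrame,
    labels_train: np.ndarray | pd.Series,
) -> NomogramModel:
    """Fit the combined logistic model on training radscores + covariates."""
    y = np.asarray(labels_train)
    X = inputs_train.astype(float)
    ridge = False
    corr = X.corr().to_numpy()
    if X.shape[1] > 1 and np.any(np.abs(corr[~np.eye(len(corr), dtype=bool)]) > 0.999):
        warnings.warn("near-collinear nomogram inputs; ridge-stabilized fit",
                      stacklevel=2)
        ridge = True
    res, flagged = _logit_fit(X, y)
    ridge = ridge or flagged
    coefs = np.array([res.params[c] for c in X.columns])
    ranges = {c: (float(X[c].min()), float(X[c].max())) for c in X.columns}
    return NomogramModel(
        input_names=list(X.columns),
        coefficients=coefs,
        intercept=float(res.params["const"]),
        input_ranges=ranges,
        ridge_stabilized=ridge,
    )
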