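"""Classifier training, metrics, and permutation-test significance.

Binary classification of baseline vs. VNS windows with a small model zoo
(random forest, linear/RBF SVM, Gaussian naive Bayes, logistic
regression), all at pinned default parameters, evaluated by stratified
unshuffled 5-fold cross-validation.  Significance of the cross-validated
ROC-AUC is assessed with a label-permutation test: the five observed fold
AUCs are compared against the pooled fold AUCs of (by default) 1000
label shuffles using a two-sample Kolmogorov-Smirnov test.  Pooling the
5 x n_perm null AUCs (rather than per-shuffle means) gives the null
sample the size needed for p-values below 1e-3, which a 5-vs-5
comparison can never reach.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "SplitSpec",
    "CVResult",
    "PermutationTestResult",
    "ComparisonReport",
    "make_model",
    "stratified_split",
    "compute_metrics",
    "cross_validate",
    "permutation_ks_test",
    "compare_feature_sets",
    "tune_best_model",
]

MODEL_NAMES = (
    "random_forest",
    "svm_linear",
    "svm_rbf",
    "gaussian_nb",
    "logistic_regression",
)


def make_model(model_name: str, seed: int = 0, **params):
    """Instantiate a classifier at its pinned default parameters.

    Defaults are pinned here (100 trees for the forest, C = 1 for the
    SVMs) so results do not drift with library releases.
    """
    defaults: dict
    if model_name == "random_forest":
        cls, defaults = RandomForestClassifier, dict(n_estimators=100, random_state=seed)
    elif model_name == "svm_linear":
        cls, defaults = SVC, dict(kernel="linear", C=1.0, random_state=seed)
    elif model_name == "svm_rbf":
        cls, defaults = SVC, dict(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    elif model_name == "gaussian_nb":
        cls, defaults = GaussianNB, {}
    elif model_name == "logistic_regression":
        cls, defaults = LogisticRegression, dict(max_iter=2000, random_state=seed)
    else:
        raise ValueError(f"unknown model {model_name!r}")
    return cls(**{**defaults, **params})


def _scores(model, x: np.ndarray) -> np.ndarray:
    """Continuous class-1 score: probability if available, else margin."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


@dataclass
class SplitSpec:
    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0


@dataclass
class CVResult:
    model_name: str
    fold_aucs: list
    fold_accuracy: list
    fold_f1: list
    fold_f2: list
    feature_importances: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass
class PermutationTestResult:
    observed_aucs: np.ndarray
    null_aucs: np.ndarray
    ks_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ComparisonReport:
    """AUC distributions of the five feature-set configurations plus the
    KS comparisons of the selected set against random subsets and
    shuffled labels."""

    selected_aucs: np.ndarray
    other_scenario_aucs: np.ndarray
    all_features_aucs: np.ndarray
    random_subset_aucs: np.ndarray
    shuffled_label_aucs: np.ndarray
    ks_vs_random_subsets: tuple
    ks_vs_shuffled_labels: tuple


def stratified_split(table: pd.DataFrame, spec: SplitSpec, label_col: str = "label"):
    """Stratified train/test split: per class, round(test_fraction * n_c)
    samples (at least one) go to the held-out set; deterministic given the
    seed."""
    y = table[label_col].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(spec.seed)
    test_idx = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        n_test = max(1, round(spec.test_fraction * len(idx)))
        test_idx.extend(rng.permutation(idx)[:n_test])
    test_mask = np.zeros(len(table), dtype=bool)
    test_mask[np.array(test_idx)] = True
    return table.iloc[~test_mask], table.iloc[test_mask]


def _auc_mann_whitney(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """ROC-AUC as the Mann-Whitney rank statistic, half credit for ties."""
    y_true = np.asarray(y_true)
    pos = y_true == np.max(y_true)
    n1 = int(pos.sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: y_true has a single class")
    ranks = rankdata(y_score)  # average ranks handle ties with 0.5 credit
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def compute_metrics(y_true, y_score, y_pred) -> tuple[float, float, float, float]:
    """(AUC, accuracy, F1, F2) for one evaluation fold.

    F_beta = (1 + b^2) P R / (b^2 P + R); F2 weights recall twice as
    heavily as precision, relevant when missing a stimulation window is
    costlier than a false alarm.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    auc = _auc_mann_whitney(y_true, np.asarray(y_score, dtype=float))
    acc = float(np.mean(y_true == y_pred))
    pos = np.max(y_true)
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    fp = int(np.sum((y_pred == pos) & (y_true != pos)))
    fn = int(np.sum((y_pred != pos) & (y_true == pos)))

    def fbeta(beta: float) -> float:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        if p == 0 and r == 0:
            return 0.0
        return (1 + beta**2) * p * r / (beta**2 * p + r)

    return auc, acc, fbeta(1.0), fbeta(2.0)


def cross_validate(
    model_name: str,
    X: pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified unshuffled k-fold cross-validation at pinned defaults.

    Folds are contiguous in the input order (shuffle off), mirroring the
    session ordering of the windows; tree-model impurity importances are
    averaged across folds.
    """
    y = np.asarray(y)
    xv = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=False)
    aucs, accs, f1s, f2s = [], [], [], []
    importances = []
    for i, (tr, te) in enumerate(skf.split(xv, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {i} contains a single class")
        model = make_model(model_name, seed=seed)
        model.fit(xv[tr], y[tr])
        score = _scores(model, xv[te])
        pred = model.predict(xv[te])
        auc, acc, f1, f2 = compute_metrics(y[te], score, pred)
        aucs.append(auc)
        accs.append(acc)
        f1s.append(f1)
        f2s.append(f2)
        if hasattr(model, "feature_importances_"):
            importances.append(model.feature_importances_)
    imp = (
        dict(zip(X.columns, np.mean(importances, axis=0))) if importances else {}
    )
    return CVResult(
        model_name=model_name,
        fold_aucs=aucs,
        fold_accuracy=accs,
        fold_f1=f1s,
        fold_f2=f2s,
        feature_importances=imp,
    )


def _ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and p-value; exact when both samples are
    small (<= 25), asymptotic otherwise."""
    method = "exact" if max(len(a), len(b)) <= 25 else "asymp"
    res = ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def permutation_ks_test(
    model_name: str,
    X: pd.DataFrame,
    y,
    n_perm: int = 1000,
    seed: int = 0,
    k: int = 5,
) -> PermutationTestResult:
    """Label-permutation significance test of the cross-validated AUC.

    Observed sample: the k fold AUCs with true labels.  Null sample: the
    pooled k x n_perm fold AUCs over seeded label shuffles.  The two
    samples are compared with a two-sample KS test; p < 0.05 rejects the
    chance-level null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y)
    observed = np.array(cross_validate(model_name, X, y, k=k, seed=seed).fold_aucs)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_perm):
        y_shuf = rng.permutation(y)
        null.extend(cross_validate(model_name, X, y_shuf, k=k, seed=seed).fold_aucs)
    null = np.array(null)
    stat, p = _ks_two_sample(observed, null)
    return PermutationTestResult(
        observed_aucs=observed, null_aucs=null, ks_statistic=stat, p_value=p
    )


def compare_feature_sets(
    table: pd.DataFrame,
    scenario_selected: list,
    other_scenario_selected: list,
    seed: int = 0,
    model_name: str = "random_forest",
    feature_cols: list | None = None,
    n_perm: int = 100,
    label_col: str = "label",
) -> ComparisonReport:
    """The five-configuration feature-set comparison.

    Cross-validated AUCs for (a) this scenario's selected features,
    (b) the other scenario's selected features, (c) all features,
    (d) ``n_perm`` random subsets the size of (a), (e) ``n_perm`` label
    shuffles on (a); KS tests compare (a) against the pooled (d) and (e)
    distributions.
    """
    if not scenario_selected or not other_scenario_selected:
        raise ValueError("selected feature sets must be non-empty")
    universe = feature_cols if feature_cols is not None else [
        c for c in table.columns
        if c not in (label_col, "subject_id", "session_id", "stim_freq_hz")
    ]
    for s in (scenario_selected, other_scenario_selected):
        missing = set(s) - set(universe)
        if missing:
            raise ValueError(f"selected features outside the table: {missing}")
    y = table[label_col].to_numpy()
    rng = np.random.default_rng(seed)

    def cv_aucs(cols, labels) -> np.ndarray:
        return np.array(
            cross_validate(model_name, table[list(cols)], labels, seed=seed).fold_aucs
        )

    a = cv_aucs(scenario_selected, y)
    b = cv_aucs(other_scenario_selected, y)
    c = cv_aucs(universe, y)
    d = np.concatenate([
        cv_aucs(rng.choice(universe, size=len(scenario_selected), replace=False), y)
        for _ in range(n_perm)
    ])
    e = np.concatenate([
        cv_aucs(scenario_selected, rng.permutation(y)) for _ in range(n_perm)
    ])
    return ComparisonReport(
        selected_aucs=a,
        other_scenario_aucs=b,
        all_features_aucs=c,
        random_subset_aucs=d,
        shuffled_label_aucs=e,
        ks_vs_random_subsets=_ks_two_sample(a, d),
        ks_vs_shuffled_labels=_ks_two_sample(a, e),
    )


#: random-search grid for the forest (the best model in practice)
_RF_GRID = {
    "n_estimators": [50, 100, 200, 400],
    "max_depth": [None, 3, 5, 10],
    "max_features": ["sqrt", "log2", None],
    "min_samples_leaf": [1, 2, 4],
}


def tune_best_model(
    table: pd.DataFrame,
    budget: int = 20,
    seed: int = 0,
    model_name: str = "random_forest",
    feature_cols: list | None = None,
    label_col: str = "label",
) -> tuple[dict, float]:
    """Seeded random search over a documented grid.

    The first candidate is always the pinned default configuration, so
    the returned score never falls below the default's; returns (params,
    mean CV AUC).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    cols = feature_cols if feature_cols is not None else [
        c for c in table.columns
        if c not in (label_col, "subject_id", "session_id", "stim_freq_hz")
    ]
    X, y = table[list(cols)], table[label_col].to_numpy()
    rng = np.random.default_rng(seed)
    candidates: list[dict] = [{}]  # defaults first
    for _ in range(budget - 1):
        candidates.append(
            {k: v[rng.integers(len(v))] for k, v in _RF_GRID.items()}
        )
    best_params, best_score = {}, -np.inf
    for params in candidates:
        y_arr = y
        xv = X.to_numpy(dtype=float)
        skf = StratifiedKFold(n_splits=5, shuffle=False)
        aucs = []
        for tr, te in skf.split(xv, y_arr):
            model = make_model(model_name, seed=seed, **params)
            model.fit(xv[tr], y_arr[tr])
            aucs.append(_auc_mann_whitney(y_arr[te], _scores(model, xv[te])))
        score = float(np.mean(aucs))
        if score > best_score:
            best_params, best_score = params, score
    return best_params, best_score
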