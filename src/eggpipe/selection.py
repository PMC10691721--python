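"""Ensemble-voting feature selection and correlation diagnostics.

With roughly three windows per feature, no single selector can be
trusted; instead a battery of selectors (ANOVA F, mutual information,
L1/L2 linear SVC, RFE and permutation importance over random forests,
forward/backward sequential selection, variance thresholding) each
produces a non-negative weight vector summing to one, the per-method
vectors are averaged and re-normalized, and the final subset is the
shortest descending-weight prefix whose cumulative weight reaches the
cutoff (default 0.9).

A Spearman correlation clustering (distance = 1 - rho, average linkage)
is provided as the redundancy diagnostic used to inspect the battery
before voting.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import (
    RFE,
    SequentialFeatureSelector,
    VarianceThreshold,
    f_classif,
    mutual_info_classif,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

__all__ = [
    "SELECTOR_METHODS",
    "SelectorWeights",
    "VotingResult",
    "CorrelationClustering",
    "spearman_distance_cluster",
    "run_selector",
    "vote_and_select",
    "run_all_selectors",
    "plot_correlation_heatmap",
]

SELECTOR_METHODS = (
    "anova_f",
    "mutual_info",
    "l1_lsvc",
    "l2_lsvc",
    "rfe_rf",
    "sfs_backward",
    "sfs_forward",
    "perm_importance_rf",
    "variance_threshold",
)

#: selectors whose importances are scale-sensitive and therefore see
#: z-scored features (train-fold statistics); tree methods use raw values
_SCALED_METHODS = {"l1_lsvc", "l2_lsvc", "sfs_backward", "sfs_forward"}


@dataclass
class SelectorWeights:
    method_name: str
    weights: pd.Series  # feature -> weight >= 0, sums to 1

    def __post_init__(self) -> None:
        total = float(self.weights.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.method_name}: weights sum to {total}, not 1")


@dataclass
class VotingResult:
    avg_weights: pd.Series  # feature -> averaged weight, sums to 1
    ranked_features: list
    selected: list
    cumulative_cutoff: float = 0.9


@dataclass
class CorrelationClustering:
    spearman: pd.DataFrame
    distance: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list


def spearman_distance_cluster(feature_table: pd.DataFrame) -> CorrelationClustering:
    """Spearman correlation matrix over feature columns, distance
    ``1 - rho``, average-linkage dendrogram and its leaf order.

    Constant columns have undefined rank correlation; their off-diagonal
    entries are set to 0 with a warning.
    """
    if feature_table.shape[1] < 2 or feature_table.shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 samples")
    cols = list(feature_table.columns)
    x = feature_table.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(x, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    constant = x.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant feature columns {list(np.array(cols)[constant])}: "
            "correlations set to 0"
        )
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [cols[i] for i in leaves_list(z)]
    return CorrelationClustering(
        spearman=pd.DataFrame(rho, index=cols, columns=cols),
        distance=pd.DataFrame(dist, index=cols, columns=cols),
        linkage=z,
        leaf_order=order,
    )


def _uniform_over(selected: np.ndarray, columns) -> np.ndarray:
    """Equal weights 1/k over a boolean selection mask."""
    w = np.zeros(len(columns))
    k = int(selected.sum())
    if k > 0:
        w[selected] = 1.0 / k
    return w


def _fold_importances(
    method: str,
    x: np.ndarray,
    y: np.ndarray,
    columns,
    seed: int,
    n_select: int,
) -> np.ndarray:
    """Raw (unnormalized) importance vector for one training fold."""
    if method in _SCALED_METHODS:
        x = StandardScaler().fit_transform(x)
    if method == "anova_f":
        f, _ = f_classif(x, y)
        return np.nan_to_num(f, nan=0.0)
    if method == "mutual_info":
        return mutual_info_classif(x, y, random_state=seed)
    if method in ("l1_lsvc", "l2_lsvc"):
        penalty = "l1" if method == "l1_lsvc" else "l2"
        clf = LinearSVC(
            penalty=penalty, dual=False, C=1.0, max_iter=5000, random_state=seed
        )
        clf.fit(x, y)
        return np.abs(clf.coef_).ravel()
    if method == "rfe_rf":
        rfe = RFE(
            RandomForestClassifier(n_estimators=100, random_state=seed),
            n_features_to_select=n_select,
        )
        rfe.fit(x, y)
        # surviving features share rank 1; weight falls with elimination rank
        return 1.0 / rfe.ranking_
    if method in ("sfs_backward", "sfs_forward"):
        direction = "backward" if method == "sfs_backward" else "forward"
        sfs = SequentialFeatureSelector(
            LogisticRegression(max_iter=2000),
            n_features_to_select=n_select,
            direction=direction,
            cv=3,
        )
        sfs.fit(x, y)
        return _uniform_over(sfs.get_support(), columns)
    if method == "perm_importance_rf":
        rf = RandomForestClassifier(n_estimators=100, random_state=seed)
        rf.fit(x, y)
        imp = permutation_importance(
            rf, x, y, n_repeats=5, random_state=seed
        ).importances_mean
        return np.clip(imp, 0.0, None)
    raise ValueError(f"unknown selection method {method!r}")


def run_selector(
    method: str,
    X: pd.DataFrame,
    y,
    cv_folds: int = 5,
    seed: int = 0,
    variance_threshold: float = 0.0,
) -> SelectorWeights:
    """One base selector's normalized weight vector.

    All methods except variance thresholding run per training fold of a
    stratified, unshuffled k-fold split; fold importances are averaged,
    clipped at zero and normalized to sum one.  Variance thresholding is
    label-free, runs once on all data, and spreads weight 1/k over the
    surviving features.
    """
    if method not in SELECTOR_METHODS:
        raise ValueError(f"unknown selection method {method!r}")
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    cols = list(X.columns)
    xv = X.to_numpy(dtype=float)
    n_select = math.ceil(len(cols) / 2)

    if method == "variance_threshold":
        vt = VarianceThreshold(threshold=variance_threshold)
        vt.fit(xv)
        w = _uniform_over(vt.get_support(), cols)
    else:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=False)
        per_fold = []
        for i, (train_idx, _) in enumerate(skf.split(xv, y)):
            y_tr = y[train_idx]
            if len(np.unique(y_tr)) < 2:
                raise ValueError(f"fold {i} of {method} has a single class")
            per_fold.append(
                _fold_importances(method, xv[train_idx], y_tr, cols, seed, n_select)
            )
        w = np.clip(np.mean(per_fold, axis=0), 0.0, None)
    total = w.sum()
    w = w / total if total > 0 else np.full(len(cols), 1.0 / len(cols))
    return SelectorWeights(method_name=method, weights=pd.Series(w, index=cols))


def vote_and_select(
    all_weights: list[SelectorWeights], cutoff: float = 0.9
) -> VotingResult:
    """Average the per-method weight vectors and pick the winning subset.

    Features missing from a method's vector count as weight 0.  The
    averaged vector is re-normalized to sum one and sorted descending
    (ties broken alphabetically); the selected subset is the shortest
    prefix whose cumulative weight reaches ``cutoff``, including the
    crossing feature.
    """
    if not all_weights:
        raise ValueError("no selector results to vote over")
    universe = sorted({f for sw in all_weights for f in sw.weights.index})
    mat = pd.DataFrame(
        {sw.method_name: sw.weights.reindex(universe).fillna(0.0) for sw in all_weights}
    )
    avg = mat.mean(axis=1)
    avg = avg / avg.sum()
    # descending weight, alphabetical tie-break
    order = sorted(universe, key=lambda f: (-avg[f], f))
    csum = np.cumsum([avg[f] for f in order])
    n_sel = int(np.searchsorted(csum, cutoff - 1e-12)) + 1
    n_sel = min(n_sel, len(order))
    return VotingResult(
        avg_weights=avg.reindex(order),
        ranked_features=order,
        selected=order[:n_sel],
        cumulative_cutoff=cutoff,
    )


def run_all_selectors(
    X: pd.DataFrame,
    y,
    methods=SELECTOR_METHODS,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[SelectorWeights]:
    """Run every base selector with a shared seed."""
    return [run_selector(m, X, y, cv_folds=cv_folds, seed=seed) for m in methods]


def plot_correlation_heatmap(clustering: CorrelationClustering, path=None):
    """Render the leaf-ordered Spearman heatmap (redundancy diagnostic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clustering.leaf_order
    mat = clustering.spearman.loc[order, order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
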