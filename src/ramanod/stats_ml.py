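"""Statistics and machine learning on standardized biomolecular profiles.

Per-size-group PCA of the water-standardized component intensities,
random-forest regression (RFR) of acetylene-reduction activity with
grid-searched hyperparameters and a held-out test split, impurity-based
feature importances, and the Welch t-test for nodule-size contrasts of
ARA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split

from .datatypes import ConcentrationProfile

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [None, 3, 6],
    "min_samples_leaf": [1, 2, 4],
}


# ---------------------------------------------------------------------------
# PCA per size group

@dataclass
class GroupPCA:
    scores: np.ndarray
    loadings: np.ndarray  # (n_pc, n_features)
    explained_variance_ratio: np.ndarray
    feature_names: list[str]
    index: pd.DataFrame


def pca_scores(
    profile: ConcentrationProfile,
    group_by: str = "size_group",
    n_components: int | None = None,
) -> dict[str, GroupPCA]:
    """Per-feature-centered PCA of the profiles, separately per group.

    The sign convention fixes each loading vector so its
    largest-magnitude entry is positive.
    """
    results: dict[str, GroupPCA] = {}
    frame = profile.metadata
    for group, idx in frame.groupby(group_by, sort=True).groups.items():
        X = profile.values[np.asarray(idx)]
        n_feat = X.shape[1]
        k = n_components if n_components is not None else min(X.shape[0], n_feat)
        if X.shape[0] < max(3, k):
            raise ValueError(
                f"group {group!r} has {X.shape[0]} cells; need >= max(3, {k})"
            )
        pca = PCA(n_components=k)
        scores = pca.fit_transform(X)
        loadings = pca.components_.copy()
        for j in range(loadings.shape[0]):
            lead = np.argmax(np.abs(loadings[j]))
            if loadings[j, lead] < 0:
                loadings[j] *= -1.0
                scores[:, j] *= -1.0
        results[str(group)] = GroupPCA(
            scores=scores,
            loadings=loadings,
            explained_variance_ratio=pca.explained_variance_ratio_,
            feature_names=list(profile.components),
            index=frame.loc[idx].reset_index(drop=True),
        )
    return results


# ---------------------------------------------------------------------------
# Aggregation of single-cell profiles to ARA measurement units

def aggregate_profiles(
    profile: ConcentrationProfile, level: str = "nodule"
) -> pd.DataFrame:
    """Mean standardized profile per nodule or per (phase, size) condition.

    Returns one row per unit with the component means, the identifying
    metadata and the contributing cell count.
    """
    if level not in ("nodule", "condition"):
        raise ValueError("level must be 'nodule' or 'condition'")
    keys = ["nodule_id"] if level == "nodule" else ["phase", "size_group"]
    frame = profile.to_frame()
    grouped = frame.groupby(keys, sort=True)
    agg = grouped[list(profile.components)].mean()
    agg["n_cells"] = grouped.size()
    meta_cols = [c for c in ("phase", "size_group") if c not in keys]
    if meta_cols:
        agg[meta_cols] = grouped[meta_cols].first()
    return agg.reset_index()


# ---------------------------------------------------------------------------
# Random-forest regression of ARA

class ARAForest(BaseEstimator, RegressorMixin):
    """Random-forest regressor with grid-searched hyperparameters.

    Thin estimator around ``GridSearchCV(RandomForestRegressor)`` with
    k-fold CV on the training data only; exposes normalized
    impurity-based importances (``feature_importances_``) and the chosen
    grid point (``best_params_``).
    """

    def __init__(self, grid: dict | None = None, cv_folds: int = 5, random_state: int | None = None):
        self.grid = grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if np.ptp(y) == 0:
            raise ValueError("degenerate target: all ARA values are identical")
        grid = self.grid if self.grid else DEFAULT_GRID
        if not grid:
            raise ValueError("hyperparameter grid must be non-empty")
        folds = self.cv_folds
        if folds > X.shape[0]:
            raise ValueError(
                f"cv_folds={folds} exceeds the {X.shape[0]} training observations"
            )
        if folds < 2:
            raise ValueError("cv_folds must be >= 2")
        cv = KFold(n_splits=folds, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            RandomForestRegressor(random_state=self.random_state),
            param_grid=grid,
            cv=cv,
            scoring="neg_mean_squared_error",
        )
        search.fit(X, y)
        self.search_ = search
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        total = self.model_.feature_importances_.sum()
        self.feature_importances_ = (
            self.model_.feature_importances_ / total
            if total > 0
            else np.full(X.shape[1], 1.0 / X.shape[1])
        )
        return self

    def predict(self, X):
        return self.model_.predict(np.atleast_2d(np.asarray(X, dtype=float)))


@dataclass
class ModelReport:
    """Train/eval record for one size group's ARA prediction model."""

    size_group: str
    train_fraction: float
    seed: int | None
    cv_folds: int
    grid: dict
    best_params: dict
    test_r2: float
    train_r2: float
    importances: dict
    predictions: list  # (actual, predicted) pairs on the test set
    n_train: int
    n_test: int
    importance_kind: str = "impurity"
    permutation_importances: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def rfr_train_eval(
    features: pd.DataFrame,
    ara_values: np.ndarray | pd.Series,
    size_group: str,
    feature_names: list[str] | None = None,
    grid: dict | None = None,
    cv_folds: int = 5,
    train_fraction: float = 0.75,
    seed: int | None = 0,
    stratify: np.ndarray | pd.Series | None = None,
    permutation: bool = False,
) -> ModelReport:
    """Split 75/25, grid-search a random forest on the training part by
    k-fold CV, and report held-out R^2 with normalized importances.

    ``stratify`` (e.g. growth phase) keeps every stratum represented in
    both halves of the split, which matters at the study's small
    per-group sample sizes.
    """
    names = feature_names if feature_names is not None else list(features.columns)
    X = np.asarray(features[names] if isinstance(features, pd.DataFrame) else features, dtype=float)
    y = np.asarray(ara_values, dtype=float).ravel()
    if X.shape[0] < 8:
        raise ValueError(f"need >= 8 observations per size group, got {X.shape[0]}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=train_fraction,
        random_state=seed,
        stratify=np.asarray(stratify) if stratify is not None else None,
    )
    grid_used = grid if grid else DEFAULT_GRID
    forest = ARAForest(grid=grid_used, cv_folds=cv_folds, random_state=seed)
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    importances = dict(zip(names, forest.feature_importances_.tolist()))
    perm = None
    if permutation:
        res = permutation_importance(
            forest.model_, X_te, y_te, n_repeats=30, random_state=seed
        )
        perm = dict(zip(names, res.importances_mean.tolist()))
    return ModelReport(
        size_group=size_group,
        train_fraction=train_fraction,
        seed=seed,
        cv_folds=cv_folds,
        grid={k: list(v) for k, v in grid_used.items()},
        best_params=forest.best_params_,
        test_r2=float(r2_score(y_te, pred)),
        train_r2=float(r2_score(y_tr, forest.predict(X_tr))),
        importances=importances,
        predictions=[(float(a), float(p)) for a, p in zip(y_te, pred)],
        n_train=int(X_tr.shape[0]),
        n_test=int(X_te.shape[0]),
        permutation_importances=perm,
    )


# ---------------------------------------------------------------------------
# Size-contrast t-test of ARA

@dataclass
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    note: str = ""


def group_ttest(
    ara: pd.DataFrame,
    contrast: tuple[str, str] = ("G3", "G1"),
    within: str = "Nod",
    value: str = "ara_total",
) -> TTestResult:
    """Welch two-sample t-test of ARA between two size groups in one phase."""
    sub = ara[ara["phase"] == within]
    a = sub.loc[sub["size_group"] == contrast[0], value].to_numpy(dtype=float)
    b = sub.loc[sub["size_group"] == contrast[1], value].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each contrasted group needs >= 2 replicates")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0,
                           note="zero variance in both groups with equal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
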