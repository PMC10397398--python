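"""Model-based expected mortality-rate surfaces.

The scan statistic downstream needs, for every geographic unit, an expected
rate given its sociodemographic profile. This module produces it the way
ecological ML studies do: candidate regressors are compared by repeated
k-fold cross-validated R-squared on a train split, the winning family is
tuned by random search, and the final surface is the out-of-fold (OOF)
prediction from k-fold cross-validation over the whole dataset — each
unit's prediction comes from a model that never saw that unit.

Preprocessing (min-max scaling to [0, 1] and K-nearest-neighbour
imputation of missing covariate cells) is embedded in an sklearn Pipeline
so its statistics are fit inside each training fold; a ``global`` scope is
available for fidelity experiments with workflows that preprocess once
up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.impute import KNNImputer
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold, RepeatedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR, LinearSVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from .errors import ConfigurationError, DataError
from .synthetic import covariate_columns

logger = logging.getLogger(__name__)

__all__ = [
    "CVSpec",
    "ModelSpec",
    "ExpectedSurface",
    "FAMILIES",
    "impute_knn",
    "minmax_scale",
    "split_train_test",
    "select_model",
    "tune",
    "oof_predict",
    "feature_importance",
]


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation design: 70/30 split, 3x10-fold selection by default."""

    k_folds: int = 10
    repeats: int = 3
    train_fraction: float = 0.70
    search_iterations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be at least 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus a concrete hyperparameter assignment."""

    family: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILIES)}"
            )


# family -> (estimator class, defaults, random-search grid). The nine
# families mirror the usual ecological-regression toolbox;
# "conditional-tree" is backed by a cost-complexity-pruned CART, the
# closest Python analog of conditional inference trees. Classes whose
# defaults include ``random_state`` are seeded at build time.
FAMILIES: dict[str, tuple] = {
    "gradient-boosted-trees": (
        XGBRegressor,
        {"n_estimators": 200, "max_depth": 4, "learning_rate": 0.1,
         "subsample": 0.9, "n_jobs": 1, "verbosity": 0, "tree_method": "hist",
         "random_state": None},
        {
            "n_estimators": [50, 100, 200, 300, 500],
            "max_depth": [2, 3, 4, 6, 8],
            "learning_rate": [0.01, 0.03, 0.1, 0.2, 0.3],
            "subsample": [0.6, 0.8, 1.0],
        },
    ),
    "random-forest": (
        RandomForestRegressor,
        {"n_estimators": 200, "n_jobs": 1, "random_state": None},
        {
            "n_estimators": [100, 200, 300, 500],
            "max_features": [0.2, 0.4, 0.6, 0.8, 1.0],
            "min_samples_leaf": [1, 2, 5, 10],
        },
    ),
    "polynomial-svm": (
        SVR,
        {"kernel": "poly", "C": 10.0, "degree": 2, "coef0": 1.0},
        {
            "C": [0.1, 1.0, 10.0, 100.0],
            "degree": [2, 3, 4],
            "epsilon": [0.01, 0.1, 1.0],
        },
    ),
    "lasso": (
        Lasso,
        {"alpha": 0.01, "max_iter": 20000},
        {"alpha": list(np.logspace(-4, 1, 12))},
    ),
    "ridge": (Ridge, {"alpha": 1.0}, {"alpha": list(np.logspace(-4, 2, 12))}),
    "linear": (LinearRegression, {}, {}),
    "linear-svm": (
        LinearSVR,
        {"C": 1.0, "max_iter": 20000, "dual": "auto", "random_state": None},
        {"C": [0.01, 0.1, 1.0, 10.0], "epsilon": [0.0, 0.1, 1.0]},
    ),
    "decision-tree": (
        DecisionTreeRegressor,
        {"min_samples_leaf": 5, "random_state": None},
        {"min_samples_leaf": [2, 5, 10, 20], "max_depth": [3, 5, 8, None]},
    ),
    "conditional-tree": (
        DecisionTreeRegressor,
        {"min_samples_leaf": 10, "ccp_alpha": 1.0, "random_state": None},
        {"min_samples_leaf": [5, 10, 20], "ccp_alpha": [0.1, 1.0, 10.0]},
    ),
}


def _build_estimator(family: str, params: Mapping[str, object], seed: int):
    cls, defaults, _ = FAMILIES[family]
    merged = {**defaults, **dict(params)}
    if "random_state" in merged and merged["random_state"] is None:
        merged["random_state"] = seed
    return cls(**merged)


def impute_knn(covariates: np.ndarray | pd.DataFrame, k: int = 5) -> np.ndarray:
    """Fill missing cells with the mean of the k nearest rows.

    Distances are (NaN-aware) Euclidean on mutually observed features; the
    caller is expected to pass scaled features. Columns must each retain at
    least ``k`` observed values; a fully missing column is a data error.
    """
    x = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) \
        else np.asarray(covariates, float)
    observed = (~np.isnan(x)).sum(axis=0)
    if (observed == 0).any():
        raise DataError("a covariate column is entirely missing")
    if (observed < k).any():
        raise DataError(f"every column needs at least k={k} observed values")
    if not np.isnan(x).any():
        return x.copy()
    return KNNImputer(n_neighbors=k, weights="uniform").fit_transform(x)


def minmax_scale(
    train: np.ndarray | pd.DataFrame,
    apply: np.ndarray | pd.DataFrame | None = None,
) -> np.ndarray:
    """Scale columns to [0, 1] with statistics from ``train`` only.

    Constant columns map to 0; apply-set values outside the training range
    are clipped to [0, 1].
    """
    scaler = MinMaxScaler(clip=True)
    scaler.fit(np.asarray(train, float))
    target = train if apply is None else apply
    return scaler.transform(np.asarray(target, float))


def _make_pipeline(spec: ModelSpec, seed: int, knn_k: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", MinMaxScaler(clip=True)),
            ("impute", KNNImputer(n_neighbors=knn_k)),
            ("model", _build_estimator(spec.family, spec.params, seed)),
        ]
    )


def _xy(units: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    cols = covariate_columns(units)
    if not cols:
        raise DataError("unit table has no covariate (x_) columns")
    if outcome not in units.columns:
        raise DataError(f"outcome column {outcome!r} not found")
    return units[cols].to_numpy(float), units[outcome].to_numpy(float)


def split_train_test(
    units: pd.DataFrame, train_fraction: float = 0.70, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 70/30-style split of units into train and test tables."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(units)
    perm = rng.permutation(n)
    cut = int(round(train_fraction * n))
    return units.iloc[perm[:cut]].copy(), units.iloc[perm[cut:]].copy()


def _cv_scores(
    spec: ModelSpec,
    x: np.ndarray,
    y: np.ndarray,
    cv: CVSpec,
    *,
    repeats: int | None = None,
    knn_k: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-level (R2, RMSE) arrays under repeated k-fold CV."""
    rk = RepeatedKFold(
        n_splits=cv.k_folds,
        n_repeats=cv.repeats if repeats is None else repeats,
        random_state=cv.seed,
    )
    r2s, rmses = [], []
    for tr, te in rk.split(x):
        pipe = _make_pipeline(spec, cv.seed, knn_k)
        pipe.fit(x[tr], y[tr])
        pred = pipe.predict(x[te])
        r2s.append(r2_score(y[te], pred))
        rmses.append(float(np.sqrt(mean_squared_error(y[te], pred))))
    return np.array(r2s), np.array(rmses)


def select_model(
    train: pd.DataFrame,
    candidates: Sequence[str],
    cv: CVSpec,
    *,
    outcome: str = "adjusted_rate",
    knn_k: int = 5,
) -> pd.DataFrame:
    """Rank candidate families by mean CV R-squared on the train split.

    Returns one row per family with ``mean_r2``, a 95% normal-approximation
    CI over fold-level R-squared values, and mean RMSE, sorted by ``mean_r2``
    descending.
    """
    if len(candidates) < 2:
        raise ConfigurationError("need at least 2 candidate families")
    x, y = _xy(train, outcome)
    rows = []
    for family in candidates:
        r2s, rmses = _cv_scores(ModelSpec(family), x, y, cv, knn_k=knn_k)
        m = r2s.mean()
        half = 1.96 * r2s.std(ddof=1) / np.sqrt(len(r2s))
        rows.append(
            {
                "family": family,
                "mean_r2": m,
                "ci_low": m - half,
                "ci_high": m + half,
                "rmse": rmses.mean(),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("mean_r2", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def tune(
    family: str,
    train: pd.DataFrame,
    cv: CVSpec,
    *,
    outcome: str = "adjusted_rate",
    knn_k: int = 5,
) -> ModelSpec:
    """Random search over the family's documented grid.

    Each iteration samples one value per parameter uniformly from the grid
    and scores it by repeated k-fold mean R-squared; ties break by lower
    RMSE, then lexicographic parameter order. Deterministic given the CV
    seed.
    """
    if cv.search_iterations < 1:
        raise ConfigurationError("search_iterations must be at least 1")
    grid = FAMILIES[family][2]
    x, y = _xy(train, outcome)
    rng = np.random.default_rng(cv.seed)
    best = None
    for _ in range(cv.search_iterations):
        params = {name: values[rng.integers(len(values))]
                  for name, values in sorted(grid.items())}
        spec = ModelSpec(family, params)
        r2s, rmses = _cv_scores(spec, x, y, cv, knn_k=knn_k)
        key = (-r2s.mean(), rmses.mean(), sorted(params.items()).__repr__())
        if best is None or key < best[0]:
            best = (key, spec)
    return best[1]


@dataclass
class ExpectedSurface:
    """Out-of-fold predicted-rate surface plus model metadata.

    ``frame`` has columns unit_id, observed_rate, predicted_rate, fold.
    """

    frame: pd.DataFrame
    model: ModelSpec
    r2_full: float
    rmse_full: float
    r2_test: float | None = None
    rmse_test: float | None = None
    r2_ci: tuple[float, float] | None = None

    @property
    def predicted_rate(self) -> np.ndarray:
        return self.frame["predicted_rate"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def oof_predict(
    full: pd.DataFrame,
    model: ModelSpec,
    k: int = 10,
    seed: int = 0,
    *,
    outcome: str = "adjusted_rate",
    knn_k: int = 5,
    preprocess_scope: str = "fold",
) -> ExpectedSurface:
    """Whole-set k-fold out-of-fold predictions.

    Every unit's prediction is produced by a pipeline fit on the k-1 folds
    that exclude it, so the surface is an honest expectation. Negative
    predictions (possible for linear families) are clipped to 0 because
    they feed expected case counts. With a constant outcome R-squared is
    undefined and reported as 0 with a warning.
    """
    if k > len(full):
        raise ConfigurationError(f"k={k} exceeds the {len(full)} units")
    if preprocess_scope not in ("fold", "global"):
        raise ConfigurationError("preprocess_scope must be 'fold' or 'global'")
    x, y = _xy(full, outcome)
    if preprocess_scope == "global":
        x = minmax_scale(x)
        x = impute_knn(x, knn_k)
    pred = np.empty(len(full))
    fold_of = np.empty(len(full), dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(kf.split(x)):
        pipe = _make_pipeline(model, seed, knn_k)
        pipe.fit(x[tr], y[tr])
        pred[te] = pipe.predict(x[te])
        fold_of[te] = fold
    n_neg = int((pred < 0).sum())
    if n_neg:
        logger.warning("clipping %d negative predicted rates to 0", n_neg)
    pred = np.maximum(pred, 0.0)
    if np.var(y) == 0:
        logger.warning("constant outcome: R-squared undefined, reporting 0")
        r2 = 0.0
    else:
        r2 = r2_score(y, pred)
    rmse = float(np.sqrt(mean_squared_error(y, pred)))
    frame = pd.DataFrame(
        {
            "unit_id": full["unit_id"].to_numpy()
            if "unit_id" in full.columns
            else np.arange(len(full)),
            "observed_rate": y,
            "predicted_rate": pred,
            "fold": fold_of,
        }
    )
    return ExpectedSurface(frame=frame, model=model, r2_full=r2, rmse_full=rmse)


def feature_importance(
    units: pd.DataFrame,
    model: ModelSpec,
    *,
    outcome: str = "adjusted_rate",
    seed: int = 0,
    n_repeats: int = 5,
    knn_k: int = 5,
) -> pd.DataFrame:
    """Permutation variable importance of the final model, ranked descending.

    A lightweight stand-alone attribution hook: the pipeline is fit on the
    full data and each covariate is permuted ``n_repeats`` times.
    """
    from sklearn.inspection import permutation_importance

    x, y = _xy(units, outcome)
    pipe = _make_pipeline(model, seed, knn_k)
    pipe.fit(x, y)
    res = permutation_importance(pipe, x, y, n_repeats=n_repeats, random_state=seed)
    return (
        pd.DataFrame(
            {
                "feature": covariate_columns(units),
                "importance": res.importances_mean,
                "importance_sd": res.importances_std,
            }
        )
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
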