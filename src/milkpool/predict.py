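"""Macronutrient prediction: model suite, selection, and bottle-level scoring.

The bank only ever measures ~2-L single-donor pools, so models are trained on
pool-level rows (pool-averaged days postpartum and volume per expression,
joined with donor covariates) and then applied to individual bottles, whose
own days postpartum and volume stand in for the pool averages.  That
pool-to-bottle transfer is an approximation and the reason a per-nutrient MAE
bound is carried into the robustness analysis downstream.

The suite covers ordinary linear regression, L1 least-angle regression
(LassoLars), random forest, gradient-boosted trees, boosted stumps
(AdaBoost), an RBF-kernel support-vector regressor (standardised inputs),
and an unweighted averaging ensemble of all of the above.  Each learner is
tuned by k-fold cross-validated grid search (small, documented grids) on a
random 80% training split; reported metrics come from the held-out 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
    VotingRegressor,
)
from sklearn.linear_model import LassoLars, LinearRegression
from sklearn.model_selection import GridSearchCV, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .exceptions import UnsupportedModelError, ValidationError
from .records import BottleRecord, DonorRecord
from .synthetic import TRAINING_FEATURES

__all__ = [
    "mae",
    "rmse",
    "mape",
    "CVConfig",
    "MetricReport",
    "train_suite",
    "select_best",
    "feature_importance",
    "predict_bottles",
    "build_feature_frame",
    "MODEL_NAMES",
]

MODEL_NAMES = [
    "linear",
    "lasso_lars",
    "random_forest",
    "gradient_boosting",
    "adaboost",
    "svr",
    "ensemble",
]

_NUTRIENT_COLUMN = {"protein": "crude_protein", "energy": "energy"}

#: physical floors applied to bottle-level predictions, per 100 mL
PREDICTION_FLOORS = {"protein": 0.3, "energy": 40.0}


def _check_pair(actual, predicted):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValidationError(f"need equal-length vectors, got {a.shape} / {p.shape}")
    if len(a) == 0:
        raise ValidationError("need at least one observation")
    return a, p


def mae(actual, predicted) -> float:
    """Mean absolute error, in the nutrient's own units."""
    a, p = _check_pair(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def rmse(actual, predicted) -> float:
    """Root mean squared error, in the nutrient's own units."""
    a, p = _check_pair(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error (percent of the actual value)."""
    a, p = _check_pair(actual, predicted)
    if np.any(a == 0):
        raise ValidationError("mape undefined when an actual value is 0")
    return float(100.0 * np.mean(np.abs(a - p) / np.abs(a)))


@dataclass
class CVConfig:
    """Cross-validation and tuning settings.

    ``k`` folds; small per-learner grids (kept <= 24 combinations each so a
    full suite run stays desk-scale); ``learner_seed`` fixes every stochastic
    learner.  ``grids`` may override any learner's grid.
    """

    k: int = 5
    learner_seed: int = 0
    grids: dict = field(default_factory=dict)


def _default_suite(cfg: CVConfig):
    seed = cfg.learner_seed
    suite = {
        "linear": (LinearRegression(), {}),
        "lasso_lars": (LassoLars(), {"alpha": [1e-4, 1e-3, 1e-2, 1e-1]}),
        "random_forest": (
            RandomForestRegressor(n_estimators=100, random_state=seed),
            {"max_depth": [None, 10], "min_samples_leaf": [1, 2]},
        ),
        "gradient_boosting": (
            GradientBoostingRegressor(n_estimators=100, random_state=seed),
            {"learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
        ),
        "adaboost": (
            AdaBoostRegressor(
                estimator=DecisionTreeRegressor(max_depth=1), random_state=seed
            ),
            {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]},
        ),
        "svr": (
            Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))]),
            {"svr__C": [1.0, 10.0], "svr__epsilon": [0.05, 0.1]},
        ),
    }
    for name, grid in cfg.grids.items():
        if name in suite:
            suite[name] = (suite[name][0], grid)
    return suite


@dataclass
class MetricReport:
    """Held-out test metrics per model for one nutrient.

    ``table`` has one row per model: mae, rmse, mape, cv_score_sd (the SD of
    the k cross-validated fold scores at the selected hyperparameters).  The
    split and learner seeds are recorded for reproducibility.
    """

    nutrient: str
    table: pd.DataFrame
    split_seed: int
    learner_seed: int
    best_params: dict = field(default_factory=dict)

    def metrics(self, model_name: str) -> pd.Series:
        return self.table.loc[model_name]


def train_suite(
    training_pools: pd.DataFrame,
    nutrient: str,
    split_seed: int = 0,
    cv_config: CVConfig | None = None,
) -> tuple[dict, MetricReport]:
    """Fit and tune the whole model suite for one nutrient.

    80/20 random split by pool (``split_seed``), k-fold grid search on the
    training split, metrics on the held-out split.  Returns the fitted
    models keyed by name and the metric report.  Deterministic given the two
    seeds.
    """
    if nutrient not in _NUTRIENT_COLUMN:
        raise ValidationError(f"nutrient must be one of {sorted(_NUTRIENT_COLUMN)}, got {nutrient!r}")
    cfg = cv_config or CVConfig()
    target_col = _NUTRIENT_COLUMN[nutrient]
    missing = [c for c in TRAINING_FEATURES + [target_col] if c not in training_pools.columns]
    if missing:
        raise ValidationError(f"training pools missing column(s): {', '.join(missing)}")
    if len(training_pools) < 50:
        raise ValidationError(
            f"need at least 50 training pools, got {len(training_pools)}"
        )
    X = training_pools[TRAINING_FEATURES].astype(float)
    y = training_pools[target_col].astype(float)
    if np.ptp(y.to_numpy()) == 0:
        raise ValidationError(f"target {target_col!r} is constant; nothing to learn")

    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=0.2, random_state=split_seed
    )

    fitted: dict = {}
    rows = {}
    best_params: dict = {}
    for name, (estimator, grid) in _default_suite(cfg).items():
        search = GridSearchCV(
            estimator,
            grid if grid else {},
            cv=cfg.k,
            scoring="neg_mean_absolute_error",
            n_jobs=1,
            refit=True,
        )
        search.fit(X_train, y_train)
        model = search.best_estimator_
        cv_sd = float(search.cv_results_["std_test_score"][search.best_index_])
        fitted[name] = model
        best_params[name] = dict(search.best_params_)
        pred = model.predict(X_test)
        rows[name] = {
            "mae": mae(y_test, pred),
            "rmse": rmse(y_test, pred),
            "mape": mape(y_test, pred),
            "cv_score_sd": cv_sd,
        }

    # unweighted averaging ensemble of the tuned base learners
    ensemble = VotingRegressor(
        [(name, clone(model)) for name, model in fitted.items()]
    )
    cv_scores = cross_val_score(
        ensemble, X_train, y_train, cv=cfg.k, scoring="neg_mean_absolute_error", n_jobs=1
    )
    ensemble.fit(X_train, y_train)
    pred = ensemble.predict(X_test)
    fitted["ensemble"] = ensemble
    best_params["ensemble"] = {}
    rows["ensemble"] = {
        "mae": mae(y_test, pred),
        "rmse": rmse(y_test, pred),
        "mape": mape(y_test, pred),
        "cv_score_sd": float(np.std(cv_scores)),
    }

    table = pd.DataFrame.from_dict(rows, orient="index").loc[MODEL_NAMES]
    table.index.name = "model"
    report = MetricReport(
        nutrient=nutrient,
        table=table,
        split_seed=split_seed,
        learner_seed=cfg.learner_seed,
        best_params=best_params,
    )
    return fitted, report


def select_best(report: MetricReport) -> str:
    """Best model by held-out MAE; ties broken by RMSE, then model name."""
    if report.table.empty:
        raise ValidationError("metric report is empty")
    ordered = report.table.sort_values(
        by=["mae", "rmse"], kind="mergesort"
    )  # stable sort; index already lexicographic-stable within ties
    ties = ordered[(ordered.mae == ordered.mae.iloc[0]) & (ordered.rmse == ordered.rmse.iloc[0])]
    return sorted(ties.index)[0]


def feature_importance(model) -> pd.Series:
    """Impurity-based feature importances of a fitted tree ensemble.

    Scores are nonnegative and sum to 1.
    """
    if not hasattr(model, "feature_importances_"):
        raise UnsupportedModelError(
            f"{type(model).__name__} has no impurity-based feature importances"
        )
    return pd.Series(model.feature_importances_, index=TRAINING_FEATURES, name="importance")


def build_feature_frame(
    bottles: list[BottleRecord], donors: list[DonorRecord]
) -> pd.DataFrame:
    """Bottle-level feature rows in the fixed training order.

    The bottle's own days postpartum and volume stand in for the pool
    averages the models were trained on.
    """
    donor_map = {d.donor_id: d for d in donors}
    rows = []
    for b in bottles:
        donor = donor_map.get(b.donor_id)
        if donor is None:
            raise ValidationError(f"bottle {b.bottle_id}: unknown donor {b.donor_id!r}")
        if b.days_postpartum is None:
            raise ValidationError(f"bottle {b.bottle_id}: missing feature days_postpartum")
        rows.append(
            {
                "bottle_id": b.bottle_id,
                "days_postpartum": float(b.days_postpartum),
                "avg_volume": float(b.volume_ml),
                "bmi": donor.bmi,
                "preterm": donor.preterm,
                "age": donor.age,
                "vegetarian": donor.vegetarian,
            }
        )
    return pd.DataFrame(rows)


def predict_bottles(
    models: dict, bottles: list[BottleRecord], donors: list[DonorRecord]
) -> pd.DataFrame:
    """Predict crude protein and energy for individual bottles.

    ``models`` maps ``"protein"`` and ``"energy"`` to fitted regressors.
    Predictions are clipped to physical floors (0.3 g protein, 40 kcal per
    100 mL); deterministic for fitted models.
    """
    for nutrient in ("protein", "energy"):
        if nutrient not in models:
            raise ValidationError(f"missing fitted model for {nutrient!r}")
    features = build_feature_frame(bottles, donors)
    X = features[TRAINING_FEATURES]
    out = pd.DataFrame({"bottle_id": features["bottle_id"]})
    for nutrient, col in (("protein", "pred_protein"), ("energy", "pred_energy")):
        pred = np.asarray(models[nutrient].predict(X), dtype=float)
        out[col] = np.maximum(pred, PREDICTION_FLOORS[nutrient])
    return out
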