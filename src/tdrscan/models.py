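"""The seven black-box learners behind a uniform fit/predict contract.

Every algorithm is fitted as a numeric regression — binary targets are
encoded 0/1 and regressed, which keeps a continuous score for ROC analysis.
The fitted model remembers its target orientation (inherited from the
response transform) so :func:`orient_scores` can flip continuous ln(IC50)
scale predictions into "higher = more likely responder" scores.

Algorithms
----------
linear      ordinary least squares (minimum-norm when features >= samples)
lasso       L1 path with lambda chosen by 10-fold cross-validation
elasticnet  mixing parameter alpha = 0.5, lambda by 10-fold CV
ridge       L2 penalty chosen by efficient leave-one-out CV
rf          regression forest, 500 trees
rf_ranger   regression forest, 10,000 trees of unlimited depth
svm         support vector regression with a radial kernel

Tree counts and the CV grid are configurable through :class:`ModelParams`
so that large scans can trade forest size for runtime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, LassoCV, LinearRegression, RidgeCV
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .core_data import BLACK_BOXES, DataError
from .response_transform import TransformedResponse

__all__ = ["ModelParams", "FittedModel", "fit", "predict", "orient_scores"]


@dataclass(frozen=True)
class ModelParams:
    """Tunable fitting knobs shared by all pipelines of a scan."""

    n_trees_rf: int = 500
    n_trees_ranger: int = 10_000
    cv_folds: int = 10
    n_alphas: int = 30
    ridge_alphas: tuple = tuple(np.logspace(-3, 3, 25))


DEFAULT_MODEL_PARAMS = ModelParams()


@dataclass
class FittedModel:
    algorithm: str
    estimator: object  # fitted sklearn estimator or a constant fallback
    target_orientation: str
    training_feature_ids: list[str]
    constant_value: Optional[float] = None


class _ConstantModel:
    """Intercept-only fallback used when the target is constant."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, x):
        return np.full(len(x), self.value)


def _make_estimator(algorithm: str, seed: int, params: ModelParams, n_samples: int):
    cv = KFold(n_splits=params.cv_folds, shuffle=True, random_state=seed)
    if algorithm == "linear":
        return LinearRegression()
    if algorithm == "lasso":
        return LassoCV(cv=cv, alphas=params.n_alphas, random_state=seed, max_iter=5000)
    if algorithm == "elasticnet":
        return ElasticNetCV(
            l1_ratio=0.5, cv=cv, alphas=params.n_alphas, random_state=seed,
            max_iter=5000,
        )
    if algorithm == "ridge":
        return RidgeCV(alphas=params.ridge_alphas)
    if algorithm == "rf":
        return RandomForestRegressor(
            n_estimators=params.n_trees_rf,
            max_features=1.0 / 3.0,
            min_samples_leaf=5,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "rf_ranger":
        return RandomForestRegressor(
            n_estimators=params.n_trees_ranger,
            max_features="sqrt",
            max_depth=None,
            min_samples_leaf=5,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "svm":
        return SVR(kernel="rbf", gamma="scale")
    raise DataError(f"unknown black box {algorithm!r}")


def fit(
    features: pd.DataFrame,
    target: TransformedResponse,
    algorithm: str,
    seed: int = 0,
    params: ModelParams = DEFAULT_MODEL_PARAMS,
) -> FittedModel:
    """Fit one black box on a samples x features matrix.

    The target series must cover every feature row; binary targets are
    regressed on their 0/1 encoding.  Cross-validated learners need at
    least ``cv_folds`` samples.  A constant target short-circuits to an
    intercept-only model with a warning.
    """
    if algorithm not in BLACK_BOXES:
        raise DataError(f"unknown black box {algorithm!r}")
    if features.shape[0] < 2:
        raise DataError("need at least two training samples")
    y = target.values.loc[features.index].to_numpy(dtype=float)
    x = features.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        warnings.warn(f"constant training target; {algorithm} fit as intercept-only")
        est: object = _ConstantModel(y[0])
        return FittedModel(
            algorithm, est, target.orientation, list(features.columns), float(y[0])
        )
    needs_cv = algorithm in ("lasso", "elasticnet")
    if needs_cv and features.shape[0] < params.cv_folds:
        raise DataError(
            f"{algorithm} needs >= {params.cv_folds} samples for cross-validation"
        )
    est = _make_estimator(algorithm, seed, params, features.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(x, y)
    return FittedModel(algorithm, est, target.orientation, list(features.columns))


def predict(model: FittedModel, features: pd.DataFrame) -> pd.Series:
    """Score samples with a fitted model; feature ids must match training."""
    got = list(features.columns)
    want = model.training_feature_ids
    if got != want:
        missing = [f for f in want if f not in got]
        extra = [f for f in got if f not in want]
        if missing or extra:
            raise DataError(
                f"feature mismatch: missing={missing[:5]}, extra={extra[:5]}"
            )
        raise DataError("feature columns are ordered differently than at training")
    scores = model.estimator.predict(features.to_numpy(dtype=float))
    return pd.Series(np.asarray(scores, dtype=float), index=features.index)


def orient_scores(predictions: pd.Series, orientation: str) -> pd.Series:
    """Turn raw predictions into 'higher = more likely responder' scores.

    Continuous targets live on the ln(IC50) scale where lower means more
    sensitive, so their predictions are negated; binary-target scores
    already point the right way.
    """
    if orientation == "lower_is_sensitive":
        return -predictions
    if orientation == "higher_is_sensitive":
        return predictions
    raise DataError(f"unknown orientation {orientation!r}")
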