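"""Fruit diameter estimators from projected areas.

Two routes are implemented:

* the single-variable ratio curve ``d = a * sqrt(ratio) + b`` — the
  inverse of the quadratic area-diameter relation (the silhouette area
  grows with d^2, so diameter is linear in the square root of the
  fruit/marker area ratio);
* a suite of standard regressors (linear, ridge, lasso, elasticNet,
  random forest, gradient-boosted trees, support-vector regression) over
  any subset of the three candidate features (fruit area, marker area,
  ratio), with normalization statistics learned from the training split
  only.

Evaluation reports MAE, RMSE, the squared Pearson correlation between
estimates and truths, and the count of outliers (absolute error >= 5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.svm import SVR

from .config import MODEL_FAMILIES

FEATURES: tuple[str, ...] = ("area_fruit_px", "area_marker_px", "ratio")

#: the four feature subsets compared in the analysis
SUBSETS: dict[str, tuple[str, ...]] = {
    "all": ("area_fruit_px", "area_marker_px", "ratio"),
    "areas": ("area_fruit_px", "area_marker_px"),
    "fruit_ratio": ("area_fruit_px", "ratio"),
    "marker_ratio": ("area_marker_px", "ratio"),
}

OUTLIER_MM = 5.0


class DegenerateDesignError(ValueError):
    """Raised when the training design has no usable variation."""


@dataclass(frozen=True)
class NormStats:
    """Per-feature location/scale learned from the training split."""

    mean: dict[str, float]
    scale: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.scale.items():
            if not s > 0:
                raise ValueError(f"scale for feature {name!r} must be positive")

    def transform(self, frame: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
        cols = [(frame[f].to_numpy(float) - self.mean[f]) / self.scale[f] for f in features]
        return np.column_stack(cols)


@dataclass
class SizeModel:
    """A fitted diameter estimator with its feature subset and scaling."""

    family: str
    feature_subset: tuple[str, ...]
    norm: NormStats | None
    params: Any = None  # (a, b) for the ratio curve
    estimator: Any = None  # fitted sklearn regressor otherwise

    def __post_init__(self) -> None:
        if not self.feature_subset:
            raise ValueError("feature_subset must be non-empty")
        if self.family == "ratio_curve" and tuple(self.feature_subset) != ("ratio",):
            raise ValueError("the ratio curve uses only the ratio feature")


@dataclass(frozen=True)
class EvalReport:
    """Accuracy summary of a diameter estimator on one split."""

    r2: float
    mae_mm: float
    rmse_mm: float
    n: int
    n_outliers: int


# ---------------------------------------------------------------------------
# ratio curve
# ---------------------------------------------------------------------------

def fit_ratio_curve(train: pd.DataFrame) -> SizeModel:
    """Least-squares fit of ``d = a*sqrt(ratio) + b`` on training data.

    ``train`` needs columns ``ratio`` (positive) and ``truth_diameter_mm``.
    In the far-field spherical limit the exact relation is
    ``d = (2s/sqrt(pi)) * sqrt(ratio)`` for marker side ``s``, which the
    fit recovers on noiseless data.
    """
    if len(train) < 3:
        raise ValueError("need at least 3 training rows")
    ratio = train["ratio"].to_numpy(float)
    truth = train["truth_diameter_mm"].to_numpy(float)
    if np.any(ratio <= 0):
        raise ValueError("ratios must be positive")
    x = np.sqrt(ratio)
    if np.ptp(x) < 1e-12:
        raise DegenerateDesignError("all training ratios are identical")
    design = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(design, truth, rcond=None)
    return SizeModel(family="ratio_curve", feature_subset=("ratio",),
                     norm=None, params=(float(a), float(b)))


# ---------------------------------------------------------------------------
# regression suite
# ---------------------------------------------------------------------------

def _make_estimator(family: str, seed: int):
    # hyperparameters are fixed, seeded defaults (no search): unit
    # regularization for the penalized linear models, 300 trees for the
    # ensembles, RBF kernel with C=100 for SVR.
    if family == "linear":
        return LinearRegression()
    if family == "ridge":
        return Ridge(alpha=1.0)
    if family == "lasso":
        return Lasso(alpha=1.0)
    if family == "elasticnet":
        return ElasticNet(alpha=1.0)
    if family == "random_forest":
        return RandomForestRegressor(n_estimators=300, random_state=seed, n_jobs=1)
    if family == "gbdt":
        return GradientBoostingRegressor(n_estimators=300, random_state=seed)
    if family == "svr":
        return SVR(kernel="rbf", C=100.0, epsilon=0.1, gamma="scale")
    raise ValueError(f"unknown model family {family!r}")


def fit_regressor(family: str, feature_subset: str | Sequence[str],
                  train: pd.DataFrame, seed: int = 0) -> SizeModel:
    """Fit one regression family on normalized training features.

    ``feature_subset`` is either a named subset key from :data:`SUBSETS`
    or an explicit sequence of feature names.  Normalization statistics
    (mean/std) are computed from the training split only and stored with
    the model, so the test cohort never leaks into fitting.
    """
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    if isinstance(feature_subset, str):
        if feature_subset not in SUBSETS:
            raise ValueError(f"unknown feature subset {feature_subset!r}")
        features = SUBSETS[feature_subset]
    else:
        features = tuple(feature_subset)
        unknown = set(features) - set(FEATURES)
        if unknown or not features:
            raise ValueError(f"invalid feature subset {features}")
    if len(train) < 10:
        raise ValueError("need at least 10 training rows")

    mean, scale = {}, {}
    for f in features:
        col = train[f].to_numpy(float)
        mean[f] = float(col.mean())
        sd = float(col.std())
        scale[f] = sd if sd > 0 else 1.0  # constant feature carries no signal
    norm = NormStats(mean=mean, scale=scale)

    x = norm.transform(train, features)
    y = train["truth_diameter_mm"].to_numpy(float)
    est = _make_estimator(family, seed)
    est.fit(x, y)
    return SizeModel(family=family, feature_subset=features, norm=norm, estimator=est)


def predict(model: SizeModel, features: pd.DataFrame) -> np.ndarray:
    """Predict diameters (mm) for a feature table using a fitted model."""
    missing = [f for f in model.feature_subset if f not in features.columns]
    if missing:
        raise KeyError(f"missing features {missing} for {model.family} model")
    if model.family == "ratio_curve":
        a, b = model.params
        ratio = features["ratio"].to_numpy(float)
        if np.any(ratio < 0):
            raise ValueError("ratios must be non-negative")
        return a * np.sqrt(ratio) + b
    x = model.norm.transform(features, model.feature_subset)
    return np.asarray(model.estimator.predict(x), dtype=float)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(estimates: Sequence[float], truths: Sequence[float]) -> EvalReport:
    """MAE, RMSE, squared-Pearson R2 and outlier count for one split.

    R2 is the squared Pearson correlation between estimates and truths
    (the convention of the linear-regression utility used for scoring),
    not the identity-line coefficient of determination.  Outliers are
    predictions off by 5 mm or more.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal length")
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    err = est - tru
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.ptp(est) < 1e-300 or np.ptp(tru) < 1e-300:
        r2 = 0.0  # correlation undefined for a constant vector
    else:
        r2 = float(stats.pearsonr(est, tru)[0] ** 2)
    return EvalReport(r2=r2, mae_mm=mae, rmse_mm=rmse, n=int(n),
                      n_outliers=int(np.sum(np.abs(err) >= OUTLIER_MM)))


def feature_subset_sweep(train_by_tier: dict[str, pd.DataFrame],
                         test_by_tier: dict[str, pd.DataFrame],
                         families: Sequence[str] = MODEL_FAMILIES,
                         seed: int = 0) -> pd.DataFrame:
    """Evaluate every family over the four feature subsets and both tiers.

    Returns a long-format table (family, subset, tier, r2, mae_mm,
    rmse_mm, n, n_outliers) analogous to the model/feature comparison
    tables of the study.
    """
    rows = []
    for tier, train in train_by_tier.items():
        test = test_by_tier[tier]
        for family in families:
            for subset_name in SUBSETS:
                model = fit_regressor(family, subset_name, train, seed=seed)
                report = evaluate(predict(model, test),
                                  test["truth_diameter_mm"].to_numpy(float))
                rows.append((family, subset_name, tier, report.r2, report.mae_mm,
                             report.rmse_mm, report.n, report.n_outliers))
    return pd.DataFrame(rows, columns=["family", "subset", "tier", "r2",
                                       "mae_mm", "rmse_mm", "n", "n_outliers"])
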