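"""Supervised mapping of axis position from cytoarchitectural features.

A 20-column feature table (16 depth-wise intensities plus the four central
moments), z-standardized, feeds a random-forest regression of the
iso-to-allocortical axis with repeated 70/30 splits, impurity-based
feature importance, above-average importance selection and cubic
post-hoc feature curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, train_test_split

from .depths import ProfileMatrix, central_moments, depth_percent_names

__all__ = [
    "FeatureTable",
    "build_feature_table",
    "train_axis_regressor",
    "RegressionResult",
    "select_and_refit",
    "feature_axis_curves",
    "DEFAULT_GRID",
]

#: hyperparameter grid for the 5-fold cross-validated search
DEFAULT_GRID = {
    "n_estimators": [100],
    "max_depth": [None, 8],
    "min_samples_leaf": [1, 5],
}

MOMENT_NAMES = ["mean", "sd", "skewness", "kurtosis"]


@dataclass
class FeatureTable:
    """z-standardized features plus the prediction target."""

    features: pd.DataFrame
    target: np.ndarray
    means: pd.Series
    sds: pd.Series

    @property
    def names(self) -> list[str]:
        return list(self.features.columns)

    def inverse_transform(self) -> pd.DataFrame:
        return self.features * self.sds + self.means


def build_feature_table(profiles: ProfileMatrix) -> FeatureTable:
    """Assemble and z-standardize the 20-feature table.

    Column order is fixed: the depth intensities (named by nominal depth
    percentage, inner to outer) followed by mean, sd, skewness, kurtosis.
    Standardization parameters are stored for the inverse transform.
    """
    moments = central_moments(profiles)
    depth_names = depth_percent_names(profiles.n_depths)
    raw = pd.DataFrame(profiles.intensities, columns=depth_names)
    for name in MOMENT_NAMES:
        raw[name] = moments[name].to_numpy()
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValueError(f"undefined feature values in columns {bad}")
    sds = raw.std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    means = raw.mean()
    z = (raw - means) / sds
    return FeatureTable(features=z, target=np.asarray(profiles.axis_mm, float),
                        means=means, sds=sds)


@dataclass
class RegressionResult:
    r2_per_repeat: np.ndarray
    importances: pd.DataFrame         # repeats x features
    hyperparameters: dict
    feature_names: list[str] = field(default_factory=list)

    @property
    def r2_mean(self) -> float:
        return float(self.r2_per_repeat.mean())

    @property
    def r2_sd(self) -> float:
        return float(self.r2_per_repeat.std())

    def mean_importance(self) -> pd.Series:
        return self.importances.mean(axis=0)


def _search_hyperparameters(x, y, grid, seed) -> dict:
    rf = RandomForestRegressor(random_state=seed, n_jobs=1)
    search = GridSearchCV(rf, grid, cv=5, scoring="r2", n_jobs=1)
    search.fit(x, y)
    return dict(search.best_params_)


def train_axis_regressor(
    table: FeatureTable,
    train_fraction: float = 0.7,
    n_repeats: int = 100,
    seed: int = 0,
    grid: dict | None = None,
    hyperparameters: dict | None = None,
    feature_subset: list[str] | None = None,
) -> RegressionResult:
    """Repeated-split random-forest regression of the axis.

    Hyperparameters are grid-searched with 5-fold cross validation on the
    training part of the first split (unless supplied); each repeat draws a
    fresh 70/30 split, fits on the training part and records the held-out
    R² and the impurity-based (mean decrease in variance) importances.
    """
    x = table.features if feature_subset is None else table.features[feature_subset]
    names = list(x.columns)
    x = x.to_numpy(float)
    y = np.asarray(table.target, dtype=float)
    if y.size < 50:
        raise ValueError("need at least 50 vertices")
    if np.ptp(y) == 0:
        raise ValueError("constant target; axis regression is degenerate")
    rng = np.random.default_rng(seed)
    if hyperparameters is None:
        x_tr, _, y_tr, _ = train_test_split(
            x, y, train_size=train_fraction,
            random_state=int(rng.integers(2**31 - 1)))
        hyperparameters = _search_hyperparameters(
            x_tr, y_tr, grid or DEFAULT_GRID, seed)
    r2s = np.empty(n_repeats)
    imps = np.empty((n_repeats, x.shape[1]))
    for rep in range(n_repeats):
        state = int(rng.integers(2**31 - 1))
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, train_size=train_fraction, random_state=state)
        rf = RandomForestRegressor(random_state=state, n_jobs=1,
                                   **hyperparameters)
        rf.fit(x_tr, y_tr)
        r2s[rep] = rf.score(x_te, y_te)
        imps[rep] = rf.feature_importances_
    return RegressionResult(
        r2_per_repeat=r2s,
        importances=pd.DataFrame(imps, columns=names),
        hyperparameters=hyperparameters,
        feature_names=names,
    )


def select_and_refit(
    result: RegressionResult,
    table: FeatureTable,
    n_repeats: int = 100,
    seed: int = 0,
) -> tuple[list[str], RegressionResult]:
    """Keep features with above-average importance and refit.

    The threshold is the uniform average 1/n_features; the refit reuses the
    hyperparameters of the full model.
    """
    mean_imp = result.mean_importance()
    threshold = 1.0 / len(mean_imp)
    selected = mean_imp[mean_imp > threshold].index.tolist()
    if not selected:
        warnings.warn("all importances at the uniform average; keeping all features")
        selected = list(mean_imp.index)
    reduced = train_axis_regressor(
        table,
        n_repeats=n_repeats,
        seed=seed,
        hyperparameters=result.hyperparameters,
        feature_subset=selected,
    )
    return selected, reduced


def selection_stability(importances: pd.DataFrame) -> float:
    """Mean per-repeat agreement of the above-average selection with the
    consensus selection (1 = perfectly stable)."""
    threshold = 1.0 / importances.shape[1]
    per_repeat = importances.gt(threshold)
    consensus = importances.mean(axis=0).gt(threshold)
    return float(per_repeat.eq(consensus, axis=1).mean(axis=1).mean())


def feature_axis_curves(table: FeatureTable, selected: list[str],
                        degree: int = 3) -> pd.DataFrame:
    """Least-squares cubic fit of each selected feature against the axis.

    Returns coefficients (ascending powers) plus the fraction of the axis
    range over which the fitted derivative is positive.
    """
    if not selected:
        raise ValueError("no features selected")
    x = np.asarray(table.target, dtype=float)
    grid = np.linspace(x.min(), x.max(), 512)
    rows = []
    for name in selected:
        y = table.features[name].to_numpy(float)
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
        deriv = np.polynomial.polynomial.polyval(
            grid, np.polynomial.polynomial.polyder(coeffs))
        rows.append({
            "feature": name,
            **{f"c{k}": coeffs[k] for k in range(degree + 1)},
            "fraction_increasing": float(np.mean(deriv > 0)),
        })
    return pd.DataFrame(rows).set_index("feature")
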