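"""Age-of-acquisition estimation, boosted-tree regression, and Shapley attribution.

AoA is the age in months at which half the children in a longitudinal
corpus understand a word, estimated here as the midpoint of a
two-parameter logistic fitted to the proportion-knowing curve.  The
regression stage fits a gradient-boosted tree ensemble of AoA on
per-word features (frequency, word type, category-structure metrics,
cross-modal alignment) and decomposes each prediction into additive
per-feature Shapley values; global feature importance is the mean
absolute attribution across words.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import optimize, stats

FEATURE_COLUMNS = (
    "log_frequency",
    "word_type",
    "visual_variability",
    "linguistic_variability",
    "alignment",
    "visual_discriminability",
    "linguistic_discriminability",
)

#: Boosted-tree settings used throughout: 10,000 rounds, depth 10, learning
#: rate 0.02, squared-error objective, fitted in-sample (the model is
#: explanatory, not predictive).
DEFAULT_HYPERPARAMS = {
    "n_estimators": 10_000,
    "max_depth": 10,
    "learning_rate": 0.02,
}


@dataclasses.dataclass(frozen=True)
class AoAEstimate:
    """Logistic-midpoint AoA with an out-of-range flag."""

    aoa_months: float
    slope: float
    in_range: bool


@dataclasses.dataclass(frozen=True)
class AttributionReport:
    """Per-word, per-feature Shapley values for a fitted AoA model.

    ``base_value + attributions.sum(axis=1)`` reproduces the model
    prediction for every word (local accuracy).
    """

    words: tuple[str, ...]
    features: tuple[str, ...]
    attributions: np.ndarray  # (n_words, n_features), months
    base_value: float
    predictions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.attributions, columns=list(self.features))
        frame.insert(0, "word", list(self.words))
        return frame


def estimate_aoa(curve: pd.DataFrame | np.ndarray) -> AoAEstimate:
    """Fit a two-parameter logistic to (age_months, proportion_knowing) data.

    Returns the logistic midpoint — the age at which the fitted curve
    crosses 50% — or flags the estimate out-of-range when the observed
    proportions never bracket 0.5 (no silent extrapolation).
    """
    arr = np.asarray(curve, dtype=float)
    if isinstance(curve, pd.DataFrame):
        arr = curve[["age_months", "proportion_knowing"]].to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("curve must have >= 3 rows of (age_months, proportion)")
    ages, props = arr[:, 0], arr[:, 1]
    if np.any((props < 0) | (props > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("proportions must be finite and in [0, 1]")

    def logistic(x, midpoint, slope):
        return 1.0 / (1.0 + np.exp(-slope * (x - midpoint)))

    mid0 = float(np.interp(0.5, np.sort(props), ages[np.argsort(props)]))
    try:
        popt, _ = optimize.curve_fit(
            logistic, ages, props, p0=[mid0, 0.3], maxfev=10_000
        )
    except RuntimeError:
        popt = [mid0, 0.3]
    midpoint, slope = float(popt[0]), float(popt[1])
    in_range = bool(props.min() <= 0.5 <= props.max())
    return AoAEstimate(aoa_months=midpoint, slope=slope, in_range=in_range)


def fit_aoa_model(
    table: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
    features: tuple[str, ...] = FEATURE_COLUMNS,
) -> xgb.XGBRegressor:
    """Fit the boosted-tree AoA regression on the full table (in-sample)."""
    if len(table) < 20:
        raise ValueError("need at least 20 rows to fit the AoA model")
    missing = [c for c in (*features, "aoa_months") if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns: {missing}")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    model = xgb.XGBRegressor(
        objective="reg:squarederror",
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        **params,
    )
    x = table.loc[:, list(features)].to_numpy(dtype=float)
    y = table["aoa_months"].to_numpy(dtype=float)
    model.fit(x, y)
    return model


def attribute(
    model: xgb.XGBRegressor,
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_COLUMNS,
) -> AttributionReport:
    """Exact tree-Shapley attribution of each word's predicted AoA.

    Uses the tree-path Shapley decomposition built into the boosted-tree
    library, so local accuracy (base value + attributions = prediction)
    holds to numerical tolerance.
    """
    missing = [c for c in features if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature columns: {missing}")
    x = table.loc[:, list(features)].to_numpy(dtype=float)
    booster = model.get_booster()
    contribs = booster.predict(xgb.DMatrix(x), pred_contribs=True)
    attributions = contribs[:, :-1]
    base = float(contribs[0, -1])
    preds = model.predict(x)
    words = tuple(table["word"].astype(str)) if "word" in table.columns else tuple(
        str(i) for i in range(len(table))
    )
    return AttributionReport(
        words=words,
        features=tuple(features),
        attributions=attributions,
        base_value=base,
        predictions=np.asarray(preds, dtype=float),
    )


def global_importance(
    report: AttributionReport, table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean absolute attribution per feature, with the direction of effect.

    When the feature table is supplied, each feature's direction is the
    sign of the Spearman correlation between feature value and
    attribution (positive = the feature raises predicted AoA when
    large).
    """
    importance = np.abs(report.attributions).mean(axis=0)
    directions = []
    for j, feature in enumerate(report.features):
        if table is not None and feature in table.columns:
            col = table[feature].to_numpy(dtype=float)
            att = report.attributions[:, j]
            if np.all(att == att[0]) or np.all(col == col[0]):
                directions.append(0.0)
            else:
                directions.append(float(np.sign(stats.spearmanr(col, att).statistic)))
        else:
            directions.append(np.nan)
    frame = pd.DataFrame(
        {
            "feature": list(report.features),
            "mean_abs_attribution": importance,
            "direction": directions,
        }
    )
    return frame.sort_values("mean_abs_attribution", ascending=False).reset_index(
        drop=True
    )
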