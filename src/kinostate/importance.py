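"""Shapley-value explanation of the fitted tree models.

Per-row, per-feature attributions are computed with the exact TreeSHAP
algorithm built into the tree libraries (XGBoost's ``pred_contribs`` /
LightGBM's ``pred_contrib``), which satisfies local accuracy: for every row
the base value plus the signed attributions equals the model prediction.
Feature importance is the mean absolute attribution across a seeded
fixed-size row subsample, split by feature class (kinome state vs baseline
expression) and optionally joined against an annotation table marking
understudied ("dark") kinases and known kinase interactors.  For the linear
LASSO comparison model the importance analog is the absolute standardized
coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xgboost as xgb

from .data_io import KINOME_PREFIX
from .modeling import FittedModel

__all__ = [
    "shapley_attributions",
    "rank_importances",
    "lasso_importances",
]

DEFAULT_SHAP_ROWS = 2000


def shapley_attributions(
    fitted: FittedModel,
    X: pd.DataFrame,
    max_rows: int = DEFAULT_SHAP_ROWS,
    seed: int = 0,
) -> tuple[np.ndarray, float, pd.Index]:
    """Exact tree-Shapley attributions on a seeded row subsample.

    Returns ``(attributions, base_value, row_index)`` where ``attributions``
    has one column per model feature and ``base_value + attributions.sum(1)``
    reproduces the model predictions.  Only tree families are supported.
    """
    missing = [f for f in fitted.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"rows lack model feature(s) {missing[:5]}")
    if len(X) > max_rows:
        rng = np.random.default_rng([seed, 303])
        rows = np.sort(rng.choice(len(X), size=max_rows, replace=False))
        X = X.iloc[rows]
    A = np.ascontiguousarray(X[fitted.feature_names].to_numpy(dtype=np.float32))
    if fitted.family == "xgboost":
        contrib = fitted.model.predict(xgb.DMatrix(A), pred_contribs=True)
    elif fitted.family == "random_forest":
        contrib = fitted.model.predict(A, pred_contrib=True)
        # LightGBM's rf mode averages tree outputs in predict() but reports
        # per-tree contribution sums; rescale so local accuracy holds
        contrib = contrib / fitted.model.num_trees()
    else:
        raise ValueError("Shapley attributions require a tree model")
    base = float(contrib[:, -1].mean())
    return contrib[:, :-1], base, X.index


def rank_importances(
    attributions: np.ndarray,
    feature_names: list[str],
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean |attribution| per feature, sorted descending, annotation-joined.

    Returns an ImportanceTable frame with columns ``feature_id,
    feature_class, mean_abs_attribution`` plus ``dark_flag`` /
    ``interactor_flag`` where the annotation table covers the feature.
    """
    if attributions.shape[1] != len(feature_names):
        raise ValueError("attribution columns do not match feature names")
    table = pd.DataFrame(
        {
            "feature_id": feature_names,
            "feature_class": [
                "kinome_state" if str(f).startswith(KINOME_PREFIX) else "expression"
                for f in feature_names
            ],
            "mean_abs_attribution": np.abs(attributions).mean(axis=0),
        }
    )
    table = table.sort_values(
        ["mean_abs_attribution", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if annotations is not None:
        table = table.merge(annotations, on="feature_id", how="left")
    return table


def lasso_importances(fitted: FittedModel) -> pd.DataFrame:
    """|standardized coefficient| importance analog for the LASSO model."""
    if fitted.family != "lasso":
        raise ValueError("expected a fitted lasso model")
    coefs = np.abs(np.asarray(fitted.model.coef_, dtype=float))
    table = pd.DataFrame(
        {
            "feature_id": fitted.feature_names,
            "feature_class": [
                "kinome_state" if str(f).startswith(KINOME_PREFIX) else "expression"
                for f in fitted.feature_names
            ],
            "mean_abs_attribution": coefs,
        }
    )
    return table.sort_values(
        ["mean_abs_attribution", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)
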