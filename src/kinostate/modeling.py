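"""Cross-validated comparison of LASSO, random-forest and XGBoost regressors.

One row of the design matrix is a (drug, cell line) pair: the drug's kinome
inhibition state block (``act_``) concatenated with the cell line's baseline
expression block (``exp_``), with the dose-response summaries (AUC and
log10 IC50) as candidate outcomes.  Models are compared under random 10-fold
cross-validation: within each fold, features are ranked by bivariate
correlation on the training rows only, the top-k subset is selected, the
model is fitted and held-out rows are scored by the coefficient of
determination R² (squared Pearson is reported alongside) and RMSE.  Random
hyperparameter search draws a fixed number of configurations per family
within the documented ranges.  The winning specification is refitted on the
full table to predict untested drug x cell-line pairs.

Implementation notes: model fitting is delegated to scikit-learn (LASSO),
LightGBM in random-forest mode (bagged trees with per-tree mtry = sqrt(p)
feature subsampling), and XGBoost with histogram trees.  Because a random
forest with t trees is exactly the average of the first t trees of a longer
forest, tree-count tuning reuses a single maximal fit per fold and derives
each configuration's predictions from its leading trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .feature_selection import bivariate_rank, select_top_k
from .integration import KinomeStateMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "HYPERPARAMETER_RANGES",
    "ModelSpec",
    "CVResult",
    "FittedModel",
    "build_design_matrix",
    "make_folds",
    "sample_hyperparameters",
    "evaluate_r2",
    "evaluate_rmse",
    "cross_validate",
    "tune_and_compare",
    "fit_final_and_predict",
]

FAMILIES = ("lasso", "random_forest", "xgboost")

#: Documented random-search ranges per family.
HYPERPARAMETER_RANGES = {
    "lasso": {"penalty": (1e-10, 0.9)},
    "random_forest": {"trees": (100, 2000)},
    "xgboost": {"trees": (100, 1000), "depth": (4, 30)},
}

_XGB_BASE = dict(
    objective="reg:squarederror",
    tree_method="hist",
    max_bin=64,
    nthread=1,
)

_LGB_RF_BASE = dict(
    objective="regression",
    boosting="rf",
    bagging_freq=1,
    bagging_fraction=0.632,
    min_data_in_leaf=5,
    max_bin=64,
    num_threads=1,
    deterministic=True,
    force_row_wise=True,
    verbosity=-1,
)


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict
    n_features: int
    outcome: str = "auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        ranges = HYPERPARAMETER_RANGES[self.family]
        for name, (lo, hi) in ranges.items():
            if name not in self.hyperparameters:
                raise ValueError(f"{self.family} spec missing hyperparameter {name!r}")
            v = self.hyperparameters[name]
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class CVResult:
    spec: ModelSpec
    per_fold_r2: tuple[float, ...]
    per_fold_rmse: tuple[float, ...]
    #: squared Pearson between predicted and actual — the alternative reading
    #: of "R² between predicted and actual"; coefficient of determination is
    #: the headline metric
    per_fold_r2_pearson: tuple[float, ...] = ()

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_fold_r2))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.per_fold_rmse))

    @property
    def mean_r2_pearson(self) -> float:
        return float(np.mean(self.per_fold_r2_pearson))


@dataclass
class FittedModel:
    family: str
    model: object
    feature_names: list[str]
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd) for lasso

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        A = X[self.feature_names].to_numpy(dtype=np.float32)
        return _predict_array(self, A)


def _predict_array(fitted: FittedModel, A: np.ndarray) -> np.ndarray:
    if fitted.family == "lasso":
        mean, sd = fitted.scaler
        return fitted.model.predict((A - mean) / sd)
    if fitted.family == "random_forest":
        return fitted.model.predict(A)
    return fitted.model.predict(xgb.DMatrix(A, feature_names=fitted.feature_names))


# ---------------------------------------------------------------------------
# Design matrix and folds
# ---------------------------------------------------------------------------

def build_design_matrix(
    kinome: KinomeStateMatrix,
    expression: pd.DataFrame,
    sensitivities: pd.DataFrame,
) -> pd.DataFrame:
    """One row per screened (drug, cell line) pair with both feature blocks.

    Inner join: sensitivity rows whose drug is absent from the kinome matrix
    or whose cell line is absent from the expression matrix are dropped with
    a logged count.  Adds a ``log10_ic50`` outcome column next to ``auc``.
    """
    sens = sensitivities.copy()
    n0 = len(sens)
    sens = sens[
        sens["drug_id"].isin(kinome.values.index)
        & sens["cell_line_id"].isin(expression.index)
    ]
    dropped = n0 - len(sens)
    if dropped:
        logger.info("build_design_matrix: dropped %d pair(s) lacking features", dropped)
    if sens.empty:
        raise ValueError("no (drug, cell line) pairs with complete features")
    if "ic50" in sens.columns and "log10_ic50" not in sens.columns:
        sens["log10_ic50"] = np.log10(sens["ic50"])
    act = kinome.values.loc[sens["drug_id"]].reset_index(drop=True)
    exp = expression.loc[sens["cell_line_id"]].reset_index(drop=True)
    design = pd.concat([sens.reset_index(drop=True), act, exp], axis=1)
    return design


def make_folds(
    n_rows: int, k: int = 10, seed: int = 0, groups: Sequence | None = None
) -> np.ndarray:
    """Random partition of rows into k near-equal folds (labels 0..k-1).

    With ``groups`` (one label per row, e.g. drug ids), whole groups are
    assigned to folds so no group spans a fold boundary — the grouped CV
    variants that probe extrapolation to unseen drugs or cell lines.
    """
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != n_rows:
            raise ValueError("groups must have one label per row")
        unique = np.unique(groups)
        if len(unique) < k:
            raise ValueError(f"need at least {k} groups for {k}-fold grouped CV")
        rng = np.random.default_rng([seed, 102])
        group_fold = dict(
            zip(unique[rng.permutation(len(unique))], np.arange(len(unique)) % k)
        )
        return np.array([group_fold[g] for g in groups])
    if n_rows < k:
        raise ValueError(f"need at least {k} rows for {k}-fold CV, got {n_rows}")
    rng = np.random.default_rng([seed, 101])
    labels = np.arange(n_rows) % k
    return labels[rng.permutation(n_rows)]


def sample_hyperparameters(family: str, n: int = 30, seed: int = 0) -> list[dict]:
    """Random configurations within the family's documented ranges.

    The LASSO penalty is sampled log-uniformly (its range spans nine decades);
    tree counts and depths uniformly on integers.  Deterministic under seed.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng([seed, 202, FAMILIES.index(family)])
    configs: list[dict] = []
    if family == "lasso":
        lo, hi = HYPERPARAMETER_RANGES["lasso"]["penalty"]
        for v in 10 ** rng.uniform(np.log10(lo), np.log10(hi), n):
            configs.append({"penalty": float(v)})
    elif family == "random_forest":
        lo, hi = HYPERPARAMETER_RANGES["random_forest"]["trees"]
        for v in rng.integers(lo, hi + 1, n):
            configs.append({"trees": int(v)})
    else:
        t_lo, t_hi = HYPERPARAMETER_RANGES["xgboost"]["trees"]
        d_lo, d_hi = HYPERPARAMETER_RANGES["xgboost"]["depth"]
        trees = rng.integers(t_lo, t_hi + 1, n)
        depths = rng.integers(d_lo, d_hi + 1, n)
        for t, d in zip(trees, depths):
            configs.append({"trees": int(t), "depth": int(d)})
    return configs


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate_r2(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(a) != len(p) or len(a) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual outcome is constant")
    return float(1.0 - np.sum((a - p) ** 2) / ss_tot)


def evaluate_rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def squared_pearson(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """The alternative reading of "R² between predicted and actual"."""
    if np.std(predicted) == 0:
        return 0.0
    return float(stats.pearsonr(actual, predicted).statistic ** 2)


# ---------------------------------------------------------------------------
# Fitting primitives
# ---------------------------------------------------------------------------

def _fit_lasso(Xtr: np.ndarray, ytr: np.ndarray, penalty: float, seed: int):
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import Lasso

    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    model = Lasso(alpha=max(penalty, 1e-10), max_iter=3000, tol=1e-4, random_state=seed)
    with warnings.catch_warnings():
        # near-zero penalties are effectively OLS on collinear features; the
        # coordinate-descent duality gap stalls without affecting predictions
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit((Xtr - mean) / sd, ytr)
    return model, (mean, sd)


def _fit_rf(Xtr: np.ndarray, ytr: np.ndarray, trees: int, seed: int) -> lgb.Booster:
    p = Xtr.shape[1]
    params = dict(
        _LGB_RF_BASE,
        feature_fraction=max(np.sqrt(p) / p, 1.0 / p),
        num_leaves=max(4, int(np.ceil(0.632 * len(ytr) / 5))),
        seed=seed,
    )
    ds = lgb.Dataset(Xtr, label=ytr, params={"max_bin": 64})
    return lgb.train(params, ds, num_boost_round=trees)


def _fit_xgb(
    Xtr: np.ndarray, ytr: np.ndarray, trees: int, depth: int, seed: int
) -> xgb.Booster:
    dtrain = xgb.DMatrix(Xtr, label=ytr)
    params = dict(_XGB_BASE, max_depth=depth, seed=seed)
    return xgb.train(params, dtrain, num_boost_round=trees)


def fit_model(design: pd.DataFrame, spec: ModelSpec, features: list[str]) -> FittedModel:
    """Fit one specification on all rows of the design table."""
    Xtr = np.ascontiguousarray(design[features].to_numpy(dtype=np.float32))
    ytr = design[spec.outcome].to_numpy(dtype=float)
    if spec.family == "lasso":
        model, scaler = _fit_lasso(Xtr, ytr, spec.hyperparameters["penalty"], spec.seed)
        return FittedModel("lasso", model, features, scaler)
    if spec.family == "random_forest":
        model = _fit_rf(Xtr, ytr, spec.hyperparameters["trees"], spec.seed)
        return FittedModel("random_forest", model, features)
    model = _fit_xgb(
        Xtr, ytr, spec.hyperparameters["trees"], spec.hyperparameters["depth"], spec.seed
    )
    return FittedModel("xgboost", model, features)


# ---------------------------------------------------------------------------
# Cross-validation and tuning
# ---------------------------------------------------------------------------

def _fold_features(
    design: pd.DataFrame,
    train_mask: np.ndarray,
    outcome: str,
    rank_per_fold: bool,
    ranking: pd.DataFrame | None,
) -> pd.DataFrame:
    if rank_per_fold:
        return bivariate_rank(design.loc[train_mask], outcome=outcome)
    if ranking is None:
        raise ValueError("rank_per_fold=False requires a precomputed ranking")
    return ranking


def cross_validate(
    design: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    rank_per_fold: bool = True,
    ranking: pd.DataFrame | None = None,
    group_by: str | None = None,
) -> CVResult:
    """10-fold CV of one specification; feature selection inside each fold.

    With ``rank_per_fold`` (the default) the correlation ranking is recomputed
    on the training rows of every fold so held-out outcomes never leak into
    feature selection; passing ``rank_per_fold=False`` with a full-data
    ranking reproduces the simpler single-ranking protocol.  ``group_by``
    (``"drug_id"`` or ``"cell_line_id"``) switches to grouped folds that hold
    out whole drugs or cell lines, probing extrapolation instead of random
    within-screen interpolation.
    """
    groups = design[group_by].to_numpy() if group_by is not None else None
    folds = make_folds(len(design), k, spec.seed, groups=groups)
    r2s, rmses, pearsons = [], [], []
    y = design[spec.outcome].to_numpy(dtype=float)
    for f in range(k):
        te = folds == f
        tr = ~te
        if tr.sum() < 2 or te.sum() < 2:
            raise ValueError("fold too small to fit and score")
        fold_rank = _fold_features(design, tr, spec.outcome, rank_per_fold, ranking)
        feats = select_top_k(fold_rank, spec.n_features)
        fitted = fit_model(design.loc[tr], spec, feats)
        pred = _predict_array(
            fitted, np.ascontiguousarray(design.loc[te, feats].to_numpy(dtype=np.float32))
        )
        r2s.append(evaluate_r2(y[te], pred))
        rmses.append(evaluate_rmse(y[te], pred))
        pearsons.append(squared_pearson(y[te], pred))
    return CVResult(
        spec=spec,
        per_fold_r2=tuple(r2s),
        per_fold_rmse=tuple(rmses),
        per_fold_r2_pearson=tuple(pearsons),
    )


def tune_and_compare(
    design: pd.DataFrame,
    cutoffs: Sequence[int],
    families: Sequence[str] = FAMILIES,
    n_configs: int = 30,
    seed: int = 0,
    outcome: str = "auc",
    k: int = 10,
    rank_per_fold: bool = True,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Evaluate the full (cutoff x family x config) grid under shared folds.

    Returns the best specification by mean CV R² and a comparison table with
    one best-of-configs row per (cutoff, family) — the model-comparison plot's
    underlying data.  All families see identical folds and identical per-fold
    feature rankings.
    """
    configs = {fam: sample_hyperparameters(fam, n_configs, seed) for fam in families}
    folds = make_folds(len(design), k, seed)
    y = design[outcome].to_numpy(dtype=float)
    full_ranking = None if rank_per_fold else bivariate_rank(design, outcome=outcome)

    # accumulate per (family, cutoff, config) fold scores
    scores: dict[tuple[str, int, int], list[tuple[float, float]]] = {
        (fam, c, i): [] for fam in families for c in cutoffs for i in range(n_configs)
    }
    for f in range(k):
        te = folds == f
        tr = ~te
        fold_rank = _fold_features(design, tr, outcome, rank_per_fold, full_ranking)
        ytr, yte = y[tr], y[te]
        for cutoff in cutoffs:
            feats = select_top_k(fold_rank, cutoff)
            Xtr = np.ascontiguousarray(design.loc[tr, feats].to_numpy(dtype=np.float32))
            Xte = np.ascontiguousarray(design.loc[te, feats].to_numpy(dtype=np.float32))
            for fam in families:
                if fam == "random_forest":
                    # one maximal forest; each config reads its leading trees
                    tree_counts = [cfg["trees"] for cfg in configs[fam]]
                    booster = _fit_rf(Xtr, ytr, max(tree_counts), seed)
                    for i, t in enumerate(tree_counts):
                        pred = booster.predict(Xte, num_iteration=t)
                        scores[(fam, cutoff, i)].append(
                            (evaluate_r2(yte, pred), evaluate_rmse(yte, pred))
                        )
                    continue
                for i, cfg in enumerate(configs[fam]):
                    if fam == "lasso":
                        model, scaler = _fit_lasso(Xtr, ytr, cfg["penalty"], seed)
                        pred = model.predict((Xte - scaler[0]) / scaler[1])
                    else:
                        booster = _fit_xgb(Xtr, ytr, cfg["trees"], cfg["depth"], seed)
                        pred = booster.predict(xgb.DMatrix(Xte))
                    scores[(fam, cutoff, i)].append(
                        (evaluate_r2(yte, pred), evaluate_rmse(yte, pred))
                    )

    rows = []
    for fam in families:
        for cutoff in cutoffs:
            for i, cfg in enumerate(configs[fam]):
                fold_scores = scores[(fam, cutoff, i)]
                rows.append(
                    {
                        "family": fam,
                        "cutoff": int(cutoff),
                        "config_index": i,
                        "hyperparameters": repr(cfg),
                        "mean_r2": float(np.mean([s[0] for s in fold_scores])),
                        "mean_rmse": float(np.mean([s[1] for s in fold_scores])),
                    }
                )
    all_results = pd.DataFrame(rows)
    best_per = (
        all_results.sort_values(["mean_r2", "family", "cutoff", "config_index"],
                                ascending=[False, True, True, True])
        .groupby(["family", "cutoff"], as_index=False)
        .first()
        .sort_values(["family", "cutoff"])
        .reset_index(drop=True)
    )
    top = all_results.sort_values(
        ["mean_r2", "family", "cutoff", "config_index"],
        ascending=[False, True, True, True],
    ).iloc[0]
    best_spec = ModelSpec(
        family=top["family"],
        hyperparameters=configs[top["family"]][int(top["config_index"])],
        n_features=int(top["cutoff"]),
        outcome=outcome,
        seed=seed,
    )
    return best_spec, best_per


def spec_from_comparison_row(
    row, n_configs: int, seed: int, outcome: str = "auc"
) -> ModelSpec:
    """Reconstruct the ModelSpec behind one comparison-table row.

    The random hyperparameter draw is deterministic under (family, n_configs,
    seed), so a row's ``config_index`` identifies its configuration exactly.
    """
    configs = sample_hyperparameters(str(row["family"]), n_configs, seed)
    return ModelSpec(
        family=str(row["family"]),
        hyperparameters=configs[int(row["config_index"])],
        n_features=int(row["cutoff"]),
        outcome=outcome,
        seed=seed,
    )


def fit_final_and_predict(
    design: pd.DataFrame,
    spec: ModelSpec,
    new_pairs: pd.DataFrame,
    kinome: KinomeStateMatrix,
    expression: pd.DataFrame,
) -> tuple[FittedModel, pd.DataFrame, pd.DataFrame]:
    """Fit the winning spec on the full table and predict requested pairs.

    ``new_pairs`` needs columns ``drug_id, cell_line_id``.  Pairs lacking a
    kinome or expression row are returned in an exclusions report rather than
    silently dropped.  Returns (fitted model, prediction grid, exclusions);
    the grid flags pairs that were part of the training table.
    """
    ranking = bivariate_rank(design, outcome=spec.outcome)
    feats = select_top_k(ranking, spec.n_features)
    fitted = fit_model(design, spec, feats)

    ok = new_pairs["drug_id"].isin(kinome.values.index) & new_pairs[
        "cell_line_id"
    ].isin(expression.index)
    excluded = new_pairs.loc[~ok].copy()
    excluded["reason"] = np.where(
        ~new_pairs.loc[~ok, "drug_id"].isin(kinome.values.index),
        "missing kinome profile",
        "missing expression profile",
    )
    pairs = new_pairs.loc[ok].reset_index(drop=True)
    act = kinome.values.loc[pairs["drug_id"]].reset_index(drop=True)
    exp = expression.loc[pairs["cell_line_id"]].reset_index(drop=True)
    X = pd.concat([act, exp], axis=1)
    pred = _predict_array(
        fitted, np.ascontiguousarray(X[feats].to_numpy(dtype=np.float32))
    )
    training_keys = set(zip(design["drug_id"], design["cell_line_id"]))
    grid = pd.DataFrame(
        {
            "drug_id": pairs["drug_id"],
            "cell_line_id": pairs["cell_line_id"],
            "predicted_outcome": pred,
            "was_in_training": [
                (d, c) in training_keys
                for d, c in zip(pairs["drug_id"], pairs["cell_line_id"])
            ],
        }
    )
    return fitted, grid, excluded.reset_index(drop=True)
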