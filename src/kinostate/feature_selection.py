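"""Bivariate correlation ranking of candidate features and top-k selection.

Every candidate column of the modeling table — drug-side kinome inhibition
states (``act_`` prefix) and cell-side baseline expression (``exp_`` prefix)
— is correlated with the sensitivity outcome over all drug x cell-line rows.
Features are ranked by decreasing absolute Pearson correlation (Spearman
statistics are reported alongside); zero-variance features are assigned r = 0
and sort last.  Ties in |r| break by ascending feature id so the ranking is
deterministic across platforms.  Incremental top-k subsets of this ranking
feed the model comparison, and the per-cutoff class composition (how many
kinome-state vs expression features enter at each cutoff) summarizes which
data type carries the signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_io import EXPRESSION_PREFIX, KINOME_PREFIX

__all__ = [
    "DEFAULT_CUTOFFS",
    "feature_columns",
    "bivariate_rank",
    "select_top_k",
    "class_composition",
]

DEFAULT_CUTOFFS = (100, 200, 300, 400, 500, 1000, 2000, 3000, 4000, 5000)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Candidate feature columns: those with the act_/exp_ prefix."""
    return [
        c
        for c in table.columns
        if str(c).startswith(KINOME_PREFIX) or str(c).startswith(EXPRESSION_PREFIX)
    ]


def _corr_with_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r and two-sided p against y; constants get r=0, p=1."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    denom = np.where(constant, 1.0, sx * sy)
    r = (Xc * yc[:, None]).sum(axis=0) / denom
    r = np.where(constant, 0.0, np.clip(r, -1.0, 1.0))
    # two-sided p from the exact t reference distribution
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * special.stdtr(n - 2, -np.abs(t))
    p = np.where(constant, 1.0, np.clip(p, 0.0, 1.0))
    return r, p


def bivariate_rank(
    table: pd.DataFrame, outcome: str = "auc", collapse_by_drug: bool = False
) -> pd.DataFrame:
    """Rank every feature by |Pearson r| with the outcome column.

    Returns a FeatureRanking frame with one row per feature: ``feature_id,
    feature_class, pearson_r, pearson_p, spearman_rho, spearman_p, rank``,
    sorted by rank (1 = most correlated).  Requires >= 3 rows.  The outcome
    must be non-constant; individual features may be constant and rank last
    with r = 0.

    By default correlations run over the full drug x cell-line table, where
    a drug's kinome state repeats across its cell lines.
    ``collapse_by_drug`` first averages each drug's rows (features and
    outcome), removing that repetition at the cost of discarding the
    cell-line axis; off by default.
    """
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} not in table")
    if collapse_by_drug:
        if "drug_id" not in table.columns:
            raise ValueError("collapse_by_drug requires a drug_id column")
        keep = feature_columns(table) + [outcome]
        table = table.groupby("drug_id", as_index=False)[keep].mean()
    features = feature_columns(table)
    if not features:
        raise ValueError("no act_/exp_ feature columns found")
    if len(table) < 3:
        raise ValueError("need at least 3 rows to correlate")
    y = table[outcome].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("outcome is constant")
    X = table[features].to_numpy(dtype=float)

    r, p = _corr_with_pvalues(X, y)
    Xr = stats.rankdata(X, axis=0)
    yr = stats.rankdata(y)
    rho, rho_p = _corr_with_pvalues(Xr, yr)

    ranking = pd.DataFrame(
        {
            "feature_id": features,
            "feature_class": [
                "kinome_state" if f.startswith(KINOME_PREFIX) else "expression"
                for f in features
            ],
            "pearson_r": r,
            "pearson_p": p,
            "spearman_rho": rho,
            "spearman_p": rho_p,
        }
    )
    order = np.lexsort((ranking["feature_id"].to_numpy(), -np.abs(r)))
    ranking = ranking.iloc[order].reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def select_top_k(ranking: pd.DataFrame, k: int) -> list[str]:
    """The k best-correlated feature ids, in rank order."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k must lie in [1, {len(ranking)}], got {k}")
    return ranking.nsmallest(k, "rank")["feature_id"].tolist()


def class_composition(
    ranking: pd.DataFrame, cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Per-cutoff counts of kinome-state vs expression features in the top-k."""
    if max(cutoffs) > len(ranking):
        raise ValueError("a cutoff exceeds the number of features")
    ordered = ranking.sort_values("rank")["feature_class"].to_numpy()
    rows = []
    for k in cutoffs:
        head = ordered[:k]
        rows.append(
            {
                "cutoff": k,
                "kinome_state": int((head == "kinome_state").sum()),
                "expression": int((head == "expression").sum()),
            }
        )
    return pd.DataFrame(rows)
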