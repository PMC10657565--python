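"""Plate normalization and four-parameter log-logistic dose-response summaries.

Raw per-well luminescence readings are normalized row-wise to the plate's
DMSO-only control wells (relative viability = replicate-mean reading / mean
DMSO reading), with a quality-control rule excluding plate rows where any
normalized value reaches 120% of DMSO.  Each (drug, cell line) curve is then
summarized by a least-squares fit of the four-parameter log-logistic model

    v(d) = lower + (upper - lower) / (1 + 10^(hill * (log10 d - log10 IC50)))

from which two scalars are extracted: the normalized area under the viability
curve over log10-dose (AUC; a flat curve at viability c scores exactly c) and
the absolute half-viability crossing concentration (IC50), capped at the dose
range boundary with an explicit flag when the fitted curve never crosses 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "FourPLFit",
    "normalize_plate",
    "fit_4pl",
    "compute_auc",
    "compute_ic50",
    "summarize_viability",
]

# Optimizer box constraints.  Asymptotes may stray slightly outside [0, 1] to
# absorb normalization noise; the IC50 may sit up to two decades outside the
# tested range; Hill slopes below 0.2 are indistinguishable from flat curves.
_LOWER_BOUNDS = (-0.2, 0.5, None, 0.2)   # lower, upper, log10_ic50, hill
_UPPER_BOUNDS = (1.2, 1.3, None, 10.0)

QC_VIABILITY_LIMIT = 1.2  # plate rows reaching 120% of DMSO are excluded


@dataclass(frozen=True)
class FourPLFit:
    lower: float
    upper: float
    log10_ic50: float
    hill: float
    converged: bool
    residual_sse: float

    def viability(self, dose: np.ndarray | float) -> np.ndarray | float:
        x = np.log10(dose)
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.power(10.0, self.hill * (x - self.log10_ic50))
        )


def normalize_plate(
    readings: pd.DataFrame, dmso_readings: np.ndarray | pd.Series
) -> tuple[pd.DataFrame, bool]:
    """Normalize one plate row's readings to its DMSO control wells.

    ``readings`` needs columns ``dose_molar`` and ``reading`` (replicate
    wells as repeated doses).  Returns a per-dose frame with columns
    ``dose_molar, viability`` (replicate means divided by the mean DMSO
    reading) and a flag that is True when the row fails the <120%-of-DMSO
    quality rule and must be excluded.
    """
    dmso = np.asarray(dmso_readings, dtype=float)
    if dmso.size == 0:
        raise ValueError("no DMSO wells")
    dmso_mean = float(dmso.mean())
    if dmso_mean <= 0:
        raise ValueError("mean DMSO reading must be positive")
    per_dose = (
        readings.groupby("dose_molar", as_index=False)["reading"].mean()
        .sort_values("dose_molar")
        .reset_index(drop=True)
    )
    per_dose["viability"] = per_dose["reading"] / dmso_mean
    qc_failed = bool((per_dose["viability"] >= QC_VIABILITY_LIMIT).any())
    return per_dose[["dose_molar", "viability"]], qc_failed


def _fourpl(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    lower, upper, m, hill = params
    return lower + (upper - lower) / (1.0 + np.power(10.0, hill * (x - m)))


def fit_4pl(doses: np.ndarray, viabilities: np.ndarray) -> FourPLFit:
    """Least-squares 4PL fit with deterministic multi-start initialization.

    Five starts place the initial IC50 at the dose-range quantiles
    {0, 0.25, 0.5, 0.75, 1}; the best converged solution wins.  If no start
    converges the best-effort parameters are returned with
    ``converged=False``.
    """
    doses = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    x = np.log10(doses)
    x_lo, x_hi = x.min(), x.max()
    m_bounds = (x_lo - 2.0, x_hi + 2.0)
    lb = np.array([_LOWER_BOUNDS[0], _LOWER_BOUNDS[1], m_bounds[0], _LOWER_BOUNDS[3]])
    ub = np.array([_UPPER_BOUNDS[0], _UPPER_BOUNDS[1], m_bounds[1], _UPPER_BOUNDS[3]])

    lower0 = float(np.clip(v.min(), lb[0], ub[0]))
    upper0 = float(np.clip(v.max(), lb[1], ub[1]))
    best = None
    for q in (0.0, 0.25, 0.5, 0.75, 1.0):
        m0 = x_lo + q * (x_hi - x_lo)
        p0 = np.clip(np.array([lower0, upper0, m0, 1.0]), lb, ub)
        try:
            res = optimize.least_squares(
                lambda p: _fourpl(p, x) - v, p0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[1] - 1e-15:
            best = (res, sse)
        if res.success and sse < 1e-16:
            break  # exact fit; remaining starts cannot improve
    if best is None:
        return FourPLFit(lower0, upper0, float(x_lo), 1.0, False, float(np.inf))
    res, sse = best
    lower, upper, m, hill = (float(p) for p in res.x)
    converged = bool(res.success) and upper >= lower
    return FourPLFit(lower, upper, m, hill, converged, sse)


def compute_auc(fit: FourPLFit, dose_min: float, dose_max: float) -> float:
    """Normalized area under the fitted curve over log10-dose.

    ``AUC = (1 / (log10 dmax - log10 dmin)) * int v(d) d(log10 d)`` evaluated
    by adaptive quadrature, so a flat curve at viability c gives exactly c and
    values are comparable across dose grids.
    """
    if dose_min >= dose_max:
        raise ValueError("dose_min must be < dose_max")
    x0, x1 = np.log10(dose_min), np.log10(dose_max)
    integral, _ = integrate.quad(
        lambda x: fit.lower
        + (fit.upper - fit.lower) / (1.0 + 10.0 ** (fit.hill * (x - fit.log10_ic50))),
        x0,
        x1,
        limit=200,
    )
    return float(integral / (x1 - x0))


def compute_ic50(
    fit: FourPLFit, dose_min: float, dose_max: float
) -> tuple[float, bool]:
    """Absolute half-viability crossing within the tested dose range.

    Solved in closed form from the 4PL: v(d) = 0.5 requires
    ``10^(hill (x - m)) = (upper - 0.5) / (0.5 - lower)``, which has a
    solution only when the asymptotes bracket 0.5.  Curves that never reach
    half viability are capped at ``dose_max``; curves already below half
    viability at the lowest tested dose are capped at ``dose_min`` (the
    potency exceeds the tested range).  The flag marks either cap.
    """
    if dose_min >= dose_max:
        raise ValueError("dose_min must be < dose_max")
    lo, hi = sorted((fit.lower, fit.upper))
    if lo >= 0.5:
        return float(dose_max), True  # stays above half viability everywhere
    if hi <= 0.5:
        return float(dose_min), True  # below half viability even untreated
    ratio = (fit.upper - 0.5) / (0.5 - fit.lower)
    x = fit.log10_ic50 + np.log10(ratio) / fit.hill
    dose = 10.0**x
    if dose < dose_min:
        return float(dose_min), True
    if dose > dose_max:
        return float(dose_max), True
    return float(dose), False


def summarize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Full plate-to-summary pipeline over a tidy viability table.

    Expects the :func:`kinostate.data_io.read_plate_viability` layout.  Each
    (drug, cell line) plate row is DMSO-normalized, QC-checked, 4PL-fitted and
    summarized into AUC and IC50.  Returns a curve-parameter table with one
    row per surviving pair plus fit diagnostics; QC-failed rows are dropped
    with a logged count.
    """
    rows = []
    n_qc_failed = 0
    for (drug, cell), grp in plate.groupby(["drug_id", "cell_line_id"], sort=True):
        dmso = grp.loc[grp["is_dmso"], "reading"]
        treated = grp.loc[~grp["is_dmso"], ["dose_molar", "reading"]]
        if dmso.empty or treated.empty:
            raise ValueError(f"plate row ({drug}, {cell}) lacks DMSO or treated wells")
        per_dose, qc_failed = normalize_plate(treated, dmso)
        if qc_failed:
            n_qc_failed += 1
            continue
        doses = per_dose["dose_molar"].to_numpy()
        fit = fit_4pl(doses, per_dose["viability"].to_numpy())
        auc = compute_auc(fit, doses.min(), doses.max())
        ic50, capped = compute_ic50(fit, doses.min(), doses.max())
        rows.append(
            {
                "drug_id": drug,
                "cell_line_id": cell,
                "auc": auc,
                "ic50": ic50,
                "ic50_capped": capped,
                "fit_lower": fit.lower,
                "fit_upper": fit.upper,
                "fit_log10_ic50": fit.log10_ic50,
                "fit_hill": fit.hill,
                "fit_converged": fit.converged,
                "fit_sse": fit.residual_sse,
            }
        )
    if n_qc_failed:
        logger.info("summarize_viability: excluded %d plate row(s) by the 120%% QC rule", n_qc_failed)
    return pd.DataFrame(rows)
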