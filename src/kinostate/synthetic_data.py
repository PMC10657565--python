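"""Synthetic kinome-profiling, expression and viability data with a planted signal.

The generator emulates the statistical structure of the inputs the pipeline is
designed for:

* two single-dose kinome profiling dialects — a kinobead-style assay reporting
  relative intensity (non-negative, occasionally above 1 due to quantification
  artifacts) and a KINOMEscan-style assay reporting "Percent Control" on a
  0-100 scale — with partially overlapping kinase panels, a set of drugs
  profiled in both, independent per-assay noise, and missing drug-kinase pairs;
* a TPM-like baseline expression matrix for a panel of cell lines, in which a
  designated set of "context" genes is bimodally on/off across cell lines;
* raw 8-dose plate viability tables (replicate wells plus DMSO controls) whose
  underlying dose-response curves are four-parameter log-logistic.

A latent sensitivity model ties the three together: a small set of *driver*
kinases carries positive weights, each gated per cell line by the on/off state
of its context genes, so that a drug's effect on a cell line is a monotone
function of how strongly it inhibits active drivers in that cellular context.
The :class:`GroundTruth` record exposes the planted parameters so downstream
feature-ranking and model-explanation steps can be scored for signal recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DOSE_GRID",
    "AUC_FLOOR",
    "EXPRESSION_ON_THRESHOLD",
    "SimConfig",
    "GroundTruth",
    "make_ground_truth",
    "simulate_kinome_profiles",
    "simulate_expression",
    "latent_sensitivity",
    "simulate_sensitivities",
    "simulate_viability_curves",
    "fourpl_viability",
    "fourpl_auc_closed_form",
]

#: Eight-point dose grid in molar units (3 nM .. 30 uM), ascending.
DEFAULT_DOSE_GRID: tuple[float, ...] = (
    3e-9, 1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6, 3e-5,
)

#: Asymptotic AUC of a maximally effective drug in the latent model.  Even a
#: potent cytotoxic rarely drives the area under an 8-dose viability curve to
#: zero, because low doses contribute near-full viability.
AUC_FLOOR = 0.2

#: TPM threshold above which a context gene counts as "on" in a cell line.
EXPRESSION_ON_THRESHOLD = 10.0

#: A driver whose cellular context is fully "off" retains this fraction of its
#: effect: expression modulates driver dependence rather than abolishing it.
GATE_FLOOR = 0.5

#: Fraction of simulated drugs that inhibit no driver kinase (inactive
#: compounds, ubiquitous in real screens and the anchor of the potency axis).
INERT_DRUG_FRACTION = 0.35

# Deterministic rng sub-streams derived from the master seed.
_STREAM_GROUND_TRUTH = 0
_STREAM_PROFILES = 1
_STREAM_EXPRESSION = 2
_STREAM_SENSITIVITY = 3
_STREAM_VIABILITY = 4

_DMSO_SCALE = 1000.0  # raw luminescence counts of an untreated well


@dataclass(frozen=True)
class SimConfig:
    """Size and noise parameters of a simulated study.

    Defaults describe a desk-scale analog of the integrated public data the
    pipeline targets: tens of drugs profiled per assay dialect with a modest
    shared subset, a few hundred kinases of which ~30% sit on both assay
    panels, a ~62% screening coverage of the drug x cell-line grid, and the
    standard eight-dose viability titration.
    """

    n_kinases: int = 400
    n_genes: int = 2000
    n_cell_lines: int = 40
    n_drugs_kinobead: int = 35
    n_drugs_kinomescan: int = 35
    n_shared_drugs: int = 10
    panel_overlap_fraction: float = 0.3
    assay_noise_sd: float = 0.06
    assay_noise_sd_weak: float = 0.5
    missing_rate: float = 0.25
    nonbinder_report_rate: float = 0.1
    sensitivity_coverage: float = 0.62
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared_drugs > min(self.n_drugs_kinobead, self.n_drugs_kinomescan):
            raise ValueError("n_shared_drugs exceeds a dialect's drug count")
        if not 0.0 <= self.panel_overlap_fraction <= 1.0:
            raise ValueError("panel_overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.nonbinder_report_rate <= 1.0:
            raise ValueError("nonbinder_report_rate must lie in [0, 1]")
        if not 0.0 < self.sensitivity_coverage <= 1.0:
            raise ValueError("sensitivity_coverage must lie in (0, 1]")
        if self.assay_noise_sd < 0 or self.assay_noise_sd_weak < 0:
            raise ValueError("assay noise sds must be >= 0")
        grid = np.asarray(self.dose_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2:
            raise ValueError("dose_grid needs at least two doses")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("dose_grid must be strictly increasing and positive")

    @property
    def n_drugs_total(self) -> int:
        return self.n_drugs_kinobead + self.n_drugs_kinomescan - self.n_shared_drugs

    def kinase_ids(self) -> list[str]:
        return [f"KIN{i:04d}" for i in range(self.n_kinases)]

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def cell_line_ids(self) -> list[str]:
        return [f"CL{i:03d}" for i in range(self.n_cell_lines)]

    def drug_ids(self) -> list[str]:
        return [f"DRUG{i:03d}" for i in range(self.n_drugs_total)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted generative parameters enabling recovery tests."""

    driver_kinases: tuple[str, ...]
    driver_weights: dict[str, float]
    context_genes: dict[str, tuple[str, ...]]
    noise_sd_latent: float = 0.04
    noise_sd_viability: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.driver_weights.values()):
            raise ValueError("driver weights must be positive")
        if set(self.driver_weights) != set(self.driver_kinases):
            raise ValueError("driver_weights keys must match driver_kinases")
        if set(self.context_genes) != set(self.driver_kinases):
            raise ValueError("context_genes keys must match driver_kinases")


def make_ground_truth(
    config: SimConfig,
    n_drivers: int = 20,
    *,
    n_context_genes: int = 3,
    noise_sd_latent: float = 0.04,
    noise_sd_viability: float = 0.05,
) -> GroundTruth:
    """Draw driver kinases, effect weights and per-driver context genes.

    Deterministic for a fixed ``config.seed``.
    """
    if not 1 <= n_drivers <= config.n_kinases:
        raise ValueError(
            f"n_drivers must lie in [1, {config.n_kinases}], got {n_drivers}"
        )
    rng = np.random.default_rng([config.seed, _STREAM_GROUND_TRUTH])
    kinases = np.array(config.kinase_ids())
    drivers = np.sort(rng.choice(kinases, size=n_drivers, replace=False))
    weights = {k: float(w) for k, w in zip(drivers, rng.uniform(0.7, 1.3, n_drivers))}
    genes = np.array(config.gene_ids())
    context = {
        k: tuple(np.sort(rng.choice(genes, size=n_context_genes, replace=False)))
        for k in drivers
    }
    return GroundTruth(
        driver_kinases=tuple(drivers),
        driver_weights=weights,
        context_genes=context,
        noise_sd_latent=noise_sd_latent,
        noise_sd_viability=noise_sd_viability,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Kinome profiles
# ---------------------------------------------------------------------------

def _assay_panels(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Kinase panels of the two dialects; a configured fraction sits on both."""
    kinases = np.array(config.kinase_ids())
    n_common = int(round(config.panel_overlap_fraction * config.n_kinases))
    perm = rng.permutation(config.n_kinases)
    common = perm[:n_common]
    rest = perm[n_common:]
    half = len(rest) // 2
    kb = np.sort(np.concatenate([common, rest[:half]]))
    ks = np.sort(np.concatenate([common, rest[half:]]))
    return kinases[kb], kinases[ks]


def _drug_dialects(config: SimConfig) -> tuple[list[str], list[str]]:
    """Drug lists per dialect; the first ``n_shared_drugs`` ids sit in both."""
    drugs = config.drug_ids()
    shared = drugs[: config.n_shared_drugs]
    kb_only = drugs[config.n_shared_drugs : config.n_drugs_kinobead]
    ks_only = drugs[config.n_drugs_kinobead :]
    return shared + kb_only, shared + ks_only


def true_inhibition_profiles(gt: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Noise-free drug x kinase inhibition states (fraction of control).

    Each drug strongly inhibits a handful of targets (values near 0) and
    leaves everything else at the no-interaction value 1.  Driver kinases are
    hit by a designated subset of drugs so that the planted signal is carried
    by the profiling data.
    """
    rng = np.random.default_rng([gt.seed, _STREAM_PROFILES, 0])
    kinases = config.kinase_ids()
    drugs = config.drug_ids()
    drivers = list(gt.driver_kinases)
    non_drivers = [k for k in kinases if k not in set(drivers)]
    profile = pd.DataFrame(1.0, index=drugs, columns=kinases)

    # off-targets come from a shared promiscuity pool (conserved ATP-pocket
    # kinases are hit by many unrelated compounds), so no single off-target
    # uniquely fingerprints a drug
    pool_size = max(1, min(len(non_drivers), config.n_kinases // 4))
    promiscuous = list(rng.choice(non_drivers, size=pool_size, replace=False))

    # an INERT_DRUG_FRACTION of drugs hits no driver (inactive compounds);
    # the rest get 1-3 driver hits dealt from a reshuffled deck so every
    # driver is covered by a comparable number of drugs without additive
    # saturation of the latent link
    active = rng.random(len(drugs)) >= INERT_DRUG_FRACTION
    n_hits = np.where(active, rng.integers(2, 5, size=len(drugs)), 0)
    deck: list[str] = []
    while len(deck) < int(n_hits.sum()):
        deck.extend(rng.permutation(drivers))
    cursor = 0
    for d, n_h in zip(drugs, n_hits):
        hit_drivers: list[str] = []
        while len(hit_drivers) < min(int(n_h), len(drivers)):
            candidate = deck[cursor % len(deck)]
            cursor += 1
            if candidate not in hit_drivers:
                hit_drivers.append(candidate)
        n_off = int(rng.integers(1, 4))
        off_targets = list(rng.choice(promiscuous, size=n_off, replace=False))
        targets = hit_drivers + off_targets
        profile.loc[d, targets] = rng.uniform(0.0, 0.25, size=len(targets))
        # weak partial engagements of promiscuous kinases: reported by the
        # assays but far from the strong-hit regime
        n_weak = min(int(rng.integers(8, 17)), pool_size)
        weak = [k for k in rng.choice(promiscuous, size=n_weak, replace=False)
                if k not in off_targets]
        profile.loc[d, weak] = rng.uniform(0.35, 0.9, size=len(weak))
    return profile


def simulate_kinome_profiles(gt: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Long-format profiling records in both assay dialects.

    Returns a DataFrame with columns ``drug_id, kinase_id, value, assay,
    mutant_flag``.  Kinobead values are relative intensities (>= 0, a small
    fraction above 1); KINOMEscan values are Percent Control on the 0-100
    scale.  Shared drugs are measured in both dialects with independent noise.

    Competition assays detect *engaged* kinases: an engaged pair is reported
    unless it is among the ``missing_rate`` fraction lost per dialect, while a
    non-interacting pair is reported (at the control level, with noise) only
    at ``nonbinder_report_rate`` — everything else is simply absent from the
    table, to be imputed downstream with the no-interaction value 1.  A few
    KINOMEscan records describe recombinantly mutated kinase constructs
    (``mutant_flag``) that the integration step must drop.
    """
    truth = true_inhibition_profiles(gt, config)
    panel_rng = np.random.default_rng([gt.seed, _STREAM_PROFILES, 1])
    kb_panel, ks_panel = _assay_panels(config, panel_rng)
    kb_drugs, ks_drugs = _drug_dialects(config)

    frames = []
    for assay, drugs, panel, stream in (
        ("kinobead", kb_drugs, kb_panel, 2),
        ("kinomescan", ks_drugs, ks_panel, 3),
    ):
        rng = np.random.default_rng([gt.seed, _STREAM_PROFILES, stream])
        base = truth.loc[drugs, panel].to_numpy()
        engaged_mask = base < 1.0
        # engaged pairs: per-pair read noise; the dialects agree on strong
        # engagement but diverge on weak partial engagement (molecularly
        # different assays).  Non-binders: the whole run shares one
        # normalization bias — control-level readings move together, they do
        # not fingerprint individual kinases.
        sd = np.where(base < 0.3, config.assay_noise_sd, config.assay_noise_sd_weak)
        if config.assay_noise_sd == 0:
            sd = np.zeros_like(sd)
            run_bias = np.zeros(len(drugs))
        else:
            run_bias = rng.normal(0.0, 0.05, size=len(drugs))
        noisy = base + rng.normal(0.0, 1.0, size=base.shape) * sd
        noisy = np.where(engaged_mask, noisy, 1.0 + run_bias[:, None])
        noisy = np.clip(noisy, 0.0, None)
        if assay == "kinobead":
            if config.assay_noise_sd > 0:
                # heavy-tailed quantification artifacts, occasionally far above 1
                spike = rng.random(size=base.shape) < 0.001
                noisy = np.where(spike, noisy + rng.uniform(0.5, 3.0, size=base.shape), noisy)
        else:
            noisy = np.clip(noisy * 100.0, 0.0, 100.0)
        engaged = base < 1.0
        draw = rng.random(size=base.shape)
        keep = np.where(
            engaged,
            draw >= config.missing_rate,
            draw < config.nonbinder_report_rate * (1.0 - config.missing_rate),
        )
        di, ki = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "drug_id": np.asarray(drugs)[di],
                    "kinase_id": np.asarray(panel)[ki],
                    "value": noisy[keep],
                    "assay": assay,
                    "mutant_flag": False,
                }
            )
        )
        if assay == "kinomescan" and config.assay_noise_sd > 0:
            # mutated-construct assays: same kinase ids, flagged, value shifted
            n_mut = max(1, int(0.02 * keep.sum()))
            rows = rng.integers(0, len(drugs), n_mut)
            cols = rng.integers(0, len(panel), n_mut)
            frames.append(
                pd.DataFrame(
                    {
                        "drug_id": np.asarray(drugs)[rows],
                        "kinase_id": np.asarray(panel)[cols],
                        "value": np.clip(
                            base[rows, cols] * 100.0
                            + rng.normal(0, 25.0, n_mut),
                            0.0,
                            100.0,
                        ),
                        "assay": "kinomescan",
                        "mutant_flag": True,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(gt: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """TPM-like cell line x gene matrix (unprefixed gene ids, non-negative).

    Context genes are bimodal across cell lines: "on" cells express them well
    above :data:`EXPRESSION_ON_THRESHOLD`, "off" cells well below, with the on
    fraction drawn per gene from [0.3, 0.7].  All other genes are log-normal
    background.  Deterministic under the ground-truth seed.
    """
    rng = np.random.default_rng([gt.seed, _STREAM_EXPRESSION])
    cells = config.cell_line_ids()
    genes = config.gene_ids()
    n_c, n_g = len(cells), len(genes)
    gene_mu = rng.normal(1.5, 1.0, n_g)
    values = np.exp(gene_mu[None, :] + rng.normal(0.0, 0.3, size=(n_c, n_g)))

    context = sorted({g for gs in gt.context_genes.values() for g in gs})
    col = {g: i for i, g in enumerate(genes)}
    for g in context:
        on_frac = rng.uniform(0.3, 0.7)
        on = rng.random(n_c) < on_frac
        hi = np.exp(rng.normal(4.1, 0.4, n_c))   # ~40-120 TPM
        lo = np.exp(rng.normal(-1.2, 0.4, n_c))  # ~0.2-0.5 TPM
        values[:, col[g]] = np.where(on, hi, lo)
    return pd.DataFrame(values, index=pd.Index(cells, name="cell_line_id"), columns=genes)


# ---------------------------------------------------------------------------
# Latent sensitivity
# ---------------------------------------------------------------------------

def _context_gate(gt: GroundTruth, driver: str, cell_expression: Mapping[str, float]) -> float:
    genes = gt.context_genes[driver]
    frac_on = float(
        np.mean([cell_expression[g] > EXPRESSION_ON_THRESHOLD for g in genes])
    )
    return GATE_FLOOR + (1.0 - GATE_FLOOR) * frac_on


def latent_sensitivity(
    gt: GroundTruth,
    drug_profile: Mapping[str, float],
    cell_expression: Mapping[str, float],
) -> float:
    """Noise-free AUC-like sensitivity of one cell line to one drug.

    Computes ``z = sum_k w_k * max(0, 1 - x_k) * g_k(cell)`` over driver
    kinases ``k`` (``x_k`` the drug's inhibition state, absent entries imputed
    to the no-interaction value 1; ``g_k`` the context gate, ranging from
    :data:`GATE_FLOOR` when all of the driver's context genes are off to 1
    when all are expressed above threshold) and maps it through the
    decreasing logistic link ``AUC = floor + (1 - floor) * 2 / (1 + e^z)``,
    so an inert drug (all ``x_k = 1``) scores exactly 1 and stronger driver
    inhibition monotonically lowers the score toward :data:`AUC_FLOOR`.
    """
    z = 0.0
    for k in gt.driver_kinases:
        x = float(drug_profile.get(k, 1.0))
        inhibition = max(0.0, 1.0 - x)
        if inhibition == 0.0:
            continue
        z += gt.driver_weights[k] * inhibition * _context_gate(gt, k, cell_expression)
    return AUC_FLOOR + (1.0 - AUC_FLOOR) * 2.0 / (1.0 + np.exp(z))


def latent_auc_matrix(gt: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Noise-free latent AUC for every (drug, cell line) pair (drugs x cells)."""
    truth = true_inhibition_profiles(gt, config)
    expression = simulate_expression(gt, config)
    drugs = config.drug_ids()
    cells = config.cell_line_ids()

    drivers = list(gt.driver_kinases)
    weights = np.array([gt.driver_weights[k] for k in drivers])
    inhib = np.clip(1.0 - truth[drivers].to_numpy(), 0.0, None)  # drugs x drivers
    gates = np.empty((len(cells), len(drivers)))
    for j, k in enumerate(drivers):
        on = expression[list(gt.context_genes[k])].to_numpy() > EXPRESSION_ON_THRESHOLD
        gates[:, j] = GATE_FLOOR + (1.0 - GATE_FLOOR) * on.mean(axis=1)
    z = np.einsum("dk,ck,k->dc", inhib, gates, weights)
    auc = AUC_FLOOR + (1.0 - AUC_FLOOR) * 2.0 / (1.0 + np.exp(z))
    return pd.DataFrame(auc, index=drugs, columns=cells)


def simulate_sensitivities(gt: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Latent AUC per screened (drug, cell line) pair.

    A ``sensitivity_coverage`` fraction of the full grid is screened (the rest
    stands in for untested pairs available for later prediction).  Columns:
    ``drug_id, cell_line_id, latent_auc``.
    """
    rng = np.random.default_rng([gt.seed, _STREAM_SENSITIVITY])
    drugs = config.drug_ids()
    cells = config.cell_line_ids()
    auc = latent_auc_matrix(gt, config).to_numpy()
    auc = auc + rng.normal(0.0, gt.noise_sd_latent, size=auc.shape)
    auc = np.clip(auc, 0.05, 1.0)

    screened = rng.random(size=auc.shape) < config.sensitivity_coverage
    di, ci = np.nonzero(screened)
    return pd.DataFrame(
        {
            "drug_id": np.asarray(drugs)[di],
            "cell_line_id": np.asarray(cells)[ci],
            "latent_auc": auc[screened],
        }
    )


# ---------------------------------------------------------------------------
# Viability curves
# ---------------------------------------------------------------------------

def fourpl_viability(
    dose: np.ndarray | float,
    lower: float,
    upper: float,
    log10_ic50: float,
    hill: float,
) -> np.ndarray | float:
    """Four-parameter log-logistic viability, decreasing in dose for hill > 0."""
    x = np.log10(dose)
    return lower + (upper - lower) / (1.0 + np.power(10.0, hill * (x - log10_ic50)))


def fourpl_auc_closed_form(
    lower: float,
    upper: float,
    log10_ic50: float,
    hill: float,
    dose_min: float,
    dose_max: float,
) -> float:
    """Normalized area under the 4PL over log10-dose, in closed form.

    Uses the antiderivative ``F(s) = s - log10(1 + 10^s)`` of
    ``1 / (1 + 10^s)``; a flat curve at viability c yields exactly c.
    """
    x0, x1 = np.log10(dose_min), np.log10(dose_max)
    if x0 >= x1:
        raise ValueError("dose_min must be < dose_max")

    def _f(s: float) -> float:
        # s - log10(1 + 10^s), evaluated stably for large |s|
        return s - np.logaddexp(0.0, s * np.log(10.0)) / np.log(10.0)

    integral = (_f(hill * (x1 - log10_ic50)) - _f(hill * (x0 - log10_ic50))) / hill
    return float(lower + (upper - lower) * integral / (x1 - x0))


def _solve_log10_ic50_for_auc(
    target_auc: float, hill: float, dose_min: float, dose_max: float
) -> float:
    """Invert the closed-form AUC in log10_ic50 (monotone increasing)."""
    from scipy.optimize import brentq

    lo = np.log10(dose_min) - 2.5
    hi = np.log10(dose_max) + 2.5
    return float(
        brentq(
            lambda m: fourpl_auc_closed_form(0.0, 1.0, m, hill, dose_min, dose_max)
            - target_auc,
            lo,
            hi,
            xtol=1e-12,
        )
    )


def simulate_viability_curves(
    gt: GroundTruth,
    config: SimConfig,
    sensitivities: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw plate viability tables realizing the latent sensitivities.

    For each (drug, cell line) pair a 4PL curve (lower 0, upper 1, drug-
    specific Hill slope) is chosen whose normalized AUC over the dose grid
    equals the latent value; latent values outside the achievable range are
    clamped to a flat curve and flagged.  Readings are viability times a
    plate luminescence scale plus Gaussian noise of sd ``noise_sd_viability``
    (on the viability scale), in ``n_replicates`` wells per dose, alongside
    DMSO-only control wells for each plate row.

    Returns ``(plate_table, curve_truth)`` where ``plate_table`` has columns
    ``drug_id, cell_line_id, dose_molar, replicate, reading`` (DMSO wells have
    empty ``dose_molar``... encoded as the string "DMSO" on write) and
    ``curve_truth`` records the generating parameters per pair.
    """
    rng = np.random.default_rng([gt.seed, _STREAM_VIABILITY])
    doses = np.asarray(config.dose_grid, dtype=float)
    dmin, dmax = float(doses[0]), float(doses[-1])

    drug_hill = {
        d: float(h)
        for d, h in zip(
            config.drug_ids(),
            np.random.default_rng([gt.seed, _STREAM_VIABILITY, 1]).uniform(
                0.8, 2.5, config.n_drugs_total
            ),
        )
    }
    # achievable AUC window per hill slope (sloped-curve family, lower=0, upper=1)
    auc_ceiling = {
        d: fourpl_auc_closed_form(0.0, 1.0, np.log10(dmax) + 2.5, h, dmin, dmax)
        for d, h in drug_hill.items()
    }
    auc_floor = {
        d: fourpl_auc_closed_form(0.0, 1.0, np.log10(dmin) - 2.5, h, dmin, dmax)
        for d, h in drug_hill.items()
    }

    plate_rows = []
    truth_rows = []
    n_rep = config.n_replicates
    for drug, cell, latent in sensitivities[
        ["drug_id", "cell_line_id", "latent_auc"]
    ].itertuples(index=False):
        hill = drug_hill[drug]
        clamped = False
        if latent >= auc_ceiling[drug] or latent >= 0.995:
            lower, upper, m = float(latent), float(latent), np.nan  # flat curve
            clamped = latent > 1.0
            v = np.full_like(doses, latent)
        elif latent <= auc_floor[drug]:
            lower, upper, m = 0.0, 1.0, np.log10(dmin) - 2.5
            clamped = True
            v = fourpl_viability(doses, lower, upper, m, hill)
        else:
            lower, upper = 0.0, 1.0
            m = _solve_log10_ic50_for_auc(float(latent), hill, dmin, dmax)
            v = fourpl_viability(doses, lower, upper, m, hill)
        truth_rows.append((drug, cell, lower, upper, m, hill, float(latent), clamped))

        noise = rng.normal(0.0, gt.noise_sd_viability, size=(n_rep, len(doses)))
        readings = np.clip(v[None, :] + noise, 0.0, None) * _DMSO_SCALE
        for rep in range(n_rep):
            for j, dose in enumerate(doses):
                plate_rows.append((drug, cell, dose, rep + 1, readings[rep, j]))
        dmso = np.clip(
            1.0 + rng.normal(0.0, gt.noise_sd_viability, size=n_rep), 0.0, None
        ) * _DMSO_SCALE
        for rep in range(n_rep):
            plate_rows.append((drug, cell, np.nan, rep + 1, dmso[rep]))

    plate = pd.DataFrame(
        plate_rows,
        columns=["drug_id", "cell_line_id", "dose_molar", "replicate", "reading"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "drug_id", "cell_line_id", "lower", "upper", "log10_ic50", "hill",
            "latent_auc", "clamped",
        ],
    )
    return plate, truth
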