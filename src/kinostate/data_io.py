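"""CSV readers and writers for every table the pipeline touches.

All formats are long/wide UTF-8 CSV with a header row and molar dose units:

* profiling table (long): ``drug_id, kinase_id, value, mutant_flag`` — one row
  per measured drug-kinase pair in a single assay dialect;
* expression matrix (wide): first column ``cell_line_id``, remaining columns
  genes; on read every gene label is given the ``exp_`` prefix unless already
  present, keeping expression features distinct from same-named kinases;
* curve-parameter table (long): ``drug_id, cell_line_id, auc, ic50,
  ic50_capped`` — the dose-response summary per screened pair; ``ic50_capped``
  is an explicit flag instead of a sentinel concentration;
* plate viability table (long): ``drug_id, cell_line_id, dose_molar,
  replicate, reading`` with DMSO control wells encoded as ``dose_molar ==
  "DMSO"``;
* compound map: ``source_name, reference_id`` linking local drug names to a
  shared reference identifier for cross-dataset matching.

Readers validate rather than coerce: malformed numerics are rejected (row- or
file-level as documented per reader) and ``read(write(x)) == x`` on valid
tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import GroundTruth

logger = logging.getLogger(__name__)

EXPRESSION_PREFIX = "exp_"
KINOME_PREFIX = "act_"

_FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """A table violates its documented schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Profiling tables
# ---------------------------------------------------------------------------

def read_profiling_table(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read a long-format single-dose profiling table for one assay dialect.

    Rows with non-numeric values are dropped with a logged count; KINOMEscan
    values stay on their native 0-100 Percent Control scale (rescaling is the
    integration step's job).
    """
    if dialect not in ("kinobead", "kinomescan"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    _require_columns(df, ["drug_id", "kinase_id", "value"], path)
    if "mutant_flag" not in df.columns:
        df["mutant_flag"] = False
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        logger.warning("%s: dropped %d row(s) with non-numeric values", path, bad.sum())
    df = df.loc[~values.isna()].copy()
    df["value"] = values.loc[df.index].astype(float)
    df["mutant_flag"] = df["mutant_flag"].astype(bool)
    df["assay"] = dialect
    if (df["value"] < 0).any():
        raise FormatError(f"{path}: negative inhibition values")
    if df["kinase_id"].isna().any() or (df["kinase_id"].astype(str) == "").any():
        raise FormatError(f"{path}: empty kinase_id")
    return df[["drug_id", "kinase_id", "value", "assay", "mutant_flag"]].reset_index(drop=True)


def write_profiling_table(records: pd.DataFrame, path: str | Path) -> None:
    records[["drug_id", "kinase_id", "value", "mutant_flag"]].to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a cell line x gene TPM-like matrix; gene labels get ``exp_``."""
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))[1:]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"{path}: duplicate gene column(s) {dupes[:5]}")
    df = pd.read_csv(path, index_col=0)
    df.index.name = "cell_line_id"
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression values") from exc
    if values.isna().any().any():
        raise FormatError(f"{path}: missing expression values")
    if (values < 0).any().any():
        raise FormatError(f"{path}: negative expression values")
    values.columns = [
        c if str(c).startswith(EXPRESSION_PREFIX) else EXPRESSION_PREFIX + str(c)
        for c in values.columns
    ]
    return values


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Curve parameters
# ---------------------------------------------------------------------------

def read_curve_parameters(path: str | Path) -> pd.DataFrame:
    """Read a dose-response curve summary table keyed by (drug, cell line)."""
    df = pd.read_csv(path)
    _require_columns(df, ["drug_id", "cell_line_id", "auc", "ic50", "ic50_capped"], path)
    for col in ("auc", "ic50"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if (coerced.isna() & df[col].notna()).any():
            raise FormatError(f"{path}: non-numeric {col}")
        df[col] = coerced
    df["ic50_capped"] = df["ic50_capped"].astype(bool)
    if (df["auc"].dropna() < 0).any():
        raise FormatError(f"{path}: negative AUC")
    if df.duplicated(subset=["drug_id", "cell_line_id"]).any():
        raise FormatError(f"{path}: duplicate (drug_id, cell_line_id) keys")
    return df.reset_index(drop=True)


def write_curve_parameters(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["drug_id", "cell_line_id", "auc", "ic50", "ic50_capped"]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Plate viability
# ---------------------------------------------------------------------------

def read_plate_viability(path: str | Path) -> pd.DataFrame:
    """Read raw plate readings; DMSO wells are ``dose_molar == "DMSO"``.

    Returns a tidy frame with float ``dose_molar`` (NaN for DMSO wells) and an
    ``is_dmso`` column.  Every (drug, cell line) plate row must carry at least
    one DMSO well, otherwise normalization is impossible.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["drug_id", "cell_line_id", "dose_molar", "replicate", "reading"], path)
    dose_raw = df["dose_molar"].astype(str).str.strip()
    is_dmso = dose_raw.str.upper().eq("DMSO") | dose_raw.eq("") | dose_raw.eq("nan")
    dose = pd.to_numeric(df["dose_molar"], errors="coerce")
    bad = dose.isna() & ~is_dmso
    if bad.any():
        raise FormatError(f"{path}: non-numeric dose_molar outside DMSO wells")
    if (dose.dropna() <= 0).any():
        raise FormatError(f"{path}: non-positive dose")
    reading = pd.to_numeric(df["reading"], errors="coerce")
    if reading.isna().any():
        raise FormatError(f"{path}: non-numeric reading")
    out = pd.DataFrame(
        {
            "drug_id": df["drug_id"],
            "cell_line_id": df["cell_line_id"],
            "dose_molar": dose,
            "replicate": df["replicate"],
            "reading": reading.astype(float),
            "is_dmso": is_dmso.to_numpy(),
        }
    )
    no_dmso = out.groupby(["drug_id", "cell_line_id"])["is_dmso"].any()
    if not no_dmso.all():
        missing = no_dmso[~no_dmso].index.tolist()
        raise FormatError(f"{path}: no DMSO wells for plate row(s) {missing[:5]}")
    return out


def write_plate_viability(plate: pd.DataFrame, path: str | Path) -> None:
    out = plate.copy()
    dose = out["dose_molar"]
    out["dose_molar"] = np.where(
        dose.isna(), "DMSO", pd.Series(dose).map(lambda d: _FLOAT_FORMAT % d)
    )
    out[["drug_id", "cell_line_id", "dose_molar", "replicate", "reading"]].to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# Compound map, annotations, ground truth
# ---------------------------------------------------------------------------

def read_compound_map(path: str | Path) -> pd.DataFrame:
    """Read a (source_name, reference_id) mapping table."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["source_name", "reference_id"], path)
    if df["reference_id"].isna().any() or (df["reference_id"] == "").any():
        raise FormatError(f"{path}: empty reference_id")
    if df.duplicated(subset=["source_name"]).any():
        raise FormatError(f"{path}: a source_name maps to multiple reference ids")
    return df[["source_name", "reference_id"]].reset_index(drop=True)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a feature annotation table: feature_id, dark_flag, interactor_flag."""
    df = pd.read_csv(path)
    _require_columns(df, ["feature_id"], path)
    for col in ("dark_flag", "interactor_flag"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df.reset_index(drop=True)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "driver_kinases": list(gt.driver_kinases),
        "driver_weights": gt.driver_weights,
        "context_genes": {k: list(v) for k, v in gt.context_genes.items()},
        "noise_sd_latent": gt.noise_sd_latent,
        "noise_sd_viability": gt.noise_sd_viability,
        "seed": gt.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        driver_kinases=tuple(payload["driver_kinases"]),
        driver_weights={k: float(v) for k, v in payload["driver_weights"].items()},
        context_genes={k: tuple(v) for k, v in payload["context_genes"].items()},
        noise_sd_latent=float(payload["noise_sd_latent"]),
        noise_sd_viability=float(payload["noise_sd_viability"]),
        seed=int(payload["seed"]),
    )
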