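"""Combine two assay dialects into one kinome inhibition state matrix.

The kinobead dialect reports relative intensity (non-negative, occasionally
above 1); the KINOMEscan dialect reports Percent Control (0-100).  The fixed
order of operations is: drop recombinant-mutant assays, rescale Percent
Control to 0-1, truncate kinobead outliers at a high percentile (the cap must
reflect only kinobead intensities, so truncation precedes merging), then merge
into a dense drug x kinase matrix — duplicate measurements are mean-merged and
absent pairs are imputed with the no-interaction value 1.  The module also
quantifies cross-assay concordance on drug-kinase pairs measured by both
dialects, both as a raw-value Pearson correlation and as agreement of binary
"strong hit" calls at an inhibition cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import KINOME_PREFIX

logger = logging.getLogger(__name__)

__all__ = [
    "KinomeStateMatrix",
    "normalize_percent_control",
    "filter_mutant_assays",
    "truncate_outliers",
    "merge_assays",
    "match_compounds",
    "cross_assay_correlation",
    "hit_agreement",
]


@dataclass(frozen=True)
class KinomeStateMatrix:
    """Dense drug x kinase inhibition states with ``act_``-prefixed columns."""

    values: pd.DataFrame
    truncation_cap: float

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("kinome state matrix must have no missing entries")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def kinase_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_percent_control(records: pd.DataFrame) -> pd.DataFrame:
    """Divide KINOMEscan Percent Control values by 100; other rows untouched."""
    out = records.copy()
    mask = out["assay"] == "kinomescan"
    if (out.loc[mask, "value"] < 0).any():
        raise ValueError("negative Percent Control value")
    out.loc[mask, "value"] = out.loc[mask, "value"] / 100.0
    return out


def filter_mutant_assays(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records from recombinantly mutated kinase constructs."""
    n_mut = int(records["mutant_flag"].sum())
    out = records.loc[~records["mutant_flag"]].reset_index(drop=True)
    if n_mut:
        logger.info("filter_mutant_assays: removed %d mutant-assay record(s)", n_mut)
    if out.empty:
        logger.warning("filter_mutant_assays: no records remain")
    return out


def truncate_outliers(
    records: pd.DataFrame, percentile: float = 99.99
) -> tuple[pd.DataFrame, float]:
    """Cap extreme relative-intensity values at a high percentile.

    Applied to the kinobead dialect before merging, so that quantification
    artifacts (values far above 1) do not enter the combined matrix.  The cap
    is the linear-interpolation percentile of the observed values (numpy's
    default definition); everything above it is set to the cap.  Idempotent.
    """
    if records.empty:
        raise ValueError("cannot truncate an empty record set")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    cap = float(np.percentile(records["value"].to_numpy(), percentile, method="linear"))
    out = records.copy()
    n_over = int((out["value"] > cap).sum())
    out["value"] = out["value"].clip(upper=cap)
    if n_over:
        logger.info("truncate_outliers: capped %d value(s) at %.4g", n_over, cap)
    return out, cap


def merge_assays(
    kinobead_records: pd.DataFrame,
    kinomescan_records: pd.DataFrame,
    truncation_cap: float | None = None,
) -> KinomeStateMatrix:
    """Merge both dialects into a dense kinome state matrix.

    Expects KINOMEscan records already rescaled to 0-1, mutants filtered and
    kinobeads truncated.  Duplicate (drug, kinase) measurements within one
    dialect are mean-merged (logged), then overlapping pairs across dialects
    are mean-merged; pairs absent everywhere are imputed with the
    no-interaction value 1.  Kinase columns carry the ``act_`` prefix.
    """
    per_dialect = []
    for name, rec in (("kinobead", kinobead_records), ("kinomescan", kinomescan_records)):
        if rec.empty:
            continue
        n_dup = int(rec.duplicated(subset=["drug_id", "kinase_id"]).sum())
        if n_dup:
            logger.info("merge_assays: mean-merged %d within-%s duplicate(s)", n_dup, name)
        per_dialect.append(
            rec.groupby(["drug_id", "kinase_id"], as_index=False)["value"].mean()
        )
    if not per_dialect:
        raise ValueError("no records to merge")
    combined = (
        pd.concat(per_dialect, ignore_index=True)
        .groupby(["drug_id", "kinase_id"], as_index=False)["value"]
        .mean()
    )
    wide = combined.pivot(index="drug_id", columns="kinase_id", values="value")
    wide = wide.sort_index(axis=0).sort_index(axis=1).fillna(1.0)
    wide.columns = [KINOME_PREFIX + str(c) for c in wide.columns]
    wide.columns.name = None
    cap = truncation_cap if truncation_cap is not None else max(1.0, float(wide.max().max()))
    return KinomeStateMatrix(values=wide, truncation_cap=float(cap))


def match_compounds(map_a: pd.DataFrame, map_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two compound maps on reference_id; unmatched names logged.

    Duplicate reference ids within one map make the match ambiguous and raise.
    """
    for name, m in (("a", map_a), ("b", map_b)):
        if m.duplicated(subset=["reference_id"]).any():
            raise ValueError(f"duplicate reference ids in map {name}")
    merged = map_a.merge(map_b, on="reference_id", suffixes=("_a", "_b"))
    unmatched_a = set(map_a["source_name"]) - set(merged["source_name_a"])
    unmatched_b = set(map_b["source_name"]) - set(merged["source_name_b"])
    if unmatched_a or unmatched_b:
        logger.info(
            "match_compounds: %d unmatched in a, %d unmatched in b",
            len(unmatched_a),
            len(unmatched_b),
        )
    return merged[["reference_id", "source_name_a", "source_name_b"]].reset_index(drop=True)


def _shared_pairs(
    kinobead_records: pd.DataFrame, kinomescan_records: pd.DataFrame
) -> pd.DataFrame:
    """Per-pair dialect means for drug-kinase pairs measured in both assays."""
    kb = kinobead_records.groupby(["drug_id", "kinase_id"])["value"].mean()
    ks = kinomescan_records.groupby(["drug_id", "kinase_id"])["value"].mean()
    shared = pd.concat([kb.rename("kinobead"), ks.rename("kinomescan")], axis=1).dropna()
    return shared


def cross_assay_correlation(
    kinobead_records: pd.DataFrame, kinomescan_records: pd.DataFrame
) -> tuple[float, int]:
    """Pearson correlation of inhibition states over shared drug-kinase pairs.

    Both inputs must already be on the 0-1 fraction-of-control scale.
    """
    shared = _shared_pairs(kinobead_records, kinomescan_records)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared pairs, found {len(shared)}")
    if shared["kinobead"].std() == 0 or shared["kinomescan"].std() == 0:
        # degenerate but well-defined for identical constant vectors
        r = 1.0 if np.allclose(shared["kinobead"], shared["kinomescan"]) else np.nan
    else:
        r = float(stats.pearsonr(shared["kinobead"], shared["kinomescan"]).statistic)
    return r, int(len(shared))


def hit_agreement(
    kinobead_records: pd.DataFrame,
    kinomescan_records: pd.DataFrame,
    inhibition_cutoff: float = 0.8,
) -> float:
    """Fraction of shared pairs with concordant binary "strong hit" calls.

    A hit is a fraction-of-control value <= 1 - cutoff (the default 0.8 calls
    a hit at >= 80% inhibition).
    """
    shared = _shared_pairs(kinobead_records, kinomescan_records)
    if shared.empty:
        raise ValueError("no shared drug-kinase pairs")
    threshold = 1.0 - inhibition_cutoff
    hits_kb = shared["kinobead"] <= threshold
    hits_ks = shared["kinomescan"] <= threshold
    return float((hits_kb == hits_ks).mean())
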