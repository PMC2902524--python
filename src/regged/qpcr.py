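"""Delta-delta-Ct relative quantification normalised to multiple reference
genes.

Each target gene's Ct is normalised per sample to the mean of the reference
genes' Cts (dCt = Ct_target - mean reference Ct); group fold change is
2^(-ddCt) with ddCt = mean dCt(case) - mean dCt(reference group).  One PCR
cycle corresponds to one doubling, so fold changes live on the 2^x scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtTable

__all__ = ["normalize_ct", "fold_change"]


def normalize_ct(
    ct: CtTable,
    reference_genes: Sequence[str],
    mean: Literal["arithmetic", "geometric"] = "arithmetic",
    include_references: bool = False,
) -> pd.DataFrame:
    """Per-sample delta-Ct table.

    dCt = Ct_target - mean(reference Cts in that sample); the mean is
    arithmetic by default (geometric available).  Every reference gene must
    be measured in every sample; a missing measurement is an error naming
    the sample and gene.  Reference genes are excluded from the output
    unless ``include_references``.
    """
    refs = list(reference_genes)
    if not refs:
        raise ValueError("at least one reference gene is required")
    data = ct.data
    missing_refs = set(refs) - set(data["gene"])
    if missing_refs:
        raise ValueError(f"reference genes never measured: {sorted(missing_refs)}")

    ref_rows = data[data["gene"].isin(refs)]
    per_sample_refs = ref_rows.groupby("sample_id")["gene"].nunique()
    for sample in pd.unique(data["sample_id"]):
        n = int(per_sample_refs.get(sample, 0))
        if n < len(refs):
            measured = set(ref_rows.loc[ref_rows["sample_id"] == sample, "gene"])
            absent = sorted(set(refs) - measured)
            raise ValueError(f"sample {sample!r} is missing reference gene(s) {absent}")

    if mean == "arithmetic":
        ref_level = ref_rows.groupby("sample_id")["ct"].mean()
    elif mean == "geometric":
        ref_level = ref_rows.groupby("sample_id")["ct"].apply(lambda v: stats.gmean(v))
    else:
        raise ValueError(f"unknown mean {mean!r}")

    out = data if include_references else data[~data["gene"].isin(refs)]
    out = out.copy()
    out["delta_ct"] = out["ct"] - out["sample_id"].map(ref_level)
    return out[["sample_id", "group", "gene", "delta_ct"]].reset_index(drop=True)


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-gene group comparison on the delta-Ct scale."""

    table: pd.DataFrame  # index gene; columns delta_delta_ct, fold, pvalue

    def fold(self, gene: str) -> float:
        return float(self.table.loc[gene, "fold"])


def fold_change(
    delta_ct: pd.DataFrame,
    case_group: str,
    reference_group: str,
    with_pvalues: bool = True,
) -> FoldChangeResult:
    """Group-mean ddCt and fold change 2^(-ddCt) per gene.

    ddCt = mean dCt(case) - mean dCt(reference group).  Mann-Whitney U
    p-values on the per-sample dCt values are reported alongside when both
    groups have >= 2 samples for a gene.
    """
    for group in (case_group, reference_group):
        if not (delta_ct["group"] == group).any():
            raise ValueError(f"group {group!r} is empty or absent")

    rows = {}
    for gene, sub in delta_ct.groupby("gene", sort=True):
        case = sub.loc[sub["group"] == case_group, "delta_ct"].to_numpy()
        ref = sub.loc[sub["group"] == reference_group, "delta_ct"].to_numpy()
        if len(case) == 0 or len(ref) == 0:
            raise ValueError(f"gene {gene!r} lacks measurements in one of the groups")
        ddct = float(np.mean(case) - np.mean(ref))
        record = {"delta_delta_ct": ddct, "fold": float(2.0 ** (-ddct))}
        if with_pvalues:
            if len(case) >= 2 and len(ref) >= 2:
                record["pvalue"] = float(stats.mannwhitneyu(case, ref, alternative="two-sided").pvalue)
            else:
                record["pvalue"] = float("nan")
        rows[gene] = record
    return FoldChangeResult(table=pd.DataFrame.from_dict(rows, orient="index"))
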