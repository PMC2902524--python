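"""Digital-differential-display-style frequency comparison of pooled cDNA /
EST libraries.

Libraries are summed into two disjoint pools; for every transcript cluster a
2x2 table (cluster count vs. rest of pool, pool A vs. pool B) is tested with
a one-sided Fisher's exact test, the documented basis of DDD-style
enrichment calls.  No multiple-testing correction is applied by default,
mirroring the classic tool; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import LibraryCounts

logger = logging.getLogger(__name__)

__all__ = ["PooledCounts", "pool_libraries", "ddd_enrichment"]


@dataclass(frozen=True)
class PooledCounts:
    """Per-cluster sequence counts summed over each pool's libraries."""

    table: pd.DataFrame  # columns: pool_a, pool_b; index: cluster_id
    total_a: int
    total_b: int


def pool_libraries(
    counts: LibraryCounts, pool_a: Sequence[str], pool_b: Sequence[str]
) -> PooledCounts:
    """Sum library columns into two disjoint, non-empty pools."""
    a, b = list(pool_a), list(pool_b)
    if not a or not b:
        raise ValueError("both pools must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"pools overlap: {sorted(set(a) & set(b))}")
    unknown = (set(a) | set(b)) - set(counts.library_ids)
    if unknown:
        raise ValueError(f"unknown library IDs: {sorted(unknown)}")
    table = pd.DataFrame(
        {
            "pool_a": counts.counts[a].sum(axis=1),
            "pool_b": counts.counts[b].sum(axis=1),
        }
    )
    return PooledCounts(
        table=table,
        total_a=int(table["pool_a"].sum()),
        total_b=int(table["pool_b"].sum()),
    )


def _one_sided_fisher_greater(a: np.ndarray, b: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    # P(X >= a) for X ~ Hypergeom(population n_a + n_b, successes n_a,
    # draws a + b): identical to fisher_exact(..., alternative="greater").
    return stats.hypergeom.sf(a - 1, n_a + n_b, n_a, a + b)


def ddd_enrichment(
    pooled: PooledCounts,
    alpha: float = 0.05,
    direction: Literal["A-enriched", "B-enriched"] = "A-enriched",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Flag clusters over-represented in one pool.

    Returns a DataFrame indexed by cluster, sorted by p-value then cluster
    ID, with pooled counts, relative frequencies, the frequency ratio
    (zero counts replaced by 0.5 for the ratio only), the one-sided Fisher
    p-value (BH-adjusted q-value if requested) and the ``enriched`` flag at
    level ``alpha``.  Clusters absent from both pools are skipped with a log
    entry.
    """
    if pooled.total_a <= 0 or pooled.total_b <= 0:
        raise ValueError("both pool totals must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if direction not in ("A-enriched", "B-enriched"):
        raise ValueError(f"unknown direction {direction!r}")

    table = pooled.table
    absent = table.index[(table["pool_a"] == 0) & (table["pool_b"] == 0)]
    if len(absent):
        logger.info("ddd: skipping %d clusters absent from both pools", len(absent))
        table = table.drop(index=absent)

    a = table["pool_a"].to_numpy(dtype=np.int64)
    b = table["pool_b"].to_numpy(dtype=np.int64)
    n_a, n_b = pooled.total_a, pooled.total_b
    if direction == "A-enriched":
        p = _one_sided_fisher_greater(a, b, n_a, n_b)
        freq_num, freq_den, tot_num, tot_den = a, b, n_a, n_b
    else:
        p = _one_sided_fisher_greater(b, a, n_b, n_a)
        freq_num, freq_den, tot_num, tot_den = b, a, n_b, n_a

    # 0.5 substitution keeps the reported ratio finite; p-values use raw counts
    num = np.where(freq_num == 0, 0.5, freq_num) / tot_num
    den = np.where(freq_den == 0, 0.5, freq_den) / tot_den
    ratio = num / den

    p_eff = p
    if bh_correction:
        p_eff = multipletests(p, method="fdr_bh")[1]

    result = pd.DataFrame(
        {
            "count_a": a,
            "count_b": b,
            "freq_a": a / n_a,
            "freq_b": b / n_b,
            "ratio": ratio,
            "pvalue": p,
        },
        index=table.index,
    )
    if bh_correction:
        result["qvalue"] = p_eff
    result["enriched"] = (p_eff < alpha) & (ratio > 1.0)
    order = np.lexsort((result.index.to_numpy(), result["pvalue"].to_numpy()))
    return result.iloc[order]
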