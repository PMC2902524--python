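"""Glomerular-enrichment selection: calibrated subtraction, mean + k*SD
thresholding, and collapse of selected probesets to a non-redundant gene list.

The selection rule is deliberately simple: after calibrating the
tubulointerstitial aggregate profile onto the glomerular one, the
per-probeset difference (glom - adjusted tub) is computed; probesets whose
difference strictly exceeds mean + k*SD of all differences (k = 2 by
default, sample SD with n-1 denominator) are called glomerulus-enriched.
The mean and SD are taken over *all* probesets in a single pass, enriched
ones included — no iterative trimming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, aggregate_profile, apply_map, symmetric_calibration
from .io import AnnotationTable, ExpressionMatrix, GeneList

__all__ = [
    "DegenerateInputError",
    "EnrichmentResult",
    "CollapseReport",
    "enrichment_differences",
    "select_enriched",
    "collapse_to_genes",
    "glomerular_enrichment",
]


class DegenerateInputError(ValueError):
    """The difference distribution has zero spread; the k*SD rule is undefined."""


@dataclass(frozen=True)
class EnrichmentResult:
    """Differences, their summary statistics, the threshold, and the
    selected probesets (strictly above threshold)."""

    differences: pd.Series
    mean_diff: float
    sd_diff: float
    k: float
    threshold: float
    selected_probesets: tuple[str, ...]

    @property
    def n_selected(self) -> int:
        return len(self.selected_probesets)


@dataclass(frozen=True)
class CollapseReport:
    """Accounting of the probeset -> gene collapse.

    Invariant: n_selected == n_genes + n_dropped_unannotated + n_collapsed_redundant.
    """

    n_selected: int
    n_genes: int
    n_dropped_unannotated: int
    n_collapsed_redundant: int


def enrichment_differences(profile_glom: pd.Series, adjusted_tub: pd.Series) -> pd.Series:
    """Elementwise glomerular minus calibrated tubulointerstitial profile."""
    if set(profile_glom.index) != set(adjusted_tub.index):
        diff = set(profile_glom.index) ^ set(adjusted_tub.index)
        raise ValueError(
            f"profiles cover different probesets; symmetric difference: {sorted(diff)[:10]}"
        )
    out = profile_glom - adjusted_tub.reindex(profile_glom.index)
    out.name = "difference"
    return out


def select_enriched(differences: pd.Series, k: float = 2.0) -> EnrichmentResult:
    """Select probesets whose difference strictly exceeds mean + k*SD.

    SD is the sample standard deviation (n-1 denominator).  A constant
    difference vector raises :class:`DegenerateInputError` rather than
    silently selecting nothing.
    """
    if len(differences) < 2:
        raise ValueError("selection needs at least 2 probesets")
    values = differences.to_numpy(dtype=float)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("difference distribution has zero standard deviation")
    threshold = mean + k * sd
    selected = tuple(differences.index[values > threshold])
    return EnrichmentResult(
        differences=differences,
        mean_diff=mean,
        sd_diff=sd,
        k=float(k),
        threshold=threshold,
        selected_probesets=selected,
    )


def collapse_to_genes(
    selected_probesets: tuple[str, ...] | list[str],
    annotation: AnnotationTable,
    name: str = "enriched",
) -> tuple[GeneList, CollapseReport]:
    """Drop unannotated probesets and collapse redundant ones so each gene
    symbol appears once.

    Probesets missing from the annotation are treated as unannotated and
    counted with the dropped ones.  First occurrence (in selection order)
    of each symbol is kept.
    """
    symbols: list[str] = []
    seen: set[str] = set()
    dropped = 0
    collapsed = 0
    for pid in selected_probesets:
        sym = annotation.symbol_of(pid)
        if sym == "":
            dropped += 1
        elif sym in seen:
            collapsed += 1
        else:
            seen.add(sym)
            symbols.append(sym)
    genes = GeneList(name=name, symbols=tuple(symbols))
    report = CollapseReport(
        n_selected=len(selected_probesets),
        n_genes=len(genes),
        n_dropped_unannotated=dropped,
        n_collapsed_redundant=collapsed,
    )
    return genes, report


@dataclass(frozen=True)
class EnrichmentPipelineResult:
    calibration: CalibrationResult
    enrichment: EnrichmentResult
    genes: GeneList | None
    collapse: CollapseReport | None


def glomerular_enrichment(
    glom: ExpressionMatrix,
    tub: ExpressionMatrix,
    annotation: AnnotationTable | None = None,
    k: float = 2.0,
) -> EnrichmentPipelineResult:
    """End-to-end enrichment: aggregate, calibrate symmetrically, subtract,
    select at mean + k*SD, and (if an annotation is given) collapse to genes."""
    profile_glom = aggregate_profile(glom)
    profile_tub = aggregate_profile(tub)
    calibration = symmetric_calibration(profile_glom, profile_tub)
    adjusted = apply_map(calibration.final_map, profile_tub)
    differences = enrichment_differences(profile_glom, adjusted)
    result = select_enriched(differences, k=k)
    genes = collapse = None
    if annotation is not None:
        genes, collapse = collapse_to_genes(result.selected_probesets, annotation)
    return EnrichmentPipelineResult(
        calibration=calibration, enrichment=result, genes=genes, collapse=collapse
    )
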