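"""Synthetic stand-ins for the published glomerular gene lists.

The original supplementary gene lists of the five glomerular profiling
studies (and the derived neuronal / smooth-muscle / muscle-heart lists) are
distributed only as word-processor documents and are not redistributable
here.  This module builds *synthetic* stand-in lists, deterministic and
generated in code, that reproduce the published summary structure exactly:

* five study lists of the published sizes — 677 (Affymetrix compartment
  comparison, "REGGED"), 153 and 492 (the two SAGE studies), 102 (cDNA
  microarray), 205 (plasmid library);
* exactly six genes present in all five lists: CDKN1C, PTPRO, SPARC, PLAT,
  EMCN and IGFBP5;
* the 17 a-priori glomerular marker genes all contained in the 677-gene
  list;
* a 414-gene neuronal/brain-associated list sharing exactly 38 genes with
  the 677-gene list, a 90-gene smooth-muscle list sharing 9, and a 161-gene
  muscle/heart list sharing 17.

Genes that the publications name are kept under their real symbols; all
remaining entries are synthetic filler symbols (``RGD_``, ``SAGE1_``, ...),
so overlap and coverage arithmetic — not biology — is what these lists
exercise.
"""

from __future__ import annotations

from .io import GeneList
from .listcompare import GeneListCollection

__all__ = [
    "CORE_SIX",
    "GLOMERULAR_MARKERS",
    "synthetic_regged_list",
    "synthetic_five_study_collection",
    "synthetic_neuronal_list",
    "synthetic_smooth_muscle_list",
    "synthetic_muscle_heart_list",
    "glomerular_marker_list",
]

#: The six genes reported in all five glomerular datasets: podocyte-expressed
#: CDKN1C, PTPRO, SPARC and PLAT, the endothelial marker EMCN and the
#: mesangial IGFBP5.
CORE_SIX: tuple[str, ...] = ("CDKN1C", "PTPRO", "SPARC", "PLAT", "EMCN", "IGFBP5")

#: A-priori known glomerulus-enriched transcripts used as positive controls.
GLOMERULAR_MARKERS: tuple[str, ...] = (
    "CDKN1", "DAG1", "DDN", "EHD3", "MYH9", "NES", "NPHS1", "NPHS2", "PDPN",
    "PLA2R1", "PLCE1", "PODXL", "PTPRO", "SYNPO", "TCF21", "TJP1", "WT1",
)

# Designed shared blocks (disjoint from CORE_SIX and the markers).
_NEURON_SHARED = ("ROBO1", "ROBO2", "NRN1", "NPDC1") + tuple(
    f"NEUROSHARE{i:03d}" for i in range(1, 35)
)  # 38 genes
_SMOOTH_MUSCLE_SHARED = tuple(f"SMCSHARE{i:03d}" for i in range(1, 10))  # 9 genes
_MUSCLE_HEART_SHARED = ("GSN", "NEBL", "TNNC1") + tuple(
    f"MUSCLESHARE{i:03d}" for i in range(1, 15)
)  # 17 genes
# Five genes shared by four of the five studies (all but the cDNA microarray),
# so the Venn structure has a non-trivial 4-way region.
_QUAD_SHARED = tuple(f"QUADSHARE{i:03d}" for i in range(1, 6))


def _fill(prefix: str, existing: tuple[str, ...], size: int) -> tuple[str, ...]:
    n_fill = size - len(set(existing))
    if n_fill < 0:
        raise ValueError("designed genes exceed requested list size")
    return existing + tuple(f"{prefix}{i:04d}" for i in range(1, n_fill + 1))


def synthetic_regged_list() -> GeneList:
    """Synthetic 677-gene glomerulus-enriched list (REGGED stand-in)."""
    designed = (
        CORE_SIX
        + GLOMERULAR_MARKERS  # PTPRO repeats; GeneList construction de-duplicates
        + _NEURON_SHARED
        + _SMOOTH_MUSCLE_SHARED
        + _MUSCLE_HEART_SHARED
        + _QUAD_SHARED
    )
    return GeneList.from_iterable("REGGED", _fill("RGD", designed, 677))


def synthetic_five_study_collection() -> GeneListCollection:
    """Synthetic stand-ins for the five glomerular profiling studies.

    Sizes follow the publications (677 / 153 / 102 / 205 / 492); exactly the
    six core genes occur in all five lists.
    """
    sage1 = GeneList.from_iterable("SAGE_nephron", _fill("SAGE1", CORE_SIX + _QUAD_SHARED, 153))
    cdna = GeneList.from_iterable("cDNA_microarray", _fill("CDNA", CORE_SIX, 102))
    plasmid = GeneList.from_iterable("plasmid_library", _fill("PLAS", CORE_SIX + _QUAD_SHARED, 205))
    sage2 = GeneList.from_iterable("SAGE_glom", _fill("SAGE2", CORE_SIX + _QUAD_SHARED, 492))
    return GeneListCollection.from_lists(
        [synthetic_regged_list(), sage1, cdna, plasmid, sage2]
    )


def synthetic_neuronal_list() -> GeneList:
    """Synthetic 414-gene neuronal/brain-associated list (38 shared with the
    REGGED stand-in)."""
    return GeneList.from_iterable("neuronal_brain", _fill("NEURO", _NEURON_SHARED, 414))


def synthetic_smooth_muscle_list() -> GeneList:
    """Synthetic 90-gene coronary-artery smooth-muscle list (9 shared)."""
    return GeneList.from_iterable("smooth_muscle", _fill("SMC", _SMOOTH_MUSCLE_SHARED, 90))


def synthetic_muscle_heart_list() -> GeneList:
    """Synthetic 161-gene muscle/heart list (17 shared, including GSN, NEBL
    and TNNC1)."""
    return GeneList.from_iterable("muscle_heart", _fill("MUSC", _MUSCLE_HEART_SHARED, 161))


def glomerular_marker_list() -> GeneList:
    """The 17 a-priori glomerular marker genes as a GeneList."""
    return GeneList.from_iterable("glomerular_markers", GLOMERULAR_MARKERS)
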