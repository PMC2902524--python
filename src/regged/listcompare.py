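"""Cross-dataset gene-list comparison: presence/absence matrices, Venn-region
counts, pairwise overlaps and marker-coverage checks.

All comparisons operate on upper-cased gene symbols; no alias or identifier
mapping is attempted — published symbol lists are compared as distributed,
which is a documented limitation (nomenclature drift between studies lowers
apparent overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .io import GeneList

__all__ = [
    "GeneListCollection",
    "presence_matrix",
    "intersection_count",
    "venn_regions",
    "overlap",
    "marker_coverage",
    "MarkerCoverage",
]


@dataclass(frozen=True)
class GeneListCollection:
    """An ordered collection of uniquely-named gene lists."""

    lists: tuple[GeneList, ...]

    def __post_init__(self) -> None:
        if not self.lists:
            raise ValueError("collection must contain at least one gene list")
        names = [gl.name for gl in self.lists]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate list names: {names}")

    @classmethod
    def from_lists(cls, lists: Iterable[GeneList]) -> "GeneListCollection":
        return cls(lists=tuple(lists))

    @property
    def names(self) -> list[str]:
        return [gl.name for gl in self.lists]

    def __len__(self) -> int:
        return len(self.lists)

    def __getitem__(self, name: str) -> GeneList:
        for gl in self.lists:
            if gl.name == name:
                return gl
        raise KeyError(name)


def presence_matrix(collection: GeneListCollection) -> pd.DataFrame:
    """0/1 membership matrix over the union of symbols, one column per
    dataset plus a ``Sum`` column; rows sorted alphabetically."""
    union = sorted(set().union(*(gl.as_set() for gl in collection.lists)))
    data = {gl.name: [1 if s in gl.as_set() else 0 for s in union] for gl in collection.lists}
    df = pd.DataFrame(data, index=union, dtype=int)
    df["Sum"] = df.sum(axis=1)
    return df


def intersection_count(
    matrix: pd.DataFrame, min_datasets: int, exact: bool = False
) -> tuple[tuple[str, ...], int]:
    """Genes present in at least (or, with ``exact``, in exactly)
    ``min_datasets`` of the datasets.  Returns (genes, count)."""
    n_datasets = matrix.shape[1] - 1  # minus the Sum column
    if not 1 <= min_datasets <= n_datasets:
        raise ValueError(f"min_datasets must be in [1, {n_datasets}], got {min_datasets}")
    mask = matrix["Sum"] == min_datasets if exact else matrix["Sum"] >= min_datasets
    genes = tuple(matrix.index[mask])
    return genes, len(genes)


def venn_regions(collection: GeneListCollection) -> dict[frozenset[str], frozenset[str]]:
    """Exact Venn regions: for every non-empty subset of dataset names, the
    genes present in exactly those datasets (and no others).

    The region sizes sum to the size of the union.
    """
    names = collection.names
    sets = {name: collection[name].as_set() for name in names}
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = set()
    union = set().union(*sets.values())
    for gene in union:
        membership = frozenset(n for n in names if gene in sets[n])
        regions[membership].add(gene)
    return {k: frozenset(v) for k, v in regions.items()}


def overlap(list_a: GeneList, list_b: GeneList) -> GeneList:
    """Symmetric intersection of two gene lists (order follows ``list_a``)."""
    b = list_b.as_set()
    shared = tuple(s for s in list_a.symbols if s in b)
    return GeneList(name=f"{list_a.name}&{list_b.name}", symbols=shared)


@dataclass(frozen=True)
class MarkerCoverage:
    """Which validation markers were found in a target list."""

    found: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def coverage(self) -> float:
        return len(self.found) / (len(self.found) + len(self.missing))


def marker_coverage(markers: GeneList, target: GeneList) -> MarkerCoverage:
    """Fraction of known marker genes present in the target list.

    An empty marker list makes coverage undefined and raises ``ValueError``.
    """
    if len(markers) == 0:
        raise ValueError("coverage is undefined for an empty marker list")
    target_set = target.as_set()
    found = tuple(m for m in markers.symbols if m in target_set)
    missing = tuple(m for m in markers.symbols if m not in target_set)
    return MarkerCoverage(found=found, missing=missing)
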