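"""Readers, writers and domain containers for every tabular artifact in the
pipeline.

All canonical files are plain tab-delimited UTF-8 text with a header row.
Comma-delimited files are rejected, never silently re-interpreted.  Gene
symbols are compared case-insensitively throughout the package and are
therefore upper-cased on load.  Missing expression values are a load error,
not imputed: the enrichment procedure assumes a complete post-normalization
(log2 RMA-style) matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TableFormatError",
    "ExpressionMatrix",
    "AnnotationTable",
    "GeneList",
    "LibraryCounts",
    "CtTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_gene_list",
    "read_library_counts",
    "write_library_counts",
    "read_ct_table",
    "write_ct_table",
]


class TableFormatError(ValueError):
    """An input file violates the expected tab-delimited contract."""


def _read_text_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise TableFormatError(f"{path}: file is empty")
    return lines


def _split_header(line: str, path: str | Path) -> list[str]:
    if "\t" not in line and "," in line:
        raise TableFormatError(
            f"{path}: header contains commas but no tabs; "
            "comma-delimited files are not accepted (canonical dialect is TSV)"
        )
    return line.split("\t")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A probeset x sample matrix of log2 expression values for one renal
    compartment (e.g. glomerulus or tubulointerstitium).

    ``data`` is indexed by probeset ID with one column per sample; values
    must be finite floats.
    """

    data: pd.DataFrame
    compartment_label: str

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate probeset IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample IDs: {dups}")
        if self.data.shape[1] == 0:
            raise TableFormatError("expression matrix has no samples")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = self.data.index[~np.isfinite(values).all(axis=1)].tolist()
            raise TableFormatError(f"non-finite expression values in probesets: {bad[:10]}")
        self.data = self.data.astype(float)

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_expression_matrix(path: str | Path, compartment_label: str) -> ExpressionMatrix:
    """Load a ``probeset_id<TAB>sample1<TAB>...`` matrix.

    Duplicate IDs, non-numeric cells and ragged rows raise
    :class:`TableFormatError` naming the offending line; nothing is dropped
    silently.
    """
    lines = _read_text_lines(path)
    header = _split_header(lines[0], path)
    sample_ids = header[1:]
    if not sample_ids:
        raise TableFormatError(f"{path}: header row has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        raise TableFormatError(f"{path}: duplicate sample IDs in header")

    n_fields = len(header)
    probeset_ids: list[str] = []
    seen: set[str] = set()
    rows = np.empty((len(lines) - 1, len(sample_ids)), dtype=float)
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise TableFormatError(
                f"{path}: line {lineno}: expected {n_fields} fields, found {len(fields)}"
            )
        pid = fields[0]
        if pid in seen:
            raise TableFormatError(f"{path}: line {lineno}: duplicate probeset ID {pid!r}")
        seen.add(pid)
        probeset_ids.append(pid)
        for j, cell in enumerate(fields[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} "
                    f"for probeset {pid!r}, sample {sample_ids[j]!r}"
                ) from None
            if not math.isfinite(v):
                raise TableFormatError(
                    f"{path}: line {lineno}: non-finite value for probeset {pid!r}"
                )
            rows[lineno - 2, j] = v
    data = pd.DataFrame(rows, index=probeset_ids, columns=sample_ids)
    return ExpressionMatrix(data=data, compartment_label=compartment_label)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probeset_id")


# ---------------------------------------------------------------------------
# Probeset -> gene symbol annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Mapping probeset ID -> gene symbol; the empty string marks an
    unannotated probeset.  Several probesets may share one symbol
    (platform redundancy)."""

    symbols: pd.Series  # index: probeset_id, values: upper-case symbol or ""

    def __post_init__(self) -> None:
        if self.symbols.index.has_duplicates:
            dups = self.symbols.index[self.symbols.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate probeset IDs in annotation: {dups}")
        self.symbols = self.symbols.fillna("").astype(str).str.upper()

    def symbol_of(self, probeset_id: str) -> str:
        """Symbol for a probeset; '' if unannotated or unknown."""
        return str(self.symbols.get(probeset_id, ""))

    def is_annotated(self, probeset_id: str) -> bool:
        return self.symbol_of(probeset_id) != ""

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_unannotated(self) -> int:
        return int((self.symbols == "").sum())

    @property
    def distinct_symbols(self) -> set[str]:
        return set(self.symbols[self.symbols != ""])


def read_annotation(path: str | Path) -> AnnotationTable:
    """Load a two-column ``probeset_id<TAB>gene_symbol`` table (header row).

    An empty or missing second field marks the probeset as unannotated.  A
    probeset listed twice with conflicting symbols is an error; an exact
    repeat is collapsed with a log message.
    """
    lines = _read_text_lines(path)
    _split_header(lines[0], path)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) > 2:
            raise TableFormatError(f"{path}: line {lineno}: expected 2 fields, found {len(fields)}")
        pid = fields[0]
        symbol = fields[1].strip().upper() if len(fields) == 2 else ""
        if pid in mapping:
            if mapping[pid] != symbol:
                raise TableFormatError(
                    f"{path}: line {lineno}: probeset {pid!r} annotated twice with "
                    f"conflicting symbols {mapping[pid]!r} and {symbol!r}"
                )
            logger.info("annotation: exact duplicate entry for %s collapsed", pid)
            continue
        mapping[pid] = symbol
    return AnnotationTable(symbols=pd.Series(mapping, dtype=str))


def write_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    annotation.symbols.rename("gene_symbol").to_csv(path, sep="\t", index_label="probeset_id")


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneList:
    """A named, ordered, case-normalized set of gene symbols."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"gene list {self.name!r} contains duplicates")
        if any(s != s.upper() for s in self.symbols):
            raise ValueError(f"gene list {self.name!r} contains non-upper-case symbols")

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[str]) -> "GeneList":
        seen: dict[str, None] = {}
        for s in symbols:
            s = s.strip().upper()
            if s:
                seen.setdefault(s)
        return cls(name=name, symbols=tuple(seen))

    def as_set(self) -> frozenset[str]:
        return frozenset(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return isinstance(symbol, str) and symbol.upper() in self.as_set()


def read_gene_list(path: str | Path, name: str) -> GeneList:
    """One symbol per line; blank lines ignored; an empty file yields an
    empty list with a warning, not an error."""
    text = Path(path).read_text(encoding="utf-8")
    symbols = [line.strip() for line in text.splitlines() if line.strip()]
    if not symbols:
        logger.warning("gene list %s (%s) is empty", name, path)
    return GeneList.from_iterable(name, symbols)


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_list.symbols) + "\n" if gene_list.symbols else "",
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# cDNA/EST library counts (digital differential display inputs)
# ---------------------------------------------------------------------------


@dataclass
class LibraryCounts:
    """Transcript-cluster x cDNA-library sequence counts.

    Rows are UniGene-style transcript clusters, columns are expression
    libraries; each cell is the number of sequences from that library
    assigned to that cluster.  Column sums are the library sizes.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise TableFormatError("duplicate cluster IDs in library counts")
        if self.counts.columns.has_duplicates:
            raise TableFormatError("duplicate library IDs in library counts")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                raise TableFormatError("library counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise TableFormatError("library counts must be non-negative")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_library_counts(path: str | Path) -> LibraryCounts:
    lines = _read_text_lines(path)
    header = _split_header(lines[0], path)
    libraries = header[1:]
    records: dict[str, list[int]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TableFormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        cid = fields[0]
        if cid in records:
            raise TableFormatError(f"{path}: line {lineno}: duplicate cluster ID {cid!r}")
        try:
            records[cid] = [int(c) for c in fields[1:]]
        except ValueError:
            raise TableFormatError(
                f"{path}: line {lineno}: non-integer count for cluster {cid!r}"
            ) from None
    df = pd.DataFrame.from_dict(records, orient="index", columns=libraries, dtype=np.int64)
    return LibraryCounts(counts=df)


def write_library_counts(counts: LibraryCounts, path: str | Path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="cluster_id")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold measurements.

    Columns: ``sample_id``, ``group`` (e.g. glomerulus / tubulointerstitium),
    ``gene``, ``ct``.  Ct values must be finite and inside ``ct_range``
    (PCR cycles; the default 5-40 brackets plausible real-time runs).
    """

    data: pd.DataFrame
    ct_range: tuple[float, float] = (5.0, 40.0)

    def __post_init__(self) -> None:
        required = ["sample_id", "group", "gene", "ct"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"Ct table missing columns: {missing}")
        ct = pd.to_numeric(self.data["ct"], errors="coerce")
        if ct.isna().any():
            raise TableFormatError("Ct table contains non-numeric Ct values")
        lo, hi = self.ct_range
        bad = self.data.loc[(ct < lo) | (ct > hi)]
        if len(bad):
            raise TableFormatError(
                f"Ct values outside plausible range [{lo}, {hi}]: "
                f"{bad[['sample_id', 'gene']].to_dict('records')[:5]}"
            )
        self.data = self.data.assign(ct=ct.astype(float)).reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene"]))


def read_ct_table(path: str | Path, ct_range: tuple[float, float] = (5.0, 40.0)) -> CtTable:
    lines = _read_text_lines(path)
    header = _split_header(lines[0], path)
    if header != ["sample_id", "group", "gene", "ct"]:
        raise TableFormatError(
            f"{path}: expected header 'sample_id\\tgroup\\tgene\\tct', got {header}"
        )
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    return CtTable(data=df, ct_range=ct_range)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
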