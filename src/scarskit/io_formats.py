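"""Readers and writers for the on-disk formats the pipeline touches.

Formats
-------
* expression matrices — dense TSV (genes as rows, one header row of cell
  identifiers) and sparse matrix-market triplets with gene/cell sidecar files
  (the CellRanger-style triplet layout);
* genomic intervals — BED (0-based, half-open), at least four columns,
  optional score and strand;
* gene-set libraries — GMT (set name, description, tab-separated members).

All readers validate strictly and raise :class:`FormatError` with file/line
context; nothing is silently dropped.  Read/write pairs are inverse up to the
documented normalisations (GMT member de-duplication, default strand ``.``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GenomicInterval",
    "GeneSetLibrary",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violated the format contract; the message carries location context."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes × cells matrix of non-negative expression values.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in ``cell_ids[j]``.
    Identifiers must be unique along each axis, and every value finite and
    non-negative; :meth:`validate` enforces this and is called on
    construction.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.cell_ids)
        if dup is not None:
            raise FormatError(f"duplicate cell id {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a dense genes × cells TSV (header row of cell ids, gene-id index)."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, header=0, comment="#",
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if frame.isna().any().any():
        row = frame.index[frame.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing or ragged value in row {row!r}")
    body = frame.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        row = frame.index[body.isna().any(axis=1)][0]
        raise FormatError(f"{path}: non-numeric value in row {row!r}")
    try:
        return ExpressionMatrix.from_frame(body)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a dense TSV with full ``repr`` precision so round-trips are exact."""
    frame = matrix.to_frame()
    frame.to_csv(Path(path), sep="\t", index_label="gene_id", float_format="%.17g")


def write_expression_mtx(matrix: ExpressionMatrix, prefix: str | Path) -> None:
    """Write a sparse matrix-market triplet ``<prefix>.mtx`` with id sidecars.

    Gene and cell identifiers go to ``<prefix>_genes.txt`` and
    ``<prefix>_cells.txt`` (one per line), since matrix-market itself carries
    no labels.
    """
    prefix = Path(prefix)
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(prefix) + ".mtx", sparse, precision=17)
    Path(str(prefix) + "_genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
    Path(str(prefix) + "_cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")


def read_expression_mtx(prefix: str | Path) -> ExpressionMatrix:
    """Read the triplet written by :func:`write_expression_mtx`."""
    prefix = Path(prefix)
    mtx_path = Path(str(prefix) + ".mtx")
    if not mtx_path.exists():
        raise FormatError(f"{mtx_path}: no such matrix-market file")
    values = scipy.io.mmread(str(mtx_path)).toarray()
    genes = Path(str(prefix) + "_genes.txt").read_text().splitlines()
    cells = Path(str(prefix) + "_cells.txt").read_text().splitlines()
    try:
        return ExpressionMatrix(genes, cells, values)
    except FormatError as exc:
        raise FormatError(f"{mtx_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Genomic intervals (BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-convention interval: 0-based start (inclusive), end exclusive."""

    chrom: str
    start: int
    end: int
    id: str
    strand: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"interval {self.id!r}: negative start {self.start}")
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"interval {self.id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path, one_based: bool = False) -> list[GenomicInterval]:
    """Read a BED file (≥4 tab-separated columns) into validated intervals.

    ``one_based=True`` converts a 1-based, fully-closed input dialect to the
    internal 0-based half-open convention at the boundary.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            score = 0.0
            if len(fields) >= 5 and fields[4] not in {"", "."}:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, strand=strand, score=score)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6, preserving interval order."""
    with open(Path(path), "w") as handle:
        for iv in intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{iv.score:g}\t{iv.strand}\n"
            )


def to_tss_intervals(genes: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse gene bodies to strand-aware single-bp transcription start sites.

    ``+`` and unstranded genes anchor at ``start``; ``-`` genes at ``end``.
    Used by the proximity analysis when the anchor is ``tss`` rather than the
    whole gene body.
    """
    out = []
    for g in genes:
        pos = g.start if g.strand in {"+", "."} else g.end - 1
        out.append(GenomicInterval(g.chrom, pos, pos + 1, g.id, strand=g.strand))
    return out


# ---------------------------------------------------------------------------
# Gene-set libraries (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetLibrary:
    """A named mapping of gene sets: ``name -> (description, members)``.

    Member lists are de-duplicated (first occurrence kept) and must be
    non-empty.
    """

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        deduped = list(dict.fromkeys(str(m) for m in members))
        if len(deduped) == 0:
            raise FormatError(f"gene set {name!r} has no members")
        self.sets[name] = (description, deduped)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT library; duplicate members within a set collapse with a warning."""
    path = Path(path)
    library = GeneSetLibrary()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected name, description and >=1 member"
                )
            name, description, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m != ""]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if len(set(members)) < len(members):
                logger.warning(
                    "%s:%d: gene set %r has duplicate members; collapsing",
                    path,
                    lineno,
                    name,
                )
            try:
                library.add(name, description, members)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return library


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(Path(path), "w") as handle:
        for name, (description, members) in library.items():
            handle.write("\t".join([name, description, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file, skipping blanks and ``#`` comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
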