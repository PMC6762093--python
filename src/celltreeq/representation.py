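"""Peak libraries and binary character matrices.

A ChIP-Seq peak library (one per cell-type) is a set of genomic intervals where
a histone mark was called present.  Two encodings turn a collection of
libraries into a binary character matrix whose rows are cell-types:

* **overlap representation** -- consider every peak from every library as a
  vertex of an interval graph (edge iff two intervals share at least one
  base).  Each connected component is an "interesting region" and becomes one
  column; a cell is 1 iff the row's library contributed at least one peak to
  the region.  This is the compact default.
* **windowing representation** -- tile each chromosome into fixed-size bins;
  a cell is 1 iff at least one peak of the library intersects the bin.

Coordinates follow the BED convention: 0-based, half-open.  Abutting
intervals ([0,10) and [10,20)) do *not* overlap.  Strand and peak scores are
ignored: the encoding is presence/absence only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PeakInterval",
    "PeakLibrary",
    "OverlapRegion",
    "BinaryMatrix",
    "PeakParseError",
    "MatrixParseError",
    "read_peaks",
    "write_bed",
    "overlap_regions",
    "overlap_matrix",
    "window_matrix",
    "concatenate_matrices",
    "write_matrix",
    "read_matrix",
    "write_regions",
]


class PeakParseError(ValueError):
    """Raised when a peak (BED/narrowPeak) file cannot be parsed."""


class MatrixParseError(ValueError):
    """Raised when a binary-matrix file cannot be parsed."""


@dataclass(frozen=True, order=True)
class PeakInterval:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")

    def overlaps(self, other: "PeakInterval") -> bool:
        """True iff the intervals share at least one base (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakLibrary:
    """One cell-type's peak intervals, grouped by chromosome.

    Overlapping peaks within a library are kept as read; merging them first
    does not change the overlap representation (a tested invariant).
    """

    def __init__(self, name: str, intervals: Iterable[PeakInterval] = ()) -> None:
        if not name:
            raise ValueError("library name must be non-empty")
        self.name = str(name)
        self._by_chrom: dict[str, list[PeakInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def intervals(self, chrom: str | None = None) -> list[PeakInterval]:
        if chrom is not None:
            return list(self._by_chrom.get(chrom, []))
        return [iv for c in self.chromosomes for iv in self._by_chrom[c]]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def merged(self) -> "PeakLibrary":
        """Return a copy with overlapping intervals within the library merged."""
        out: list[PeakInterval] = []
        for chrom in self.chromosomes:
            ivs = sorted(self._by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
            cur_s, cur_e = None, None
            for iv in ivs:
                if cur_s is None or iv.start >= cur_e:
                    if cur_s is not None:
                        out.append(PeakInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
                else:
                    cur_e = max(cur_e, iv.end)
            if cur_s is not None:
                out.append(PeakInterval(chrom, cur_s, cur_e))
        return PeakLibrary(self.name, out)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PeakLibrary({self.name!r}, {len(self)} intervals)"


@dataclass(frozen=True)
class OverlapRegion:
    """A connected component of the interval graph over all libraries."""

    chrom: str
    span_start: int
    span_end: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("region must have at least one member library")


class BinaryMatrix:
    """Rows = cell-types, columns = presence/absence characters (0/1)."""

    def __init__(self, row_labels: Sequence[str], data) -> None:
        labels = tuple(str(x) for x in row_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("row labels must be unique")
        arr = np.asarray(data, dtype=np.int8)
        if arr.ndim != 2:
            raise ValueError(f"matrix data must be 2-D, got shape {arr.shape}")
        if arr.shape[0] != len(labels):
            raise ValueError(
                f"{len(labels)} labels but {arr.shape[0]} data rows"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        self.row_labels = labels
        self.data = arr

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        try:
            i = self.row_labels.index(label)
        except ValueError:
            raise KeyError(f"no row labelled {label!r}") from None
        return self.data[i]

    def subset(self, labels: Sequence[str]) -> "BinaryMatrix":
        """Row-restricted matrix in the given label order."""
        idx = [self.row_labels.index(l) for l in labels]
        return BinaryMatrix(list(labels), self.data[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return self.row_labels == other.row_labels and np.array_equal(
            self.data, other.data
        )

    def __hash__(self):  # matrices are mutable via .data; not hashable
        raise TypeError("BinaryMatrix is not hashable")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"BinaryMatrix({self.n_rows} x {self.n_cols})"


_SKIP_PREFIXES = ("#", "track", "browser")


def read_peaks(path, name: str) -> PeakLibrary:
    """Read a BED/narrowPeak file into a :class:`PeakLibrary`.

    Only the first three columns (chrom, start, end) are used; narrowPeak's
    extra columns are ignored.  Comment, ``track`` and ``browser`` lines are
    skipped.  Malformed coordinates raise :class:`PeakParseError` naming the
    line number.
    """
    if not name:
        raise ValueError("library name must be non-empty")
    path = Path(path)
    intervals: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or any(line.startswith(p) for p in _SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PeakParseError(
                    f"{path} line {lineno}: expected at least 3 columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise PeakParseError(
                    f"{path} line {lineno}: non-integer coordinate"
                ) from None
            if start < 0 or start >= end:
                raise PeakParseError(
                    f"{path} line {lineno}: invalid interval [{start}, {end})"
                )
            intervals.append(PeakInterval(chrom, start, end))
    return PeakLibrary(name, intervals)


def write_bed(library: PeakLibrary, path) -> None:
    """Write a library as a 3-column BED file (sorted by position)."""
    with open(path, "w") as fh:
        for chrom in library.chromosomes:
            for iv in sorted(library.intervals(chrom)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _check_libraries(libraries: Sequence[PeakLibrary]) -> None:
    if not libraries:
        raise ValueError("at least one peak library is required")
    names = [lib.name for lib in libraries]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate library names: {sorted(names)}")


def overlap_regions(libraries: Sequence[PeakLibrary]) -> list[OverlapRegion]:
    """Connected components of the interval graph over all libraries' peaks.

    Per chromosome, every peak is a vertex and two peaks are adjacent iff
    they share at least one base; each connected component yields one
    :class:`OverlapRegion` whose members are the libraries contributing at
    least one peak.  Returned sorted by (chrom, span_start).
    """
    _check_libraries(libraries)
    regions: list[OverlapRegion] = []
    chroms = sorted({c for lib in libraries for c in lib.chromosomes})
    for chrom in chroms:
        events = sorted(
            (iv.start, iv.end, lib.name)
            for lib in libraries
            for iv in lib.intervals(chrom)
        )
        cur_s = cur_e = None
        members: set[str] = set()
        for s, e, nm in events:
            if cur_s is None or s >= cur_e:  # strict: abutting do not overlap
                if cur_s is not None:
                    regions.append(
                        OverlapRegion(chrom, cur_s, cur_e, frozenset(members))
                    )
                cur_s, cur_e, members = s, e, {nm}
            else:
                cur_e = max(cur_e, e)
                members.add(nm)
        if cur_s is not None:
            regions.append(OverlapRegion(chrom, cur_s, cur_e, frozenset(members)))
    return regions


def overlap_matrix(libraries: Sequence[PeakLibrary]) -> BinaryMatrix:
    """Overlap representation: one column per interesting region.

    Row order follows the input library order; columns are sorted by genomic
    position so the matrix is reproducible byte-for-byte.  No column is ever
    all-zero (every region has a contributing library).
    """
    regions = overlap_regions(libraries)
    labels = [lib.name for lib in libraries]
    data = np.zeros((len(labels), len(regions)), dtype=np.int8)
    for j, region in enumerate(regions):
        for i, nm in enumerate(labels):
            if nm in region.members:
                data[i, j] = 1
    return BinaryMatrix(labels, data)


def window_matrix(
    libraries: Sequence[PeakLibrary],
    bin_size: int,
    chrom_sizes: Mapping[str, int],
) -> BinaryMatrix:
    """Windowing representation: one column per fixed-size genomic bin."""
    _check_libraries(libraries)
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    for lib in libraries:
        for chrom in lib.chromosomes:
            if chrom not in chrom_sizes:
                raise ValueError(
                    f"chromosome {chrom!r} (library {lib.name}) not in chrom_sizes"
                )
    chroms = sorted(chrom_sizes)
    n_bins = {c: max(1, math.ceil(chrom_sizes[c] / bin_size)) for c in chroms}
    offsets = {}
    total = 0
    for c in chroms:
        offsets[c] = total
        total += n_bins[c]
    labels = [lib.name for lib in libraries]
    data = np.zeros((len(labels), total), dtype=np.int8)
    for i, lib in enumerate(libraries):
        for chrom in lib.chromosomes:
            off, nb = offsets[chrom], n_bins[chrom]
            for iv in lib.intervals(chrom):
                b0 = min(iv.start // bin_size, nb - 1)
                b1 = min((iv.end - 1) // bin_size, nb - 1)
                data[i, off + b0 : off + b1 + 1] = 1
    return BinaryMatrix(labels, data)


def concatenate_matrices(matrices: Sequence[BinaryMatrix]) -> BinaryMatrix:
    """Combined (supermatrix) analysis: column-wise concatenation.

    Only cell-types present in *every* input matrix are kept (row order from
    the first matrix); dropped labels are reported to the log.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to concatenate")
    shared = set(matrices[0].row_labels)
    for m in matrices[1:]:
        shared &= set(m.row_labels)
    if not shared:
        raise ValueError("matrices share no row labels")
    dropped = sorted(
        {l for m in matrices for l in m.row_labels if l not in shared}
    )
    if dropped:
        logger.info("concatenate_matrices: dropping non-shared labels %s", dropped)
    order = [l for l in matrices[0].row_labels if l in shared]
    blocks = [m.subset(order).data for m in matrices]
    return BinaryMatrix(order, np.hstack(blocks))


def write_matrix(matrix: BinaryMatrix, path, format: str = "phylip") -> None:
    """Write a matrix as relaxed sequential PHYLIP or 0/1-alphabet FASTA."""
    path = Path(path)
    if format == "phylip":
        for label in matrix.row_labels:
            if any(ch.isspace() for ch in label):
                raise ValueError(
                    f"label {label!r} contains whitespace; not writable as phylip"
                )
        with open(path, "w") as fh:
            fh.write(f"{matrix.n_rows} {matrix.n_cols}\n")
            for label in matrix.row_labels:
                row = "".join(str(int(v)) for v in matrix.data[matrix.row_labels.index(label)])
                fh.write(f"{label}  {row}\n")
    elif format == "fasta01":
        records = [
            SeqRecord(Seq("".join(str(int(v)) for v in matrix.row(l))), id=l, description="")
            for l in matrix.row_labels
        ]
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(path, format: str = "phylip") -> BinaryMatrix:
    """Inverse of :func:`write_matrix`; round-trip identity is guaranteed."""
    path = Path(path)
    if format == "phylip":
        labels: list[str] = []
        rows: list[str] = []
        n = ncols = None
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if n is None:
                    parts = line.split()
                    if len(parts) != 2:
                        raise MatrixParseError(
                            f"{path} line {lineno}: expected 'n_rows n_cols' header"
                        )
                    try:
                        n, ncols = int(parts[0]), int(parts[1])
                    except ValueError:
                        raise MatrixParseError(
                            f"{path} line {lineno}: non-integer header"
                        ) from None
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise MatrixParseError(
                        f"{path} line {lineno}: expected 'label sequence'"
                    )
                labels.append(parts[0])
                rows.append("".join(parts[1:]))
        if n is None:
            raise MatrixParseError(f"{path}: missing phylip header")
        if len(labels) != n:
            raise MatrixParseError(
                f"{path}: header declares {n} rows, found {len(labels)}"
            )
        return _rows_to_matrix(path, labels, rows, ncols)
    if format == "fasta01":
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq))
        if not labels:
            raise MatrixParseError(f"{path}: no FASTA records")
        return _rows_to_matrix(path, labels, rows, len(rows[0]))
    raise ValueError(f"unknown matrix format {format!r}")


def _rows_to_matrix(path, labels, rows, ncols) -> BinaryMatrix:
    data = np.zeros((len(labels), ncols), dtype=np.int8)
    for i, (label, row) in enumerate(zip(labels, rows)):
        if len(row) != ncols:
            raise MatrixParseError(
                f"{path}: row {label!r} has {len(row)} characters, expected {ncols}"
            )
        for j, ch in enumerate(row):
            if ch == "1":
                data[i, j] = 1
            elif ch != "0":
                raise MatrixParseError(
                    f"{path}: row {label!r} position {j + 1}: "
                    f"unexpected character {ch!r}"
                )
    return BinaryMatrix(labels, data)


def write_regions(regions: Sequence[OverlapRegion], path, header: str | None = None) -> None:
    """Region table as TSV: chrom, span_start, span_end, comma-joined members."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("chrom\tspan_start\tspan_end\tmembers\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.span_start}\t{r.span_end}\t{','.join(sorted(r.members))}\n"
            )
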