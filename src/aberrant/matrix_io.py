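"""Tab-separated count/score matrix I/O and count-based gene filtering.

The on-disk dialect is the ubiquitous gene-expression table: a header row
whose first cell is an arbitrary label followed by sample identifiers, then
one row per gene (gene identifier first, counts/scores after), tab-delimited,
UTF-8, no quoting.  Files ending in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountMatrix",
    "RealMatrix",
    "MatrixFormatError",
    "RaggedRowError",
    "NonNumericValueError",
    "NegativeCountError",
    "DuplicateIdError",
    "MatrixShapeError",
    "read_counts",
    "read_reals",
    "write_matrix",
    "filter_zero_genes",
]


class MatrixFormatError(ValueError):
    """Base class for malformed matrix files or invalid matrix contents."""


class RaggedRowError(MatrixFormatError):
    """A data row has a different number of fields than the header."""


class NonNumericValueError(MatrixFormatError):
    """A count/score field could not be parsed as a number."""


class NegativeCountError(MatrixFormatError):
    """A count field is negative."""


class DuplicateIdError(MatrixFormatError):
    """Gene or sample identifiers are not unique."""


class MatrixShapeError(MatrixFormatError):
    """Matrix violates the minimal-shape contract (J >= 2, N >= 2)."""


def _check_ids(ids: list[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise DuplicateIdError(f"duplicate {kind} identifier: {dup!r}")


@dataclass
class CountMatrix:
    """A J x N matrix of non-negative integer read counts.

    Attributes
    ----------
    genes : list of str
        Row (gene) identifiers, unique, order preserved.
    samples : list of str
        Column (sample) identifiers, unique, order preserved.
    values : ndarray of shape (J, N), integer dtype
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = np.asarray(self.values, dtype=np.int64)
            if not np.array_equal(as_int, self.values):
                raise NonNumericValueError("count values must be integral")
            self.values = as_int
        if self.values.ndim != 2:
            raise MatrixShapeError("values must be 2-dimensional")
        j, n = self.values.shape
        if j < 2 or n < 2:
            raise MatrixShapeError(f"need at least 2 genes and 2 samples, got {j}x{n}")
        if len(self.genes) != j or len(self.samples) != n:
            raise MatrixShapeError("identifier lists do not match value shape")
        _check_ids(self.genes, "gene")
        _check_ids(self.samples, "sample")
        if (self.values < 0).any():
            jj, ii = np.argwhere(self.values < 0)[0]
            raise NegativeCountError(
                f"negative count at gene {self.genes[jj]!r}, sample {self.samples[ii]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and np.array_equal(self.values, other.values)
        )


@dataclass
class RealMatrix:
    """A J x N matrix of finite reals with gene/sample identifiers."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise MatrixShapeError("values must be 2-dimensional")
        j, n = self.values.shape
        if len(self.genes) != j or len(self.samples) != n:
            raise MatrixShapeError("identifier lists do not match value shape")
        _check_ids(self.genes, "gene")
        _check_ids(self.samples, "sample")
        if not np.isfinite(self.values).all():
            jj, ii = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixFormatError(
                f"non-finite value at gene {self.genes[jj]!r}, sample {self.samples[ii]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _open_text(path: str | os.PathLike, mode: str) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8")


def _read_table(path: str | os.PathLike) -> tuple[list[str], list[str], list[list[str]]]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    with _open_text(path, "r") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixFormatError(f"{path}: empty file")
        samples = header.split("\t")[1:]
        width = len(samples)
        genes: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != width + 1:
                raise RaggedRowError(
                    f"{path}: line {lineno} has {len(fields) - 1} value fields, expected {width}"
                )
            genes.append(fields[0])
            rows.append(fields[1:])
    return samples, genes, rows


def _locate_bad_field(
    rows: list[list[str]], genes: list[str], samples: list[str], caster
) -> str:
    for j, row in enumerate(rows):
        for i, cell in enumerate(row):
            try:
                caster(cell)
            except ValueError:
                return (
                    f"non-numeric value {cell!r} at gene {genes[j]!r}, "
                    f"sample {samples[i]!r}"
                )
    return "non-numeric value"


def read_counts(path: str | os.PathLike) -> CountMatrix:
    """Parse a TSV count file into a :class:`CountMatrix`.

    Raises
    ------
    FileNotFoundError, RaggedRowError, NonNumericValueError,
    NegativeCountError, DuplicateIdError, MatrixShapeError
        One distinct error type per malformation, naming the offending cell
        where applicable.
    """
    samples, genes, rows = _read_table(path)
    try:
        values = np.array(rows, dtype=np.int64)
    except (ValueError, OverflowError):
        raise NonNumericValueError(
            f"{path}: " + _locate_bad_field(rows, genes, samples, int)
        ) from None
    return CountMatrix(genes=genes, samples=samples, values=values)


def read_reals(path: str | os.PathLike) -> RealMatrix:
    """Parse a TSV file of real-valued scores into a :class:`RealMatrix`."""
    samples, genes, rows = _read_table(path)
    try:
        values = np.array(rows, dtype=np.float64)
    except ValueError:
        raise NonNumericValueError(
            f"{path}: " + _locate_bad_field(rows, genes, samples, float)
        ) from None
    return RealMatrix(genes=genes, samples=samples, values=values)


def write_matrix(
    matrix: CountMatrix | RealMatrix,
    path: str | os.PathLike,
    label: str = "geneID",
) -> None:
    """Write a matrix in the fixed TSV dialect.

    Integer matrices are written verbatim; reals with 17 significant digits
    so that read-back reproduces them bit-for-bit at parse precision.
    """
    is_int = np.issubdtype(matrix.values.dtype, np.integer) or np.issubdtype(
        matrix.values.dtype, np.bool_
    )
    fmt = (lambda v: str(int(v))) if is_int else (lambda v: format(v, ".17g"))
    with _open_text(path, "w") as fh:
        fh.write(label + "\t" + "\t".join(matrix.samples) + "\n")
        for gene, row in zip(matrix.genes, matrix.values):
            fh.write(gene + "\t" + "\t".join(fmt(v) for v in row) + "\n")


def filter_zero_genes(counts: CountMatrix, max_zero_fraction: float = 0.75) -> CountMatrix:
    """Drop genes whose fraction of zero-count samples exceeds the threshold.

    A gene is retained iff ``(# samples with count 0) / N <= max_zero_fraction``,
    so the default 0.75 removes genes with zeros in *more than* 75% of samples.
    Gene order is preserved.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must lie in [0, 1]")
    zero_frac = (counts.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if keep.sum() < 2:
        raise MatrixShapeError(
            f"zero-count filter would retain {int(keep.sum())} genes (< 2)"
        )
    genes = [g for g, k in zip(counts.genes, keep) if k]
    return CountMatrix(genes=genes, samples=list(counts.samples), values=counts.values[keep])
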