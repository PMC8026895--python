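"""Labeled pairwise-value matrices and the file dialects that carry them.

Whole-genome relatedness pipelines exchange two table shapes: square
label×label matrices (pyANI-style ``percentage_identity`` /
``alignment_coverage`` TSVs, dDDH tables in the same dialect) and long
all-vs-all record lists (FastANI's five-column output).  Both are read into
:class:`LabeledMatrix`, the in-memory container the clustering stages
consume.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledMatrix",
    "LongRecord",
    "LongRecordSet",
    "MatrixFormatError",
    "read_square_matrix",
    "write_square_matrix",
    "read_long_records",
    "long_to_matrix",
    "comparison_plan",
]

KINDS = ("identity", "coverage", "distance")
SCALES = ("percent", "fraction")

#: tokens accepted as an explicit missing-value marker in matrix cells
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "N/A", "na", "None"})


class MatrixFormatError(ValueError):
    """A pairwise-matrix or record file violates its dialect."""


def _scale_max(scale: str) -> float:
    return 100.0 if scale == "percent" else 1.0


@dataclass
class LabeledMatrix:
    """Square pairwise-value table keyed by genome labels.

    ``values[i, j]`` is the measure from ``labels[i]`` to ``labels[j]``.
    Missing values are NaN and are treated downstream as "criterion not
    met" — absence of evidence never creates an edge.

    Parameters
    ----------
    labels : sequence of str
        Unique, non-empty genome labels; order is meaningful.
    values : (n, n) float array
        Pairwise values on the declared scale; NaN marks missing.
    kind : {'identity', 'coverage', 'distance'}
    scale : {'percent', 'fraction'}
        Percent means values in [0, 100]; fraction means [0, 1].
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "identity"
    scale: str = "percent"

    def __post_init__(self) -> None:
        self.labels = tuple(str(l) for l in self.labels)
        if not self.labels:
            raise ValueError("matrix must have at least one label")
        if any(not l for l in self.labels):
            raise ValueError("labels must be non-empty strings")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values must be {n}x{n} to match labels, got {self.values.shape}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.isinf(finite).any():
            raise ValueError("values must be finite or NaN")
        if self.kind in ("identity", "coverage") and finite.size:
            hi = _scale_max(self.scale)
            if finite.min() < 0 or finite.max() > hi + 1e-9:
                raise ValueError(
                    f"{self.kind} values outside [0, {hi}] for scale={self.scale}"
                )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def loc(self, a: str, b: str) -> float:
        """Value from label ``a`` to label ``b``."""
        return float(self.values[self.index(a), self.index(b)])

    def to_percent(self) -> "LabeledMatrix":
        """Return a copy on the percent scale (identity transform if already)."""
        if self.scale == "percent":
            return LabeledMatrix(self.labels, self.values.copy(), self.kind, "percent")
        return LabeledMatrix(self.labels, self.values * 100.0, self.kind, "percent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class LongRecord:
    query: str
    reference: str
    value: float
    numerator: int
    denominator: int


@dataclass
class LongRecordSet:
    """All-vs-all records in FastANI's long layout (query, ref, value, counts)."""

    records: list[LongRecord]
    scale: str = "percent"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.query, r.reference)
            if key in seen:
                raise ValueError(f"duplicate (query, reference) pair: {key}")
            seen.add(key)
            if r.numerator < 0 or r.denominator < 0 or r.numerator > r.denominator:
                raise ValueError(
                    f"counts must satisfy 0 <= numerator <= denominator, got "
                    f"{r.numerator}/{r.denominator} for {key}"
                )

    def __len__(self) -> int:
        return len(self.records)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _detect_scale(values: np.ndarray, diagonal_mask: np.ndarray | None = None) -> str:
    """Fraction if every finite off-diagonal value is <= 1.0, else percent."""
    vals = values
    if diagonal_mask is not None:
        vals = values[~diagonal_mask]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return "percent"
    return "fraction" if float(finite.max()) <= 1.0 else "percent"


def read_square_matrix(
    path: str | Path,
    kind: str = "identity",
    dialect: str = "tab-labeled",
    scale: str | None = None,
    strip_labels: bool = True,
) -> LabeledMatrix:
    """Read a labeled square matrix (pyANI-style TSV or CSV).

    The first row and first column carry genome labels; the corner cell is
    blank or a caption such as ``label``.  Row order is preserved; columns
    are aligned to the row order.  Scale is auto-detected (all finite
    off-diagonal values <= 1.0 means fraction) unless ``scale`` overrides.

    Raises
    ------
    MatrixFormatError
        Non-square body, duplicate labels, mismatched row/column label
        sets, or an unparseable cell (reported with its coordinates).
    """
    sep = "\t" if dialect == "tab-labeled" else ","
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split(sep)
    col_labels = [c.strip() if strip_labels else c for c in header[1:]]
    ncol = len(col_labels)
    row_labels: list[str] = []
    body = np.full((len(lines) - 1, ncol), np.nan)
    for i, ln in enumerate(lines[1:]):
        cells = ln.split(sep)
        if len(cells) - 1 != ncol:
            raise MatrixFormatError(
                f"{path}: row {i + 2} ({cells[0]!r}) has {len(cells) - 1} value "
                f"cells, expected {ncol} — matrix body is not square"
            )
        row_labels.append(cells[0].strip() if strip_labels else cells[0])
        for j, cell in enumerate(cells[1:]):
            tok = cell.strip()
            if tok in MISSING_TOKENS:
                continue
            try:
                body[i, j] = float(tok)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: unparseable cell {tok!r} at row {i + 2}, "
                    f"column {j + 2} (row label {cells[0]!r}, "
                    f"column label {col_labels[j]!r})"
                ) from None
    if len(row_labels) != ncol:
        raise MatrixFormatError(
            f"{path}: {len(row_labels)} rows but {ncol} columns — not square"
        )
    for seq, what in ((row_labels, "row"), (col_labels, "column")):
        if len(set(seq)) != len(seq):
            dupes = sorted({l for l in seq if seq.count(l) > 1})
            raise MatrixFormatError(f"{path}: duplicate {what} label(s): {dupes}")
    if set(row_labels) != set(col_labels):
        diff = sorted(set(row_labels) ^ set(col_labels))
        raise MatrixFormatError(
            f"{path}: row and column label sets differ: {diff}"
        )
    if col_labels != row_labels:  # align columns to row order
        perm = [col_labels.index(l) for l in row_labels]
        body = body[:, perm]
    if scale is None:
        n = len(row_labels)
        scale = _detect_scale(body, np.eye(n, dtype=bool))
    return LabeledMatrix(tuple(row_labels), body, kind=kind, scale=scale)


def write_square_matrix(m: LabeledMatrix, path: str | Path) -> None:
    """Write the tab-labeled square dialect; inverse of :func:`read_square_matrix`.

    Cells are formatted with 17 significant digits so values round-trip
    bit-exactly; missing values are written as ``NA``.
    """
    with _open_text(path, "wt") as fh:
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            cells = [
                "NA" if not np.isfinite(v) else format(float(v), ".17g")
                for v in m.values[i]
            ]
            fh.write(lab + "\t" + "\t".join(cells) + "\n")


def read_long_records(
    path: str | Path, strip_paths: bool = False, scale: str | None = None
) -> LongRecordSet:
    """Read FastANI-style long output: query, reference, value, num, denom.

    ``strip_paths`` drops directory components and the final extension from
    the query/reference labels (FastANI emits file paths).
    """
    records: list[LongRecord] = []
    with _open_text(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            cells = ln.split()
            if len(cells) != 5:
                raise MatrixFormatError(
                    f"{path}: line {lineno} has {len(cells)} columns, expected 5"
                )
            q, r, val, num, den = cells
            if strip_paths:
                q = Path(q).stem
                r = Path(r).stem
            try:
                records.append(
                    LongRecord(q, r, float(val), int(num), int(den))
                )
            except ValueError as e:
                raise MatrixFormatError(f"{path}: line {lineno}: {e}") from None
    values = np.array([r.value for r in records], dtype=float)
    if scale is None:
        scale = _detect_scale(values) if values.size else "percent"
    try:
        return LongRecordSet(records, scale=scale)
    except ValueError as e:
        raise MatrixFormatError(f"{path}: {e}") from None


def long_to_matrix(
    rs: LongRecordSet, missing_policy: str = "fill-floor", kind: str = "identity"
) -> LabeledMatrix:
    """Tabulate long records into a square matrix.

    Labels are the union of query and reference labels in first-appearance
    order.  Pairs never reported get 0 under ``fill-floor`` (guaranteeing
    no edge under any >= criterion) or NaN under ``absent-marker``.  The
    diagonal is set to the scale maximum.
    """
    if not rs.records:
        raise ValueError("record set is empty")
    if missing_policy not in ("fill-floor", "absent-marker"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    labels: list[str] = []
    seen: set[str] = set()
    for r in rs.records:
        for lab in (r.query, r.reference):
            if lab not in seen:
                seen.add(lab)
                labels.append(lab)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    fill = 0.0 if missing_policy == "fill-floor" else np.nan
    values = np.full((n, n), fill)
    for r in rs.records:
        values[idx[r.query], idx[r.reference]] = r.value
    np.fill_diagonal(values, _scale_max(rs.scale))
    return LabeledMatrix(tuple(labels), values, kind=kind, scale=rs.scale)


def comparison_plan(labels: Sequence[str]) -> list[tuple[str, str]]:
    """Ordered all-vs-all comparison plan over genome identifiers.

    Pairwise genome-identity tools compare every ordered (query, reference)
    pair including self-comparisons, so ``n`` genomes yield ``n**2``
    planned comparisons (520 genomes -> 270,400).
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    return [(q, r) for q in labels for r in labels]
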