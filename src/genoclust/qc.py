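"""Genome-quality and 16S-identity screening rules.

Two screens precede any genome-relatedness clustering:

* a **quality screen** over marker-gene completeness/redundancy estimates
  (consumed as upstream tabular output, e.g. from miComplete): genomes
  with weighted completeness <= 0.9 or weighted redundancy >= 1.1 are
  flagged as unreliable input for taxonomy;
* an **authenticity screen** over 16S rRNA genes extracted from the
  assemblies: short sequences (<= 400 nt ungapped) are removed, pairwise
  identities are computed from a pre-built alignment comparing only
  gap-free column pairs, and an assembly's identity is confirmed when its
  16S shares >= 99% identity with the type-strain reference (same OTU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .matrix import LabeledMatrix

__all__ = [
    "QCRecord",
    "AlignedSeqSet",
    "qc_flag",
    "read_qc_table",
    "length_filter",
    "ungapped_length",
    "pairwise_identity",
    "confirm_same_otu",
]

GAP_CHARS = frozenset("-.")
_UNAMBIGUOUS = frozenset(b"ACGT")


@dataclass(frozen=True)
class QCRecord:
    """Per-genome quality metadata from a marker-gene completeness tool."""

    accession: str
    organism: str
    length_mb: float
    contigs: int
    completeness: float
    redundancy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 1.0):
            raise ValueError(
                f"{self.accession}: completeness must be in [0, 1], "
                f"got {self.completeness}"
            )
        if self.redundancy < 0:
            raise ValueError(f"{self.accession}: redundancy must be >= 0")
        if self.contigs < 1:
            raise ValueError(f"{self.accession}: contigs must be >= 1")


@dataclass
class AlignedSeqSet:
    """Pre-aligned nucleotide sequences (equal-length rows over ACGTUN-. )."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows or not self.rows[0]:
            raise ValueError("alignment is empty")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(
                    f"row {self.ids[i]!r} has length {len(row)}, expected {width}"
                )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignedSeqSet":
        aln = AlignIO.read(str(path), "fasta")
        return cls([rec.id for rec in aln], [str(rec.seq) for rec in aln])

    @property
    def width(self) -> int:
        return len(self.rows[0])


def qc_flag(
    records: Sequence[QCRecord],
    completeness_max: float = 0.9,
    redundancy_min: float = 1.1,
) -> list[QCRecord]:
    """Flag genomes failing the quality screen, preserving input order.

    A record is flagged when completeness <= ``completeness_max`` OR
    redundancy >= ``redundancy_min`` (both bounds inclusive).
    """
    if not (0.0 <= completeness_max <= 1.0):
        raise ValueError("completeness_max must be in [0, 1]")
    if redundancy_min < 0:
        raise ValueError("redundancy_min must be >= 0")
    return [
        r
        for r in records
        if r.completeness <= completeness_max or r.redundancy >= redundancy_min
    ]


def read_qc_table(path: str | Path) -> list[QCRecord]:
    """Read a headered QC TSV: accession, organism, length_mb, contigs,
    completeness, redundancy (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    required = ["accession", "organism", "length_mb", "contigs", "completeness", "redundancy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        QCRecord(
            accession=str(row.accession),
            organism=str(row.organism),
            length_mb=float(row.length_mb),
            contigs=int(row.contigs),
            completeness=float(row.completeness),
            redundancy=float(row.redundancy),
        )
        for row in df.itertuples()
    ]


def ungapped_length(row: str) -> int:
    return sum(1 for ch in row if ch not in GAP_CHARS)


def length_filter(
    seqs: Iterable[tuple[str, int]], min_exclusive: int = 400
) -> list[tuple[str, int]]:
    """Drop sequences whose ungapped length is <= ``min_exclusive``.

    Short 16S fragments (<= 400 nt by default) carry too little signal for
    a reliable identity comparison and are removed before alignment
    analysis.
    """
    return [(sid, ln) for sid, ln in seqs if ln > min_exclusive]


def _encode(row: str) -> np.ndarray:
    # uppercase, U->T so RNA and DNA alignments compare identically
    return np.frombuffer(
        row.upper().replace("U", "T").encode("ascii"), dtype="S1"
    )


def pairwise_identity(
    a: AlignedSeqSet, complete_deletion: bool = False
) -> LabeledMatrix:
    """Percent identity between every pair of aligned sequences.

    By default each pair is compared over the columns where *both* rows
    carry a non-gap character (pairwise deletion); ``complete_deletion``
    instead restricts every comparison to columns gap-free across all
    rows.  A match requires equal unambiguous bases (A/C/G/T after U->T);
    N and other ambiguity codes count as compared-but-mismatched.  A pair
    with zero comparable columns is marked missing with a warning.
    """
    if len(a.rows) < 2:
        raise ValueError("need at least two sequences")
    if len(set(a.ids)) != len(a.ids):
        raise ValueError("sequence ids must be unique")
    enc = np.vstack([_encode(r) for r in a.rows])
    nongap = ~np.isin(enc, [b"-", b"."])
    if complete_deletion:
        keep = nongap.all(axis=0)
        enc = enc[:, keep]
        nongap = nongap[:, keep]
    n = len(a.ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    unamb = np.isin(enc, [b"A", b"C", b"G", b"T"])
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            compared = int(both.sum())
            if compared == 0:
                warnings.warn(
                    f"no comparable columns between {a.ids[i]!r} and "
                    f"{a.ids[j]!r}; identity marked missing",
                    stacklevel=2,
                )
                continue
            matches = int(
                (both & (enc[i] == enc[j]) & unamb[i] & unamb[j]).sum()
            )
            values[i, j] = values[j, i] = 100.0 * matches / compared
    return LabeledMatrix(tuple(a.ids), values, kind="identity", scale="percent")


def confirm_same_otu(identity_percent: float, threshold: float = 99.0) -> bool:
    """Same operational taxonomic unit when 16S identity >= threshold (%)."""
    if not (0.0 <= identity_percent <= 100.0):
        raise ValueError("identity must be a percentage in [0, 100]")
    return identity_percent >= threshold
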