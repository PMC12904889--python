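"""Partitioned supermatrix: concatenation, gappy trimming, serialization.

The supermatrix concatenates per-locus alignments row-wise by genome; a
genome absent from a locus is padded with a gap run of that locus's width.
Columns whose gap fraction strictly exceeds the gappyness threshold
(default 0.05) are trimmed, with a :class:`ColumnMap` recording survivors
so partitions stay consistent.

For recombination inference the matrix is serialized as a single-block XMFA
dialect in which gene partitions are separated by fixed-length gap spacers
(default 1000 columns); :class:`XmfaMap` is the invertible coordinate map
between XMFA columns and matrix columns, needed to translate inferred
recombinant intervals back onto the matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import ValidationError
from .harvest import NUCLEOTIDE
from .locus_align import LocusAlignment

DEFAULT_GAPPY_THRESHOLD = 0.05
DEFAULT_SPACER_LEN = 1000

#: Sentinel returned by :func:`xmfa_to_matrix_coord` for spacer columns.
SPACER = None

GAP = "-"
#: Characters counted as gaps when computing column gappyness; '?' is a
#: missing-data code some tools emit for nucleotide alignments.
GAP_CHARS = frozenset({"-", "?"})


@dataclass(frozen=True)
class Partition:
    """One locus's column span in the supermatrix, 0-based half-open."""

    target: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"partition {self.target}: invalid span [{self.start},{self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class Supermatrix:
    """Concatenated alignment with a partition table and fixed row order."""

    rows: dict[str, str]  # genome id -> residues, insertion-ordered
    partitions: list[Partition]
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("supermatrix has no rows")
        width = sum(p.width for p in self.partitions)
        for g, seq in self.rows.items():
            if len(seq) != width:
                raise ValidationError(
                    f"row {g} has length {len(seq)}, expected {width} "
                    f"(sum of partition widths)"
                )
        pos = 0
        for p in self.partitions:
            if p.start != pos:
                raise ValidationError(
                    f"partitions not contiguous at {p.target} "
                    f"(starts {p.start}, expected {pos})"
                )
            pos = p.end

    @property
    def width(self) -> int:
        return sum(p.width for p in self.partitions)

    @property
    def genomes(self) -> list[str]:
        return list(self.rows.keys())

    def to_array(self) -> np.ndarray:
        """Rows as a (n_genomes, width) array of single characters."""
        return np.array([list(seq) for seq in self.rows.values()])


@dataclass
class ColumnMap:
    """Original column indices surviving a trim, strictly increasing."""

    kept: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.kept, self.kept[1:])):
            raise ValidationError("column map indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.kept)


@dataclass
class XmfaMap:
    """Layout of the spacer-separated XMFA serialization.

    Partition k occupies XMFA columns
    ``[offset_k, offset_k + width_k)`` with
    ``offset_k = sum(widths[:k]) + spacer_len * k``; everything between
    blocks is spacer.
    """

    spacer_len: int
    partitions: list[Partition]
    matrix_offsets: list[int] = field(init=False)
    xmfa_offsets: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.spacer_len < 0:
            raise ValidationError("spacer length must be >= 0")
        if not self.partitions:
            raise ValidationError("XMFA map needs at least one partition")
        self.matrix_offsets = [p.start for p in self.partitions]
        self.xmfa_offsets = [
            p.start + self.spacer_len * k for k, p in enumerate(self.partitions)
        ]

    @property
    def matrix_width(self) -> int:
        return sum(p.width for p in self.partitions)

    @property
    def xmfa_width(self) -> int:
        return self.matrix_width + self.spacer_len * (len(self.partitions) - 1)

    def to_matrix(self, xmfa_col: int) -> int | None:
        return xmfa_to_matrix_coord(self, xmfa_col)

    def to_xmfa(self, matrix_col: int) -> int:
        """Inverse map: matrix column -> XMFA column."""
        if not 0 <= matrix_col < self.matrix_width:
            raise ValidationError(f"matrix column {matrix_col} out of range")
        for k, p in enumerate(self.partitions):
            if p.start <= matrix_col < p.end:
                return self.xmfa_offsets[k] + (matrix_col - p.start)
        raise ValidationError(f"matrix column {matrix_col} not covered")  # pragma: no cover


def concatenate(
    alignments: Sequence[LocusAlignment], genomes: Sequence[str]
) -> Supermatrix:
    """Concatenate locus alignments over a retained, ordered genome list.

    Missing (genome, locus) pairs are padded with gap runs; rows for genomes
    not in the retained list (already excluded upstream) are dropped.
    """
    if not alignments:
        raise ValidationError("no alignments to concatenate")
    if not genomes:
        raise ValidationError("no genomes retained; nothing to concatenate")
    alphabet = alignments[0].alphabet
    parts: list[Partition] = []
    pieces: dict[str, list[str]] = {g: [] for g in genomes}
    pos = 0
    for aln in alignments:
        parts.append(Partition(aln.target, pos, pos + aln.length))
        pos += aln.length
        by_id = {r.id: r.residues for r in aln.rows}
        for g in genomes:
            pieces[g].append(by_id.get(g, GAP * aln.length))
    rows = {g: "".join(pieces[g]) for g in genomes}
    return Supermatrix(rows=rows, partitions=parts, alphabet=alphabet)


def column_gappyness(sm: Supermatrix, col: int) -> float:
    """Gap fraction of one column."""
    if not 0 <= col < sm.width:
        raise ValidationError(f"column {col} out of range [0,{sm.width})")
    gaps = sum(1 for seq in sm.rows.values() if seq[col] in GAP_CHARS)
    return gaps / len(sm.rows)


def trim_gappy(
    sm: Supermatrix, threshold: float = DEFAULT_GAPPY_THRESHOLD
) -> tuple[Supermatrix, ColumnMap]:
    """Remove columns with gappyness strictly above the threshold.

    Partitions are recomputed from surviving-column counts; a partition
    trimmed away entirely is removed from the table.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"gappy threshold must be in [0,1], got {threshold}")
    arr = sm.to_array()
    gappy = np.isin(arr, list(GAP_CHARS)).mean(axis=0)
    kept_mask = gappy <= threshold
    kept = np.flatnonzero(kept_mask)
    if kept.size == 0:
        raise ValidationError("alignment fully trimmed: no column survived")
    new_parts: list[Partition] = []
    pos = 0
    for p in sm.partitions:
        surviving = int(kept_mask[p.start:p.end].sum())
        if surviving:
            new_parts.append(Partition(p.target, pos, pos + surviving))
            pos += surviving
    trimmed_arr = arr[:, kept]
    rows = {
        g: "".join(trimmed_arr[i]) for i, g in enumerate(sm.rows)
    }
    trimmed = Supermatrix(rows=rows, partitions=new_parts, alphabet=sm.alphabet)
    return trimmed, ColumnMap(kept=[int(c) for c in kept])


def _to_bio_alignment(sm: Supermatrix) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        BioSeqRecord(Seq(seq), id=g, description="") for g, seq in sm.rows.items()
    )


def write_fasta(sm: Supermatrix, path: str | os.PathLike) -> Path:
    path = Path(path)
    SeqIO.write(
        (BioSeqRecord(Seq(seq), id=g, description="") for g, seq in sm.rows.items()),
        path,
        "fasta",
    )
    return path


def read_fasta(path: str | os.PathLike, partitions: list[Partition] | None = None,
               alphabet: str = NUCLEOTIDE) -> Supermatrix:
    """Read an alignment FASTA back into a Supermatrix.

    Without a partition table the whole width becomes one partition.
    """
    rows = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    if not rows:
        raise ValidationError(f"{path} contains no records")
    if partitions is None:
        width = len(next(iter(rows.values())))
        partitions = [Partition("all", 0, width)]
    return Supermatrix(rows=rows, partitions=partitions, alphabet=alphabet)


def write_clustal(sm: Supermatrix, path: str | os.PathLike) -> Path:
    """Interleaved clustal output: ``CLUSTAL`` header, 60-column blocks."""
    path = Path(path)
    pad = max(len(g) for g in sm.rows) + 3
    with open(path, "w") as fh:
        fh.write("CLUSTAL multiple sequence alignment\n\n")
        for start in range(0, sm.width, 60):
            for g, seq in sm.rows.items():
                fh.write(f"{g:<{pad}}{seq[start:start + 60]}\n")
            fh.write("\n")
    return path


def read_clustal(path: str | os.PathLike) -> dict[str, str]:
    """Read an interleaved clustal file back to {id: residues}."""
    aln = AlignIO.read(path, "clustal")
    return {rec.id: str(rec.seq) for rec in aln}


def write_partition_table(sm: Supermatrix, path: str | os.PathLike) -> Path:
    """Tab-delimited partition table, 1-based inclusive coordinates."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("target\tstart\tend\n")
        for p in sm.partitions:
            fh.write(f"{p.target}\t{p.start + 1}\t{p.end}\n")
    return path


def write_xmfa(
    sm: Supermatrix,
    path: str | os.PathLike,
    spacer_len: int = DEFAULT_SPACER_LEN,
) -> tuple[Path, XmfaMap]:
    """Serialize with ``spacer_len`` gap characters between gene partitions.

    One record per genome; record width = matrix width +
    spacer_len * (n_partitions - 1).  With a single partition there is no
    spacer at all.
    """
    if not sm.partitions:
        raise ValidationError("supermatrix has no partitions")
    if spacer_len < 0:
        raise ValidationError("spacer length must be >= 0")
    path = Path(path)
    xmap = XmfaMap(spacer_len=spacer_len, partitions=list(sm.partitions))
    spacer = GAP * spacer_len
    with open(path, "w") as fh:
        for g, seq in sm.rows.items():
            blocks = [seq[p.start:p.end] for p in sm.partitions]
            body = spacer.join(blocks)
            fh.write(f">{g}:1-{len(body)} + concatenated_orthologs\n")
            for i in range(0, len(body), 80):
                fh.write(body[i:i + 80] + "\n")
        fh.write("=\n")
    return path, xmap


def xmfa_to_matrix_coord(xmap: XmfaMap, xmfa_col: int) -> int | None:
    """Map a 0-based XMFA column to its matrix column, or SPACER (None)."""
    if not 0 <= xmfa_col < xmap.xmfa_width:
        raise ValidationError(
            f"XMFA column {xmfa_col} out of range [0,{xmap.xmfa_width})"
        )
    for k, p in enumerate(xmap.partitions):
        off = xmap.xmfa_offsets[k]
        if xmfa_col < off:
            return SPACER
        if xmfa_col < off + p.width:
            return p.start + (xmfa_col - off)
    return SPACER  # pragma: no cover - trailing column is always in-block
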