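"""Recombination masking from ClonalFrameML importation intervals.

ClonalFrameML infers recombinant imports on the spacer-separated XMFA
alignment and reports them as 1-based inclusive (Node, Beg, End) rows in an
``importation_status`` file.  Intervals attributed to an internal node
apply to every descendant leaf (mirroring maskrc-svg).  Each interval is
mapped back to supermatrix coordinates through the XmfaMap — spans crossing
a spacer split into one sub-interval per touched partition, spans wholly
inside a spacer vanish — and the affected rows are overwritten with the
mask character ('N' by default, so masked sites stay distinguishable from
alignment gaps; existing gaps are left untouched).

Masking is nucleotide-only: ClonalFrameML models nucleotide substitution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import ParseError, ValidationError
from .harvest import NUCLEOTIDE
from .supermatrix import Supermatrix, XmfaMap
from .tree import Tree

DEFAULT_MASK_CHAR = "N"
DEFAULT_EMSIM = 100

IMPORTATION_HEADER = ("Node", "Beg", "End")


@dataclass(frozen=True)
class MaskInterval:
    """A recombinant span: node label plus 1-based inclusive XMFA columns."""

    node_label: str
    beg: int
    end: int

    def __post_init__(self) -> None:
        if self.beg < 1 or self.end < self.beg:
            raise ValidationError(
                f"invalid interval [{self.beg},{self.end}] for node {self.node_label!r}"
            )


@dataclass
class MaskReport:
    mask_char: str
    per_genome: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_genome.values())


def parse_importation_status(path: str | os.PathLike) -> list[MaskInterval]:
    """Parse a tab-delimited Node/Beg/End file into intervals."""
    path = Path(path)
    intervals: list[MaskInterval] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or tuple(lines[0].split("\t")[:3]) != IMPORTATION_HEADER:
        raise ParseError(
            f"{path}: line 1: expected header 'Node\\tBeg\\tEnd'"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 tab-delimited fields")
        node, beg_s, end_s = fields[0], fields[1], fields[2]
        try:
            beg, end = int(beg_s), int(end_s)
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-integer coordinates {beg_s!r}, {end_s!r}"
            ) from None
        if beg > end:
            raise ParseError(f"{path}: line {lineno}: Beg {beg} > End {end}")
        intervals.append(MaskInterval(node_label=node, beg=beg, end=end))
    return intervals


def resolve_node_to_leaves(tree: Tree, node_label: str) -> list[str]:
    """A leaf label maps to itself; an internal label to its descendant leaves."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == node_label:
            return [node_label]
    for node in tree.preorder_node_iter():
        if node.label == node_label or (
            node.taxon is not None and node.taxon.label == node_label
        ):
            return sorted(l.taxon.label for l in node.leaf_iter())
    raise ValidationError(f"node label {node_label!r} not found in tree")


def map_interval_to_matrix(
    interval: MaskInterval, xmap: XmfaMap
) -> list[tuple[int, int]]:
    """Map a 1-based inclusive XMFA interval to 0-based half-open matrix spans.

    Spacer columns are dropped; one sub-interval is returned per partition
    the span touches; a span entirely inside a spacer maps to nothing.
    """
    if interval.end > xmap.xmfa_width:
        raise ValidationError(
            f"interval [{interval.beg},{interval.end}] exceeds XMFA width "
            f"{xmap.xmfa_width}"
        )
    lo, hi = interval.beg - 1, interval.end  # 0-based half-open
    out: list[tuple[int, int]] = []
    for k, p in enumerate(xmap.partitions):
        off = xmap.xmfa_offsets[k]
        a = max(lo, off)
        b = min(hi, off + p.width)
        if a < b:
            out.append((p.start + (a - off), p.start + (b - off)))
    return out


def apply_mask(
    sm: Supermatrix,
    tree: Tree,
    intervals: Sequence[MaskInterval],
    xmap: XmfaMap,
    mask_char: str = DEFAULT_MASK_CHAR,
) -> tuple[Supermatrix, MaskReport]:
    """Overwrite recombinant spans with the mask character.

    Every interval's node is resolved to leaves; the mapped matrix columns
    of those rows are set to ``mask_char`` unless already a gap.  Width,
    row order and all other rows are unchanged.
    """
    if sm.alphabet != NUCLEOTIDE:
        raise ValidationError(
            "recombination masking applies to nucleotide supermatrices only"
        )
    report = MaskReport(mask_char=mask_char, per_genome={g: 0 for g in sm.genomes})
    rows = {g: list(seq) for g, seq in sm.rows.items()}
    for interval in intervals:
        leaves = resolve_node_to_leaves(tree, interval.node_label)
        spans = map_interval_to_matrix(interval, xmap)
        for genome in leaves:
            if genome not in rows:
                continue  # excluded genome; nothing to mask
            row = rows[genome]
            for a, b in spans:
                for col in range(a, b):
                    if row[col] != "-" and row[col] != mask_char:
                        row[col] = mask_char
                        report.per_genome[genome] += 1
    masked = Supermatrix(
        rows={g: "".join(r) for g, r in rows.items()},
        partitions=list(sm.partitions),
        alphabet=sm.alphabet,
    )
    return masked, report


def build_cfml_command(
    tree_path: str, xmfa_path: str, out_prefix: str, emsim: int = DEFAULT_EMSIM
) -> list[str]:
    """ClonalFrameML argument vector: EM algorithm, 100 pseudo-bootstraps."""
    if not str(tree_path) or not str(xmfa_path) or not str(out_prefix):
        raise ValidationError("tree, alignment and prefix paths must be non-empty")
    return [
        "ClonalFrameML",
        str(tree_path),
        str(xmfa_path),
        str(out_prefix),
        "-em", "true",
        "-emsim", str(emsim),
        "-xmfa_file", "true",
    ]
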