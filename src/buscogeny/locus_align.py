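"""Per-locus alignment: MAFFT command construction and validation.

Alignment itself is delegated to MAFFT behind the subprocess boundary; this
module builds the command (with automatic input-direction adjustment) and
validates the result.  MAFFT's ``--adjustdirection`` prepends ``_R_`` to the
id of any record it reverse-complemented; that prefix is stripped during
validation so downstream genome keying is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import AlignmentError, ValidationError
from .harvest import SeqRecord

REVERSED_PREFIX = "_R_"


@dataclass
class LocusAlignment:
    """One locus's aligned rows: one per genome, all the same length."""

    target: str
    rows: list[SeqRecord]
    alphabet: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError(f"alignment {self.target} has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"alignment {self.target} has ragged rows (lengths {sorted(lengths)})"
            )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"alignment {self.target} has duplicate row ids")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def genome_ids(self) -> list[str]:
        return [r.id for r in self.rows]


def build_aligner_command(multifasta_path: str, out_path: str) -> list[str]:
    """MAFFT argument vector; the aligned output goes to stdout (the
    executor redirects it to ``out_path``, carried as the final element)."""
    if not str(multifasta_path) or not str(out_path):
        raise ValidationError("aligner input and output paths must be non-empty")
    return ["mafft", "--auto", "--adjustdirection", str(multifasta_path), str(out_path)]


def validate_alignment(
    records: Sequence[SeqRecord], target: str = "locus"
) -> LocusAlignment:
    """Check equal lengths and unique ids; strip the aligner's ``_R_`` prefix."""
    if not records:
        raise ValidationError("cannot validate an empty alignment")
    normalized = []
    for rec in records:
        rid = rec.id
        if rid.startswith(REVERSED_PREFIX):
            rid = rid[len(REVERSED_PREFIX):]
        normalized.append(SeqRecord(id=rid, residues=rec.residues, alphabet=rec.alphabet))
    ref_len = len(normalized[0])
    for rec in normalized:
        if len(rec) != ref_len:
            raise AlignmentError(
                f"unaligned input: row {rec.id!r} has length {len(rec)}, "
                f"expected {ref_len}"
            )
    return LocusAlignment(target=target, rows=normalized, alphabet=normalized[0].alphabet)
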