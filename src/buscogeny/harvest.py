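"""Harvest single-copy BUSCO orthologs from per-genome result directories.

BUSCO writes, for every genome, the sequences of the ortholog targets it
found exactly once into a ``single_copy_busco_sequences`` directory (protein
as ``<target>.faa``, nucleotide as ``<target>.fna``).  This module reads the
lineage dataset's target list, collects each target's sequences across
genomes into a :class:`LocusSet`, and writes per-target multifasta files.
Record ids are rewritten from BUSCO's contig-derived headers to the genome
id, because every downstream step keys rows by genome.

Actual BUSCO execution is an external interface: :func:`build_busco_command`
only constructs the argument vector; the cli module runs it through the
subprocess boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import HarvestError, LineageDatasetError, ValidationError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NUC_CHARS = set("ACGTNacgtn-") | set("acgt")
_PROT_CHARS = set("ACDEFGHIKLMNPQRSTVWYBZJUOX*-") | set("acdefghiklmnpqrstvwybzjuox")

#: File suffix of the single-copy sequence files, per alphabet.
SEQ_SUFFIX = {PROTEIN: ".faa", NUCLEOTIDE: ".fna"}

SINGLE_COPY_DIRNAME = "single_copy_busco_sequences"
SCORES_CUTOFF_FILENAME = "scores_cutoff"


def genome_id_from_path(path: str | os.PathLike) -> str:
    """Genome id = filename with its (last) extension removed."""
    stem = Path(path).stem
    if not stem:
        raise ValidationError(f"cannot derive a genome id from {path!r}")
    return stem


@dataclass(frozen=True)
class SeqRecord:
    """One harvested sequence: genome id, residues, and alphabet."""

    id: str
    residues: str
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.id or any(c in self.id for c in " \t/\\"):
            raise ValidationError(f"invalid record id {self.id!r}")
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has empty residues")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = _NUC_CHARS if self.alphabet == NUCLEOTIDE else _PROT_CHARS
        bad = set(self.residues) - allowed
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains characters {sorted(bad)!r} "
                f"outside the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LocusSet:
    """All single-copy sequences of one target, at most one per genome."""

    target: str
    records: list[SeqRecord] = field(default_factory=list)
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"locus {self.target}: duplicate genome ids {dup}"
            )
        for r in self.records:
            if r.alphabet != self.alphabet:
                raise ValidationError(
                    f"locus {self.target}: record {r.id} has alphabet "
                    f"{r.alphabet}, expected {self.alphabet}"
                )

    @property
    def genome_ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def list_targets(lineage_dir: str | os.PathLike) -> list[str]:
    """Read the ortholog target ids from a lineage dataset directory.

    The first column of the tab-delimited ``scores_cutoff`` file is the
    target id.  Ids are deduplicated and returned sorted, so the order is
    deterministic and invariant to file row order.
    """
    lineage_dir = Path(lineage_dir)
    cutoff = lineage_dir / SCORES_CUTOFF_FILENAME
    if not cutoff.is_file():
        raise LineageDatasetError(
            f"lineage dataset invalid: {lineage_dir} does not contain the "
            f"expected {SCORES_CUTOFF_FILENAME!r} file"
        )
    targets = set()
    with open(cutoff) as fh:
        for line in fh:
            line = line.strip()
            if line:
                targets.add(line.split("\t")[0])
    if not targets:
        raise LineageDatasetError(f"{cutoff} lists no targets")
    return sorted(targets)


def build_busco_command(
    genome_path: str | os.PathLike,
    lineage_dir: str | os.PathLike,
    out_name: str,
    threads: int = 8,
    mode: str = "genome",
) -> list[str]:
    """Construct (without running) the BUSCO 5.x argument vector."""
    if not str(genome_path) or not str(lineage_dir) or not out_name:
        raise ValidationError("genome path, lineage dir and output name must be non-empty")
    if threads < 1:
        raise ValidationError(f"threads must be >= 1, got {threads}")
    return [
        "busco",
        "-i", str(genome_path),
        "-l", str(lineage_dir),
        "-o", out_name,
        "-m", mode,
        "-c", str(threads),
        "-f",
    ]


def _single_copy_dir(results_root: Path, genome: str) -> Path | None:
    genome_dir = results_root / genome
    # BUSCO 5.x canonical layout first, then any fallback location (the
    # layout drifted across 5.x minor versions).
    hits = sorted(genome_dir.glob(f"run_*/busco_sequences/{SINGLE_COPY_DIRNAME}"))
    if hits:
        return hits[0]
    hits = sorted(p for p in genome_dir.rglob(SINGLE_COPY_DIRNAME) if p.is_dir())
    return hits[0] if hits else None


def harvest_locus(
    results_root: str | os.PathLike,
    genomes: Sequence[str],
    target: str,
    seq_type: str = PROTEIN,
) -> LocusSet:
    """Collect one target's single-copy sequences across genomes.

    Genomes lacking the target file are silently absent from the returned
    set: absence is data, accounted for by the qc module.  A target file
    holding more than one sequence violates the single-copy premise and is
    an error.
    """
    if seq_type not in SEQ_SUFFIX:
        raise ValidationError(f"unknown seq_type {seq_type!r}")
    results_root = Path(results_root)
    suffix = SEQ_SUFFIX[seq_type]
    records = []
    for genome in genomes:
        sc_dir = _single_copy_dir(results_root, genome)
        if sc_dir is None:
            continue
        path = sc_dir / f"{target}{suffix}"
        if not path.is_file():
            continue
        try:
            seqs = list(SeqIO.parse(path, "fasta"))
        except (OSError, ValueError) as exc:
            raise HarvestError(
                f"cannot read {target} for genome {genome}: {exc}"
            ) from exc
        if not seqs:
            raise HarvestError(f"{path} is empty (genome {genome}, target {target})")
        if len(seqs) > 1:
            raise HarvestError(
                f"target {target} is not single-copy in genome {genome}: "
                f"{path} holds {len(seqs)} sequences"
            )
        records.append(SeqRecord(id=genome, residues=str(seqs[0].seq), alphabet=seq_type))
    return LocusSet(target=target, records=records, alphabet=seq_type)


def compile_multifasta(locus_set: LocusSet, out_path: str | os.PathLike) -> Path:
    """Write a locus set as a multifasta, one record per genome, 60-col wrapped."""
    if not locus_set.records:
        raise ValidationError(f"locus {locus_set.target} is empty; nothing to write")
    out_path = Path(out_path)
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="")
        for r in locus_set.records
    ]
    SeqIO.write(bio, out_path, "fasta")
    return out_path


def read_fasta(path: str | os.PathLike, alphabet: str = NUCLEOTIDE) -> list[SeqRecord]:
    """Read a FASTA file into this module's record type."""
    records = [
        SeqRecord(id=rec.id, residues=str(rec.seq), alphabet=alphabet)
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise HarvestError(f"{path} contains no FASTA records")
    return records


def harvest_all(
    results_root: str | os.PathLike,
    genomes: Sequence[str],
    targets: Iterable[str],
    seq_type: str = PROTEIN,
) -> list[LocusSet]:
    """Harvest every target; loci found in no genome are dropped."""
    sets = []
    for target in targets:
        ls = harvest_locus(results_root, genomes, target, seq_type)
        if len(ls):
            sets.append(ls)
    return sets
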