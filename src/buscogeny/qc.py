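"""Ortholog occupancy QC: presence/absence matrix, exclusion, bar plot.

A genome missing from too many loci would drag the trimmed supermatrix
length down for everyone, so genomes whose missing fraction strictly
exceeds the exclusion threshold (default 0.20) are dropped before
concatenation.  "Strictly exceeds" matters: a genome sitting exactly at
the threshold is retained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import ValidationError  # noqa: E402
from .harvest import LocusSet  # noqa: E402

DEFAULT_EXCLUDE_THRESHOLD = 0.20


@dataclass
class PresenceMatrix:
    """Genomes x targets boolean occupancy."""

    genomes: list[str]
    targets: list[str]
    present: np.ndarray  # bool, shape (n_genomes, n_targets)

    def __post_init__(self) -> None:
        if len(set(self.genomes)) != len(self.genomes):
            raise ValidationError("duplicate genome ids in presence matrix")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("duplicate target ids in presence matrix")
        if self.present.shape != (len(self.genomes), len(self.targets)):
            raise ValidationError(
                f"presence array shape {self.present.shape} does not match "
                f"{len(self.genomes)} genomes x {len(self.targets)} targets"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.present, index=self.genomes, columns=self.targets)

    def counts(self) -> dict[str, int]:
        """Per-genome ortholog count (row sums)."""
        sums = self.present.sum(axis=1)
        return {g: int(c) for g, c in zip(self.genomes, sums)}


@dataclass
class ExclusionReport:
    threshold: float
    missing: dict[str, float]  # per-genome missing fraction
    excluded: list[str]

    def retained(self, genomes: Sequence[str]) -> list[str]:
        drop = set(self.excluded)
        return [g for g in genomes if g not in drop]


def presence_matrix(locus_sets: Sequence[LocusSet], genomes: Sequence[str]) -> PresenceMatrix:
    """Build the occupancy matrix from harvested loci."""
    targets = [ls.target for ls in locus_sets]
    if len(set(targets)) != len(targets):
        raise ValidationError("locus sets carry duplicate target ids")
    genome_index = {g: i for i, g in enumerate(genomes)}
    present = np.zeros((len(genomes), len(targets)), dtype=bool)
    for j, ls in enumerate(locus_sets):
        for rec in ls.records:
            if rec.id not in genome_index:
                raise ValidationError(
                    f"locus {ls.target} contains genome {rec.id!r} absent "
                    f"from the declared genome list"
                )
            present[genome_index[rec.id], j] = True
    return PresenceMatrix(list(genomes), targets, present)


def missing_fraction(matrix: PresenceMatrix, genome: str) -> float:
    """Fraction of targets this genome is absent from."""
    try:
        i = matrix.genomes.index(genome)
    except ValueError:
        raise ValidationError(f"unknown genome {genome!r}") from None
    n = len(matrix.targets)
    return float((~matrix.present[i]).sum()) / n


def excluded_genomes(
    matrix: PresenceMatrix, threshold: float = DEFAULT_EXCLUDE_THRESHOLD
) -> ExclusionReport:
    """Flag genomes whose missing fraction strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"exclusion threshold must be in [0,1], got {threshold}")
    missing = {g: missing_fraction(matrix, g) for g in matrix.genomes}
    excluded = [g for g, f in missing.items() if f > threshold]
    return ExclusionReport(threshold=threshold, missing=missing, excluded=excluded)


def render_count_plot(counts: Mapping[str, int], out_path: str | os.PathLike) -> Path:
    """Bar plot of per-genome ortholog counts, one bar per genome, declared order."""
    if not counts:
        raise ValidationError("no counts to plot")
    out_path = Path(out_path)
    genomes = list(counts.keys())
    values = [counts[g] for g in genomes]
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(genomes)), 4))
    ax.bar(range(len(genomes)), values, color="steelblue")
    ax.set_xticks(range(len(genomes)))
    ax.set_xticklabels(genomes, rotation=90, fontsize=7)
    ax.set_ylabel("single-copy orthologs")
    ax.set_xlabel("genome")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def write_counts_tsv(counts: Mapping[str, int], out_path: str | os.PathLike) -> Path:
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for g, c in counts.items():
            fh.write(f"{g}\t{c}\n")
    return out_path
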