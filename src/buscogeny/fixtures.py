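"""Synthetic pipeline fixtures: trees, sequences, missingness, recombination.

Every pipeline stage is testable without BUSCO, MAFFT, IQ-TREE or
ClonalFrameML: this module simulates a Yule (pure-birth) genealogy, evolves
indel-free nucleotide loci along it under Jukes-Cantor (JC69), drops
(genome, locus) pairs at a chosen missingness rate, injects horizontal
transfers (donor residues copied over a recipient span) as ground truth for
recombination masking, and emits the whole thing as a BUSCO v5-style result
directory plus lineage dataset.

Because JC69 introduces no indels, the simulated loci are pre-aligned —
the external aligner can stay stubbed.  A :class:`SimulationManifest`
records every simulated fact (tree, presence pattern, injected spans), so
tests can compare pipeline output against the generator's own bookkeeping.
All randomness flows from a single seed; the same seed reproduces the same
bytes.
"""

from __future__ import annotations

import json
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from . import tree as treemod
from .errors import ValidationError
from .harvest import (
    NUCLEOTIDE,
    SCORES_CUTOFF_FILENAME,
    SINGLE_COPY_DIRNAME,
    LocusSet,
    SeqRecord,
)
from .recomb import MaskInterval
from .supermatrix import XmfaMap

_BASES = np.array(list("ACGT"))
DEFAULT_LINEAGE_NAME = "synthfungi_odb10"


@dataclass
class RecombinationEvent:
    """Ground truth for one injected transfer, in matrix coordinates."""

    donor: str
    recipient: str
    target: str
    locus_span: tuple[int, int]   # 0-based half-open within the locus
    matrix_span: tuple[int, int]  # 0-based half-open within the untrimmed matrix


@dataclass
class SimulationManifest:
    """Everything the generator decided, for oracle-style assertions."""

    seed: int
    tree_newick: str
    locus_lengths: dict[str, int]
    presence: dict[str, list[str]]  # target -> genomes carrying it
    recombination: list[RecombinationEvent] = field(default_factory=list)

    @property
    def genomes(self) -> list[str]:
        out: list[str] = []
        for gs in self.presence.values():
            for g in gs:
                if g not in out:
                    out.append(g)
        return sorted(out)

    def to_json(self, path: str | os.PathLike) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "tree_newick": self.tree_newick,
            "locus_lengths": self.locus_lengths,
            "presence": self.presence,
            "recombination": [
                {
                    "donor": e.donor,
                    "recipient": e.recipient,
                    "target": e.target,
                    "locus_span": list(e.locus_span),
                    "matrix_span": list(e.matrix_span),
                }
                for e in self.recombination
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def simulate_yule_tree(n_leaves: int, birth_rate: float = 1.0, seed: int = 0):
    """Pure-birth tree with exponential waiting times; leaves g1..gN."""
    if n_leaves < 3:
        raise ValidationError(f"need at least 3 leaves, got {n_leaves}")
    if birth_rate <= 0:
        raise ValidationError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # each active lineage: [children-or-None, accumulated length]
    root = {"children": None, "len": 0.0}
    root["children"] = [{"children": None, "len": 0.0}, {"children": None, "len": 0.0}]
    active = list(root["children"])
    while len(active) < n_leaves:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node["len"] += wait
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        kids = [{"children": None, "len": 0.0}, {"children": None, "len": 0.0}]
        parent["children"] = kids
        active.extend(kids)
    final = rng.exponential(1.0 / (birth_rate * n_leaves))
    for node in active:
        node["len"] += final

    counter = [0]

    def render(node) -> str:
        if node["children"] is None:
            counter[0] += 1
            return f"g{counter[0]}:{node['len']:.10g}"
        inner = ",".join(render(c) for c in node["children"])
        return f"({inner}):{node['len']:.10g}"

    newick = "(" + ",".join(render(c) for c in root["children"]) + ");"
    return treemod.parse_newick(newick)


def evolve_jc69(tree, length: int, mu: float, seed: int = 0) -> dict[str, str]:
    """Evolve one indel-free locus along the tree under JC69.

    The root sequence is uniform over {A,C,G,T}; along a branch of length t
    each site substitutes independently with probability
    p(t) = (3/4)(1 - exp(-(4/3) mu t)), the JC69 closed form, landing
    uniformly on one of the three other bases.
    """
    if length < 1:
        raise ValidationError("locus length must be >= 1")
    if mu <= 0:
        raise ValidationError("substitution rate must be positive")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    states = {id(tree.seed_node): root_seq}
    rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        p = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * mu * t))
        hit = rng.random(length) < p
        child = parent_seq.copy()
        n_hit = int(hit.sum())
        if n_hit:
            child[hit] = (child[hit] + rng.integers(1, 4, size=n_hit)) % 4
        states[id(node)] = child
        if node.is_leaf():
            rows[node.taxon.label] = "".join(_BASES[child])
    return rows


def jc69_expected_p(mu: float, t: float) -> float:
    """Closed-form JC69 substitution probability for branch length t."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * mu * t))


def jc69_distance(p_hat: float) -> float:
    """Invert the observed mismatch fraction to a JC69 distance."""
    if p_hat >= 0.75:
        raise ValidationError("mismatch fraction at or beyond JC69 saturation")
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p_hat)


def make_locus_sets(
    tree,
    n_loci: int,
    locus_lengths: int | Sequence[int],
    missing_rate: float = 0.0,
    seed: int = 0,
    mu: float = 0.1,
) -> tuple[list[LocusSet], SimulationManifest]:
    """Evolve n_loci loci and drop (genome, locus) pairs at missing_rate.

    Target ids are t0001..tN; the manifest records exactly which genome
    carries which locus.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError("missing rate must be in [0,1)")
    if isinstance(locus_lengths, int):
        lengths = [locus_lengths] * n_loci
    else:
        lengths = list(locus_lengths)
        if len(lengths) != n_loci:
            raise ValidationError("locus_lengths does not match n_loci")
    rng = np.random.default_rng(seed)
    genomes = sorted(
        (l.taxon.label for l in tree.leaf_node_iter()),
        key=lambda s: (len(s), s),
    )
    loci: list[LocusSet] = []
    presence: dict[str, list[str]] = {}
    locus_len_map: dict[str, int] = {}
    for i in range(n_loci):
        target = f"t{i + 1:04d}"
        locus_seed = int(rng.integers(0, 2**31 - 1))
        rows = evolve_jc69(tree, lengths[i], mu=mu, seed=locus_seed)
        kept = [g for g in genomes if rng.random() >= missing_rate]
        records = [
            SeqRecord(id=g, residues=rows[g], alphabet=NUCLEOTIDE) for g in kept
        ]
        loci.append(LocusSet(target=target, records=records, alphabet=NUCLEOTIDE))
        presence[target] = kept
        locus_len_map[target] = lengths[i]
    manifest = SimulationManifest(
        seed=seed,
        tree_newick=treemod.write_newick(tree),
        locus_lengths=locus_len_map,
        presence=presence,
    )
    return loci, manifest


def inject_recombination(
    loci: Sequence[LocusSet],
    manifest: SimulationManifest,
    donor: str,
    recipient: str,
    target: str,
    span: tuple[int, int],
) -> RecombinationEvent:
    """Copy the donor's residues over the recipient's span at one locus.

    Modifies the locus in place and appends the ground-truth event (with
    its untrimmed-matrix coordinates) to the manifest.
    """
    if donor == recipient:
        raise ValidationError("donor and recipient must differ")
    locus = next((ls for ls in loci if ls.target == target), None)
    if locus is None:
        raise ValidationError(f"no locus {target!r}")
    by_id = {r.id: r for r in locus.records}
    for g in (donor, recipient):
        if g not in by_id:
            raise ValidationError(f"genome {g!r} absent at locus {target}")
    a, b = span
    width = len(by_id[recipient])
    if not 0 <= a <= b <= width:
        raise ValidationError(f"span {span} outside locus width {width}")
    if a < b:
        rec = by_id[recipient]
        don = by_id[donor]
        new_res = rec.residues[:a] + don.residues[a:b] + rec.residues[b:]
        idx = locus.records.index(rec)
        locus.records[idx] = SeqRecord(
            id=rec.id, residues=new_res, alphabet=rec.alphabet
        )
    offset = 0
    for t in sorted(manifest.locus_lengths):
        if t == target:
            break
        offset += manifest.locus_lengths[t]
    event = RecombinationEvent(
        donor=donor,
        recipient=recipient,
        target=target,
        locus_span=(a, b),
        matrix_span=(offset + a, offset + b),
    )
    manifest.recombination.append(event)
    return event


def events_to_intervals(
    events: Sequence[RecombinationEvent], xmap: XmfaMap
) -> list[MaskInterval]:
    """Express manifest events as 1-based inclusive XMFA intervals."""
    out = []
    for e in events:
        a, b = e.matrix_span
        if a >= b:
            continue
        out.append(
            MaskInterval(
                node_label=e.recipient,
                beg=xmap.to_xmfa(a) + 1,
                end=xmap.to_xmfa(b - 1) + 1,
            )
        )
    return out


def write_importation_status(
    intervals: Sequence[MaskInterval], path: str | os.PathLike
) -> Path:
    """Serialize intervals in ClonalFrameML's importation_status layout."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Node\tBeg\tEnd\n")
        for iv in intervals:
            fh.write(f"{iv.node_label}\t{iv.beg}\t{iv.end}\n")
    return path


def _translate(nuc: str) -> str:
    padded = nuc + "N" * (-len(nuc) % 3)
    prot = str(Seq(padded).translate()).replace("*", "X")
    return prot or "X"


def emit_lineage_dir(targets: Sequence[str], lineage_dir: str | os.PathLike) -> Path:
    """Write a minimal lineage dataset: a scores_cutoff listing the targets."""
    lineage_dir = Path(lineage_dir)
    lineage_dir.mkdir(parents=True, exist_ok=True)
    with open(lineage_dir / SCORES_CUTOFF_FILENAME, "w") as fh:
        for t in targets:
            fh.write(f"{t}\t50.00\n")
    return lineage_dir


def emit_busco_layout(
    loci: Sequence[LocusSet],
    root_dir: str | os.PathLike,
    lineage_name: str = DEFAULT_LINEAGE_NAME,
) -> Path:
    """Write BUSCO v5-style per-genome result trees for every present pair.

    Headers carry a contig-style id (``<genome>:contig1``) deliberately
    different from the genome id, so harvesting must rewrite them.
    """
    root_dir = Path(root_dir)
    genomes = sorted({r.id for ls in loci for r in ls.records})
    for genome in genomes:
        sc = (
            root_dir / genome / f"run_{lineage_name}" / "busco_sequences"
            / SINGLE_COPY_DIRNAME
        )
        sc.mkdir(parents=True, exist_ok=True)
        for ls in loci:
            rec = next((r for r in ls.records if r.id == genome), None)
            if rec is None:
                continue
            header = f"{genome}:contig1:1-{len(rec)}"
            (sc / f"{ls.target}.fna").write_text(f">{header}\n{rec.residues}\n")
            (sc / f"{ls.target}.faa").write_text(
                f">{header}\n{_translate(rec.residues)}\n"
            )
    return root_dir


def emit_genome_dir(genomes: Sequence[str], genome_dir: str | os.PathLike) -> Path:
    """Write placeholder assembly FASTAs (only filenames feed the core)."""
    genome_dir = Path(genome_dir)
    genome_dir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        (genome_dir / f"{g}.fna").write_text(f">{g}_contig1\nACGT\n")
    return genome_dir


def demo_run(
    workdir: str | os.PathLike,
    seed: int = 7,
    n_genomes: int = 6,
    n_loci: int = 8,
    locus_length: int = 510,
    missing_rate: float = 0.1,
    mu: float = 0.1,
    rc_filt: bool = True,
    exclude_threshold: float = 0.20,
    prefix: str = "demo",
):
    """Simulate a study and run the whole pipeline offline.

    Builds a Yule genealogy, evolves ``n_loci`` JC69 loci, injects one
    recombinant transfer, emits the BUSCO-style layout, and drives
    ``run_pipeline`` with a :class:`FixtureExecutor`.  Returns
    ``(artifacts, manifest)``.
    """
    from . import supermatrix as smmod
    from .cli import RunConfig, run_pipeline

    workdir = Path(workdir)
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_genomes, birth_rate=1.0, seed=int(rng.integers(2**31 - 1)))
    loci, manifest = make_locus_sets(
        tree, n_loci, locus_length, missing_rate=missing_rate,
        seed=int(rng.integers(2**31 - 1)), mu=mu,
    )
    intervals = []
    if rc_filt:
        # inject a transfer at a fully occupied locus so trimming cannot
        # disturb its coordinates
        # donor/recipient must survive the missingness exclusion, and the
        # target locus must be fully occupied by the retained genomes so
        # trimming leaves its coordinates intact
        n_loci_total = len(loci)
        def _missing(g):
            return 1 - sum(g in ls.genome_ids for ls in loci) / n_loci_total
        retained = [g for g in sorted(manifest.genomes, key=lambda s: (len(s), s))
                    if _missing(g) <= exclude_threshold]
        locus = max(loci, key=lambda ls: sum(g in ls.genome_ids for g in retained))
        survivors = [g for g in retained if g in locus.genome_ids]
        donor, recipient = survivors[0], survivors[-1]
        span_w = locus_length // 4
        a = int(rng.integers(locus_length - span_w))
        event = inject_recombination(
            loci, manifest, donor, recipient, locus.target, (a, a + span_w)
        )
        # express the event in XMFA coordinates of the trimmed matrix: the
        # FixtureExecutor hands these to the pipeline as ClonalFrameML output
        from .locus_align import LocusAlignment

        alns = [LocusAlignment(target=ls.target, rows=list(ls.records),
                               alphabet=ls.alphabet) for ls in loci]
        sm = smmod.concatenate(alns, retained)
        trimmed, cmap = smmod.trim_gappy(sm, smmod.DEFAULT_GAPPY_THRESHOLD)
        orig_to_trim = {orig: i for i, orig in enumerate(cmap.kept)}
        kept_cols = [orig_to_trim[c]
                     for c in range(*event.matrix_span) if c in orig_to_trim]
        if kept_cols:
            xmap = XmfaMap(spacer_len=smmod.DEFAULT_SPACER_LEN,
                           partitions=list(trimmed.partitions))
            intervals = [MaskInterval(
                node_label=recipient,
                beg=xmap.to_xmfa(min(kept_cols)) + 1,
                end=xmap.to_xmfa(max(kept_cols)) + 1,
            )]

    genome_dir = emit_genome_dir(manifest.genomes, workdir / "genomes")
    lineage_dir = emit_lineage_dir([ls.target for ls in loci], workdir / "lineage")
    config = RunConfig(
        input_dir=genome_dir,
        lineage_dir=lineage_dir,
        output_prefix=str(workdir / prefix),
        seq_type=NUCLEOTIDE,
        rc_filt=rc_filt,
        exclude_threshold=exclude_threshold,
    )
    emit_busco_layout(loci, config.out_dir / "busco")
    executor = FixtureExecutor(intervals=intervals)
    artifacts = run_pipeline(config, executor=executor)
    manifest.to_json(config.out_dir / "manifest.json")
    return artifacts, manifest


class FixtureExecutor:
    """Stub subprocess boundary: materializes each external tool's output.

    * busco       - no-op (the BUSCO result layout is pre-seeded on disk)
    * mafft       - copies the (already aligned) multifasta to the output
    * iqtree2     - p-distance + neighbor-joining, written as ``.treefile``
    * ClonalFrameML - writes an importation_status file from the intervals
      supplied at construction (empty by default: no recombination found)
    """

    def __init__(self, intervals: Sequence[MaskInterval] = ()) -> None:
        self.intervals = list(intervals)
        self.calls: list[list[str]] = []

    def run(self, argv: Sequence[str]) -> int:
        from . import supermatrix as smmod  # local import avoids a cycle

        argv = list(argv)
        self.calls.append(argv)
        prog = Path(argv[0]).name
        if prog == "busco":
            return 0
        if prog == "mafft":
            src, dst = argv[-2], argv[-1]
            shutil.copyfile(src, dst)
            return 0
        if prog == "iqtree2":
            aln = argv[argv.index("-s") + 1]
            sm = smmod.read_fasta(aln)
            t = treemod.nj(treemod.p_distance_matrix(sm))
            Path(aln + ".treefile").write_text(treemod.write_newick(t) + "\n")
            return 0
        if prog == "ClonalFrameML":
            prefix = argv[3]
            write_importation_status(self.intervals, f"{prefix}.importation_status.txt")
            return 0
        raise ValidationError(f"FixtureExecutor: unknown tool {prog!r}")
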