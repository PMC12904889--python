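# Methods

## Pipeline model

The package assumes the standard single-copy-ortholog supermatrix model of
phylogenomics: each BUSCO target found exactly once in a genome is an
orthologous marker; per-target sequences are aligned; alignments are
concatenated row-wise by genome into one matrix with a partition table.
A genome absent from a locus contributes a gap run of the locus width, so
missing data is explicit rather than imputed. Fragmented and duplicated
BUSCOs are never harvested — only the `single_copy_busco_sequences`
directory is read — because duplication breaks the orthology assumption
the concatenation relies on.

Sequence ids are rewritten to the genome id (the genome filename minus its
extension) at harvest time. BUSCO writes contig-derived headers; every
later stage (occupancy counting, exclusion, concatenation, masking, tree
leaves) keys on genomes, so the rewrite happens once, at the boundary.

## Parameters

| parameter | default | meaning |
|---|---|---|
| exclusion threshold | 0.20 | max fraction of loci a genome may be missing from; **strictly** greater excludes, so a genome at exactly the threshold is retained. The CLI accepts percentages (values in (1,100] are divided by 100). |
| gappyness threshold | 0.05 | max gap fraction of a surviving column; removal is strict (`> threshold`), so `--gappy_threshold 1.0` trims nothing. `-` and `?` count as gaps. |
| XMFA spacer | 1000 | gap columns inserted between gene partitions in the recombination-input serialization; with one partition no spacer is emitted. |
| mask character | `N` | overwrites recombinant sites; distinguishable from alignment gaps, which are left untouched. |
| threads | 8 | forwarded to external tools only. |
| seq_type | protein | protein (`.faa`) or nucleotide (`.fna`) harvesting; recombination filtering is refused in protein mode because ClonalFrameML models nucleotide substitution. |
| UFboot replicates | 1000 | ultrafast bootstrap setting in the constructed IQ-TREE command. |
| ClonalFrameML | `-em -emsim 100` | EM parameter estimation with 100 pseudo-bootstrap replicates. |

## Coordinate systems

Partitions and column maps are 0-based half-open internally; 1-based
inclusive appears only at serialization boundaries (the partition table
and ClonalFrameML's `importation_status` intervals). The XMFA layout is a
single aligned block with in-sequence spacers, not the classic
`=`-separated multi-block XMFA: partition *k* starts at XMFA column
`sum(widths[:k]) + spacer·k`, making the map invertible on non-spacer
columns; intervals crossing a spacer split into one sub-interval per
touched partition, and intervals wholly inside a spacer map to nothing.
Recombination inference consumes the **trimmed** supermatrix — the same
alignment the initial tree is built from — so inferred intervals and tree
branch lengths refer to one coordinate system.

Imports attributed to an internal node are masked in all of its descendant
leaves. Masking maps intervals to matrix columns first and then
overwrites (rather than masking in XMFA space and stripping spacers);
the two orders give identical matrices.

## Tree machinery

Newick parsing and writing are backed by dendropy; internal labels and
branch lengths round-trip. The neighbor-joining fallback is a standard
Q-criterion implementation with deterministic tie-breaking (smallest index
pair; new nodes append at the end) and negative branch estimates clamped
to zero; on additive matrices it recovers the generating tree exactly,
which the tests exploit as an oracle.

The weighted Robinson–Foulds distance sums |ℓ₁(s) − ℓ₂(s)| over the union
of bipartitions, pendant splits included, splits absent from one tree
contributing 0 there. Splits are canonicalized to the side not containing
the lexicographically smallest leaf, and the two root-adjacent edges of a
rooted binary tree collapse into one split with summed length, so the set
is invariant to rooting. Bootstrap support values on internal labels are
parsed but ignored by the weighting. Because wRF is unbounded, the
package reports a transformed similarity `1 − wRF/(L₁+L₂)` alongside the
raw distance; it is bounded in [0,1] (|a−b| ≤ a+b termwise), equals 1 for
identical trees, and is monotone in the distance. Other bounded
normalizations exist; this one was chosen for interpretability, and the
raw distance is always available.

## Synthetic data

The fixture generator simulates a Yule (pure-birth) genealogy (default
birth rate 1.0), evolves indel-free nucleotide loci along it under JC69
(substitution probability p(t) = (3/4)(1 − e^(−(4/3)μt)), default site
rate μ = 0.1 so typical pairwise divergence stays well below saturation),
drops (genome, locus) pairs independently at a missingness rate, injects
recombinant transfers by copying a donor's residues over a recipient's
span, and emits the results as a BUSCO v5-style directory tree plus a
lineage dataset with a `scores_cutoff` file. Protein files are naive
codon translations of the nucleotide loci — sufficient because protein
mode differs only in suffix and alphabet validation. A manifest records
every simulated fact; tests compare pipeline output against it.

What the generator does *not* emulate: indels (so the external aligner
can stay stubbed and "aligned" fixtures are exact), rate heterogeneity,
fragmented or duplicated BUSCOs, and assembly artifacts. Passing tests
therefore demonstrate the correctness of the bookkeeping — harvesting,
occupancy, exclusion, concatenation, trimming, coordinate mapping,
masking, tree comparison — not the biological accuracy of BUSCO, MAFFT,
IQ-TREE or ClonalFrameML themselves, which remain external.

The default study size (6 genomes × 8 loci × 510 bp, missingness 0.1, one
injected transfer of 127 retained sites) keeps an end-to-end run under a
second while giving every stage nontrivial work: one genome is excluded,
padded columns are trimmed, and the injected transfer spans enough sites
that masking visibly changes the inferred tree's branch lengths without
breaking its topology.

## Numerical and degenerate-input choices

* All stochastic code takes an explicit seed and uses a single
  `numpy.random.Generator` stream per call; identical seeds reproduce
  identical bytes, which the acceptance script verifies by re-running the
  whole pipeline.
* p-distances ignore columns where either row has a gap, `?`, `N`/`n` or
  `X`/`x`; a pair with zero comparable sites is an error naming the pair.
* A supermatrix trimmed to zero columns is an error ("alignment fully
  trimmed") rather than an empty artifact.
* JC69 distance inversion refuses mismatch fractions ≥ 3/4 (saturation).
* Masking is idempotent and conservative: matrix width, row order and
  unaffected rows are unchanged, and the report total equals the number of
  characters actually changed.

## Known limitations

* No codon-aware concatenation or per-partition model assignment.
* Per-locus (column-wise) occupancy filtering is out of scope: genomes are
  filtered, loci are not.
* The internal NJ fallback is for fixture-scale work and sanity checks; it
  is quadratic-per-iteration and not a substitute for ML inference on real
  datasets.
* Exclusion is evaluated before concatenation (the only point where it
  affects output); occupancy is computed from harvested locus membership,
  not by re-parsing alignment files.
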