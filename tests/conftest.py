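import pytest

from buscogeny import fixtures
from buscogeny.harvest import NUCLEOTIDE, SeqRecord
from buscogeny.locus_align import LocusAlignment


def make_alignment(target, rows, alphabet=NUCLEOTIDE):
    """Build a LocusAlignment from {genome: residues}."""
    return LocusAlignment(
        target=target,
        rows=[SeqRecord(id=g, residues=s, alphabet=alphabet) for g, s in rows.items()],
        alphabet=alphabet,
    )


@pytest.fixture(scope="session")
def yule6():
    return fixtures.simulate_yule_tree(6, birth_rate=1.0, seed=7)


@pytest.fixture()
def sim(yule6):
    """6 genomes x 8 loci, no missingness (pre-aligned, gap-free)."""
    loci, manifest = fixtures.make_locus_sets(
        yule6, n_loci=8, locus_lengths=510, missing_rate=0.0, seed=11, mu=0.1
    )
    return yule6, loci, manifest


@pytest.fixture()
def busco_layout(tmp_path, sim):
    """On-disk BUSCO-style results plus lineage dataset for the sim fixture."""
    _, loci, manifest = sim
    root = fixtures.emit_busco_layout(loci, tmp_path / "results")
    lineage = fixtures.emit_lineage_dir([ls.target for ls in loci], tmp_path / "lineage")
    return root, lineage, loci, manifest
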