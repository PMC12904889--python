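"""Importation-status parsing, node resolution, interval mapping, masking."""

import pytest

from buscogeny import fixtures, recomb, supermatrix as smm, tree as treemod
from buscogeny.errors import ParseError, ValidationError
from conftest import make_alignment


@pytest.fixture()
def xmap_30_40():
    parts = [smm.Partition("t1", 0, 30), smm.Partition("t2", 30, 70)]
    return smm.XmfaMap(spacer_len=1000, partitions=parts)


@pytest.fixture()
def four_leaf_tree():
    return treemod.parse_newick("((g1:1,g2:1)NODE_3:1,(g3:1,g4:1)NODE_4:1);")


class TestParseImportationStatus:
    def test_parses_rows(self, tmp_path):
        p = tmp_path / "cfml.importation_status.txt"
        p.write_text("Node\tBeg\tEnd\ng1\t5\t10\nNODE_3\t12\t20\n")
        ivs = recomb.parse_importation_status(p)
        assert [(i.node_label, i.beg, i.end) for i in ivs] == [
            ("g1", 5, 10), ("NODE_3", 12, 20)
        ]

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("Node\tBeg\tEnd\n")
        assert recomb.parse_importation_status(p) == []

    def test_missing_header(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("g1\t5\t10\n")
        with pytest.raises(ParseError, match="line 1"):
            recomb.parse_importation_status(p)

    def test_non_integer_coordinates_report_line(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("Node\tBeg\tEnd\ng1\tfive\t10\n")
        with pytest.raises(ParseError, match="line 2"):
            recomb.parse_importation_status(p)

    def test_beg_after_end(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("Node\tBeg\tEnd\ng1\t10\t5\n")
        with pytest.raises(ParseError):
            recomb.parse_importation_status(p)


class TestResolveNode:
    def test_leaf_resolves_to_itself(self, four_leaf_tree):
        assert recomb.resolve_node_to_leaves(four_leaf_tree, "g1") == ["g1"]

    def test_internal_node_resolves_to_descendants(self, four_leaf_tree):
        assert recomb.resolve_node_to_leaves(four_leaf_tree, "NODE_3") == ["g1", "g2"]

    def test_unknown_label(self, four_leaf_tree):
        with pytest.raises(ValidationError, match="NODE_99"):
            recomb.resolve_node_to_leaves(four_leaf_tree, "NODE_99")


class TestMapInterval:
    def test_within_first_partition(self, xmap_30_40):
        iv = recomb.MaskInterval("g1", 1, 10)
        assert recomb.map_interval_to_matrix(iv, xmap_30_40) == [(0, 10)]

    def test_spanning_spacer_splits(self, xmap_30_40):
        iv = recomb.MaskInterval("g1", 25, 1035)
        assert recomb.map_interval_to_matrix(iv, xmap_30_40) == [(24, 30), (30, 35)]

    def test_inside_spacer_is_empty(self, xmap_30_40):
        iv = recomb.MaskInterval("g1", 100, 500)
        assert recomb.map_interval_to_matrix(iv, xmap_30_40) == []

    def test_brute_force_column_by_column(self, xmap_30_40):
        """Interval mapping agrees with mapping each column independently."""
        iv = recomb.MaskInterval("g1", 20, 1040)
        spans = recomb.map_interval_to_matrix(iv, xmap_30_40)
        mapped = sorted(c for a, b in spans for c in range(a, b))
        expected = sorted(
            c for c in (
                smm.xmfa_to_matrix_coord(xmap_30_40, x)
                for x in range(iv.beg - 1, iv.end)
            ) if c is not smm.SPACER
        )
        assert mapped == expected

    def test_out_of_range(self, xmap_30_40):
        with pytest.raises(ValidationError):
            recomb.map_interval_to_matrix(
                recomb.MaskInterval("g1", 1, 2000), xmap_30_40
            )


class TestApplyMask:
    def _sm(self):
        a1 = make_alignment("t1", {f"g{i}": "ACGTACGTAC" for i in range(1, 5)})
        a2 = make_alignment("t2", {f"g{i}": "TTTTTTTTTT" for i in range(1, 5)})
        return smm.concatenate([a1, a2], ["g1", "g2", "g3", "g4"])

    def test_empty_intervals_noop(self, four_leaf_tree):
        sm = self._sm()
        xmap = smm.XmfaMap(spacer_len=10, partitions=sm.partitions)
        masked, report = recomb.apply_mask(sm, four_leaf_tree, [], xmap)
        assert masked.rows == sm.rows and report.total == 0

    def test_leaf_interval_masks_one_row(self, four_leaf_tree):
        sm = self._sm()
        xmap = smm.XmfaMap(spacer_len=10, partitions=sm.partitions)
        ivs = [recomb.MaskInterval("g1", 2, 7)]
        masked, report = recomb.apply_mask(sm, four_leaf_tree, ivs, xmap)
        assert masked.rows["g1"] == "A" + "N" * 6 + "TAC" + "TTTTTTTTTT"
        assert report.per_genome == {"g1": 6, "g2": 0, "g3": 0, "g4": 0}

    def test_internal_node_masks_all_descendants(self, four_leaf_tree):
        sm = self._sm()
        xmap = smm.XmfaMap(spacer_len=10, partitions=sm.partitions)
        ivs = [recomb.MaskInterval("NODE_3", 1, 5)]
        masked, report = recomb.apply_mask(sm, four_leaf_tree, ivs, xmap)
        assert report.total == 10
        assert masked.rows["g1"][:5] == "NNNNN" and masked.rows["g2"][:5] == "NNNNN"
        assert masked.rows["g3"] == sm.rows["g3"]

    def test_gaps_left_untouched(self, four_leaf_tree):
        a1 = make_alignment("t1", {"g1": "AC--AC", "g2": "ACGTAC",
                                   "g3": "ACGTAC", "g4": "ACGTAC"})
        sm = smm.concatenate([a1], ["g1", "g2", "g3", "g4"])
        xmap = smm.XmfaMap(spacer_len=0, partitions=sm.partitions)
        masked, report = recomb.apply_mask(
            sm, four_leaf_tree, [recomb.MaskInterval("g1", 1, 6)], xmap
        )
        assert masked.rows["g1"] == "NN--NN"
        assert report.per_genome["g1"] == 4

    def test_masking_conservation_and_idempotence(self, four_leaf_tree):
        sm = self._sm()
        xmap = smm.XmfaMap(spacer_len=10, partitions=sm.partitions)
        ivs = [recomb.MaskInterval("g2", 3, 9), recomb.MaskInterval("NODE_4", 12, 25)]
        once, r1 = recomb.apply_mask(sm, four_leaf_tree, ivs, xmap)
        assert once.width == sm.width and list(once.rows) == list(sm.rows)
        changed = sum(
            a != b for g in sm.rows for a, b in zip(sm.rows[g], once.rows[g])
        )
        assert changed == r1.total
        twice, r2 = recomb.apply_mask(once, four_leaf_tree, ivs, xmap)
        assert twice.rows == once.rows and r2.total == 0

    def test_protein_mode_refused(self, four_leaf_tree):
        a = make_alignment("t1", {f"g{i}": "MKLV" for i in range(1, 5)},
                           alphabet="protein")
        sm = smm.concatenate([a], ["g1", "g2", "g3", "g4"])
        xmap = smm.XmfaMap(spacer_len=0, partitions=sm.partitions)
        with pytest.raises(ValidationError, match="nucleotide"):
            recomb.apply_mask(sm, four_leaf_tree, [], xmap)


class TestCfmlCommand:
    def test_defaults_include_em_and_emsim_100(self):
        v = recomb.build_cfml_command("t.nwk", "sm.xmfa", "out")
        assert "-em" in v
        assert v[v.index("-emsim") + 1] == "100"

    def test_deterministic(self):
        assert recomb.build_cfml_command("t.nwk", "x", "o") == \
            recomb.build_cfml_command("t.nwk", "x", "o")

    def test_empty_path(self):
        with pytest.raises(ValidationError):
            recomb.build_cfml_command("", "x", "o")


def test_injected_spans_round_trip(tmp_path, sim):
    """Fixture-injected recombination, serialized to an importation-status
    file, parsed, mapped through the XMFA layout, and applied, masks exactly
    the manifest's intervals."""
    tree, loci, manifest = sim
    ev1 = fixtures.inject_recombination(loci, manifest, "g1", "g2", "t0002", (10, 35))
    ev2 = fixtures.inject_recombination(loci, manifest, "g3", "g4", "t0005", (0, 510))
    alns = [make_alignment(ls.target, {r.id: r.residues for r in ls.records})
            for ls in loci]
    genomes = sorted(manifest.genomes, key=lambda s: (len(s), s))
    sm = smm.concatenate(alns, genomes)
    _, xmap = smm.write_xmfa(sm, tmp_path / "sm.xmfa", spacer_len=1000)
    ivs = fixtures.events_to_intervals([ev1, ev2], xmap)
    path = fixtures.write_importation_status(ivs, tmp_path / "cfml.importation_status.txt")
    parsed = recomb.parse_importation_status(path)
    masked, report = recomb.apply_mask(sm, tree, parsed, xmap)
    for ev in (ev1, ev2):
        a, b = ev.matrix_span
        row = masked.rows[ev.recipient]
        assert set(row[a:b]) == {"N"}
        # nothing outside the span masked in that row
        assert "N" not in row[:a] and "N" not in row[b:]
    others = set(genomes) - {ev1.recipient, ev2.recipient}
    for g in others:
        assert masked.rows[g] == sm.rows[g]
    assert report.total == (35 - 10) + 510
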