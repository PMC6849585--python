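"""Matrix and tree I/O: TNT/NEXUS dialects, Newick, round trips, rejection."""

import random

import pytest

from morphparsimony import (
    CapabilityError,
    CellKind,
    CharKind,
    CharacterDef,
    CharacterMatrix,
    FormatError,
    MatrixError,
    PhyloTree,
    StateCell,
    TreeError,
    read_matrix,
    read_trees,
    write_matrix,
    write_trees,
)

MINIMAL_TNT = """
xread
2 3
A 00
B 01
C 11
;
proc /;
"""


def random_matrix(seed: int, n_taxa: int = 5, n_chars: int = 8) -> CharacterMatrix:
    rng = random.Random(seed)
    defs = []
    for j in range(n_chars):
        kind = rng.choice([CharKind.UNORDERED, CharKind.ORDERED, CharKind.CONTINUOUS])
        if kind is CharKind.CONTINUOUS:
            defs.append(CharacterDef(index=j, kind=kind, weight=rng.choice([1.0, 0.25])))
        else:
            defs.append(
                CharacterDef(
                    index=j,
                    kind=kind,
                    n_states=rng.randint(2, 4),
                    weight=rng.choice([1.0, 0.5]),
                    active=rng.random() > 0.1,
                )
            )
    cells = []
    for i in range(n_taxa):
        row = []
        for d in defs:
            r = rng.random()
            if r < 0.1:
                row.append(StateCell.missing())
            elif r < 0.15:
                row.append(StateCell.inapplicable())
            elif d.kind is CharKind.CONTINUOUS:
                row.append(StateCell.of_value(round(rng.uniform(-2, 5), 3)))
            elif r < 0.25 and d.n_states >= 2:
                row.append(StateCell.of_states(rng.sample(range(d.n_states), 2)))
            else:
                row.append(StateCell.of_states([rng.randrange(d.n_states)]))
        cells.append(row)
    return CharacterMatrix(
        taxa=[f"Taxon_{i}" for i in range(n_taxa)], defs=defs, cells=cells
    )


def assert_matrices_equal(a: CharacterMatrix, b: CharacterMatrix) -> None:
    assert a.taxa == b.taxa
    for da, db in zip(a.defs, b.defs):
        assert (da.kind, da.n_states, da.active) == (db.kind, db.n_states, db.active)
        assert da.weight == pytest.approx(db.weight)
    assert a.cells == b.cells


class TestReadTnt:
    def test_minimal_matrix(self):
        m = read_matrix(MINIMAL_TNT)
        assert m.taxa == ["A", "B", "C"]
        assert m.n_characters == 2
        assert all(d.kind is CharKind.UNORDERED and d.n_states == 2 for d in m.defs)
        assert m.cells[1] == [StateCell.of_states([0]), StateCell.of_states([1])]

    def test_cell_token_semantics(self):
        text = "xread\n2 2\nA ?[01]\nB -1\n;\n"
        m = read_matrix(text)
        assert m.cells[0][0].kind is CellKind.MISSING
        assert m.cells[0][1] == StateCell.of_states([0, 1])
        assert m.cells[1][0].kind is CellKind.INAPPLICABLE

    def test_ccode_sets_ordering_weights_activity(self):
        text = "xread\n4 2\nA 0120\nB 1001\n;\nccode + 1 2 ] 3 /0.5 0;\n"
        m = read_matrix(text)
        assert [d.kind for d in m.defs] == [
            CharKind.UNORDERED, CharKind.ORDERED, CharKind.ORDERED, CharKind.UNORDERED,
        ]
        assert not m.defs[3].active
        assert m.defs[0].weight == 0.5

    def test_continuous_block(self):
        text = "xread\n3 2\n&[cont]\nA 1.5 ?\nB 2.25 0.5\n&[num]\nA 0\nB 1\n;\n"
        m = read_matrix(text)
        assert [d.kind for d in m.defs] == [
            CharKind.CONTINUOUS, CharKind.CONTINUOUS, CharKind.UNORDERED,
        ]
        assert m.cells[1][0] == StateCell.of_value(2.25)
        assert m.cells[0][1].kind is CellKind.MISSING

    def test_dimension_mismatch_names_offending_row(self):
        text = "xread\n3 3\nA 000\nB 00\nC 000\n;\n"
        with pytest.raises(FormatError, match="'B'"):
            read_matrix(text)

    def test_unknown_token_reports_position(self):
        text = "xread\n2 2\nA 0X\nB 00\n;\n"
        with pytest.raises(FormatError, match="'A'.*column 2"):
            read_matrix(text)

    def test_duplicate_taxon_rejected(self):
        text = "xread\n1 2\nA 0\nA 1\n;\n"
        with pytest.raises(MatrixError, match="duplicate"):
            read_matrix(text)

    def test_header_taxon_count_enforced(self):
        text = "xread\n1 3\nA 0\nB 1\n;\n"
        with pytest.raises(FormatError):
            read_matrix(text)


class TestRoundTrips:
    @pytest.mark.parametrize("dialect", ["tnt", "nexus"])
    @pytest.mark.parametrize("seed", range(8))
    def test_read_write_identity(self, dialect, seed):
        m = random_matrix(seed)
        text = write_matrix(m, dialect=dialect)
        assert_matrices_equal(m, read_matrix(text, dialect=dialect))

    def test_auto_dialect_detection(self):
        m = random_matrix(3)
        assert read_matrix(write_matrix(m, "nexus")).taxa == m.taxa
        assert read_matrix(write_matrix(m, "tnt")).taxa == m.taxa

    def test_continuous_literals_preserved(self):
        defs = [CharacterDef(index=0, kind=CharKind.CONTINUOUS)]
        cells = [[StateCell.of_value(2.0)], [StateCell.of_value(4.0)]]
        m = CharacterMatrix(taxa=["A", "B"], defs=defs, cells=cells)
        text = write_matrix(m, dialect="tnt")
        assert "2.0" in text and "4.0" in text

    def test_empty_taxon_set_rejected(self):
        with pytest.raises(MatrixError):
            CharacterMatrix(taxa=[], defs=[], cells=[])

    def test_large_states_exceed_tnt_capability(self):
        defs = [CharacterDef(index=0, kind=CharKind.UNORDERED, n_states=12)]
        m = CharacterMatrix(
            taxa=["A", "B"], defs=defs,
            cells=[[StateCell.of_states([11])], [StateCell.of_states([0])]],
        )
        with pytest.raises(CapabilityError):
            write_matrix(m, dialect="tnt")

    @pytest.mark.parametrize("seed", range(30))
    def test_single_token_corruption_rejected_or_changed(self, seed):
        """Corrupting one character of a serialised matrix never silently
        round-trips to the original."""
        m = random_matrix(1, n_taxa=4, n_chars=5)
        text = write_matrix(m, dialect="tnt")
        rng = random.Random(seed)
        data_region = text.index("\n", text.index("mp-nstates"))
        # corrupt only the semantically meaningful region (rows + ccode);
        # the trailing no-op `proc /;` statement carries no matrix content
        data_end = text.index("proc /;")
        pos = rng.randrange(data_region, data_end)
        replacement = rng.choice("X;[)5?")
        corrupted = text[:pos] + replacement + text[pos + 1 :]
        if corrupted == text:
            return
        try:
            back = read_matrix(corrupted, dialect="tnt")
        except (FormatError, MatrixError, ValueError):
            return
        same = back.taxa == m.taxa and back.cells == m.cells and all(
            (da.kind, da.n_states, da.weight, da.active)
            == (db.kind, db.n_states, db.weight, db.active)
            for da, db in zip(back.defs, m.defs)
        )
        assert not same, f"corruption at {pos} ({replacement!r}) was silently absorbed"


class TestTrees:
    def test_unrooted_five_leaf_tree(self):
        trees = read_trees("((A,B),(C,D),E);")
        assert len(trees) == 1
        t = trees[0]
        assert t.leaf_labels() == frozenset("ABCDE")
        assert len(t.splits()) == 2

    def test_polytomy_preserved(self):
        t = read_trees("((A,B,C,D),E,(F,G));")[0]
        text = write_trees([t])
        assert read_trees(text)[0].same_topology(t)

    def test_annotation_round_trip(self):
        t = read_trees("((A,B)[&support=50.0],(C,D),E);")[0]
        node = next(n for n in t.postorder() if n.annotations)
        assert node.annotations["support"] == 50.0
        back = read_trees(write_trees([t], annotations=True))[0]
        node2 = next(n for n in back.postorder() if n.annotations)
        assert node2.annotations["support"] == 50.0

    def test_duplicate_leaf_label_rejected(self):
        with pytest.raises((TreeError, FormatError)):
            read_trees("((A,B),(A,C));")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(FormatError):
            read_trees("((A,B),(C,D);")

    def test_leaf_set_and_topology_round_trip(self):
        trees = [
            PhyloTree.from_nested((("A", "B"), ("C", "D"), "E")),
            PhyloTree.from_nested((("A", "C"), ("B", "D"), "E")),
        ]
        back = read_trees(write_trees(trees))
        assert len(back) == 2
        for orig, rt in zip(trees, back):
            assert rt.same_topology(orig)
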