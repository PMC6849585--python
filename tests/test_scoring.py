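"""Parsimony scoring: DP exactness, step bounds, homoplasy indices."""

import random

import numpy as np
import pytest

from morphparsimony import (
    CharKind,
    CharacterDef,
    CharacterMatrix,
    ParsimonyScorer,
    PhyloTree,
    ScoringError,
    StateCell,
    char_step_bounds,
    character_steps,
    homoplasy_indices,
    matrix_from_strings,
    tree_length,
)

from .conftest import random_small_matrix
from .oracles import adjacency_to_phylo, all_topologies, brute_force_steps


class TestCharacterSteps:
    def test_conflicting_binary_character_two_steps(self, quartet_matrix, quartet_tree):
        assert character_steps(quartet_tree, quartet_matrix, 0) == pytest.approx(2.0)

    def test_ordered_sisters_weighted(self):
        m = matrix_from_strings({"A": "0", "B": "2", "C": "0"}, ordered=[0])
        m.defs[0].weight = 0.5
        tree = PhyloTree.from_nested(("A", "B", "C"))
        assert character_steps(tree, m, 0) == pytest.approx(1.0)

    def test_continuous_star_l1_median(self):
        defs = [CharacterDef(index=0, kind=CharKind.CONTINUOUS, weight=1 / 3)]
        cells = [[StateCell.of_value(v)] for v in (1.0, 2.0, 4.0)]
        m = CharacterMatrix(taxa=["A", "B", "C"], defs=defs, cells=cells)
        star = PhyloTree.from_nested(("A", "B", "C"))
        assert character_steps(star, m, 0) == pytest.approx(1.0)

    def test_inactive_character_rejected(self, quartet_matrix, quartet_tree):
        quartet_matrix.defs[0].active = False
        with pytest.raises((ScoringError, Exception)):
            character_steps(quartet_tree, quartet_matrix, 0)

    def test_leaf_without_row_rejected(self, quartet_matrix):
        tree = PhyloTree.from_nested((("A", "B"), ("C", "Z")))
        with pytest.raises(ScoringError):
            character_steps(tree, quartet_matrix, 0)

    def test_missing_taxa_in_tree_are_ignored(self, quartet_matrix):
        tree = PhyloTree.from_nested(("A", "B", "C"))
        assert character_steps(tree, quartet_matrix, 0) == pytest.approx(1.0)


class TestTreeLength:
    def test_congruent_character_single_step(self):
        m = matrix_from_strings({"A": "1", "B": "1", "C": "0", "D": "0"})
        tree = PhyloTree.from_nested((("A", "B"), ("C", "D")))
        assert tree_length(tree, m).total_length == pytest.approx(1.0)

    def test_row_permutation_invariance(self, mixed_matrix):
        tree = PhyloTree.from_nested((("A", "C"), ("B", "D")))
        base = tree_length(tree, mixed_matrix).total_length
        perm = CharacterMatrix(
            taxa=list(reversed(mixed_matrix.taxa)),
            defs=[CharacterDef(**vars(d)) for d in mixed_matrix.defs],
            cells=list(reversed(mixed_matrix.cells)),
        )
        assert tree_length(tree, perm).total_length == pytest.approx(base)

    def test_polytomy_scored_exactly_as_best_resolution(self):
        rng = random.Random(5)
        for kind in ("unordered", "ordered", "continuous"):
            matrix, cells = random_small_matrix(rng, 5, kind)
            scorer = ParsimonyScorer(matrix)
            star = PhyloTree.from_nested(tuple(matrix.taxa))
            best_resolved = min(
                scorer.length(adjacency_to_phylo(adj, leaf))
                for adj, leaf in all_topologies(matrix.taxa)
            )
            # a hard polytomy can never beat its best binary resolution
            assert scorer.length(star) >= best_resolved - 1e-9
            # and the polytomy itself is scored exactly: equals brute force
            adj = {0: list(range(1, 6))}
            for i in range(1, 6):
                adj[i] = [0]
            leaf = {i: matrix.taxa[i - 1] for i in range(1, 6)}
            assert scorer.length(star) == pytest.approx(
                brute_force_steps(adj, leaf, cells, kind)
            )

    @pytest.mark.parametrize("kind", ["unordered", "ordered", "continuous"])
    def test_dp_matches_brute_force_on_random_trees(self, kind):
        rng = random.Random(hash(kind) % 10000)
        for case in range(12):
            matrix, cells = random_small_matrix(rng, rng.choice([4, 5]), kind)
            scorer = ParsimonyScorer(matrix)
            for adj, leaf in all_topologies(matrix.taxa):
                dp = scorer.length(adjacency_to_phylo(adj, leaf))
                assert dp == pytest.approx(
                    brute_force_steps(adj, leaf, cells, kind)
                ), f"{kind} case {case}: {cells}"

    def test_continuous_affine_invariance(self):
        rng = random.Random(11)
        values = [round(rng.uniform(0, 3), 2) for _ in range(5)]
        defs = [CharacterDef(index=0, kind=CharKind.CONTINUOUS)]

        def matrix_for(vals):
            return CharacterMatrix(
                taxa=[f"T{i}" for i in range(5)],
                defs=[CharacterDef(index=0, kind=CharKind.CONTINUOUS)],
                cells=[[StateCell.of_value(v)] for v in vals],
            )

        tree = PhyloTree.from_nested(
            (("T0", "T1"), ("T2", "T3"), "T4")
        )
        base = ParsimonyScorer(matrix_for(values)).length(tree)
        shifted = ParsimonyScorer(matrix_for([v + 7.5 for v in values])).length(tree)
        scaled = ParsimonyScorer(matrix_for([3.0 * v for v in values])).length(tree)
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(3.0 * base)


class TestStepBounds:
    def test_unordered_bounds(self):
        m = matrix_from_strings({"A": "0", "B": "0", "C": "1", "D": "1", "E": "2"})
        assert char_step_bounds(m, 0) == (2.0, 3.0)

    def test_two_taxon_ordered_bounds(self):
        m = matrix_from_strings({"A": "0", "B": "2"}, ordered=[0])
        assert char_step_bounds(m, 0) == (2.0, 2.0)

    def test_continuous_bounds_median(self):
        defs = [CharacterDef(index=0, kind=CharKind.CONTINUOUS)]
        cells = [[StateCell.of_value(v)] for v in (1.0, 2.0, 4.0)]
        m = CharacterMatrix(taxa=["A", "B", "C"], defs=defs, cells=cells)
        lo, hi = char_step_bounds(m, 0)
        assert lo == pytest.approx(3.0)
        assert hi == pytest.approx(3.0)

    def test_bounds_bracket_observed_steps(self):
        rng = random.Random(3)
        for kind in ("unordered", "ordered", "continuous"):
            matrix, _ = random_small_matrix(rng, 6, kind)
            lo, hi = char_step_bounds(matrix, 0)
            scorer = ParsimonyScorer(matrix)
            for adj, leaf in list(all_topologies(matrix.taxa))[::17]:
                steps = scorer.length(adjacency_to_phylo(adj, leaf))
                assert lo - 1e-9 <= steps <= hi + 1e-9

    def test_star_tree_attains_max_bound(self):
        m = matrix_from_strings({"A": "0", "B": "0", "C": "1", "D": "1", "E": "2"})
        star = PhyloTree.from_nested(tuple(m.taxa))
        _, hi = char_step_bounds(m, 0)
        assert ParsimonyScorer(m).length(star) == pytest.approx(hi)


class TestHomoplasyIndices:
    def test_perfect_congruence(self):
        m = matrix_from_strings(
            {"A": "11", "B": "11", "C": "00", "D": "01"}
        )
        tree = PhyloTree.from_nested((("A", "B"), ("C", "D")))
        rep = homoplasy_indices(tree, m)
        assert rep.ci == pytest.approx(1.0)
        assert rep.ri == pytest.approx(1.0)

    def test_conflicting_quartet(self, quartet_matrix, quartet_tree):
        rep = homoplasy_indices(quartet_tree, quartet_matrix)
        assert rep.ci == pytest.approx(0.5)
        assert rep.ri == pytest.approx(0.0)

    def test_ci_decreases_under_forced_homoplasy(self):
        m = matrix_from_strings(
            {"A": "110", "B": "111", "C": "001", "D": "000", "E": "110"}
        )
        good = PhyloTree.from_nested(((("A", "B"), "E"), ("C", "D")))
        worse = PhyloTree.from_nested(((("A", "C"), "E"), ("B", "D")))
        assert (
            homoplasy_indices(worse, m).ci < homoplasy_indices(good, m).ci
        )

    def test_all_uninformative_raises(self):
        m = matrix_from_strings({"A": "0", "B": "1", "C": "0"})
        with pytest.raises(ScoringError):
            homoplasy_indices(PhyloTree.from_nested(("A", "B", "C")), m)
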