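"""Constrained search: admissibility, random addition, TBR, consensus, pools."""

import random

import pytest

from morphparsimony import (
    CharKind,
    CharacterDef,
    CharacterMatrix,
    ConstraintScaffold,
    ParsimonyScorer,
    PhyloTree,
    SearchError,
    StateCell,
    collect_suboptimal,
    is_admissible,
    random_addition_tree,
    strict_consensus,
    tbr_search,
)

from .conftest import random_small_matrix
from .oracles import adjacency_to_phylo, all_topologies, exhaustive_best_length


def congruent_matrix(tree: PhyloTree, doubling: int = 2) -> CharacterMatrix:
    """One binary character per non-trivial split of the tree (replicated),
    so the generating topology is the unique optimum."""
    labels = sorted(tree.leaf_labels())
    columns = []
    for split in sorted(tree.splits(), key=sorted):
        columns.extend([split] * doubling)
    defs = [
        CharacterDef(index=j, kind=CharKind.UNORDERED, n_states=2)
        for j in range(len(columns))
    ]
    cells = [
        [StateCell.of_states([1 if t in col else 0]) for col in columns]
        for t in labels
    ]
    return CharacterMatrix(taxa=labels, defs=defs, cells=cells)


@pytest.fixture
def six_taxon_truth():
    return PhyloTree.from_nested(((("A", "B"), "C"), ("D", "E"), "F"))


class TestAdmissibility:
    def scaffold(self):
        backbone = PhyloTree.from_nested((("X", "Y"), ("Z", "W")))
        return ConstraintScaffold(backbone=backbone, floaters=frozenset({"F"}))

    def test_floater_invades_constrained_topology(self):
        tree = PhyloTree.from_nested(((("X", "F"), "Y"), ("Z", "W")))
        assert is_admissible(tree, self.scaffold())

    def test_backbone_violation_detected(self):
        tree = PhyloTree.from_nested((("X", "Z"), ("Y", "W"), "F"))
        assert not is_admissible(tree, self.scaffold())

    def test_backbone_polytomy_freely_resolved(self):
        backbone = PhyloTree.from_nested(("X", "Y", "Z", ("W", "V")))
        sc = ConstraintScaffold(backbone=backbone)
        for spec in [
            ((("X", "Y"), "Z"), ("W", "V")),
            ((("X", "Z"), "Y"), ("W", "V")),
        ]:
            assert is_admissible(PhyloTree.from_nested(spec), sc)

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(SearchError):
            is_admissible(PhyloTree.from_nested(("X", "Y", "Z")), self.scaffold())


class TestRandomAddition:
    def test_deterministic_for_fixed_seed(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth)
        sc = ConstraintScaffold.unconstrained(m.taxa)
        t1 = random_addition_tree(m, sc, seed=42)
        t2 = random_addition_tree(m, sc, seed=42)
        assert t1.same_topology(t2)

    def test_result_is_admissible_and_binary(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth)
        backbone = PhyloTree.from_nested((("A", "B"), ("D", "E")))
        sc = ConstraintScaffold(
            backbone=backbone, floaters=frozenset({"C", "F"})
        )
        for seed in range(5):
            t = random_addition_tree(m, sc, seed=seed)
            assert is_admissible(t, sc)
            assert t.is_binary()

    def test_clean_matrix_reaches_exhaustive_optimum(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth)
        sc = ConstraintScaffold.unconstrained(m.taxa)
        best, _ = exhaustive_best_length(ParsimonyScorer(m), m.taxa)
        t = random_addition_tree(m, sc, seed=1)
        assert ParsimonyScorer(m).length(t) == pytest.approx(best)


class TestTbrSearch:
    def test_recovers_generating_tree(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth)
        ens = tbr_search(m, n_starts=3, seed=0)
        best, _ = exhaustive_best_length(ParsimonyScorer(m), m.taxa)
        assert ens.best_length == pytest.approx(best)
        assert len(ens.mpts) == 1
        assert ens.mpts[0].same_topology(six_taxon_truth)

    @pytest.mark.parametrize("seed", range(6))
    def test_finds_global_optimum_on_random_matrices(self, seed):
        """Multi-start TBR matches exhaustive enumeration on <= 7 taxa."""
        rng = random.Random(seed)
        kind = ("unordered", "ordered", "continuous")[seed % 3]
        n_taxa = rng.choice([5, 6, 7])
        cols = []
        base, _ = random_small_matrix(rng, n_taxa, kind)
        for _ in range(3):
            extra, _ = random_small_matrix(rng, n_taxa, kind)
            cols.append(extra)
        defs = []
        cells = [[] for _ in base.taxa]
        for j, src in enumerate([base] + cols):
            d = src.defs[0]
            d2 = CharacterDef(index=j, kind=d.kind, n_states=d.n_states)
            defs.append(d2)
            for row, srow in zip(cells, src.cells):
                row.append(srow[0])
        matrix = CharacterMatrix(taxa=base.taxa, defs=defs, cells=cells)
        scorer = ParsimonyScorer(matrix)
        best, _ = exhaustive_best_length(scorer, matrix.taxa)
        ens = tbr_search(matrix, n_starts=5, seed=seed)
        assert ens.best_length == pytest.approx(best)

    def test_scaffold_respected_by_all_trees(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth)
        backbone = PhyloTree.from_nested((("A", "D"), ("C", "F")))
        sc = ConstraintScaffold(
            backbone=backbone, floaters=frozenset({"B", "E"})
        )
        ens = tbr_search(m, sc, n_starts=3, seed=0, epsilon=2.0)
        assert ens.trees
        for tree, _ in ens.trees:
            assert is_admissible(tree, sc)

    def test_epsilon_pool_monotonicity(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth, doubling=1)
        tight = tbr_search(m, n_starts=3, seed=1, epsilon=0.0)
        loose = tbr_search(m, n_starts=3, seed=1, epsilon=1.0)
        tight_keys = {t.splits() for t, _ in tight.trees}
        loose_keys = {t.splits() for t, _ in loose.trees}
        assert tight_keys <= loose_keys

    def test_reproducible_ensembles(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth)
        a = tbr_search(m, n_starts=3, seed=9, epsilon=1.0)
        b = tbr_search(m, n_starts=3, seed=9, epsilon=1.0)
        assert [t.splits() for t, _ in a.trees] == [t.splits() for t, _ in b.trees]
        assert a.best_length == b.best_length


class TestSuboptimalPool:
    def test_zero_schedule_is_mpt_set(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth)
        ens = tbr_search(m, n_starts=3, seed=0)
        pool = collect_suboptimal(m, None, ens, epsilon_schedule=[0.0])
        assert {t.splits() for t in pool.mpts} == {
            t.splits() for t in ens.mpts
        }

    def test_cap_truncation_flagged(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth, doubling=1)
        ens = tbr_search(m, n_starts=2, seed=0)
        pool = collect_suboptimal(m, None, ens, epsilon_schedule=[0.0, 2.0, 4.0], cap=5)
        assert len(pool.trees) <= 5
        assert pool.truncated

    def test_pool_matches_exhaustive_enumeration(self, six_taxon_truth):
        m = congruent_matrix(six_taxon_truth, doubling=1)
        scorer = ParsimonyScorer(m)
        ens = tbr_search(m, n_starts=3, seed=0)
        pool = collect_suboptimal(m, None, ens, epsilon_schedule=[1.0, 2.0])
        expected = set()
        best, _ = exhaustive_best_length(scorer, m.taxa)
        for adj, leaf in all_topologies(m.taxa):
            t = adjacency_to_phylo(adj, leaf)
            if scorer.length(t) <= best + 2.0 + 1e-9:
                expected.add(t.splits())
        assert {t.splits() for t, _ in pool.trees} == expected


class TestStrictConsensus:
    def test_identical_inputs(self, six_taxon_truth):
        cons = strict_consensus([six_taxon_truth, six_taxon_truth.copy()])
        assert cons.same_topology(six_taxon_truth)

    def test_shared_clade_only(self):
        t1 = PhyloTree.from_nested((("A", "B"), "C", ("D", "E")))
        t2 = PhyloTree.from_nested((("A", "B"), ("C", "D"), "E"))
        cons = strict_consensus([t1, t2])
        expected = PhyloTree.from_nested((("A", "B"), "C", "D", "E"))
        assert cons.same_topology(expected)

    def test_all_resolutions_give_star(self):
        labels = ["A", "B", "C", "D", "E"]
        trees = [adjacency_to_phylo(a, l) for a, l in all_topologies(labels)]
        cons = strict_consensus(trees)
        assert cons.splits() == frozenset()

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.from_nested((("A", "B"), "C", "D"))
        t2 = PhyloTree.from_nested((("A", "B"), "C", "E"))
        with pytest.raises(SearchError):
            strict_consensus([t1, t2])
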