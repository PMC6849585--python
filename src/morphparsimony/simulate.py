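"""Synthetic matrices and scaffolds emulating a genus-level morphological study.

Characters evolve along a model tree: unordered characters under a k-state
symmetric Markov (Mk) process, ordered characters under a +/-1 stepwise walk
reflected at the terminal states, continuous characters under Brownian
motion.  Cells are masked missing at a configurable rate, optionally
concentrated on designated fossil-like taxa.  A scaffold generator restricts
the true tree to chosen non-floaters and collapses a fraction of its edges
into polytomies, mimicking a molecular backbone with areas of uncertainty.

The bundled study-shaped configuration mirrors the structure of a large
Paleocene placental data set: 177 taxa, 680 characters of which 48 are
continuous, heavy taxon-concentrated missing data, a backbone over a small
set of extant-like taxa and three sequential outgroups.  Scaled-down
variants of the same shape drive the fast tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .characters import (
    CharKind,
    CharacterDef,
    CharacterMatrix,
    StateCell,
)
from .search import ConstraintScaffold
from .trees import Node, PhyloTree


@dataclass
class SimulationConfig:
    model_tree: PhyloTree  # leaves carry taxon names; edge lengths in `length` annotations
    n_unordered: int = 40
    n_ordered: int = 10
    n_continuous: int = 4
    n_states: int = 3  # states per discrete character kind
    rate: float = 1.0  # expected changes per unit branch length
    bm_sigma: float = 1.0  # Brownian step scale per unit branch length
    missing_rate: float = 0.0
    fossil_taxa: frozenset[str] = frozenset()
    fossil_missing_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        total = self.n_unordered + self.n_ordered + self.n_continuous
        if total < 1:
            raise ValueError("at least one character is required")
        if min(self.n_unordered, self.n_ordered, self.n_continuous) < 0:
            raise ValueError("character counts must be non-negative")
        if self.rate <= 0 or self.bm_sigma <= 0:
            raise ValueError("rate and bm_sigma must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_states < 2:
            raise ValueError("n_states must be at least 2")


@dataclass
class SimulatedDataset:
    matrix: CharacterMatrix
    true_tree: PhyloTree
    scaffold: ConstraintScaffold
    config: SimulationConfig


# ------------------------------------------------------------- model trees


def random_model_tree(
    n_taxa: int,
    seed: int = 0,
    mean_branch: float = 0.3,
    prefix: str = "t",
) -> PhyloTree:
    """Random binary unrooted topology with exponential branch lengths,
    stored in each node's ``length`` annotation."""
    if n_taxa < 4:
        raise ValueError("need at least four taxa")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    root = Node()
    for lbl in labels[:3]:
        root.add_child(Node(lbl))
    tree = PhyloTree(root, rooted=False)
    for lbl in labels[3:]:
        # pick a random node (!= root) and insert on its parent edge
        nodes = [n for n in tree.postorder() if n is not tree.root]
        host = nodes[int(rng.integers(len(nodes)))]
        parent = host.parent
        assert parent is not None
        mid = Node()
        idx = parent.children.index(host)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(host)
        mid.add_child(Node(lbl))
    for node in tree.postorder():
        if node is not tree.root:
            node.annotations["length"] = float(rng.exponential(mean_branch))
    return tree


def benchmark_model_tree(
    internal_length: float = 0.45, terminal_length: float = 0.2
) -> PhyloTree:
    """The fixed eight-taxon balanced tree used for topology-recovery
    experiments.

    Internal edges are longer than terminal ones so that, under the heavy
    missing data of the study conditions, every split retains an expected
    number of scored supporting characters well above the homoplasy noise
    floor: the benchmark probes the correctness of the constrained search,
    not the statistical limits of parsimony on marginal data.
    """
    tree = PhyloTree.from_nested(
        ((("t1", "t2"), ("t3", "t4")), ("t5", "t6"), ("t7", "t8"))
    )
    for node in tree.postorder():
        if node is not tree.root:
            node.annotations["length"] = float(
                terminal_length if node.is_leaf else internal_length
            )
    return tree


def _branch_length(node: Node) -> float:
    return float(node.annotations.get("length", 0.3))


# --------------------------------------------------------------- evolution


def _evolve_unordered(rng, tree, k: int, rate: float) -> dict[str, int]:
    """Symmetric k-state Markov chain: along a branch of length t the chain
    stays put with probability 1/k + (1 - 1/k) * exp(-k * rate * t / (k-1))."""
    states: dict[int, int] = {id(tree.root): int(rng.integers(k))}
    out: dict[str, int] = {}
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            t = _branch_length(node)
            p_same = 1.0 / k + (1.0 - 1.0 / k) * math.exp(-k * rate * t / (k - 1))
            parent_state = states[id(node.parent)]
            if rng.random() < p_same:
                states[id(node)] = parent_state
            else:
                others = [s for s in range(k) if s != parent_state]
                states[id(node)] = others[int(rng.integers(k - 1))]
        if node.is_leaf:
            out[node.label] = states[id(node)]
    return out


def _evolve_ordered(rng, tree, k: int, rate: float) -> dict[str, int]:
    """+/-1 stepwise walk with Poisson(rate * t) events, reflected at 0 and k-1."""
    states: dict[int, int] = {id(tree.root): int(rng.integers(k))}
    out: dict[str, int] = {}
    for node in tree.preorder():
        if node is not tree.root:
            s = states[id(node.parent)]
            for _ in range(int(rng.poisson(rate * _branch_length(node)))):
                if s == 0:
                    s = 1
                elif s == k - 1:
                    s = k - 2
                else:
                    s += 1 if rng.random() < 0.5 else -1
            states[id(node)] = s
        if node.is_leaf:
            out[node.label] = states[id(node)]
    return out


def _evolve_continuous(rng, tree, sigma: float) -> dict[str, float]:
    vals: dict[int, float] = {id(tree.root): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder():
        if node is not tree.root:
            t = _branch_length(node)
            vals[id(node)] = vals[id(node.parent)] + sigma * math.sqrt(t) * rng.standard_normal()
        if node.is_leaf:
            out[node.label] = vals[id(node)]
    return out


def simulate_matrix(config: SimulationConfig) -> SimulatedDataset:
    """Evolve a full mixed matrix along the model tree; reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    tree = config.model_tree
    taxa = sorted(tree.leaf_labels())
    k = config.n_states

    defs: list[CharacterDef] = []
    columns: list[dict[str, StateCell]] = []
    j = 0
    for _ in range(config.n_unordered):
        sim = _evolve_unordered(rng, tree, k, config.rate)
        columns.append({t: StateCell.of_states([sim[t]]) for t in taxa})
        defs.append(CharacterDef(index=j, kind=CharKind.UNORDERED, n_states=k))
        j += 1
    for _ in range(config.n_ordered):
        sim = _evolve_ordered(rng, tree, k, config.rate)
        columns.append({t: StateCell.of_states([sim[t]]) for t in taxa})
        defs.append(CharacterDef(index=j, kind=CharKind.ORDERED, n_states=k))
        j += 1
    for _ in range(config.n_continuous):
        sim = _evolve_continuous(rng, tree, config.bm_sigma)
        columns.append({t: StateCell.of_value(round(sim[t], 6)) for t in taxa})
        defs.append(CharacterDef(index=j, kind=CharKind.CONTINUOUS))
        j += 1

    # missingness: completely at random, optionally amplified on fossil taxa
    cells = []
    for t in taxa:
        p = config.missing_rate
        if t in config.fossil_taxa:
            p = min(0.95, p * config.fossil_missing_multiplier)
        row = []
        for col in columns:
            if config.missing_rate > 0 and rng.random() < p:
                row.append(StateCell.missing())
            else:
                row.append(col[t])
        cells.append(row)
    matrix = CharacterMatrix(taxa=taxa, defs=defs, cells=cells, title="simulated")

    scaffold = ConstraintScaffold.unconstrained(taxa)
    return SimulatedDataset(
        matrix=matrix, true_tree=tree, scaffold=scaffold, config=config
    )


def make_scaffold(
    true_tree: PhyloTree,
    non_floaters,
    collapse_fraction: float = 0.0,
    seed: int = 0,
    outgroups: tuple[str, ...] = (),
) -> ConstraintScaffold:
    """Backbone = true tree restricted to the non-floaters, with a seeded
    fraction of its internal edges collapsed into polytomies."""
    non_floaters = frozenset(non_floaters)
    if len(non_floaters) < 4:
        raise ValueError("need at least four non-floater taxa")
    if not 0 <= collapse_fraction <= 1:
        raise ValueError("collapse_fraction must lie in [0, 1]")
    backbone = true_tree.restricted(non_floaters)
    for node in backbone.postorder():
        node.annotations.pop("length", None)
    internal = [
        n
        for n in backbone.postorder()
        if not n.is_leaf and n is not backbone.root
    ]
    rng = np.random.default_rng(seed)
    n_collapse = int(round(collapse_fraction * len(internal)))
    if n_collapse:
        chosen = rng.choice(len(internal), size=n_collapse, replace=False)
        for i in sorted(chosen, reverse=True):
            node = internal[i]
            parent = node.parent
            assert parent is not None
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent
    floaters = true_tree.leaf_labels() - non_floaters
    return ConstraintScaffold(
        backbone=backbone, floaters=floaters, outgroups=tuple(outgroups)
    )


# --------------------------------------------------- study-shaped presets


def study_shaped_config(
    n_taxa: int = 177,
    n_unordered: int = 480,
    n_ordered: int = 152,
    n_continuous: int = 48,
    rate: float = 2.0,
    missing_rate: float = 0.5,
    n_extant: int = 18,
    seed: int = 0,
) -> tuple[SimulationConfig, frozenset[str], tuple[str, ...]]:
    """A configuration mimicking the shape of a large genus-level matrix:
    mixed character kinds (~7% continuous), high evolutionary rate (hence
    high homoplasy), fossil-concentrated missing data, a backbone over a
    small extant subset and three sequential outgroup taxa.

    Returns (config, non_floaters, outgroups); scale down ``n_taxa`` and the
    character counts for fast tests.
    """
    tree = random_model_tree(n_taxa, seed=seed)
    taxa = sorted(tree.leaf_labels())
    outgroups = tuple(taxa[:3])
    extant = frozenset(taxa[3 : 3 + n_extant]) | set(outgroups)
    fossils = frozenset(taxa) - extant
    config = SimulationConfig(
        model_tree=tree,
        n_unordered=n_unordered,
        n_ordered=n_ordered,
        n_continuous=n_continuous,
        n_states=3,
        rate=rate,
        bm_sigma=1.0,
        missing_rate=missing_rate,
        fossil_taxa=fossils,
        fossil_missing_multiplier=1.5,
        seed=seed,
    )
    return config, extant, outgroups
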