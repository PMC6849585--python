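"""Heuristic parsimony search under backbone constraints with floating taxa.

The scaffold fixes relationships among designated "non-floater" taxa (a
molecular backbone, possibly polytomous); floaters may attach anywhere.  A
candidate tree is admissible when its restriction to the non-floaters
displays every non-trivial backbone split — backbone polytomies may be
resolved freely.

Search is multi-start: seeded random-addition starting trees, then
hill-climbing through SPR and TBR rearrangements that preserve
admissibility, pooling every distinct admissible topology within an
epsilon of the best length found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .characters import CharacterMatrix
from .scoring import ParsimonyScorer, TOL
from .trees import Node, PhyloTree, tree_from_splits


class SearchError(ValueError):
    pass


# ---------------------------------------------------------------- scaffold


@dataclass
class ConstraintScaffold:
    """Backbone tree over non-floaters + free-floating taxa + outgroup order."""

    backbone: PhyloTree
    floaters: frozenset[str] = frozenset()
    outgroups: tuple[str, ...] = ()

    def __post_init__(self):
        self.floaters = frozenset(self.floaters)
        self.outgroups = tuple(self.outgroups)
        bl = self.backbone.leaf_labels()
        if self.floaters & bl:
            raise SearchError("floaters overlap backbone leaves")
        if not set(self.outgroups) <= bl:
            raise SearchError("outgroups must be backbone leaves")
        self._backbone_splits = self.backbone.splits()
        self._restricted_cache: dict[frozenset[str], frozenset] = {}

    def _restricted_splits(self, present: frozenset[str]) -> frozenset:
        cached = self._restricted_cache.get(present)
        if cached is None:
            cached = self.backbone.restricted(present).splits()
            self._restricted_cache[present] = cached
        return cached

    @property
    def backbone_leaves(self) -> frozenset[str]:
        return self.backbone.leaf_labels()

    @property
    def all_taxa(self) -> frozenset[str]:
        return self.backbone_leaves | self.floaters

    @staticmethod
    def unconstrained(
        taxa, outgroups: tuple[str, ...] = ()
    ) -> "ConstraintScaffold":
        """A vacuous scaffold: star backbone, so every topology is admissible."""
        root = Node()
        for t in sorted(taxa):
            root.add_child(Node(t))
        return ConstraintScaffold(
            backbone=PhyloTree(root), floaters=frozenset(), outgroups=outgroups
        )


def is_admissible(tree: PhyloTree, scaffold: ConstraintScaffold) -> bool:
    """True iff the tree restricted to non-floaters displays every
    non-trivial backbone split."""
    if tree.leaf_labels() != scaffold.all_taxa:
        raise SearchError("tree leaves do not match scaffold taxa")
    return _admissible_partial(tree, scaffold)


def _admissible_partial(tree: PhyloTree, scaffold: ConstraintScaffold) -> bool:
    if not scaffold._backbone_splits:
        return True
    present = tree.leaf_labels() & scaffold.backbone_leaves
    if len(present) < 4:
        return True
    want = scaffold._restricted_splits(present)
    if not want:
        return True
    have = tree.restricted(present).splits()
    return want <= have


# ----------------------------------------------- unrooted adjacency trees


class _Utree:
    """Mutable unrooted tree on integer node ids, for rearrangement moves."""

    __slots__ = ("adj", "labels", "_next")

    def __init__(self):
        self.adj: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def connect(self, a: int, b: int) -> None:
        self.adj[a].append(b)
        self.adj[b].append(a)

    def disconnect(self, a: int, b: int) -> None:
        self.adj[a].remove(b)
        self.adj[b].remove(a)

    def copy(self) -> "_Utree":
        t = _Utree()
        t.adj = {k: list(v) for k, v in self.adj.items()}
        t.labels = dict(self.labels)
        t._next = self._next
        return t

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(a, b), max(a, b)) for a in self.adj for b in self.adj[a] if a < b
        )

    def suppress(self, nid: int) -> None:
        """Remove a degree-2 vertex, joining its neighbours."""
        a, b = self.adj[nid]
        self.disconnect(nid, a)
        self.disconnect(nid, b)
        del self.adj[nid]
        self.connect(a, b)

    def subdivide(self, a: int, b: int) -> int:
        self.disconnect(a, b)
        w = self.new_node()
        self.connect(a, w)
        self.connect(w, b)
        return w

    def component(self, start: int, blocked: int) -> set[int]:
        """Nodes reachable from ``start`` without visiting ``blocked``."""
        seen = {start}
        stack = [start]
        while stack:
            n = stack.pop()
            for m in self.adj[n]:
                if m != blocked and m not in seen:
                    seen.add(m)
                    stack.append(m)
        return seen

    # ------------------------------------------------------- conversions
    @staticmethod
    def from_phylo(tree: PhyloTree) -> "_Utree":
        t = _Utree()
        ids: dict[int, int] = {}
        for node in tree.preorder():
            ids[id(node)] = t.new_node(node.label if node.is_leaf else None)
        for node in tree.preorder():
            for c in node.children:
                t.connect(ids[id(node)], ids[id(c)])
        # a rooted degree-2 root is an artefact in unrooted space
        root = ids[id(tree.root)]
        if len(t.adj[root]) == 2:
            t.suppress(root)
        return t

    def to_phylo(self) -> PhyloTree:
        if len(self.adj) == 1:
            (nid,) = self.adj
            return PhyloTree(Node(self.labels[nid]), rooted=False)
        root_id = min(
            (n for n in self.adj if n not in self.labels),
            default=min(self.adj),
        )
        nodes = {root_id: Node(self.labels.get(root_id))}
        stack = [root_id]
        seen = {root_id}
        while stack:
            nid = stack.pop()
            for m in sorted(self.adj[nid]):
                if m in seen:
                    continue
                seen.add(m)
                child = Node(self.labels.get(m))
                nodes[nid].add_child(child)
                nodes[m] = child
                stack.append(m)
        return PhyloTree(nodes[root_id], rooted=False)


def _attach_leaf(t: _Utree, label: str, edge: tuple[int, int]) -> None:
    w = t.subdivide(*edge)
    leaf = t.new_node(label)
    t.connect(w, leaf)


def _neighbors(t: _Utree, tbr: bool):
    """Yield SPR (or TBR) rearrangements of an unrooted binary tree."""
    for u, v in t.edges():
        for cut_from, keep in ((u, v), (v, u)):
            # prune the component containing cut_from; regraft into `keep`'s side
            moving = t.component(cut_from, keep)
            if len(moving) == len(t.adj) - 1:
                continue  # pruning everything but one node: mirror case covers it
            base = t.copy()
            base.disconnect(cut_from, keep)
            if len(base.adj[keep]) == 2:
                base.suppress(keep)
            elif len(base.adj[keep]) < 2:
                continue  # remaining side is a single leaf: no regraft edge
            target_edges = [
                e for e in base.edges() if e[0] not in moving and e[1] not in moving
            ]
            if not target_edges:
                continue
            if tbr and len(base.adj[cut_from]) == 2:
                # re-root the pruned subtree on any of its edges
                attach_points = []
                pruned = base.copy()
                pruned.suppress(cut_from)
                sub_edges = [
                    e for e in pruned.edges() if e[0] in moving and e[1] in moving
                ]
                for pe in sub_edges:
                    for te in target_edges:
                        nt = pruned.copy()
                        r = nt.subdivide(*pe)
                        w = nt.subdivide(*te)
                        nt.connect(r, w)
                        yield nt
            else:
                for te in target_edges:
                    nt = base.copy()
                    w = nt.subdivide(*te)
                    nt.connect(cut_from, w)
                    yield nt


# ------------------------------------------------------------- tree pools


@dataclass
class TreeEnsemble:
    """A scored, de-duplicated pool of trees within epsilon of the best."""

    trees: list[tuple[PhyloTree, float]]
    best_length: float
    epsilon: float
    cap: int
    seed: int = 0
    matrix_id: str = ""
    truncated: bool = False

    def __post_init__(self):
        for _, ln in self.trees:
            if ln > self.best_length + self.epsilon + TOL:
                raise SearchError("ensemble tree exceeds the suboptimality bound")
        if len(self.trees) > self.cap:
            raise SearchError("ensemble exceeds its cap")

    @property
    def mpts(self) -> list[PhyloTree]:
        return [t for t, ln in self.trees if ln <= self.best_length + TOL]

    def topologies(self) -> list[PhyloTree]:
        return [t for t, _ in self.trees]


class _Pool:
    def __init__(self, epsilon: float, cap: int):
        self.epsilon = epsilon
        self.cap = cap
        self.best = np.inf
        self.entries: dict[frozenset, tuple[PhyloTree, float]] = {}
        self.truncated = False

    def key(self, tree: PhyloTree):
        return tree.splits()

    def offer(self, tree: PhyloTree, length: float) -> bool:
        """Record a tree if within bound; returns True if it was new."""
        if length < self.best - TOL:
            self.best = length
            bound = self.best + self.epsilon + TOL
            self.entries = {
                k: v for k, v in self.entries.items() if v[1] <= bound
            }
        if length > self.best + self.epsilon + TOL:
            return False
        k = self.key(tree)
        if k in self.entries:
            return False
        if len(self.entries) >= self.cap:
            self.truncated = True
            return False
        self.entries[k] = (tree, length)
        return True

    def ensemble(self, seed: int, matrix_id: str = "") -> TreeEnsemble:
        trees = sorted(self.entries.values(), key=lambda tl: tl[1])
        return TreeEnsemble(
            trees=list(trees),
            best_length=self.best,
            epsilon=self.epsilon,
            cap=self.cap,
            seed=seed,
            matrix_id=matrix_id,
            truncated=self.truncated,
        )


# ------------------------------------------------------------- operations


def random_addition_tree(
    matrix: CharacterMatrix,
    scaffold: ConstraintScaffold,
    seed: int,
    scorer: ParsimonyScorer | None = None,
) -> PhyloTree:
    """Stepwise addition in a seeded random order.

    Each taxon goes to the admissible insertion edge of minimal length
    increase; ties break on the lowest canonical edge index, so the result
    is deterministic for a fixed seed.
    """
    if scaffold.all_taxa != frozenset(matrix.taxa):
        raise SearchError("scaffold taxa do not match the matrix")
    scorer = scorer or ParsimonyScorer(matrix)
    rng = np.random.default_rng(seed)
    order = [matrix.taxa[i] for i in rng.permutation(len(matrix.taxa))]

    t = _Utree()
    hub = t.new_node()
    for taxon in order[:3]:
        t.connect(hub, t.new_node(taxon))
    if not _admissible_partial(t.to_phylo(), scaffold):  # pragma: no cover
        raise SearchError("scaffold inconsistent at initialisation")
    for taxon in order[3:]:
        best_len = np.inf
        best_tree: _Utree | None = None
        for edge in t.edges():
            cand = t.copy()
            _attach_leaf(cand, taxon, edge)
            phylo = cand.to_phylo()
            if not _admissible_partial(phylo, scaffold):
                continue
            ln = scorer.length(phylo)
            if ln < best_len - TOL:
                best_len = ln
                best_tree = cand
        if best_tree is None:
            raise SearchError(
                f"no admissible insertion for taxon {taxon!r}; "
                "scaffold may be inconsistent"
            )
        t = best_tree
    return t.to_phylo()


def _hill_climb(
    start: _Utree,
    scorer: ParsimonyScorer,
    scaffold: ConstraintScaffold,
    pool: _Pool,
) -> None:
    """SPR-then-TBR descent from a start tree, feeding the pool."""
    current = start
    current_phylo = current.to_phylo()
    current_len = scorer.length(current_phylo)
    pool.offer(current_phylo, current_len)
    mode_tbr = False
    while True:
        best_nb = None
        best_len = current_len
        for nb in _neighbors(current, tbr=mode_tbr):
            phylo = nb.to_phylo()
            if not _admissible_partial(phylo, scaffold):
                continue
            ln = scorer.length(phylo)
            pool.offer(phylo, ln)
            if ln < best_len - TOL:
                best_len = ln
                best_nb = nb
        if best_nb is not None:
            current = best_nb
            current_len = best_len
            mode_tbr = False  # restart cheap sweeps after every improvement
        elif not mode_tbr:
            mode_tbr = True
        else:
            return


def _closure_sweep(
    pool: _Pool, scorer: ParsimonyScorer, scaffold: ConstraintScaffold
) -> None:
    """Expand the pool with admissible rearrangements that stay in bound,
    until no new topology appears (or the cap is hit)."""
    frontier = list(pool.entries.values())
    while frontier and not pool.truncated:
        tree, _ = frontier.pop()
        for nb in _neighbors(_Utree.from_phylo(tree), tbr=True):
            phylo = nb.to_phylo()
            ln = scorer.length(phylo)
            if ln > pool.best + pool.epsilon + TOL:
                continue
            if not _admissible_partial(phylo, scaffold):
                continue
            if pool.offer(phylo, ln):
                frontier.append((phylo, ln))
            if pool.truncated:
                return


def tbr_search(
    matrix: CharacterMatrix,
    scaffold: ConstraintScaffold | None = None,
    n_starts: int = 5,
    seed: int = 0,
    epsilon: float = 0.0,
    cap: int = 99999,
) -> TreeEnsemble:
    """Multi-start SPR/TBR hill-climb; returns all distinct admissible
    topologies within ``epsilon`` of the best length found."""
    if n_starts < 1 or epsilon < 0 or cap < 1:
        raise SearchError("n_starts >= 1, epsilon >= 0 and cap >= 1 required")
    scaffold = scaffold or ConstraintScaffold.unconstrained(matrix.taxa)
    scorer = ParsimonyScorer(matrix)
    pool = _Pool(epsilon, cap)
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        sub = int(rng.integers(0, 2**31 - 1))
        start = random_addition_tree(matrix, scaffold, seed=sub, scorer=scorer)
        _hill_climb(_Utree.from_phylo(start), scorer, scaffold, pool)
    _closure_sweep(pool, scorer, scaffold)
    return pool.ensemble(seed=seed, matrix_id=matrix.title)


def collect_suboptimal(
    matrix: CharacterMatrix,
    scaffold: ConstraintScaffold | None,
    ensemble: TreeEnsemble,
    epsilon_schedule: list[float],
    cap: int = 99999,
) -> TreeEnsemble:
    """Grow a pool of near-optimal trees through an increasing epsilon
    schedule, re-sweeping rearrangements at each level until the cap."""
    scaffold = scaffold or ConstraintScaffold.unconstrained(matrix.taxa)
    scorer = ParsimonyScorer(matrix)
    schedule = sorted(epsilon_schedule)
    if not schedule:
        raise SearchError("epsilon schedule is empty")
    final_eps = schedule[-1]
    pool = _Pool(schedule[0], cap)
    for tree, ln in ensemble.trees:
        pool.offer(tree, ln)
    for eps in schedule:
        pool.epsilon = eps
        _closure_sweep(pool, scorer, scaffold)
        if pool.truncated:
            break
    pool.epsilon = final_eps
    return pool.ensemble(seed=ensemble.seed, matrix_id=ensemble.matrix_id)


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the splits common to all inputs."""
    if not trees:
        raise SearchError("strict consensus of an empty tree list")
    labels = trees[0].leaf_labels()
    for t in trees[1:]:
        if t.leaf_labels() != labels:
            raise SearchError("strict consensus requires identical leaf sets")
    common = frozenset.intersection(*(t.splits() for t in trees))
    return tree_from_splits(common, labels)
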