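"""Leaf-labelled phylogenetic trees with polytomies and node annotations.

Trees are stored as rooted node structures.  An *unrooted* tree is one whose
root is just an arbitrary internal vertex (degree >= 3 after normalisation);
all topology comparisons go through unrooted bipartitions, so the choice of
that vertex never matters.  Rooted semantics (for ancestral-state work and
outgroup-rooted reports) use the same structure with ``rooted=True``, where
the root may have exactly two children.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

Split = frozenset[str]


class TreeError(ValueError):
    """Structural problem with a tree."""


class Node:
    __slots__ = ("label", "parent", "children", "annotations")

    def __init__(self, label: str | None = None):
        self.label = label
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.annotations: dict[str, object] = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or len(self.children)}>"


class PhyloTree:
    """A leaf-labelled tree; polytomies allowed, annotations per node."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate()

    # ----------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -------------------------------------------------------- construction
    @staticmethod
    def from_nested(spec, rooted: bool = False) -> "PhyloTree":
        """Build from nested tuples/lists of labels, e.g. ``(("A","B"),("C","D"),"E")``."""

        def build(obj) -> Node:
            if isinstance(obj, str):
                return Node(obj)
            node = Node()
            for child in obj:
                node.add_child(build(child))
            return node

        return PhyloTree(build(spec), rooted=rooted)

    @staticmethod
    def from_newick(text: str) -> "PhyloTree":
        from .matrix_io import read_trees

        trees = read_trees(text)
        if len(trees) != 1:
            raise TreeError(f"expected one newick tree, found {len(trees)}")
        return trees[0]

    def to_newick(self, annotations: bool = False) -> str:
        from .matrix_io import write_trees

        return write_trees([self], annotations=annotations)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(node.label)
            c.annotations = dict(node.annotations)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted)

    # ------------------------------------------------------------- topology
    def splits(self) -> frozenset[Split]:
        """Non-trivial unrooted bipartitions, each canonicalised to the side
        not containing the lexicographically smallest leaf label."""
        labels = self.leaf_labels()
        if len(labels) < 4:
            return frozenset()
        ref = min(labels)
        out = set()
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])  # type: ignore[list-item]
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node is self.root:
                continue
            side = below[node]
            if ref in side:
                side = labels - side
            if 2 <= len(side) <= len(labels) - 2:
                out.add(side)
        return frozenset(out)

    def clades(self) -> frozenset[Split]:
        """Leaf sets below each internal non-root node (rooted semantics)."""
        out = set()
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])  # type: ignore[list-item]
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
                if node is not self.root:
                    out.add(below[node])
        return frozenset(out)

    def same_topology(self, other: "PhyloTree") -> bool:
        return (
            self.leaf_labels() == other.leaf_labels()
            and self.splits() == other.splits()
        )

    def rf_distance(self, other: "PhyloTree") -> int:
        if self.leaf_labels() != other.leaf_labels():
            raise TreeError("RF distance requires identical leaf sets")
        return len(self.splits() ^ other.splits())

    def is_binary(self) -> bool:
        for node in self.postorder():
            if node.is_leaf:
                continue
            expected = 2 if (node is self.root and self.rooted) else (
                3 if node is self.root else 2
            )
            if len(node.children) != expected:
                return False
        if not self.rooted and self.n_leaves >= 3 and len(self.root.children) != 3:
            return False
        return True

    # ------------------------------------------------------------- surgery
    def suppress_unifurcations(self) -> "PhyloTree":
        """Remove degree-2 internal vertices in place; returns self."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or node is self.root:
                    continue
                if len(node.children) == 1:
                    parent = node.parent
                    child = node.children[0]
                    assert parent is not None
                    idx = parent.children.index(node)
                    node.remove_child(child)
                    parent.children[idx] = child
                    child.parent = parent
                    changed = True
            root = self.root
            while not root.is_leaf and len(root.children) == 1:
                root = root.children[0]
                root.parent = None
                self.root = root
                changed = True
        return self

    def restricted(self, keep: Iterable[str]) -> "PhyloTree":
        """Copy of the tree induced on a subset of leaves, unifurcations suppressed."""
        keep_set = set(keep)
        missing = keep_set - self.leaf_labels()
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        if len(keep_set) < 2:
            raise TreeError("restriction needs at least two leaves")
        tree = self.copy()
        for leaf in list(tree.leaves()):
            if leaf.label not in keep_set:
                parent = leaf.parent
                assert parent is not None
                parent.remove_child(leaf)
        # drop childless internals created by pruning
        pruned = True
        while pruned:
            pruned = False
            for node in list(tree.postorder()):
                if node.is_leaf and node.label is None and node is not tree.root:
                    node.parent.remove_child(node)  # type: ignore[union-attr]
                    pruned = True
        tree.suppress_unifurcations()
        return tree

    def find_clade_node(self, clade: Iterable[str]) -> Node:
        """Node whose leaf set below equals ``clade`` (rooted semantics)."""
        want = frozenset(clade)
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])  # type: ignore[list-item]
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if below[node] == want:
                return node
        raise KeyError(f"clade {sorted(want)} not present in tree")

    def rooted_at_outgroup(self, outgroups: list[str]) -> "PhyloTree":
        """Rooted copy with the first outgroup as sister to everything else.

        Remaining outgroups already branching sequentially are left as they
        lie; only the root placement is changed.
        """
        if not outgroups:
            raise TreeError("need at least one outgroup taxon")
        first = outgroups[0]
        if first not in self.leaf_labels():
            raise TreeError(f"outgroup {first!r} not in tree")
        tree = self.copy()
        leaf = next(n for n in tree.postorder() if n.label == first)
        parent = leaf.parent
        if parent is None:  # two-leaf degenerate tree already rooted at leaf edge
            tree.rooted = True
            return tree
        # reroot on the pendant edge of `first`
        new_root = Node()
        parent.remove_child(leaf)
        path = []
        node: Node | None = parent
        while node is not None:
            path.append(node)
            node = node.parent
        for upper, lower in zip(path[1:], path[:-1]):
            upper.remove_child(lower)
        for lower, upper in zip(path[:-1], path[1:]):
            lower.add_child(upper)
        new_root.add_child(leaf)
        new_root.add_child(path[0])
        out = PhyloTree(new_root, rooted=True)
        out.suppress_unifurcations()
        return out

    # ------------------------------------------------------------ internals
    def _validate(self) -> None:
        labels = [n.label for n in self.postorder() if n.is_leaf]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("unlabelled leaf")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf label(s): {', '.join(dup)}")  # type: ignore[arg-type]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {self.n_leaves} leaves>"


# -------------------------------------------------------------- split utils

def splits_compatible(a: Split, b: Split, labels: frozenset[str]) -> bool:
    """Two unrooted splits are compatible iff some pairwise intersection of
    their sides is empty (the four-point condition)."""
    a2 = labels - a
    b2 = labels - b
    return not (a & b and a & b2 and a2 & b and a2 & b2)


def displays_split(tree: PhyloTree, clade: Iterable[str]) -> bool:
    labels = tree.leaf_labels()
    side = frozenset(clade)
    if not side <= labels:
        raise TreeError("clade is not a subset of the tree's leaves")
    if min(labels) in side:
        side = labels - side
    return side in tree.splits()


def contradicts_split(tree: PhyloTree, clade: Iterable[str]) -> bool:
    labels = tree.leaf_labels()
    k = frozenset(clade)
    return any(not splits_compatible(s, k, labels) for s in tree.splits())


def tree_from_splits(
    splits: Iterable[Split], labels: frozenset[str]
) -> PhyloTree:
    """Unrooted tree containing exactly the given (compatible) splits."""
    ref = min(labels)
    clades = []
    for s in splits:
        side = s if ref not in s else labels - s
        clades.append(side)
    # laminar family check by pairwise compatibility
    for a, b in itertools.combinations(clades, 2):
        if a & b and not (a <= b or b <= a):
            raise TreeError("splits are not mutually compatible")
    clades = sorted(set(clades), key=lambda c: (-len(c), sorted(c)))
    root = Node()
    owner: dict[frozenset[str], Node] = {frozenset(labels): root}
    stack: list[frozenset[str]] = [frozenset(labels)]
    for clade in clades:
        # attach under the smallest strict superset already built
        host = min(
            (c for c in owner if clade < c), key=len
        )
        owner[clade] = owner[host].add_child(Node())
        stack.append(clade)
    for label in sorted(labels):
        host = min((c for c in owner if label in c), key=len)
        owner[host].add_child(Node(label))
    return PhyloTree(root, rooted=False)
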