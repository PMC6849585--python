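"""Independent brute-force oracles for small parsimony problems.

Everything here avoids the package's dynamic programming: topologies are
enumerated by stepwise addition over plain adjacency dicts, and parsimony
lengths come from exhaustive enumeration of ancestral-state assignments.
Only usable for a handful of leaves.
"""

from __future__ import annotations

import itertools

from morphparsimony.trees import Node, PhyloTree


def all_topologies(labels):
    """Yield (adjacency, leaf_map) for every unrooted binary topology."""

    def gen(lbls):
        if len(lbls) == 3:
            adj = {0: [1, 2, 3], 1: [0], 2: [0], 3: [0]}
            leaf = {1: lbls[0], 2: lbls[1], 3: lbls[2]}
            yield adj, leaf, 4
            return
        for adj, leaf, nxt in gen(lbls[:-1]):
            edges = sorted((a, b) for a in adj for b in adj[a] if a < b)
            for a, b in edges:
                adj2 = {k: list(v) for k, v in adj.items()}
                adj2[a].remove(b)
                adj2[b].remove(a)
                w, lf = nxt, nxt + 1
                adj2[w] = [a, b, lf]
                adj2[a].append(w)
                adj2[b].append(w)
                adj2[lf] = [w]
                leaf2 = dict(leaf)
                leaf2[lf] = lbls[-1]
                yield adj2, leaf2, nxt + 2

    if len(labels) < 3:
        raise ValueError("need at least three labels")
    for adj, leaf, _ in gen(list(labels)):
        yield adj, leaf


def adjacency_to_phylo(adj, leaf) -> PhyloTree:
    root = min(k for k in adj if k not in leaf)
    nodes = {root: Node()}
    stack = [root]
    seen = {root}
    while stack:
        n = stack.pop()
        for m in adj[n]:
            if m in seen:
                continue
            seen.add(m)
            child = Node(leaf.get(m))
            nodes[n].add_child(child)
            nodes[m] = child
            stack.append(m)
    return PhyloTree(nodes[root])


def brute_force_steps(adj, leaf, cells, kind):
    """Minimum raw steps by enumerating every ancestral assignment.

    ``cells`` maps taxon -> None (missing), a frozenset of states
    (discrete; polymorphism allowed) or a float (continuous).  ``kind`` is
    "unordered", "ordered" or "continuous".
    """
    internals = [k for k in adj if k not in leaf]
    values = []
    for c in cells.values():
        if c is None:
            continue
        if isinstance(c, frozenset):
            values += [min(c), max(c)]
        else:
            values.append(c)
    if not values:
        return 0.0
    if kind == "unordered":
        cands = sorted({s for c in cells.values() if isinstance(c, frozenset) for s in c})
        cost = lambda x, y: 0.0 if x == y else 1.0
    else:
        cands = sorted(set(values))
        cost = lambda x, y: abs(x - y)

    leaf_opts = {}
    for n, taxon in leaf.items():
        c = cells[taxon]
        if c is None:
            leaf_opts[n] = cands
        elif isinstance(c, frozenset):
            if kind == "unordered":
                leaf_opts[n] = sorted(c)
            else:  # ordered polymorphism = interval convention
                leaf_opts[n] = [v for v in cands if min(c) <= v <= max(c)]
        else:
            leaf_opts[n] = [c]

    edges = [(a, b) for a in adj for b in adj[a] if a < b]
    best = float("inf")
    leaf_ids = list(leaf)
    for internal_states in itertools.product(cands, repeat=len(internals)):
        assign = dict(zip(internals, internal_states))
        for leaf_states in itertools.product(*(leaf_opts[n] for n in leaf_ids)):
            assign.update(zip(leaf_ids, leaf_states))
            total = sum(cost(assign[x], assign[y]) for x, y in edges)
            if total < best:
                best = total
    return best


def exhaustive_best_length(scorer, labels):
    """(best length, list of optimal PhyloTrees) over all topologies,
    scored with the given scorer (used to cross-check search, not scoring)."""
    best = float("inf")
    optima = []
    for adj, leaf in all_topologies(labels):
        tree = adjacency_to_phylo(adj, leaf)
        ln = scorer.length(tree)
        if ln < best - 1e-9:
            best = ln
            optima = [tree]
        elif ln <= best + 1e-9:
            optima.append(tree)
    return best, optima
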