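"""Relative Bremer support over suboptimal tree pools, and rogue-taxon pruning.

For each clade of a reference tree, count the pool trees that display it (S)
and those that contain an incompatible clade (C); support is
100 x (S - C) / max(S, C), so a clade present in every tree scores 100, one
contradicted by every tree scores -100, and one contradicted half as often
as it is supported scores 50.  Clades at or below zero are collapsed.

Unstable ("rogue") taxa are terminals whose wandering placement across the
pool collapses consensus resolution; greedy pruning removes, one at a time,
the taxon whose removal most increases the number of resolved splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .search import SearchError, TreeEnsemble, strict_consensus
from .trees import PhyloTree, splits_compatible


@dataclass
class SupportReport:
    """Annotated consensus plus per-clade counts and pruning trail."""

    consensus: PhyloTree
    clade_table: pd.DataFrame  # clade, S, C, support
    pruned_taxa: list[tuple[str, int]] = field(default_factory=list)

    def to_tsv(self) -> str:
        return self.clade_table.to_csv(sep="\t", index=False, float_format="%.10g")


def _clade_support(
    clade: frozenset[str], pool: list[PhyloTree], labels: frozenset[str]
) -> tuple[int, int, float]:
    canonical = clade if min(labels) not in clade else labels - clade
    s = c = 0
    for tree in pool:
        tsplits = tree.splits()
        if canonical in tsplits:
            s += 1
        elif any(not splits_compatible(x, canonical, labels) for x in tsplits):
            c += 1
        # trees that neither display nor contradict count in neither tally
    denom = max(s, c)
    support = 100.0 * (s - c) / denom if denom else 0.0
    return s, c, support


def relative_bremer(ensemble: TreeEnsemble, reference: PhyloTree) -> SupportReport:
    """Annotate every non-trivial clade of the reference with its relative
    Bremer support in [-100, 100]; collapse clades with support <= 0."""
    if not ensemble.trees:
        raise SearchError("empty ensemble")
    labels = reference.leaf_labels()
    pool = ensemble.topologies()
    for t in pool:
        if t.leaf_labels() != labels:
            raise SearchError("ensemble and reference leaf sets differ")

    out = reference.copy()
    rows = []
    collapse = []
    below: dict[int, frozenset[str]] = {}
    for node in out.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        clade = below[id(node)]
        if node is out.root or len(clade) < 2 or len(labels - clade) < 2:
            continue
        s, c, support = _clade_support(clade, pool, labels)
        node.annotations.update(S=s, C=c, support=support)
        rows.append(
            {
                "clade": ",".join(sorted(clade)),
                "S": s,
                "C": c,
                "support": support,
            }
        )
        if support <= 0:
            collapse.append(node)
    for node in collapse:
        parent = node.parent
        assert parent is not None
        idx = parent.children.index(node)
        parent.children[idx : idx + 1] = node.children
        for child in node.children:
            child.parent = parent
    table = pd.DataFrame(rows, columns=["clade", "S", "C", "support"])
    return SupportReport(consensus=out, clade_table=table)


def find_unstable_taxa(
    ensemble: TreeEnsemble, max_prune: int = 5
) -> SupportReport:
    """Greedy rogue-taxon detection: repeatedly prune the taxon whose
    removal most increases strict-consensus resolution (ties: alphabetical),
    stopping when no removal helps or ``max_prune`` is reached."""
    if len(ensemble.trees) < 2:
        raise SearchError("rogue detection needs at least two trees")
    pool = ensemble.topologies()
    pruned: list[tuple[str, int]] = []
    labels = set(pool[0].leaf_labels())
    resolution = len(strict_consensus(pool).splits())
    while len(pruned) < max_prune and len(labels) > 4:
        best_taxon = None
        best_gain = 0
        for taxon in sorted(labels):
            keep = labels - {taxon}
            reduced = [t.restricted(keep) for t in pool]
            gain = len(strict_consensus(reduced).splits()) - resolution
            if gain > best_gain:
                best_gain = gain
                best_taxon = taxon
        if best_taxon is None:
            break
        pruned.append((best_taxon, best_gain))
        labels.remove(best_taxon)
        pool = [t.restricted(labels) for t in pool]
        resolution += best_gain

    reduced_ensemble = TreeEnsemble(
        trees=[(t, ln) for t, (_, ln) in zip(pool, ensemble.trees)],
        best_length=ensemble.best_length,
        epsilon=ensemble.epsilon,
        cap=ensemble.cap,
        seed=ensemble.seed,
        matrix_id=ensemble.matrix_id,
        truncated=ensemble.truncated,
    )
    report = relative_bremer(reduced_ensemble, strict_consensus(pool))
    report.pruned_taxa = pruned
    return report
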