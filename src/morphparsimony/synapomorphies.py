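"""Parsimony ancestral-state reconstruction and synapomorphy listing.

For each node and character, the MPR (most-parsimonious-reconstruction) set
holds every state — or, for ordered/continuous characters, the interval of
values — attained at that node in at least one minimum-cost reconstruction.
A character is an *unambiguous synapomorphy* of a clade when the MPR of the
branch subtending the clade is disjoint from the MPR of its parent node:
every optimal reconstruction then places a change on that branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characters import CellKind, CharKind, CharacterMatrix
from .scoring import TOL, ScoringError
from .trees import Node, PhyloTree

_INF = np.inf


class ReconstructionError(ValueError):
    pass


@dataclass
class ReconstructionTable:
    """MPR states/values for every node of one character.

    ``mpr`` maps node id to a sorted tuple of candidate states/values; the
    candidate grid is the observed leaf values (exact for linear costs).
    """

    char_index: int
    kind: CharKind
    candidates: tuple[float, ...]
    mpr: dict[int, tuple[float, ...]]
    min_cost: float

    def interval(self, node: Node) -> tuple[float, float]:
        vals = self.mpr[id(node)]
        return vals[0], vals[-1]


@dataclass
class SynapomorphyEntry:
    character: int  # 1-based in reports
    ancestral: tuple[float, ...]
    derived: tuple[float, ...]
    unambiguous: bool


@dataclass
class SynapomorphyList:
    clade: frozenset[str]
    entries: list[SynapomorphyEntry]

    def unambiguous_entries(self) -> list[SynapomorphyEntry]:
        return [e for e in self.entries if e.unambiguous]

    def to_frame(self) -> pd.DataFrame:
        def fmt(vals: tuple[float, ...]) -> str:
            return "/".join(f"{v:g}" for v in vals)

        return pd.DataFrame(
            [
                {
                    "character": e.character,
                    "ancestral": fmt(e.ancestral),
                    "derived": fmt(e.derived),
                    "unambiguous": e.unambiguous,
                }
                for e in self.entries
            ],
            columns=["character", "ancestral", "derived", "unambiguous"],
        )


def _leaf_cost(cell, kind: CharKind, candidates: np.ndarray) -> np.ndarray:
    if cell.is_blank:
        return np.zeros(len(candidates))
    if kind is CharKind.UNORDERED:
        cost = np.full(len(candidates), _INF)
        for s in cell.states:
            cost[np.flatnonzero(candidates == float(s))] = 0.0
        return cost
    if cell.kind is CellKind.CONTINUOUS:
        lo = hi = float(cell.value)
    else:
        lo, hi = float(min(cell.states)), float(max(cell.states))
    inside = (candidates >= lo - TOL) & (candidates <= hi + TOL)
    return np.where(inside, 0.0, _INF)


def _contrib(down: np.ndarray, kind: CharKind, candidates: np.ndarray) -> np.ndarray:
    """min over child states t of down[t] + cost(s, t), for each s."""
    if kind is CharKind.UNORDERED:
        return np.minimum(down, down.min() + 1.0)
    # linear cost over the sorted candidate grid
    f = down.copy()
    gaps = np.diff(candidates)
    for k in range(1, len(f)):
        f[k] = min(f[k], f[k - 1] + gaps[k - 1])
    for k in range(len(f) - 2, -1, -1):
        f[k] = min(f[k], f[k + 1] + gaps[k])
    return f


def mpr_sets(
    tree: PhyloTree, matrix: CharacterMatrix, char_index: int
) -> ReconstructionTable:
    """Marginal MPR sets on a binary rooted tree, by down-pass costs and an
    up-pass that adds each node's outside-of-subtree cost."""
    if not tree.rooted:
        raise ReconstructionError("ancestral reconstruction needs a rooted tree")
    for node in tree.postorder():
        if not node.is_leaf and len(node.children) != 2:
            raise ReconstructionError(
                "polytomous tree: reconstruct on a binary MPT instead"
            )
    d = matrix.defs[char_index]
    if not d.active:
        raise ScoringError(f"character {char_index + 1} is inactive")
    if d.kind is CharKind.UNORDERED:
        observed = sorted(
            {float(s) for c in matrix.column(char_index)
             if c.kind is CellKind.DISCRETE for s in c.states}
        )
        candidates = np.array(observed if observed else [0.0])
    else:
        obs = sorted(set(matrix.observed_numeric(char_index)))
        candidates = np.array(obs if obs else [0.0])

    rows = {t: matrix.row(t) for t in matrix.taxa}
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in rows:
                raise ScoringError(f"leaf {node.label!r} has no matrix row")
            down[id(node)] = _leaf_cost(rows[node.label][char_index], d.kind, candidates)
        else:
            down[id(node)] = sum(
                _contrib(down[id(c)], d.kind, candidates) for c in node.children
            )
    out: dict[int, np.ndarray] = {id(tree.root): np.zeros(len(candidates))}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        for child in node.children:
            siblings = [c for c in node.children if c is not child]
            acc = out[id(node)].copy()
            for s in siblings:
                acc += _contrib(down[id(s)], d.kind, candidates)
            out[id(child)] = _contrib(acc, d.kind, candidates)

    min_cost = float((down[id(tree.root)]).min())
    mpr: dict[int, tuple[float, ...]] = {}
    for node in tree.postorder():
        total = down[id(node)] + out[id(node)]
        best = total.min()
        mpr[id(node)] = tuple(candidates[total <= best + TOL])
    return ReconstructionTable(
        char_index=char_index,
        kind=d.kind,
        candidates=tuple(candidates),
        mpr=mpr,
        min_cost=min_cost,
    )


def _disjoint(
    a: tuple[float, ...], b: tuple[float, ...], kind: CharKind
) -> bool:
    if kind is CharKind.UNORDERED:
        return not set(a) & set(b)
    return a[-1] < b[0] - TOL or b[-1] < a[0] - TOL


def unambiguous_synapomorphies(
    tree: PhyloTree, matrix: CharacterMatrix, clade
) -> SynapomorphyList:
    """Characters whose MPR changes unambiguously on the branch subtending
    ``clade``; ambiguous state changes are flagged but not listed as
    unambiguous."""
    clade = frozenset(clade)
    node = tree.find_clade_node(clade)
    if node.parent is None:
        raise KeyError("clade spans the whole tree; no subtending branch")
    entries = []
    for j in matrix.active_indices():
        table = mpr_sets(tree, matrix, j)
        anc = table.mpr[id(node.parent)]
        der = table.mpr[id(node)]
        if anc == der:
            continue
        entries.append(
            SynapomorphyEntry(
                character=j + 1,
                ancestral=anc,
                derived=der,
                unambiguous=_disjoint(anc, der, matrix.defs[j].kind),
            )
        )
    return SynapomorphyList(clade=clade, entries=entries)


def consistent_synapomorphies(
    trees: list[PhyloTree], matrix: CharacterMatrix, clade
) -> list[int]:
    """1-based characters that are unambiguous synapomorphies of the clade
    on every input tree (intersection over an MPT ensemble)."""
    sets = []
    for t in trees:
        lst = unambiguous_synapomorphies(t, matrix, clade)
        sets.append({e.character for e in lst.unambiguous_entries()})
    return sorted(set.intersection(*sets)) if sets else []
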