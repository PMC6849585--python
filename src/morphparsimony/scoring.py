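"""Exact parsimony length on trees with mixed character kinds.

Unordered characters use generalized Fitch (uniform-cost Sankoff) dynamic
programming; ordered and continuous characters use linear-cost (Wagner)
dynamic programming over a finite candidate-value grid.  For linear costs the
optimum of the L1 Steiner problem on a tree is always attained at observed
leaf values, so restricting ancestral candidates to those values keeps the DP
finite and exact.  Both DPs sum over a node's children directly, so
polytomies are scored exactly without arbitrary resolution.

Polymorphic terminals: unordered cells may realise any member state at zero
cost; ordered cells are treated as the interval [min state, max state].
Missing and inapplicable cells are unconstrained.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characters import CellKind, CharKind, CharacterMatrix, MatrixError
from .trees import PhyloTree

TOL = 1e-9
_INF = np.inf


class ScoringError(ValueError):
    pass


@dataclass
class ScoreReport:
    """Weighted tree length, per-character steps and ensemble indices.

    Vectors are aligned with the matrix's characters; inactive characters
    hold NaN.  ``ci``/``ri`` are filled by :func:`homoplasy_indices` and sum
    over active, parsimony-informative characters only.
    """

    total_length: float
    per_character_steps: np.ndarray
    per_character_min: np.ndarray | None = None
    per_character_max: np.ndarray | None = None
    ci: float | None = None
    ri: float | None = None

    def to_frame(self) -> pd.DataFrame:
        n = len(self.per_character_steps)
        df = pd.DataFrame(
            {
                "character": np.arange(1, n + 1),  # 1-based for reports
                "steps": self.per_character_steps,
            }
        )
        if self.per_character_min is not None:
            df["min_steps"] = self.per_character_min
        if self.per_character_max is not None:
            df["max_steps"] = self.per_character_max
        return df

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False, float_format="%.10g")

    def to_json(self) -> str:
        obj = {
            "total_length": self.total_length,
            "ci": self.ci,
            "ri": self.ri,
            "per_character_steps": [
                None if math.isnan(x) else x for x in self.per_character_steps
            ],
        }
        return json.dumps(obj, indent=2)


# ------------------------------------------------------------------ engine


class ParsimonyScorer:
    """Reusable scorer: precomputes leaf cost tables for one matrix.

    The same instance scores any tree whose leaves are a subset of the
    matrix's taxa (taxa absent from a tree are simply not scored).
    """

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        defs = matrix.defs
        self._active = [d.index for d in defs if d.active]
        if not self._active:
            raise MatrixError("no active characters to score")
        self._weights = np.array([defs[j].weight for j in self._active])

        # partition active characters into an unordered block and a linear
        # block (ordered + continuous share the |x - y| cost)
        self._u_cols = [j for j in self._active if defs[j].kind is CharKind.UNORDERED]
        self._l_cols = [j for j in self._active if defs[j].kind is not CharKind.UNORDERED]

        self._u_K = max((int(defs[j].n_states) for j in self._u_cols), default=0)
        # candidate value grids for the linear block
        vals: list[np.ndarray] = []
        for j in self._l_cols:
            if defs[j].kind is CharKind.ORDERED:
                v = np.arange(int(defs[j].n_states), dtype=float)
            else:
                obs = sorted(set(matrix.observed_numeric(j)))
                if not obs:
                    raise MatrixError(
                        f"character {j + 1}: continuous character with no values"
                    )
                v = np.array(obs, dtype=float)
            vals.append(v)
        self._l_K = max((len(v) for v in vals), default=0)
        if self._l_cols:
            self._l_vals = np.empty((len(self._l_cols), self._l_K))
            for i, v in enumerate(vals):
                self._l_vals[i, : len(v)] = v
                self._l_vals[i, len(v):] = v[-1]  # padding repeats the top value
            self._l_gaps = np.diff(self._l_vals, axis=1)
        # per-taxon leaf cost tables
        self._u_leaf: dict[str, np.ndarray] = {}
        self._l_leaf: dict[str, np.ndarray] = {}
        for ti, taxon in enumerate(matrix.taxa):
            row = matrix.cells[ti]
            if self._u_cols:
                cost = np.zeros((len(self._u_cols), self._u_K))
                for i, j in enumerate(self._u_cols):
                    cell = row[j]
                    if cell.is_blank:
                        continue
                    cost[i, :] = _INF
                    for s in cell.states:  # type: ignore[union-attr]
                        cost[i, s] = 0.0
                self._u_leaf[taxon] = cost
            if self._l_cols:
                cost = np.zeros((len(self._l_cols), self._l_K))
                for i, j in enumerate(self._l_cols):
                    cell = row[j]
                    if cell.is_blank:
                        continue
                    if cell.kind is CellKind.CONTINUOUS:
                        lo = hi = float(cell.value)  # type: ignore[arg-type]
                    else:
                        lo = float(min(cell.states))  # type: ignore[arg-type]
                        hi = float(max(cell.states))  # type: ignore[arg-type]
                    v = self._l_vals[i]
                    inside = (v >= lo - TOL) & (v <= hi + TOL)
                    cost[i, :] = np.where(inside, 0.0, _INF)
                    if not inside.any():
                        raise MatrixError(
                            f"character {j + 1}: cell of {taxon!r} outside the "
                            "candidate grid"
                        )
                self._l_leaf[taxon] = cost

    # ------------------------------------------------------------- DP core
    def _linear_contrib(self, D: np.ndarray) -> np.ndarray:
        """min_t D[:, t] + |v_s - v_t| for each s, via forward/backward sweeps."""
        f = D.copy()
        for k in range(1, f.shape[1]):
            np.minimum(f[:, k], f[:, k - 1] + self._l_gaps[:, k - 1], out=f[:, k])
        b = D.copy()
        for k in range(b.shape[1] - 2, -1, -1):
            np.minimum(b[:, k], b[:, k + 1] + self._l_gaps[:, k], out=b[:, k])
        return np.minimum(f, b)

    @staticmethod
    def _unordered_contrib(D: np.ndarray) -> np.ndarray:
        best = D.min(axis=1, keepdims=True)
        return np.minimum(D, best + 1.0)

    def _down_pass(self, tree: PhyloTree):
        """Bottom-up cost vectors per node; returns (nodes, u_down, l_down)."""
        u_down: dict[int, np.ndarray] = {}
        l_down: dict[int, np.ndarray] = {}
        order = list(tree.postorder())
        for node in order:
            key = id(node)
            if node.is_leaf:
                label = node.label
                if self._u_cols:
                    if label not in self._u_leaf:
                        raise ScoringError(f"leaf {label!r} has no matrix row")
                    u_down[key] = self._u_leaf[label]
                if self._l_cols:
                    if label not in self._l_leaf:
                        raise ScoringError(f"leaf {label!r} has no matrix row")
                    l_down[key] = self._l_leaf[label]
            else:
                if self._u_cols:
                    acc = np.zeros((len(self._u_cols), self._u_K))
                    for c in node.children:
                        acc += self._unordered_contrib(u_down[id(c)])
                    u_down[key] = acc
                if self._l_cols:
                    acc = np.zeros((len(self._l_cols), self._l_K))
                    for c in node.children:
                        acc += self._linear_contrib(l_down[id(c)])
                    l_down[key] = acc
        return order, u_down, l_down

    # ------------------------------------------------------------- public
    def raw_steps(self, tree: PhyloTree) -> np.ndarray:
        """Unweighted minimum step counts, aligned with active characters
        in matrix order (unordered block then linear block re-interleaved)."""
        if tree.n_leaves < 2:
            raise ScoringError("tree must have at least two leaves")
        _, u_down, l_down = self._down_pass(tree)
        root = id(tree.root)
        out = np.empty(len(self._active))
        pos = {j: i for i, j in enumerate(self._active)}
        if self._u_cols:
            mins = u_down[root].min(axis=1)
            for i, j in enumerate(self._u_cols):
                out[pos[j]] = mins[i]
        if self._l_cols:
            mins = l_down[root].min(axis=1)
            for i, j in enumerate(self._l_cols):
                out[pos[j]] = mins[i]
        return out

    def steps(self, tree: PhyloTree) -> np.ndarray:
        """Weighted steps per active character (matrix order)."""
        return self.raw_steps(tree) * self._weights

    def length(self, tree: PhyloTree) -> float:
        return float(self.steps(tree).sum())

    def full_steps(self, tree: PhyloTree) -> np.ndarray:
        """Weighted steps aligned with *all* characters; NaN where inactive."""
        out = np.full(self.matrix.n_characters, np.nan)
        out[self._active] = self.steps(tree)
        return out

    def active_indices(self) -> list[int]:
        return list(self._active)


# ---------------------------------------------------------- operations API


def character_steps(tree: PhyloTree, matrix: CharacterMatrix, char_index: int) -> float:
    """Weighted minimum number of changes of one character on one tree."""
    d = matrix.defs[char_index]
    if not d.active:
        raise ScoringError(f"character {char_index + 1} is inactive")
    scorer = ParsimonyScorer(matrix)
    full = scorer.full_steps(tree)
    return float(full[char_index])


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> ScoreReport:
    scorer = ParsimonyScorer(matrix)
    full = scorer.full_steps(tree)
    return ScoreReport(
        total_length=float(np.nansum(full)), per_character_steps=full
    )


def char_step_bounds(matrix: CharacterMatrix, char_index: int) -> tuple[float, float]:
    """(minimum steps over all trees, maximum = star-tree steps), unweighted
    then scaled by the character's weight.

    Polymorphic cells are resolved to their cheapest state for both bounds;
    blank cells contribute nothing.
    """
    d = matrix.defs[char_index]
    if not d.active:
        raise ScoringError(f"character {char_index + 1} is inactive")
    cells = [c for c in matrix.column(char_index) if not c.is_blank]
    if not cells:
        return 0.0, 0.0
    if d.kind is CharKind.UNORDERED:
        state_sets = [set(c.states) for c in cells]  # type: ignore[arg-type]
        universe = sorted(set().union(*state_sets))
        # minimum over trees: smallest state subset hitting every cell, - 1
        m = None
        for r in range(1, len(universe) + 1):
            for combo in itertools.combinations(universe, r):
                cs = set(combo)
                if all(cs & s for s in state_sets):
                    m = r - 1
                    break
            if m is not None:
                break
        assert m is not None
        # star tree: best centre state
        g = min(
            sum(0 if s in ss else 1 for ss in state_sets) for s in universe
        )
    else:
        intervals = []
        for c in cells:
            if c.kind is CellKind.CONTINUOUS:
                intervals.append((float(c.value), float(c.value)))  # type: ignore[arg-type]
            else:
                intervals.append(
                    (float(min(c.states)), float(max(c.states)))  # type: ignore[arg-type]
                )
        lo_max = max(lo for lo, _ in intervals)
        hi_min = min(hi for _, hi in intervals)
        m = max(0.0, lo_max - hi_min)
        candidates = sorted({v for pair in intervals for v in pair})
        g = min(
            sum(max(0.0, lo - c, c - hi) for lo, hi in intervals)
            for c in candidates
        )
    w = d.weight
    return float(m) * w, float(g) * w


def homoplasy_indices(tree: PhyloTree, matrix: CharacterMatrix) -> ScoreReport:
    """Ensemble consistency and retention indices of a tree on a matrix.

    CI = sum(min) / sum(steps), RI = (sum(max) - sum(steps)) /
    (sum(max) - sum(min)); sums run over active, parsimony-informative
    characters (those with max > min).
    """
    scorer = ParsimonyScorer(matrix)
    full = scorer.full_steps(tree)
    n = matrix.n_characters
    mins = np.full(n, np.nan)
    maxs = np.full(n, np.nan)
    for j in scorer.active_indices():
        mins[j], maxs[j] = char_step_bounds(matrix, j)
    informative = [
        j for j in scorer.active_indices() if maxs[j] - mins[j] > TOL
    ]
    if not informative:
        raise ScoringError("all characters are parsimony-uninformative")
    s = float(full[informative].sum())
    mn = float(mins[informative].sum())
    mx = float(maxs[informative].sum())
    ci = mn / s if s > TOL else 1.0
    ri = (mx - s) / (mx - mn)
    return ScoreReport(
        total_length=float(np.nansum(full)),
        per_character_steps=full,
        per_character_min=mins,
        per_character_max=maxs,
        ci=ci,
        ri=ri,
    )
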