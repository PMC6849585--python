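"""Range normalisation: one observed character range = one parsimony step.

Continuous characters get weight 1/(max - min) over their non-missing
values, so that spanning the full observed range costs exactly one weighted
step.  Ordered multistate characters get weight 1/(max state - min state)
over observed states — a three-state character spanning 0..2 is weighted
0.5, since two changes separate its endpoints.  Binary and unordered
characters need no weighting.  Characters with zero observed range carry no
signal and are deactivated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .characters import (
    CellKind,
    CharKind,
    CharacterDef,
    CharacterMatrix,
    MatrixError,
    StateCell,
)

TOL = 1e-9


@dataclass
class WeightingReport:
    """Per-character record of observed range and assigned weight."""

    table: pd.DataFrame  # character (1-based), kind, min, max, weight, active, reason

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.10g")


def assign_range_weights(
    matrix: CharacterMatrix,
) -> tuple[CharacterMatrix, WeightingReport]:
    """Return a re-weighted copy of the matrix plus a per-character report.

    Idempotent: weights depend only on observed cell ranges, never on the
    incoming weights.
    """
    out = matrix.copy()
    records = []
    for d in out.defs:
        obs = out.observed_numeric(d.index)
        lo = min(obs) if obs else math.nan
        hi = max(obs) if obs else math.nan
        reason = ""
        if d.kind is CharKind.CONTINUOUS:
            if not obs:
                raise MatrixError(
                    f"character {d.index + 1}: continuous character with no values"
                )
            span = hi - lo
            if span <= TOL:
                d.active = False
                d.inactive_reason = reason = "invariant"
                d.weight = 1.0
            else:
                d.weight = 1.0 / span
        elif d.kind is CharKind.ORDERED:
            span = (hi - lo) if obs else 0.0
            if span < 1.0:
                d.active = False
                d.inactive_reason = reason = "invariant"
                d.weight = 1.0
            else:
                d.weight = 1.0 / span
        else:  # unordered (includes binary): no weighting
            d.weight = 1.0
            distinct = set()
            for cell in out.column(d.index):
                if cell.kind is CellKind.DISCRETE:
                    distinct |= cell.states  # type: ignore[arg-type]
            if len(distinct) < 2:
                d.active = False
                d.inactive_reason = reason = "invariant"
        if not d.active and not reason:
            reason = d.inactive_reason
        records.append(
            {
                "character": d.index + 1,
                "kind": d.kind.value,
                "observed_min": lo,
                "observed_max": hi,
                "weight": d.weight,
                "active": d.active,
                "reason": reason,
            }
        )
    if not any(d.active for d in out.defs):
        raise MatrixError("no active characters remain after range weighting")
    return out, WeightingReport(pd.DataFrame.from_records(records))


def discretize_continuous(matrix: CharacterMatrix, n_bins: int = 4) -> CharacterMatrix:
    """Equal-width binning of every continuous character into an ordered one.

    Bins are half-open [lo + k*w, lo + (k+1)*w) over the observed range with
    the last bin closed, giving ordered states 0..n_bins-1; missing cells
    stay missing.  Zero-range characters are deactivated rather than binned.
    A subsequent :func:`assign_range_weights` gives each binned character
    weight 1/(n_bins - 1).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    out = matrix.copy()
    for d in out.defs:
        if d.kind is not CharKind.CONTINUOUS:
            continue
        obs = out.observed_numeric(d.index)
        if not obs:
            raise MatrixError(
                f"character {d.index + 1}: continuous character with no values"
            )
        lo, hi = min(obs), max(obs)
        if hi - lo <= TOL:
            d.kind = CharKind.ORDERED
            d.n_states = n_bins
            d.active = False
            d.inactive_reason = "invariant"
            for row in out.cells:
                if not row[d.index].is_blank:
                    row[d.index] = StateCell.of_states([0])
            continue
        width = (hi - lo) / n_bins
        d.kind = CharKind.ORDERED
        d.n_states = n_bins
        for row in out.cells:
            cell = row[d.index]
            if cell.is_blank:
                continue
            k = int((float(cell.value) - lo) / width)  # type: ignore[arg-type]
            row[d.index] = StateCell.of_states([min(k, n_bins - 1)])
    out.validate()
    return out
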