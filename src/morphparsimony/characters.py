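"""Core data model: character matrices of mixed discrete and continuous characters.

A :class:`CharacterMatrix` is a taxa x characters grid of :class:`StateCell`
values, with a :class:`CharacterDef` per column describing its kind
(unordered / ordered / continuous), declared state count, weight and active
flag.  Cells can be missing (``?``), inapplicable (``-``), a non-empty set of
discrete states (polymorphism allowed) or a single finite real value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence


class CellKind(str, Enum):
    MISSING = "missing"
    INAPPLICABLE = "inapplicable"
    DISCRETE = "discrete-set"
    CONTINUOUS = "continuous"


class CharKind(str, Enum):
    UNORDERED = "unordered"
    ORDERED = "ordered"
    CONTINUOUS = "continuous"


class MatrixError(ValueError):
    """Validation failure in a character matrix."""


class FormatError(ValueError):
    """Malformed matrix or tree text."""


@dataclass(frozen=True)
class StateCell:
    """One observation: a state set, a real value, or an absence marker."""

    kind: CellKind
    states: frozenset[int] | None = None
    value: float | None = None

    @staticmethod
    def missing() -> "StateCell":
        return StateCell(CellKind.MISSING)

    @staticmethod
    def inapplicable() -> "StateCell":
        return StateCell(CellKind.INAPPLICABLE)

    @staticmethod
    def of_states(states: Iterable[int]) -> "StateCell":
        s = frozenset(int(x) for x in states)
        if not s:
            raise MatrixError("discrete cell needs at least one state")
        if any(x < 0 for x in s):
            raise MatrixError("discrete states must be non-negative")
        return StateCell(CellKind.DISCRETE, states=s)

    @staticmethod
    def of_value(value: float) -> "StateCell":
        v = float(value)
        if not math.isfinite(v):
            raise MatrixError("continuous cell value must be finite")
        return StateCell(CellKind.CONTINUOUS, value=v)

    @property
    def is_blank(self) -> bool:
        """True for missing and inapplicable cells (both score as no data)."""
        return self.kind in (CellKind.MISSING, CellKind.INAPPLICABLE)

    def __post_init__(self) -> None:
        if self.kind is CellKind.DISCRETE and not self.states:
            raise MatrixError("discrete cell needs a non-empty state set")
        if self.kind is CellKind.CONTINUOUS:
            if self.value is None or not math.isfinite(self.value):
                raise MatrixError("continuous cell value must be finite")
        if self.is_blank and (self.states is not None or self.value is not None):
            raise MatrixError("missing/inapplicable cells carry no payload")


@dataclass
class CharacterDef:
    """Column metadata: kind, declared state count, weight, activity, labels."""

    index: int
    kind: CharKind
    n_states: int | None = None
    weight: float = 1.0
    active: bool = True
    label: str = ""
    anatomy: str | None = None  # dental / cranial / postcranial
    inactive_reason: str = ""

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise MatrixError(f"character {self.index}: weight must be positive")
        if self.kind is CharKind.CONTINUOUS:
            if self.n_states is not None:
                raise MatrixError(
                    f"character {self.index}: continuous characters have no n_states"
                )
        else:
            if self.n_states is None or self.n_states < 2:
                raise MatrixError(
                    f"character {self.index}: discrete characters need n_states >= 2"
                )
        if self.anatomy is not None and self.anatomy not in (
            "dental",
            "cranial",
            "postcranial",
        ):
            raise MatrixError(f"character {self.index}: unknown anatomy tag {self.anatomy!r}")


@dataclass
class CharacterMatrix:
    """Taxa x characters grid with per-character definitions."""

    taxa: list[str]
    defs: list[CharacterDef]
    cells: list[list[StateCell]]
    title: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ api
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.defs)

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"taxon {name!r} not in matrix") from None

    def row(self, taxon: str) -> Sequence[StateCell]:
        return self.cells[self.taxon_index(taxon)]

    def column(self, char_index: int) -> list[StateCell]:
        return [r[char_index] for r in self.cells]

    def active_indices(self) -> list[int]:
        return [d.index for d in self.defs if d.active]

    def observed_numeric(self, char_index: int) -> list[float]:
        """All scored numeric observations in a column.

        Discrete polymorphic cells contribute both their min and max state;
        blank cells contribute nothing.
        """
        d = self.defs[char_index]
        out: list[float] = []
        for cell in self.column(char_index):
            if cell.is_blank:
                continue
            if d.kind is CharKind.CONTINUOUS:
                out.append(float(cell.value))  # type: ignore[arg-type]
            else:
                out.append(float(min(cell.states)))  # type: ignore[arg-type]
                if len(cell.states) > 1:  # type: ignore[arg-type]
                    out.append(float(max(cell.states)))  # type: ignore[arg-type]
        return out

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            defs=[replace(d) for d in self.defs],
            cells=[list(r) for r in self.cells],
            title=self.title,
        )

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        if not self.taxa:
            raise MatrixError("matrix has no taxa")
        if any(not t for t in self.taxa):
            raise MatrixError("empty taxon name")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixError(f"duplicate taxon name(s): {', '.join(dup)}")
        if len(self.cells) != len(self.taxa):
            raise MatrixError(
                f"matrix has {len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        for i, d in enumerate(self.defs):
            if d.index != i:
                raise MatrixError(f"character def at position {i} has index {d.index}")
        for t, row in zip(self.taxa, self.cells):
            if len(row) != len(self.defs):
                raise MatrixError(
                    f"row {t!r} has {len(row)} cells for {len(self.defs)} characters"
                )
            for j, cell in enumerate(row):
                d = self.defs[j]
                if cell.is_blank:
                    continue
                if d.kind is CharKind.CONTINUOUS:
                    if cell.kind is not CellKind.CONTINUOUS:
                        raise MatrixError(
                            f"taxon {t!r}, character {j + 1}: discrete cell in a "
                            "continuous character"
                        )
                else:
                    if cell.kind is not CellKind.DISCRETE:
                        raise MatrixError(
                            f"taxon {t!r}, character {j + 1}: continuous cell in a "
                            "discrete character"
                        )
                    assert cell.states is not None
                    if max(cell.states) >= int(d.n_states):  # type: ignore[arg-type]
                        raise MatrixError(
                            f"taxon {t!r}, character {j + 1}: state "
                            f"{max(cell.states)} out of range for "
                            f"{d.n_states}-state character"
                        )


def matrix_from_strings(
    rows: dict[str, str],
    kinds: Sequence[CharKind] | None = None,
    ordered: Iterable[int] = (),
) -> CharacterMatrix:
    """Build a discrete matrix from compact row strings (test/demo helper).

    ``rows`` maps taxon name to a digit string; ``[ab]`` spans polymorphism,
    ``?`` missing, ``-`` inapplicable.  ``ordered`` lists 0-based indices of
    ordered characters (the rest are unordered), unless ``kinds`` is given.
    """
    from .matrix_io import _parse_row_tokens  # local import: io depends on us

    taxa = list(rows)
    parsed = {t: _parse_row_tokens(rows[t], taxon=t) for t in taxa}
    ncols = {len(v) for v in parsed.values()}
    if len(ncols) != 1:
        raise MatrixError("rows have unequal character counts")
    n = ncols.pop()
    ordered_set = set(ordered)
    defs = []
    for j in range(n):
        kind = kinds[j] if kinds is not None else (
            CharKind.ORDERED if j in ordered_set else CharKind.UNORDERED
        )
        col_states = [
            max(parsed[t][j].states)
            for t in taxa
            if parsed[t][j].kind is CellKind.DISCRETE
        ]
        n_states = max(col_states, default=0) + 1
        defs.append(CharacterDef(index=j, kind=kind, n_states=max(2, n_states)))
    return CharacterMatrix(taxa=taxa, defs=defs, cells=[parsed[t] for t in taxa])
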