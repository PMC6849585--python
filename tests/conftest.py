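import random

import pytest

from morphparsimony import (
    CharKind,
    CharacterDef,
    CharacterMatrix,
    PhyloTree,
    StateCell,
    matrix_from_strings,
)


@pytest.fixture
def quartet_matrix():
    """One binary character in the A=0,B=1,C=0,D=1 conflict pattern."""
    return matrix_from_strings({"A": "0", "B": "1", "C": "0", "D": "1"})


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_nested((("A", "B"), ("C", "D")))


@pytest.fixture
def mixed_matrix():
    """Small matrix exercising all cell and character kinds."""
    defs = [
        CharacterDef(index=0, kind=CharKind.UNORDERED, n_states=3),
        CharacterDef(index=1, kind=CharKind.ORDERED, n_states=3),
        CharacterDef(index=2, kind=CharKind.CONTINUOUS),
    ]
    cells = [
        [StateCell.of_states([0, 1]), StateCell.of_states([0]), StateCell.of_value(2.0)],
        [StateCell.missing(), StateCell.of_states([1]), StateCell.of_value(3.0)],
        [StateCell.of_states([2]), StateCell.inapplicable(), StateCell.of_value(4.0)],
        [StateCell.of_states([1]), StateCell.of_states([2]), StateCell.missing()],
    ]
    return CharacterMatrix(taxa=["A", "B", "C", "D"], defs=defs, cells=cells)


def random_small_matrix(rng: random.Random, n_taxa: int, kind: str) -> tuple:
    """(matrix, cells-dict) with one character of the given kind; at least
    two scored taxa guaranteed."""
    labels = [f"L{i}" for i in range(n_taxa)]
    while True:
        cells = {}
        for lbl in labels:
            r = rng.random()
            if r < 0.15:
                cells[lbl] = None
            elif kind == "continuous":
                cells[lbl] = round(rng.uniform(0.0, 3.0), 2)
            elif r < 0.3:
                cells[lbl] = frozenset(rng.sample([0, 1, 2], 2))
            else:
                cells[lbl] = frozenset([rng.choice([0, 1, 2])])
        if sum(c is not None for c in cells.values()) >= 2:
            break
    if kind == "continuous":
        defs = [CharacterDef(index=0, kind=CharKind.CONTINUOUS)]
        mk = lambda c: StateCell.missing() if c is None else StateCell.of_value(c)
    else:
        ck = CharKind.UNORDERED if kind == "unordered" else CharKind.ORDERED
        defs = [CharacterDef(index=0, kind=ck, n_states=3)]
        mk = lambda c: StateCell.missing() if c is None else StateCell.of_states(c)
    matrix = CharacterMatrix(
        taxa=labels, defs=defs, cells=[[mk(cells[lbl])] for lbl in labels]
    )
    return matrix, cells
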