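"""Read/write character matrices (TNT, NEXUS) and trees (Newick).

TNT dialect
-----------
A pragmatic subset of TNT's ``xread``: an optional quoted title, ``nchar
ntax`` header, then data rows, optionally split into interleaved blocks
introduced by ``&[cont]`` (whitespace-separated reals) and ``&[num]``
(compact digit strings; ``[ab]`` polymorphism, ``?`` missing, ``-``
inapplicable).  Character typing comes from ``ccode`` statements (``+``
ordered, ``-`` unordered, ``]`` inactive, ``/w`` weight; 0-based indices,
``a.b`` ranges).  The writer records declared per-character state counts
inside the title comment (``mp-nstates``), which TNT ignores but this reader
recovers, making round-trips lossless.

NEXUS dialect
-------------
TAXA + CHARACTERS blocks (``DATATYPE=STANDARD`` and ``DATATYPE=CONTINUOUS``)
plus an ASSUMPTIONS block with ``TYPESET`` (ord/unord) and ``WTSET``.
Square-bracket comments carry the same lossless metadata (column order
across blocks and declared state counts); other NEXUS software ignores them.

Trees are Newick via dendropy; ``[&key=value]`` node comments round-trip as
annotations.
"""

from __future__ import annotations

import io
import math
import os
import re
from pathlib import Path

import dendropy

from .characters import (
    CellKind,
    CharKind,
    CharacterDef,
    CharacterMatrix,
    FormatError,
    MatrixError,
    StateCell,
)
from .trees import Node, PhyloTree, TreeError


class CapabilityError(ValueError):
    """The requested dialect cannot express a feature of the data."""


# --------------------------------------------------------------------- util

def _load_text(source: str | os.PathLike) -> str:
    """Return text content; strings containing newlines/format markers are
    treated as literal content, anything else as a path."""
    if isinstance(source, os.PathLike):
        return Path(source).read_text()
    if "\n" in source or source.lstrip().lower().startswith(("xread", "#nexus", "(")):
        return source
    return Path(source).read_text()


def _parse_row_tokens(text: str, taxon: str = "?") -> list[StateCell]:
    """Parse a compact discrete row string into cells."""
    cells: list[StateCell] = []
    i = 0
    col = 0
    while i < len(text):
        ch = text[i]
        col += 1
        if ch.isspace():
            col -= 1
            i += 1
            continue
        if ch == "?":
            cells.append(StateCell.missing())
        elif ch == "-":
            cells.append(StateCell.inapplicable())
        elif ch.isdigit():
            cells.append(StateCell.of_states([int(ch)]))
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise FormatError(
                    f"row {taxon!r}: unterminated polymorphism bracket at column {col}"
                )
            inner = text[i + 1 : j]
            if not inner or not inner.isdigit():
                raise FormatError(
                    f"row {taxon!r}: bad polymorphism token '[{inner}]' at column {col}"
                )
            cells.append(StateCell.of_states(int(c) for c in inner))
            i = j
        else:
            raise FormatError(
                f"row {taxon!r}: unknown state token {ch!r} at column {col}"
            )
        i += 1
    return cells


def _parse_continuous_tokens(tokens: list[str], taxon: str) -> list[StateCell]:
    cells: list[StateCell] = []
    for col, tok in enumerate(tokens, start=1):
        if tok == "?":
            cells.append(StateCell.missing())
        elif tok == "-":
            cells.append(StateCell.inapplicable())
        else:
            try:
                v = float(tok)
            except ValueError:
                raise FormatError(
                    f"row {taxon!r}: bad continuous value {tok!r} at column {col}"
                ) from None
            if not math.isfinite(v):
                raise FormatError(
                    f"row {taxon!r}: non-finite continuous value at column {col}"
                )
            cells.append(StateCell.of_value(v))
    return cells


def _expand_indices(tokens: list[str], n_char: int, where: str) -> list[int]:
    out: list[int] = []
    for tok in tokens:
        m = re.fullmatch(r"(\d+)\.(\d+)", tok)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            out.extend(range(lo, hi + 1))
        elif tok.isdigit():
            out.append(int(tok))
        else:
            raise FormatError(f"{where}: bad character index token {tok!r}")
    bad = [i for i in out if i >= n_char]
    if bad:
        raise FormatError(f"{where}: character index {bad[0]} out of range")
    return out


def _format_indices(indices: list[int]) -> str:
    """Compact 0-based index list with a.b ranges."""
    parts: list[str] = []
    i = 0
    while i < len(indices):
        j = i
        while j + 1 < len(indices) and indices[j + 1] == indices[j] + 1:
            j += 1
        if j - i >= 2:
            parts.append(f"{indices[i]}.{indices[j]}")
        else:
            parts.extend(str(x) for x in indices[i : j + 1])
        i = j + 1
    return " ".join(parts)


def _fmt_float(v: float) -> str:
    s = repr(float(v))
    return s


# ---------------------------------------------------------------- TNT read

def _read_tnt(text: str) -> CharacterMatrix:
    body = text
    m = re.search(r"\bxread\b", body, flags=re.IGNORECASE)
    if not m:
        raise FormatError("no xread block found in TNT input")
    pos = m.end()
    # optional quoted title
    title = ""
    nstates_decl: list[str] | None = None
    tm = re.match(r"\s*'([^']*)'", body[pos:], flags=re.DOTALL)
    if tm:
        title = tm.group(1)
        pos += tm.end()
        nm = re.search(r"mp-nstates:\s*([-\d\s]+)$", title)
        if nm:
            nstates_decl = nm.group(1).split()
            title = title[: nm.start()].rstrip("; \t\n")
    hm = re.match(r"\s*(\d+)\s+(\d+)", body[pos:])
    if not hm:
        raise FormatError("xread header must declare 'nchar ntax'")
    n_char, n_tax = int(hm.group(1)), int(hm.group(2))
    pos += hm.end()
    end = body.find(";", pos)
    if end < 0:
        raise FormatError("unterminated xread block (missing ';')")
    data = body[pos:end]
    rest = body[end + 1 :]

    # split into interleaved blocks; a block with no marker is discrete
    chunks: list[tuple[str, str]] = []
    marker_re = re.compile(r"&\[(\w+)\]")
    last = 0
    last_kind = "num"
    for mm in marker_re.finditer(data):
        if data[last : mm.start()].strip():
            chunks.append((last_kind, data[last : mm.start()]))
        last_kind = mm.group(1).lower()
        last = mm.end()
    if data[last:].strip():
        chunks.append((last_kind, data[last:]))
    if not chunks:
        raise FormatError("xread block contains no data rows")

    taxa: list[str] = []
    block_cols: list[tuple[str, list[list[StateCell]]]] = []  # (kind, rows)
    for kind, chunk in chunks:
        if kind not in ("num", "cont"):
            raise FormatError(f"unknown xread block marker '&[{kind}]'")
        rows: list[tuple[str, list[StateCell]]] = []
        for line in chunk.splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            name = parts[0]
            if kind == "cont":
                cells = _parse_continuous_tokens(parts[1:], taxon=name)
            else:
                cells = _parse_row_tokens("".join(parts[1:]), taxon=name)
            rows.append((name, cells))
        if not rows:
            raise FormatError("empty data block in xread")
        names = [n for n, _ in rows]
        if not taxa:
            taxa = names
            if len(taxa) != n_tax:
                raise FormatError(
                    f"header declares {n_tax} taxa but block lists {len(taxa)} "
                    f"(first row {names[0]!r})"
                )
        elif names != taxa:
            raise FormatError("interleaved blocks list taxa in different orders")
        width = {len(c) for _, c in rows}
        if len(width) != 1:
            bad = next(n for n, c in rows if len(c) != max(width))
            raise FormatError(f"row {bad!r} has a deviating character count")
        block_cols.append((kind, [c for _, c in rows]))

    # assemble global columns in file order
    kinds: list[CharKind] = []
    grid: list[list[StateCell]] = [[] for _ in taxa]
    for kind, rows in block_cols:
        w = len(rows[0])
        ck = CharKind.CONTINUOUS if kind == "cont" else CharKind.UNORDERED
        kinds.extend([ck] * w)
        for r, cells in zip(grid, rows):
            r.extend(cells)
    if len(kinds) != n_char:
        raise FormatError(
            f"header declares {n_char} characters but rows supply {len(kinds)} "
            f"(row {taxa[0]!r})"
        )

    defs = _defs_from_kinds(kinds, grid, nstates_decl)
    _apply_ccode(rest, defs)
    try:
        return CharacterMatrix(taxa=taxa, defs=defs, cells=grid, title=title)
    except MatrixError:
        raise


def _defs_from_kinds(
    kinds: list[CharKind],
    grid: list[list[StateCell]],
    nstates_decl: list[str] | None,
) -> list[CharacterDef]:
    if nstates_decl is not None and len(nstates_decl) != len(kinds):
        raise FormatError("mp-nstates declaration length mismatch")
    defs = []
    for j, kind in enumerate(kinds):
        n_states = None
        if kind is not CharKind.CONTINUOUS:
            if nstates_decl is not None and nstates_decl[j] != "-":
                n_states = int(nstates_decl[j])
            else:
                observed = [
                    max(row[j].states)  # type: ignore[arg-type]
                    for row in grid
                    if row[j].kind is CellKind.DISCRETE
                ]
                n_states = max(2, max(observed, default=1) + 1)
        defs.append(CharacterDef(index=j, kind=kind, n_states=n_states))
    return defs


def _apply_ccode(rest: str, defs: list[CharacterDef]) -> None:
    for stmt in re.findall(r"\bccode\b([^;]*);", rest, flags=re.IGNORECASE):
        tokens = stmt.replace("/", " / ").split()
        op: str | None = None
        weight = 1.0
        i = 0
        while i < len(tokens):
            tok = tokens[i]
            if tok in ("+", "-", "[", "]"):
                op = tok
            elif tok == "/":
                i += 1
                if i >= len(tokens):
                    raise FormatError("ccode: '/' without a weight value")
                try:
                    weight = float(tokens[i])
                except ValueError:
                    raise FormatError(
                        f"ccode: bad weight value {tokens[i]!r}"
                    ) from None
                op = "/"
            else:
                for idx in _expand_indices([tok], len(defs), where="ccode"):
                    d = defs[idx]
                    if op == "+":
                        if d.kind is CharKind.CONTINUOUS:
                            raise FormatError(
                                f"ccode: character {idx} is continuous, cannot order"
                            )
                        d.kind = CharKind.ORDERED
                    elif op == "-":
                        if d.kind is not CharKind.CONTINUOUS:
                            d.kind = CharKind.UNORDERED
                    elif op == "[":
                        d.active = True
                    elif op == "]":
                        d.active = False
                        d.inactive_reason = d.inactive_reason or "deactivated in file"
                    elif op == "/":
                        d.weight = weight
                    else:
                        raise FormatError("ccode: index before any operation token")
            i += 1


# --------------------------------------------------------------- TNT write

def _cell_to_token(cell: StateCell, kind: CharKind) -> str:
    if cell.kind is CellKind.MISSING:
        return "?"
    if cell.kind is CellKind.INAPPLICABLE:
        return "-"
    if kind is CharKind.CONTINUOUS:
        return _fmt_float(cell.value)  # type: ignore[arg-type]
    states = sorted(cell.states)  # type: ignore[arg-type]
    if any(s > 9 for s in states):
        raise CapabilityError("TNT dialect supports single-digit states only")
    if len(states) == 1:
        return str(states[0])
    return "[" + "".join(str(s) for s in states) + "]"


def _write_tnt(matrix: CharacterMatrix) -> str:
    name_w = max(len(t) for t in matrix.taxa) + 2
    nstates = " ".join(
        "-" if d.kind is CharKind.CONTINUOUS else str(d.n_states) for d in matrix.defs
    )
    title = (matrix.title + "; " if matrix.title else "") + "mp-nstates: " + nstates
    out = io.StringIO()
    out.write("xread\n")
    out.write(f"'{title}'\n")
    out.write(f"{matrix.n_characters} {matrix.n_taxa}\n")

    # contiguous runs of same storage class become interleaved blocks
    runs: list[tuple[str, list[int]]] = []
    for d in matrix.defs:
        cls = "cont" if d.kind is CharKind.CONTINUOUS else "num"
        if runs and runs[-1][0] == cls:
            runs[-1][1].append(d.index)
        else:
            runs.append((cls, [d.index]))
    lone_discrete = len(runs) == 1 and runs[0][0] == "num"
    for cls, cols in runs:
        if not lone_discrete:
            out.write(f"&[{cls}]\n")
        for ti, taxon in enumerate(matrix.taxa):
            toks = [
                _cell_to_token(matrix.cells[ti][j], matrix.defs[j].kind) for j in cols
            ]
            sep = " " if cls == "cont" else ""
            out.write(f"{taxon:<{name_w}}{sep.join(toks)}\n")
    out.write(";\n")

    ordered = [d.index for d in matrix.defs if d.kind is CharKind.ORDERED]
    if ordered:
        out.write(f"ccode + {_format_indices(ordered)};\n")
    inactive = [d.index for d in matrix.defs if not d.active]
    if inactive:
        out.write(f"ccode ] {_format_indices(inactive)};\n")
    by_weight: dict[float, list[int]] = {}
    for d in matrix.defs:
        if d.weight != 1.0:
            by_weight.setdefault(d.weight, []).append(d.index)
    for w in sorted(by_weight):
        out.write(f"ccode /{_fmt_float(w)} {_format_indices(by_weight[w])};\n")
    out.write("proc /;\n")
    return out.getvalue()


# -------------------------------------------------------------- NEXUS read

_NEXUS_COMMENT = re.compile(r"\[([^\]]*)\]")


def _read_nexus(text: str) -> CharacterMatrix:
    meta_columns: list[str] | None = None
    meta_nstates: list[str] | None = None
    for c in _NEXUS_COMMENT.findall(text):
        c = c.strip()
        if c.startswith("mp-columns:"):
            meta_columns = c.split(":", 1)[1].split()
        elif c.startswith("mp-nstates:"):
            meta_nstates = c.split(":", 1)[1].split()
    stripped = _NEXUS_COMMENT.sub(" ", text)

    blocks = re.findall(
        r"begin\s+(\w+)\s*;(.*?)\bend\s*;", stripped, flags=re.IGNORECASE | re.DOTALL
    )
    taxa: list[str] = []
    char_blocks: list[tuple[str, list[str], list[list[StateCell]]]] = []
    assumptions = ""
    for name, body in blocks:
        name = name.lower()
        if name == "taxa":
            tm = re.search(
                r"taxlabels(.*?);", body, flags=re.IGNORECASE | re.DOTALL
            )
            if tm:
                taxa = tm.group(1).split()
        elif name in ("characters", "data"):
            char_blocks.append(_parse_nexus_characters(body, taxa))
        elif name == "assumptions":
            assumptions = body
    if not char_blocks:
        raise FormatError("NEXUS input has no CHARACTERS block")
    if not taxa:
        taxa = char_blocks[0][1]

    # per-block columns, then interleave per mp-columns if given
    block_rows: dict[str, list[list[StateCell]]] = {}
    block_kind: dict[str, CharKind] = {}
    for datatype, names, rows in char_blocks:
        if names != taxa:
            if set(names) != set(taxa):
                raise FormatError("CHARACTERS block taxa differ from TAXA block")
            order = [names.index(t) for t in taxa]
            rows = [rows[i] for i in order]
        key = "C" if datatype == "continuous" else "D"
        if key in block_rows:
            # concatenate multiple blocks of the same datatype
            for r_old, r_new in zip(block_rows[key], rows):
                r_old.extend(r_new)
        else:
            block_rows[key] = [list(r) for r in rows]
        block_kind[key] = (
            CharKind.CONTINUOUS if key == "C" else CharKind.UNORDERED
        )

    counters = {k: 0 for k in block_rows}
    widths = {k: len(v[0]) for k, v in block_rows.items()}
    if meta_columns is None:
        meta_columns = ["D"] * widths.get("D", 0) + ["C"] * widths.get("C", 0)
    kinds: list[CharKind] = []
    grid: list[list[StateCell]] = [[] for _ in taxa]
    for token in meta_columns:
        key = token[0].upper()
        if key not in block_rows or counters[key] >= widths[key]:
            raise FormatError("mp-columns metadata inconsistent with data blocks")
        j = counters[key]
        counters[key] += 1
        kinds.append(block_kind[key])
        for r, src in zip(grid, block_rows[key]):
            r.append(src[j])
    if any(counters[k] != widths[k] for k in counters):
        raise FormatError("mp-columns metadata does not cover all characters")

    defs = _defs_from_kinds(kinds, grid, meta_nstates)
    _apply_nexus_assumptions(assumptions, defs)
    return CharacterMatrix(taxa=taxa, defs=defs, cells=grid)


def _parse_nexus_characters(body: str, taxa: list[str]):
    fm = re.search(r"format([^;]*);", body, flags=re.IGNORECASE | re.DOTALL)
    datatype = "standard"
    if fm and re.search(r"datatype\s*=\s*continuous", fm.group(1), re.IGNORECASE):
        datatype = "continuous"
    dm = re.search(r"nchar\s*=\s*(\d+)", body, flags=re.IGNORECASE)
    n_char = int(dm.group(1)) if dm else None
    mm = re.search(r"matrix(.*?);", body, flags=re.IGNORECASE | re.DOTALL)
    if not mm:
        raise FormatError("CHARACTERS block has no MATRIX statement")
    names: list[str] = []
    rows: list[list[StateCell]] = []
    for line in mm.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"bad matrix row: {line!r}")
        name, data = parts
        if datatype == "continuous":
            cells = _parse_continuous_tokens(data.split(), taxon=name)
        else:
            data = data.replace("(", "[").replace(")", "]")
            cells = _parse_row_tokens(data, taxon=name)
        if n_char is not None and len(cells) != n_char:
            raise FormatError(
                f"row {name!r} has {len(cells)} characters, header declares {n_char}"
            )
        names.append(name)
        rows.append(cells)
    return datatype, names, rows


def _apply_nexus_assumptions(body: str, defs: list[CharacterDef]) -> None:
    def expand(spec: str) -> list[int]:
        out = []
        for tok in spec.split():
            m = re.fullmatch(r"(\d+)-(\d+)", tok)
            if m:
                out.extend(range(int(m.group(1)) - 1, int(m.group(2))))
            elif tok.isdigit():
                out.append(int(tok) - 1)  # NEXUS is 1-based
            else:
                raise FormatError(f"ASSUMPTIONS: bad index token {tok!r}")
        bad = [i for i in out if i < 0 or i >= len(defs)]
        if bad:
            raise FormatError(f"ASSUMPTIONS: character index {bad[0] + 1} out of range")
        return out

    for stmt in re.findall(r"typeset[^;=]*=([^;]*);", body, flags=re.IGNORECASE):
        for part in stmt.split(","):
            if ":" not in part:
                continue
            typ, spec = part.split(":", 1)
            typ = typ.strip().lower()
            for idx in expand(spec):
                if defs[idx].kind is CharKind.CONTINUOUS:
                    continue
                if typ in ("ord", "ordered"):
                    defs[idx].kind = CharKind.ORDERED
                elif typ in ("unord", "unordered"):
                    defs[idx].kind = CharKind.UNORDERED
    for stmt in re.findall(r"wtset[^;=]*=([^;]*);", body, flags=re.IGNORECASE):
        for part in stmt.split(","):
            if ":" not in part:
                continue
            w, spec = part.split(":", 1)
            for idx in expand(spec):
                defs[idx].weight = float(w)
    for stmt in re.findall(r"exset[^;=]*=([^;]*);", body, flags=re.IGNORECASE):
        for idx in expand(stmt):
            defs[idx].active = False
            defs[idx].inactive_reason = "deactivated in file"


# ------------------------------------------------------------- NEXUS write

def _write_nexus(matrix: CharacterMatrix) -> str:
    disc = [d for d in matrix.defs if d.kind is not CharKind.CONTINUOUS]
    cont = [d for d in matrix.defs if d.kind is CharKind.CONTINUOUS]
    out = io.StringIO()
    out.write("#NEXUS\n")
    columns = " ".join(
        "C" if d.kind is CharKind.CONTINUOUS else "D" for d in matrix.defs
    )
    nstates = " ".join(
        "-" if d.kind is CharKind.CONTINUOUS else str(d.n_states) for d in matrix.defs
    )
    out.write(f"[mp-columns: {columns}]\n[mp-nstates: {nstates}]\n")
    out.write("BEGIN TAXA;\n")
    out.write(f"  DIMENSIONS NTAX={matrix.n_taxa};\n")
    out.write("  TAXLABELS " + " ".join(matrix.taxa) + ";\nEND;\n")
    name_w = max(len(t) for t in matrix.taxa) + 2
    if disc:
        max_state = max(int(d.n_states) for d in disc)  # type: ignore[arg-type]
        if max_state > 10:
            raise CapabilityError("NEXUS dialect supports states 0-9 only")
        symbols = "".join(str(i) for i in range(max_state))
        out.write("BEGIN CHARACTERS;\n")
        out.write(f"  DIMENSIONS NCHAR={len(disc)};\n")
        out.write(
            f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n'
        )
        out.write("  MATRIX\n")
        for ti, taxon in enumerate(matrix.taxa):
            # NEXUS spells polymorphism with parentheses; brackets are comments
            toks = "".join(
                _cell_to_token(matrix.cells[ti][d.index], d.kind)
                .replace("[", "(")
                .replace("]", ")")
                for d in disc
            )
            out.write(f"  {taxon:<{name_w}}{toks}\n")
        out.write("  ;\nEND;\n")
    if cont:
        out.write("BEGIN CHARACTERS;\n")
        out.write(f"  DIMENSIONS NCHAR={len(cont)};\n")
        out.write("  FORMAT DATATYPE=CONTINUOUS MISSING=? GAP=-;\n")
        out.write("  MATRIX\n")
        for ti, taxon in enumerate(matrix.taxa):
            toks = " ".join(
                _cell_to_token(matrix.cells[ti][d.index], d.kind) for d in cont
            )
            out.write(f"  {taxon:<{name_w}}{toks}\n")
        out.write("  ;\nEND;\n")
    # assumptions: positions within the full (original) character order, 1-based
    ordered = [d.index + 1 for d in matrix.defs if d.kind is CharKind.ORDERED]
    unordered = [d.index + 1 for d in matrix.defs if d.kind is CharKind.UNORDERED]
    lines = []
    if ordered or unordered:
        specs = []
        if ordered:
            specs.append("ord: " + " ".join(map(str, ordered)))
        if unordered:
            specs.append("unord: " + " ".join(map(str, unordered)))
        lines.append("  TYPESET * default = " + ", ".join(specs) + ";")
    by_weight: dict[float, list[int]] = {}
    for d in matrix.defs:
        if d.weight != 1.0:
            by_weight.setdefault(d.weight, []).append(d.index + 1)
    if by_weight:
        specs = [
            f"{_fmt_float(w)}: " + " ".join(map(str, by_weight[w]))
            for w in sorted(by_weight)
        ]
        lines.append("  WTSET * default = " + ", ".join(specs) + ";")
    inactive = [d.index + 1 for d in matrix.defs if not d.active]
    if inactive:
        lines.append("  EXSET * default = " + " ".join(map(str, inactive)) + ";")
    if lines:
        out.write("BEGIN ASSUMPTIONS;\n")
        out.write("\n".join(lines) + "\n")
        out.write("END;\n")
    return out.getvalue()


# ------------------------------------------------------------------ public

def read_matrix(source: str | os.PathLike, dialect: str = "auto") -> CharacterMatrix:
    """Parse a character matrix from TNT or NEXUS text (or a file path)."""
    text = _load_text(source)
    if dialect == "auto":
        dialect = "nexus" if text.lstrip().lower().startswith("#nexus") else "tnt"
    if dialect == "tnt":
        return _read_tnt(text)
    if dialect == "nexus":
        return _read_nexus(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_matrix(matrix: CharacterMatrix, dialect: str = "tnt") -> str:
    """Serialise a matrix; ``read_matrix(write_matrix(m))`` reproduces ``m``."""
    matrix.validate()
    if dialect == "tnt":
        return _write_tnt(matrix)
    if dialect == "nexus":
        return _write_nexus(matrix)
    raise ValueError(f"unknown dialect {dialect!r}")


# -------------------------------------------------------------------- trees

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            node = Node(dnode.taxon.label.replace(" ", "_") if dnode.taxon else None)
        else:
            node = Node()
        for a in dnode.annotations:
            try:
                node.annotations[a.name] = float(a.value)
            except (TypeError, ValueError):
                node.annotations[a.name] = a.value
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    tree = PhyloTree(root, rooted=len(root.children) == 2)
    tree.suppress_unifurcations()
    return tree


def read_trees(source: str | os.PathLike) -> list[PhyloTree]:
    """Read one or more Newick trees; node comments become annotations."""
    text = _load_text(source)
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at position {i}")
    if depth != 0:
        raise FormatError("unbalanced '(' in newick input")
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema="newick",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise FormatError(f"newick parse error: {exc}") from None
    trees = []
    for dt in dtrees:
        try:
            trees.append(_from_dendropy(dt))
        except TreeError:
            raise
    if not trees:
        raise FormatError("no trees found in newick input")
    return trees


def _node_to_newick(node: Node, annotations: bool) -> str:
    if node.is_leaf:
        body = node.label or ""
    else:
        body = "(" + ",".join(
            _node_to_newick(c, annotations) for c in node.children
        ) + ")"
    if annotations and node.annotations:
        items = ",".join(
            f"{k}={_fmt_float(v) if isinstance(v, float) else v}"
            for k, v in sorted(node.annotations.items())
        )
        body += f"[&{items}]"
    return body


def write_trees(trees: list[PhyloTree], annotations: bool = False) -> str:
    """Serialise trees as Newick, optionally with ``[&k=v]`` node comments."""
    return "".join(_node_to_newick(t.root, annotations) + ";\n" for t in trees)
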