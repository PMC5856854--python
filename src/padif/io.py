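"""Reading and writing per-atom score tables, cavity-atom lists and fingerprints.

The on-disk dialect is tab-separated text.  A score table carries four atom
identity columns followed by the eight interaction-term columns of the
ChemPLP scoring function; a cavity-atom list carries the identity columns
only.  Atom identity is ``(chain, residue number, insertion code, atom
name)`` rather than a serial number, because serial numbering is exactly
what differs between crystal structures of the same protein — mapping by
chemically meaningful identity is what makes fingerprints from different
structures comparable row by row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: The eight per-atom interaction terms exported per binding-site atom, in
#: canonical column order.  The first three (ChemScore-derived) terms use the
#: opposite sign convention from the rest in raw exports; see
#: :func:`padif.fingerprint.make_padif`.
TERMS: tuple[str, ...] = (
    "ChemScore_PLP.Hbond",
    "ChemScore_PLP.CHO",
    "ChemScore_PLP.Metal",
    "PLP.S(hbond)",
    "PLP.S(metal)",
    "PLP.S(buried)",
    "PLP.S(nonpolar)",
    "PLP.S(repulsive)",
)

#: Indices of the terms whose raw sign is reversed during fingerprint
#: generation (positive = favourable in raw exports).
SIGN_REVERSED_TERMS: tuple[int, ...] = (0, 1, 2)

N_TERMS = len(TERMS)

_ID_COLUMNS = ("chain", "resnum", "icode", "atom_name")

SIGN_MARKER = "#signs:normalized"


class AtomKey(NamedTuple):
    """Structure-independent identity of one binding-site atom."""

    chain_id: str
    residue_number: int
    insertion_code: str
    atom_name: str


class ParseError(ValueError):
    """Raised for malformed score-table or cavity-list files."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class AtomScoreTable:
    """Raw per-atom, per-term score contributions for one complex or pose.

    ``values`` is an ``(N, 8)`` float array in raw export sign convention;
    rows follow ``atoms``.
    """

    atoms: list[AtomKey]
    values: np.ndarray
    source_id: str = ""
    terms: tuple[str, ...] = TERMS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.atoms) < 1:
            raise ValueError("a score table needs at least one atom")
        if self.values.shape != (len(self.atoms), N_TERMS):
            raise ValueError(
                f"values must be ({len(self.atoms)}, {N_TERMS}), "
                f"got {self.values.shape}"
            )
        if tuple(self.terms) != TERMS:
            raise ValueError(f"terms must be exactly {TERMS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score values must be finite")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError("duplicate atom keys in score table")


@dataclass
class CavityAtomList:
    """Ordered, duplicate-free list of binding-site atoms.

    The order of this list governs the row order of every fingerprint
    derived for the structure.
    """

    atoms: list[AtomKey]

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("cavity-atom list must not be empty")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError("duplicate atoms in cavity-atom list")

    def index(self) -> dict[AtomKey, int]:
        return {a: i for i, a in enumerate(self.atoms)}


@dataclass
class AtomMap:
    """Injective mapping from reference-structure atoms to target atoms."""

    pairs: dict[AtomKey, AtomKey]
    unmatched: list[AtomKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        targets = list(self.pairs.values())
        if len(set(targets)) != len(targets):
            raise ValueError("atom map is not injective")


def _parse_atom_fields(chain: str, resnum: str, icode: str, name: str,
                       line: int) -> AtomKey:
    name = name.strip()
    if not name:
        raise ParseError("empty atom name", line)
    try:
        number = int(resnum)
    except ValueError:
        raise ParseError(f"non-integer residue number {resnum!r}", line) from None
    return AtomKey(chain.strip(), number, icode.strip(), name)


def read_atom_score_table(path, dialect: str = "tsv",
                          source_id: str | None = None) -> AtomScoreTable:
    """Read a per-atom score table from a TSV file.

    Parameters
    ----------
    path : path-like
        File with header ``chain resnum icode atom_name`` + the eight term
        columns, tab-separated.
    dialect : str
        Only ``"tsv"`` is supported; the parameter reserves room for
        adapters to docking programs' native rescore formats.
    source_id : str, optional
        Label for the table; defaults to the file name.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = str(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # tolerate the sign marker written by write_fingerprint
    body_start = 0
    if lines and lines[0].strip() == SIGN_MARKER:
        body_start = 1
    if body_start >= len(lines):
        raise ParseError("missing header", body_start + 1)
    header = lines[body_start].split("\t")
    expected = list(_ID_COLUMNS) + list(TERMS)
    if header != expected:
        raise ParseError(
            f"malformed header: expected {expected}, got {header}",
            body_start + 1,
        )
    atoms: list[AtomKey] = []
    rows: list[list[float]] = []
    seen: set[AtomKey] = set()
    for offset, raw in enumerate(lines[body_start + 1:],
                                 start=body_start + 2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(expected):
            raise ParseError(
                f"expected {len(expected)} fields, got {len(fields)}", offset
            )
        key = _parse_atom_fields(*fields[:4], line=offset)
        if key in seen:
            raise ParseError(f"duplicate atom {key}", offset)
        seen.add(key)
        values = []
        for col, cell in zip(TERMS, fields[4:]):
            cell = cell.strip()
            if not cell:
                raise ParseError(f"missing value in column {col}", offset)
            try:
                values.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} in column {col}", offset
                ) from None
        atoms.append(key)
        rows.append(values)
    if not atoms:
        raise ParseError("score table contains no atom rows")
    if source_id is None:
        source_id = path.rsplit("/", 1)[-1]
    return AtomScoreTable(atoms=atoms, values=np.array(rows), source_id=source_id)


def write_atom_score_table(table: AtomScoreTable, path,
                           normalized: bool = False) -> None:
    """Write a score table (or, with ``normalized=True``, a fingerprint
    matrix with its sign marker) in the canonical TSV dialect."""
    frame = pd.DataFrame(
        [(a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
         for a in table.atoms],
        columns=list(_ID_COLUMNS),
    )
    for j, term in enumerate(TERMS):
        frame[term] = table.values[:, j]
    with open(path, "w") as fh:
        if normalized:
            fh.write(SIGN_MARKER + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_cavity_atoms(path) -> CavityAtomList:
    """Read a cavity-atom list (one ``chain resnum icode atom_name`` row
    per atom, optional matching header)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    atoms: list[AtomKey] = []
    seen: set[AtomKey] = set()
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if lineno == 1 and fields == list(_ID_COLUMNS):
            continue
        if len(fields) != 4:
            raise ParseError(f"expected 4 fields, got {len(fields)}", lineno)
        key = _parse_atom_fields(*fields, line=lineno)
        if key in seen:
            raise ParseError(f"duplicate atom {key}", lineno)
        seen.add(key)
        atoms.append(key)
    return CavityAtomList(atoms=atoms)


def write_cavity_atoms(cavity: CavityAtomList, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ID_COLUMNS) + "\n")
        for a in cavity.atoms:
            fh.write(f"{a.chain_id}\t{a.residue_number}\t{a.insertion_code}"
                     f"\t{a.atom_name}\n")


def build_atom_map(ref: CavityAtomList, target: CavityAtomList) -> AtomMap:
    """Match reference atoms to target atoms by exact identity.

    Atoms are matched on ``(chain, residue number, insertion code, atom
    name)``.  Reference atoms with no counterpart are collected in
    ``unmatched`` rather than raising: different crystal structures of the
    same protein routinely resolve slightly different atom sets.
    """
    target_index = target.index()
    pairs: dict[AtomKey, AtomKey] = {}
    unmatched: list[AtomKey] = []
    for key in ref.atoms:
        if key in target_index:
            pairs[key] = key
        else:
            unmatched.append(key)
    return AtomMap(pairs=pairs, unmatched=unmatched)


def renumber_table(table: AtomScoreTable, atom_map: AtomMap,
                   target_order: CavityAtomList) -> AtomScoreTable:
    """Re-express a score table on another structure's atom ordering.

    Rows of the output follow ``target_order``.  Target atoms that no
    reference atom maps onto receive all-zero rows — zero is the "no
    interaction observed" value, so an atom absent from the reference simply
    contributes nothing to the merged fingerprint.
    """
    source_index = {a: i for i, a in enumerate(table.atoms)}
    for ref_key in atom_map.pairs:
        if ref_key not in source_index:
            raise ValueError(f"map refers to atom {ref_key} absent from table")
    n = len(target_order.atoms)
    out = np.zeros((n, N_TERMS))
    target_pos = target_order.index()
    for ref_key, tgt_key in atom_map.pairs.items():
        if tgt_key not in target_pos:
            raise ValueError(f"mapped-to atom {tgt_key} absent from target order")
        out[target_pos[tgt_key]] = table.values[source_index[ref_key]]
    return AtomScoreTable(atoms=list(target_order.atoms), values=out,
                          source_id=table.source_id)
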