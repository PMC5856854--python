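"""Sign-normalized interaction fingerprints and multi-reference merging.

A PADIF (per-atom score-contribution derived interaction fingerprint) is the
``(N, 8)`` matrix of a scoring function's per-atom contributions for the N
binding-site atoms, normalized so that a strictly negative entry always
means a favourable (attractive) interaction and a positive entry an
unfavourable one.  Several reference complexes are merged into a single
consensus fingerprint: element-wise median of the favourable values, plus a
weighting matrix holding, for each element, the fraction of reference
complexes in which that interaction is favourable.  The weighting matrix is
what the scoring consumes — an interaction seen in four of ten reference
complexes carries weight 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    N_TERMS,
    SIGN_REVERSED_TERMS,
    AtomKey,
    AtomScoreTable,
    read_atom_score_table,
    write_atom_score_table,
)

__all__ = [
    "PADIF",
    "ReferencePADIF",
    "make_padif",
    "merge_references",
    "favourable_elements",
    "read_padif",
    "write_padif",
    "write_reference",
    "read_reference",
]


@dataclass
class PADIF:
    """Sign-normalized fingerprint of one complex or docking pose."""

    atoms: list[AtomKey]
    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.atoms), N_TERMS):
            raise ValueError(
                f"values must be ({len(self.atoms)}, {N_TERMS}), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint values must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class ReferencePADIF:
    """Median consensus fingerprint plus element-wise weighting matrix.

    ``median_values[m, n]`` is the median of the favourable (negative)
    values observed at element ``(m, n)`` across the references, or 0 if the
    interaction is favourable in none of them.  ``weights[m, n]`` is the
    fraction of references in which the element is favourable, so weights
    take values ``k / n_references``.
    """

    atoms: list[AtomKey]
    median_values: np.ndarray
    weights: np.ndarray
    n_references: int

    def __post_init__(self) -> None:
        self.median_values = np.asarray(self.median_values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        shape = (len(self.atoms), N_TERMS)
        if self.median_values.shape != shape or self.weights.shape != shape:
            raise ValueError("median_values and weights must be (N, 8)")
        if self.n_references < 1:
            raise ValueError("n_references must be positive")
        if np.any(self.median_values > 0):
            raise ValueError("median_values must be <= 0 everywhere")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")
        if np.any((self.median_values < 0) != (self.weights > 0)):
            raise ValueError("weights must be positive exactly where the "
                             "median fingerprint is favourable")


def make_padif(table: AtomScoreTable, source_id: str | None = None) -> PADIF:
    """Normalize a raw score table into a fingerprint.

    Raw exports use mixed sign conventions: for the three ChemScore-derived
    terms (Hbond, CHO, Metal) positive values are favourable, for the five
    PLP terms negative values are.  The fingerprint reverses the sign of the
    first three columns so that negative means favourable everywhere.
    """
    values = table.values.copy()
    values[:, list(SIGN_REVERSED_TERMS)] *= -1.0
    return PADIF(atoms=list(table.atoms), values=values,
                 source_id=source_id if source_id is not None else table.source_id)


def merge_references(padifs: list[PADIF]) -> ReferencePADIF:
    """Merge one or more reference fingerprints into a weighted consensus.

    For every element the median is taken over the strictly negative values
    only — unfavourable (positive) entries say nothing about which
    interactions a binder should make, so they contribute neither to the
    median nor to the weight.  Elements favourable in no reference get
    median 0 and weight 0.  The weight denominator is the full reference
    count, including references where the element is 0 or positive.
    """
    if not padifs:
        raise ValueError("need at least one reference fingerprint")
    atoms = padifs[0].atoms
    for p in padifs[1:]:
        if p.atoms != atoms:
            raise ValueError(
                "reference fingerprints have mismatched atom lists; "
                "renumber the tables onto a common cavity-atom order first"
            )
    stack = np.stack([p.values for p in padifs])  # (n_ref, N, 8)
    neg = stack < 0
    counts = neg.sum(axis=0)
    n_ref = len(padifs)
    weights = counts / n_ref
    # median over the negative entries only; masked positions excluded
    masked = np.ma.masked_array(stack, mask=~neg)
    medians = np.ma.median(masked, axis=0).filled(0.0)
    medians[counts == 0] = 0.0
    return ReferencePADIF(atoms=list(atoms), median_values=medians,
                          weights=weights, n_references=n_ref)


def favourable_elements(fp: PADIF | ReferencePADIF) -> set[tuple[int, int]]:
    """Set of ``(atom_index, term_index)`` elements with strictly negative
    value (``median_values`` for a merged reference)."""
    values = fp.median_values if isinstance(fp, ReferencePADIF) else fp.values
    rows, cols = np.nonzero(values < 0)
    return set(zip(rows.tolist(), cols.tolist()))


def write_padif(fp: PADIF, path) -> None:
    """Serialize a fingerprint in the score-table TSV layout, marked as
    sign-normalized."""
    table = AtomScoreTable(atoms=list(fp.atoms), values=fp.values.copy(),
                           source_id=fp.source_id)
    write_atom_score_table(table, path, normalized=True)


def read_padif(path) -> PADIF:
    table = read_atom_score_table(path)
    return PADIF(atoms=list(table.atoms), values=table.values,
                 source_id=table.source_id)


def write_reference(ref: ReferencePADIF, median_path, weights_path) -> None:
    """Serialize a merged reference as two parallel TSV matrices."""
    for values, path in ((ref.median_values, median_path),
                         (ref.weights, weights_path)):
        table = AtomScoreTable(atoms=list(ref.atoms), values=values.copy(),
                               source_id="")
        write_atom_score_table(table, path, normalized=True)


def read_reference(median_path, weights_path,
                   n_references: int = 1) -> ReferencePADIF:
    med = read_atom_score_table(median_path)
    wts = read_atom_score_table(weights_path)
    if med.atoms != wts.atoms:
        raise ValueError("median and weight matrices list different atoms")
    return ReferencePADIF(atoms=list(med.atoms), median_values=med.values,
                          weights=wts.values, n_references=n_references)
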