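"""Synthetic reference sets and active/decoy pose tables.

The generator emulates the statistical situation of a docking-based screen
with known reference complexes: a binding site supports a fixed set of
"true" favourable interactions; each reference complex realizes a random
subset of them (references with different ligands rarely exhibit every
interaction); active poses realize most of the true pattern; decoy poses
realize a same-sized but randomly placed pattern.  Mild unfavourable
(repulsive) noise is sprinkled over every table.

Raw tables are emitted in the native export sign convention — positive =
favourable for the three ChemScore-derived terms — so that sign
normalization is exercised end-to-end.  Favourable magnitudes are
half-normal; the published score ignores magnitudes, so this choice only
exercises I/O and sign handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    N_TERMS,
    SIGN_REVERSED_TERMS,
    AtomKey,
    AtomScoreTable,
    CavityAtomList,
)

__all__ = [
    "SimulationConfig",
    "LabelledPoseSet",
    "make_cavity",
    "draw_true_pattern",
    "generate_reference_set",
    "generate_pose_set",
]

# a favourable PLP.S(repulsive) contribution would be contradictory, so the
# planted pattern avoids the repulsive column; noise may land anywhere
_PATTERN_TERMS = tuple(t for t in range(N_TERMS) if t != N_TERMS - 1)


@dataclass
class SimulationConfig:
    """Conditions of one synthetic screening experiment.

    Defaults describe a well-behaved target: 10 reference complexes sharing
    a 12-element favourable pattern on a 20-atom cavity, each reference
    showing 70% of the pattern, actives recovering 80% of it, and a 2%
    per-element chance of a spurious repulsive contact.
    """

    n_atoms: int = 20
    n_references: int = 10
    n_true_elements: int = 12
    presence_prob: float = 0.7
    strength_scale: float = 1.0
    noise_prob: float = 0.02
    n_actives: int = 50
    n_decoys: int = 50
    active_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1 or self.n_references < 1:
            raise ValueError("n_atoms and n_references must be positive")
        if not 1 <= self.n_true_elements <= len(_PATTERN_TERMS) * self.n_atoms:
            raise ValueError("n_true_elements exceeds available elements")
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence_prob must be in (0, 1]")
        if not 0 <= self.noise_prob < 1:
            raise ValueError("noise_prob must be in [0, 1)")
        if not 0 <= self.active_overlap <= 1:
            raise ValueError("active_overlap must be in [0, 1]")
        if self.strength_scale <= 0:
            raise ValueError("strength_scale must be positive")
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("pose counts must be non-negative")


@dataclass
class LabelledPoseSet:
    poses: list[tuple[AtomScoreTable, bool]]


def make_cavity(cfg: SimulationConfig) -> CavityAtomList:
    """Deterministic synthetic cavity: CA/CB-style atoms of chain A."""
    names = ("N", "CA", "CB", "CG", "OD1", "ND2", "C", "O")
    atoms = [
        AtomKey("A", 1 + i // len(names), "", f"{names[i % len(names)]}")
        for i in range(cfg.n_atoms)
    ]
    return CavityAtomList(atoms=atoms)


def draw_true_pattern(cfg: SimulationConfig,
                      rng: np.random.Generator) -> set[tuple[int, int]]:
    """Sample the shared favourable-interaction pattern."""
    grid = [(m, t) for m in range(cfg.n_atoms) for t in _PATTERN_TERMS]
    idx = rng.choice(len(grid), size=cfg.n_true_elements, replace=False)
    return {grid[i] for i in sorted(int(i) for i in idx)}


def _raw_from_normalized(values: np.ndarray) -> np.ndarray:
    raw = values.copy()
    raw[:, list(SIGN_REVERSED_TERMS)] *= -1.0
    return raw


def _fill_table(cfg: SimulationConfig, cavity: CavityAtomList,
                elements: set[tuple[int, int]], rng: np.random.Generator,
                source_id: str) -> AtomScoreTable:
    """Build one raw table: favourable values on ``elements``, repulsive
    noise elsewhere with ``noise_prob``."""
    normalized = np.zeros((cfg.n_atoms, N_TERMS))
    for m, t in elements:
        normalized[m, t] = -abs(rng.normal()) * cfg.strength_scale - 1e-6
    noise_mask = rng.random((cfg.n_atoms, N_TERMS)) < cfg.noise_prob
    for m, t in zip(*np.nonzero(noise_mask)):
        if normalized[m, t] == 0.0:
            normalized[m, t] = abs(rng.normal()) * cfg.strength_scale + 1e-6
    return AtomScoreTable(atoms=list(cavity.atoms),
                          values=_raw_from_normalized(normalized),
                          source_id=source_id)


def _subset(elements: set[tuple[int, int]], prob: float,
            rng: np.random.Generator) -> set[tuple[int, int]]:
    ordered = sorted(elements)
    keep = rng.random(len(ordered)) < prob
    return {e for e, k in zip(ordered, keep) if k}


def generate_reference_set(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    true_pattern: set[tuple[int, int]] | None = None,
) -> tuple[list[AtomScoreTable], set[tuple[int, int]], CavityAtomList]:
    """Draw the true pattern and the per-reference raw score tables.

    Each reference independently realizes each true element with
    ``presence_prob``; the expected merged weight on a true element is
    therefore exactly ``presence_prob``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cavity = make_cavity(cfg)
    if true_pattern is None:
        true_pattern = draw_true_pattern(cfg, rng)
    tables = [
        _fill_table(cfg, cavity, _subset(true_pattern, cfg.presence_prob, rng),
                    rng, source_id=f"ref_{i:03d}")
        for i in range(cfg.n_references)
    ]
    return tables, true_pattern, cavity


def generate_pose_set(
    cfg: SimulationConfig,
    true_pattern: set[tuple[int, int]],
    rng: np.random.Generator | None = None,
) -> LabelledPoseSet:
    """Generate labelled active/decoy pose tables.

    Actives realize each true element with ``active_overlap``.  Each decoy
    realizes, with the same probability, elements of its own random
    same-sized pattern, which overlaps the true pattern only by chance.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if any(m >= cfg.n_atoms or t >= N_TERMS for m, t in true_pattern):
        raise ValueError("true pattern exceeds configured dimensions")
    cavity = make_cavity(cfg)
    poses: list[tuple[AtomScoreTable, bool]] = []
    for i in range(cfg.n_actives):
        elems = _subset(true_pattern, cfg.active_overlap, rng)
        poses.append((_fill_table(cfg, cavity, elems, rng,
                                  source_id=f"active_{i:03d}"), True))
    for i in range(cfg.n_decoys):
        decoy_pattern = draw_true_pattern(cfg, rng)
        elems = _subset(decoy_pattern, cfg.active_overlap, rng)
        poses.append((_fill_table(cfg, cavity, elems, rng,
                                  source_id=f"decoy_{i:03d}"), False))
    return LabelledPoseSet(poses=poses)
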