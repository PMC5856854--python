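"""PADIF pose scoring against a weighted multi-reference fingerprint.

The score compares only interaction *patterns*, never magnitudes: a pose
earns ``+w(m, n)`` for each reference-favourable element it also realizes
favourably, ``−w(m, n)`` where it instead clashes, and 0 where it makes no
interaction.  The raw sum is then shrunk towards 0 by the relative overlap
``O_rel``, which measures how completely the pose's favourable interactions
fall inside the reference pattern.  A small ligand that makes few
interactions, all of them matching, keeps its full score (``O_rel = 1``) —
the scheme deliberately does not punish small molecules for not filling the
whole site, which is what makes it friendlier to scaffold hopping than
whole-fingerprint similarity metrics.

The scorer follows the scikit-learn estimator protocol: ``fit`` consumes
the reference fingerprints, ``decision_function`` returns the total score
``S_tot`` per pose (higher = better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .fingerprint import PADIF, ReferencePADIF, make_padif, merge_references
from .io import AtomScoreTable

__all__ = [
    "ScoreBreakdown",
    "RankedList",
    "PadifScorer",
    "score_pose",
    "rank_by_score",
    "combined_rank",
]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Full decomposition of one pose score.

    Attributes
    ----------
    R, P : int
        Number of favourable (strictly negative) elements in the reference
        and pose fingerprints.
    overlap_count : int
        Reference-favourable elements that the pose also realizes, |P ∩ R|.
    O_max : float
        Maximum achievable overlap, ``min(P / R, 1)``.
    O_real : float
        Realized overlap, ``|P ∩ R| / R``.
    O_rel : float
        ``O_real / O_max`` (0 for an interaction-free pose, where the ratio
        is formally 0/0).
    sum_S : float
        Weighted sum of per-element scores over the reference elements.
    S_tot : float
        ``sum_S − (1 − O_rel)·|sum_S|``, the final score (higher = better).
    """

    R: int
    P: int
    overlap_count: int
    O_max: float
    O_real: float
    O_rel: float
    sum_S: float
    S_tot: float


@dataclass(frozen=True)
class RankedList:
    """Poses ordered best-first; rank 1 is the top pose."""

    entries: list[tuple[str, float, int]]

    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]


class PadifScorer(BaseEstimator):
    """Score docking poses by weighted overlap with reference fingerprints.

    Parameters
    ----------
    sign_normalized : bool, default False
        If True, ``fit`` and ``decision_function`` accept already
        sign-normalized :class:`~padif.fingerprint.PADIF` objects; otherwise
        raw :class:`~padif.io.AtomScoreTable` inputs are normalized
        internally.

    Attributes
    ----------
    reference_ : ReferencePADIF
        Merged consensus fingerprint with weighting matrix.
    n_favourable_ : int
        Number of favourable elements R in the merged reference.
    """

    def __init__(self, sign_normalized: bool = False):
        self.sign_normalized = sign_normalized

    def _as_padif(self, item: PADIF | AtomScoreTable) -> PADIF:
        if isinstance(item, PADIF):
            if not self.sign_normalized:
                raise TypeError(
                    "received a PADIF but sign_normalized=False; pass raw "
                    "AtomScoreTables or construct with sign_normalized=True"
                )
            return item
        if isinstance(item, AtomScoreTable):
            if self.sign_normalized:
                raise TypeError(
                    "received a raw AtomScoreTable but sign_normalized=True"
                )
            return make_padif(item)
        raise TypeError(f"cannot interpret {type(item).__name__} as a fingerprint")

    def fit(self, X: Sequence[PADIF | AtomScoreTable], y=None) -> "PadifScorer":
        """Merge the reference complexes' fingerprints.

        Parameters
        ----------
        X : sequence of AtomScoreTable or PADIF
            One entry per reference complex, all on the same cavity-atom
            order.  A pre-merged :class:`ReferencePADIF` may be passed
            directly instead of a sequence.
        """
        if isinstance(X, ReferencePADIF):
            reference = X
        else:
            padifs = [self._as_padif(item) for item in X]
            if not padifs:
                raise ValueError("need at least one reference complex")
            reference = merge_references(padifs)
        n_fav = int(np.count_nonzero(reference.median_values < 0))
        if n_fav == 0:
            raise ValueError(
                "reference carries no favourable interaction (R = 0); "
                "the PADIF score is undefined"
            )
        self.reference_ = reference
        self.n_favourable_ = n_fav
        return self

    def score_breakdowns(
        self, X: Sequence[PADIF | AtomScoreTable]
    ) -> list[ScoreBreakdown]:
        """Per-pose score decompositions (R, P, overlaps, ΣS, S_tot)."""
        check_is_fitted(self, "reference_")
        return [self._score_one(self._as_padif(item)) for item in X]

    def decision_function(self, X: Sequence[PADIF | AtomScoreTable]) -> np.ndarray:
        """Total score ``S_tot`` per pose; higher = better."""
        return np.array([b.S_tot for b in self.score_breakdowns(X)])

    def _score_one(self, pose: PADIF) -> ScoreBreakdown:
        ref = self.reference_
        if pose.atoms != ref.atoms:
            first_bad = next(
                (i for i, (a, b) in enumerate(zip(pose.atoms, ref.atoms))
                 if a != b),
                min(len(pose.atoms), len(ref.atoms)),
            )
            detail = (
                f"first mismatch at row {first_bad}"
                if first_bad < min(len(pose.atoms), len(ref.atoms))
                else f"lengths {len(pose.atoms)} vs {len(ref.atoms)}"
            )
            if first_bad < len(pose.atoms):
                detail += f": pose atom {pose.atoms[first_bad]}"
            raise ValueError(
                f"pose '{pose.source_id}' atom list does not match the "
                f"reference ({detail}); renumber onto the docking "
                "structure's cavity-atom order first"
            )
        ref_fav = ref.median_values < 0
        pose_fav = pose.values < 0
        R = int(np.count_nonzero(ref_fav))
        P = int(np.count_nonzero(pose_fav))
        o_max = min(P / R, 1.0)
        # per-element score over the reference elements only
        s = np.zeros_like(ref.weights)
        s[ref_fav & pose_fav] = ref.weights[ref_fav & pose_fav]
        clash = ref_fav & (pose.values > 0)
        s[clash] = -ref.weights[clash]
        sum_s = float(s.sum())
        overlap = int(np.count_nonzero(ref_fav & pose_fav))
        o_real = overlap / R
        o_rel = o_real / o_max if o_max > 0 else 0.0
        s_tot = sum_s - (1.0 - o_rel) * abs(sum_s)
        return ScoreBreakdown(R=R, P=P, overlap_count=overlap, O_max=o_max,
                              O_real=o_real, O_rel=o_rel, sum_S=sum_s,
                              S_tot=s_tot)


def score_pose(ref: ReferencePADIF, pose: PADIF) -> ScoreBreakdown:
    """Score one sign-normalized pose fingerprint against a merged
    reference; see :class:`PadifScorer` for the scheme."""
    scorer = PadifScorer(sign_normalized=True).fit(ref)
    return scorer.score_breakdowns([pose])[0]


def rank_by_score(scores: Mapping[str, float]) -> RankedList:
    """Order poses by descending score, ties broken by pose id."""
    if not scores:
        raise ValueError("no scores to rank")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedList(entries=[(pid, s, i + 1)
                               for i, (pid, s) in enumerate(ordered)])


def combined_rank(conventional: Mapping[str, float],
                  padif: Mapping[str, float],
                  top_fraction: float = 0.03) -> RankedList:
    """Combine a conventional (docking) ranking with the PADIF ranking.

    The head of the combined list is the best ``ceil(top_fraction · K)``
    poses by conventional score; the remainder follows in PADIF-score
    order.  This keeps the docking function's reliable very-early
    enrichment while letting the fingerprint order the bulk of the list.
    """
    if set(conventional) != set(padif):
        only_conv = set(conventional) - set(padif)
        only_padif = set(padif) - set(conventional)
        raise ValueError(
            f"pose id sets differ (only conventional: {sorted(only_conv)[:3]}, "
            f"only fingerprint: {sorted(only_padif)[:3]})"
        )
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    k = len(conventional)
    n_top = math.ceil(top_fraction * k)
    conv_order = rank_by_score(conventional).ids()
    head = conv_order[:n_top]
    head_set = set(head)
    tail = [pid for pid in rank_by_score(padif).ids() if pid not in head_set]
    merged = head + tail
    # re-express as a ranked list; scores shown are the ones that placed
    # the pose in its block
    entries = []
    for i, pid in enumerate(merged):
        score = conventional[pid] if i < n_top else padif[pid]
        entries.append((pid, score, i + 1))
    return RankedList(entries=entries)
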