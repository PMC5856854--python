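"""Virtual-screening success metrics: ROC AUC and enrichment factors.

Both metrics read a ranking only through the relative order of scores
(higher = better), so they are invariant under any strictly monotone
transform of the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .scorer import rank_by_score

__all__ = ["LabelledScores", "roc_auc", "enrichment_factor", "roc_curve_points"]


@dataclass
class LabelledScores:
    """Scored, labelled screening entries (actives vs decoys)."""

    entries: list[tuple[str, float, bool]]

    @property
    def n_actives(self) -> int:
        return sum(1 for _, _, a in self.entries if a)

    @property
    def n_decoys(self) -> int:
        return sum(1 for _, _, a in self.entries if not a)


def roc_auc(data: LabelledScores) -> float:
    """Probability that a random active outscores a random decoy.

    Equivalent to the Mann–Whitney U statistic normalized by
    ``n_actives · n_decoys``, with ties counting one half.
    """
    if data.n_actives < 1 or data.n_decoys < 1:
        raise ValueError("AUC needs at least one active and one decoy")
    labels = [a for _, _, a in data.entries]
    scores = [s for _, s, _ in data.entries]
    return float(roc_auc_score(labels, scores))


def enrichment_factor(data: LabelledScores, fraction: float) -> float:
    """Active rate in the top ``fraction`` of the ranking, relative to the
    whole-set active rate.

    The top set holds ``ceil(fraction · K)`` entries (never empty), ordered
    by descending score with lexicographic id tie-break.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if data.n_actives < 1:
        raise ValueError("enrichment factor needs at least one active")
    k = len(data.entries)
    n_top = math.ceil(fraction * k)
    is_active = {eid: a for eid, _, a in data.entries}
    order = rank_by_score({eid: s for eid, s, _ in data.entries}).ids()
    a_top = sum(1 for eid in order[:n_top] if is_active[eid])
    return (a_top / n_top) / (data.n_actives / k)


def roc_curve_points(data: LabelledScores) -> np.ndarray:
    """(fpr, tpr) points of the ROC curve, for optional TSV export."""
    from sklearn.metrics import roc_curve

    labels = [a for _, _, a in data.entries]
    scores = [s for _, s, _ in data.entries]
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])
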