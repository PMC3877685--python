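"""Context prediction by weighted voting of the top-ranked MISs.

A new sample (normalised with the training model) is assigned, per MIS, to
the training cluster whose median centroid is closest in Euclidean distance.
The MIS votes for the positive and negative class with weights

    w_pos = p'_c / (p'_c + n'_c),    w_neg = n'_c / (p'_c + n'_c)

where p'_c, n'_c are the normalised class counts of the nearest cluster c.
The vote sums over the top G MISs decide the class; an exact tie falls back
to *binary voting* (each MIS gives a whole vote to the strictly dominant
class of its nearest cluster, nothing on a tied cluster), which yields a
strict winner whenever G is odd and no nearest cluster is internally tied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network_io import ValidationError
from .ranking import MISClusterModel

logger = logging.getLogger(__name__)

__all__ = [
    "VoteRecord",
    "Prediction",
    "nearest_cluster",
    "vote_weights",
    "classify",
    "tally_votes",
    "choose_g",
]


@dataclass
class VoteRecord:
    mis_id: str
    nearest_cluster: int
    w_pos: float
    w_neg: float


@dataclass
class Prediction:
    sample_id: str
    W_pos: float
    W_neg: float
    label: str  # "positive" | "negative"
    mode: str  # "weighted" | "binary"
    votes: list[VoteRecord] = field(default_factory=list)

    @property
    def margin(self) -> float:
        """Continuous decision score W_pos - W_neg (weighted mode sums)."""
        return self.W_pos - self.W_neg


def nearest_cluster(sample_vector: np.ndarray, model: MISClusterModel) -> int:
    """Index of the centroid closest to the sample; ties go to the lowest index."""
    v = np.asarray(sample_vector, dtype=float)
    d = np.linalg.norm(model.centroids - v[None, :], axis=1)
    return int(np.argmin(d))


def vote_weights(model: MISClusterModel, cluster: int) -> tuple[float, float]:
    """(w_pos, w_neg) from the normalised class counts of one cluster."""
    p = model.p_norm[cluster]
    n = model.n_norm[cluster]
    if p + n == 0:
        raise ValidationError("empty cluster cannot vote")
    return float(p / (p + n)), float(n / (p + n))


def classify(
    sample_id: str,
    mis_vectors: Mapping[str, np.ndarray],
    ranked: Sequence[tuple[str, float, MISClusterModel]],
    G: int,
) -> Prediction:
    """Predict a sample's context from the top-G ranked MISs.

    ``mis_vectors`` maps each MIS id to the sample's normalised expression
    restricted to that MIS's representative probeset. The weighted vote sums
    satisfy W_pos + W_neg = G; on an exact tie the binary-voting fallback
    decides, and if that also ties the positive class is predicted with a
    logged warning (ties cannot occur with odd G unless a nearest cluster is
    internally tied).
    """
    if G < 1:
        raise ValidationError("G must be >= 1")
    if G > len(ranked):
        raise ValidationError(f"G={G} exceeds number of ranked MISs ({len(ranked)})")
    votes: list[VoteRecord] = []
    for mis_id, _entropy, model in ranked[:G]:
        c = nearest_cluster(mis_vectors[mis_id], model)
        w_pos, w_neg = vote_weights(model, c)
        votes.append(VoteRecord(mis_id=mis_id, nearest_cluster=c, w_pos=w_pos, w_neg=w_neg))
    return tally_votes(sample_id, votes, G)


def tally_votes(sample_id: str, votes: Sequence[VoteRecord], G: int) -> Prediction:
    """Decide the class from the first G vote records (rank order).

    Used by :func:`classify`, and directly when evaluating several G values
    from one set of recorded votes. The binary fallback compares each nearest
    cluster's normalised counts, which is the sign of w_pos - w_neg.
    """
    if G < 1 or G > len(votes):
        raise ValidationError(f"G={G} outside 1..{len(votes)}")
    top = votes[:G]
    W_pos = sum(v.w_pos for v in top)
    W_neg = sum(v.w_neg for v in top)
    if W_pos != W_neg:
        label = "positive" if W_pos > W_neg else "negative"
        return Prediction(sample_id, float(W_pos), float(W_neg), label, "weighted", list(top))

    # binary-voting fallback: whole votes to the strictly dominant class of
    # each nearest cluster, nothing on internally tied clusters
    b_pos = sum(1 for v in top if v.w_pos > v.w_neg)
    b_neg = sum(1 for v in top if v.w_neg > v.w_pos)
    if b_pos == b_neg:
        logger.warning(
            "sample %r: weighted and binary votes both tied; predicting positive",
            sample_id,
        )
        label = "positive"
    else:
        label = "positive" if b_pos > b_neg else "negative"
    return Prediction(sample_id, float(W_pos), float(W_neg), label, "binary", list(top))


def choose_g(
    loocv_accuracies: Mapping[int, float],
    candidates: Sequence[int] | None = None,
) -> int:
    """Smallest G among the candidates that attains the maximal accuracy."""
    if not loocv_accuracies:
        raise ValidationError("empty accuracy map")
    if candidates is None:
        candidates = sorted(loocv_accuracies)
    cands = [g for g in candidates if g in loocv_accuracies]
    if not cands:
        raise ValidationError("no candidate G has a recorded accuracy")
    best = max(loocv_accuracies[g] for g in cands)
    return min(g for g in cands if loocv_accuracies[g] == best)
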