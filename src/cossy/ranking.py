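"""Normalisation, per-MIS sample clustering and the entropy ranking score.

Training samples are quantile-normalised (each sample's values are rank-mapped
onto the mean sorted profile of the training set) and then z-scored per probe.
For each MIS, the training samples are clustered by Ward's minimum-variance
hierarchical clustering with Euclidean distance on the MIS's representative
probeset, the dendrogram is cut into k groups (k from the rule of thumb
``round(sqrt(M/2))``, floored at 2), and each cluster's centroid is the
coordinate-wise median of its members (robust to noisy samples).

The ranking score of an MIS is the weighted mean binary entropy of its
clusters' class compositions. With p'_i and n'_i the per-cluster positive and
negative counts normalised by the class totals, and q_i = p'_i/(p'_i + n'_i):

    H(c_i) = -q_i log2 q_i - (1 - q_i) log2 (1 - q_i)
    H(MIS) = sum_i w_i H(c_i),   w_i = (p'_i + n'_i) / 2

so H(MIS) = 0 exactly when every cluster is class-pure (perfectly
class-separating expression pattern) and 1 when every cluster holds equal
proportions of the two classes (uninformative). MISs are ranked by increasing
entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from .features import RepresentativeProbeset
from .network_io import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationModel",
    "MISClusterModel",
    "fit_normalization",
    "default_k",
    "cluster_samples",
    "cluster_entropy",
    "mis_entropy",
    "rank_mis",
]

_SD_FLOOR = 1e-8


@dataclass
class NormalizationModel:
    """Quantile normalisation + per-probe z-score fitted on a training set."""

    probe_ids: list[str]
    reference_quantiles: np.ndarray  # sorted, length P
    probe_mean: np.ndarray  # length P
    probe_sd: np.ndarray  # length P, floored positive

    def _quantile_map(self, values: np.ndarray) -> np.ndarray:
        """Rank-map each column (sample) onto the reference quantiles."""
        v = np.asarray(values, dtype=float)
        single = v.ndim == 1
        if single:
            v = v[:, None]
        p = len(self.reference_quantiles)
        if v.shape[0] != p:
            raise ValidationError(
                f"expected {p} probes, got {v.shape[0]}"
            )
        ranks = rankdata(v, axis=0)  # ties get average ranks
        grid = np.arange(1, p + 1, dtype=float)
        out = np.empty_like(v)
        for j in range(v.shape[1]):
            out[:, j] = np.interp(ranks[:, j], grid, self.reference_quantiles)
        return out[:, 0] if single else out

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Quantile-map then z-score a (P,) sample vector or (P, M) matrix."""
        q = self._quantile_map(values)
        if q.ndim == 1:
            return (q - self.probe_mean) / self.probe_sd
        return (q - self.probe_mean[:, None]) / self.probe_sd[:, None]


def fit_normalization(train: ExpressionDataset) -> NormalizationModel:
    """Fit quantile + z-score normalisation on the training matrix.

    Reference quantiles are the mean of the sorted per-sample expression
    vectors; probe means and standard deviations are computed *after* the
    quantile step. Constant probes get their sd floored to a small epsilon
    (with a warning) so transformation never divides by zero.
    """
    if train.n_samples < 2:
        raise ValidationError("normalisation requires >= 2 samples")
    X = train.values
    ref = np.sort(X, axis=0).mean(axis=1)
    model = NormalizationModel(
        probe_ids=list(train.probe_ids),
        reference_quantiles=ref,
        probe_mean=np.zeros(train.n_probes),
        probe_sd=np.ones(train.n_probes),
    )
    Xq = model._quantile_map(X)
    mean = Xq.mean(axis=1)
    sd = Xq.std(axis=1, ddof=0)
    n_const = int((sd < _SD_FLOOR).sum())
    if n_const:
        logger.warning("flooring sd of %d constant probes to %.0e", n_const, _SD_FLOOR)
    model.probe_mean = mean
    model.probe_sd = np.maximum(sd, _SD_FLOOR)
    return model


@dataclass
class MISClusterModel:
    """Per-MIS clustering of the training samples on its representative probeset."""

    mis_id: str
    k: int
    probes: list[str]
    centroids: np.ndarray  # (k, R) coordinate-wise medians
    p_counts: np.ndarray  # (k,) positives per cluster
    n_counts: np.ndarray  # (k,) negatives per cluster
    entropy: float | None = None
    sample_assignments: list[int] = field(default_factory=list)

    @property
    def p_norm(self) -> np.ndarray:
        total = self.p_counts.sum()
        return self.p_counts / total

    @property
    def n_norm(self) -> np.ndarray:
        total = self.n_counts.sum()
        return self.n_counts / total


def default_k(M: int) -> int:
    """Rule-of-thumb number of clusters, round(sqrt(M/2)), floored at 2."""
    if M < 4:
        raise ValidationError("rule of thumb requires M >= 4")
    return max(2, int(round(math.sqrt(M / 2))))


def cluster_samples(
    sample_matrix: np.ndarray,
    y: np.ndarray,
    k: int,
    mis_id: str = "",
    probes: list[str] | None = None,
) -> MISClusterModel:
    """Ward/Euclidean hierarchical clustering of samples, cut into k clusters.

    ``sample_matrix`` is (M, R): one row per training sample, restricted to
    the MIS's representative probeset (already normalised). Centroids are the
    coordinate-wise medians of the cluster members.
    """
    X = np.asarray(sample_matrix, dtype=float)
    y = np.asarray(y, dtype=bool)
    m = X.shape[0]
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > m:
        raise ValidationError(f"k={k} exceeds number of samples M={m}")
    Z = linkage(X, method="ward", metric="euclidean")
    assign = fcluster(Z, t=k, criterion="maxclust")  # labels 1..k
    labels_present = sorted(set(assign))
    centroids = np.vstack([np.median(X[assign == c], axis=0) for c in labels_present])
    p_counts = np.array([int((y & (assign == c)).sum()) for c in labels_present])
    n_counts = np.array([int((~y & (assign == c)).sum()) for c in labels_present])
    relabel = {c: i for i, c in enumerate(labels_present)}
    return MISClusterModel(
        mis_id=mis_id,
        k=len(labels_present),
        probes=list(probes or []),
        centroids=centroids,
        p_counts=p_counts,
        n_counts=n_counts,
        sample_assignments=[relabel[c] for c in assign],
    )


def cluster_entropy(p_norm: float, n_norm: float) -> float:
    """Binary entropy of a cluster's normalised class composition, in [0, 1]."""
    if p_norm < 0 or n_norm < 0:
        raise ValidationError("normalised counts must be nonnegative")
    total = p_norm + n_norm
    if total == 0:
        raise ValidationError("empty cluster has no entropy; skip it")
    q = p_norm / total
    h = 0.0
    for x in (q, 1.0 - q):
        if x > 0:
            h -= x * math.log2(x)
    return h


def mis_entropy(model: MISClusterModel) -> float:
    """Weighted mean cluster entropy of an MIS; stored on the model.

    Weights are w_i = (p'_i + n'_i)/2 over nonempty clusters, the unique
    convex weighting of the normalised counts for which all-pure models score
    0 and all-balanced models score 1. Empty clusters contribute nothing.
    """
    p, n = model.p_norm, model.n_norm
    h = 0.0
    for pi, ni in zip(p, n):
        if pi + ni == 0:
            continue
        h += (pi + ni) / 2.0 * cluster_entropy(pi, ni)
    model.entropy = float(h)
    return model.entropy


def rank_mis(
    probesets: list[RepresentativeProbeset],
    normalized_values: np.ndarray,
    probe_ids: list[str],
    y: np.ndarray,
    k: int | None = None,
) -> list[tuple[str, float, MISClusterModel]]:
    """Cluster and score every MIS; return (mis_id, entropy, model) ascending.

    ``normalized_values`` is the (P, M) training matrix after normalisation,
    aligned with ``probe_ids``. Ties on entropy break by mis_id.
    """
    if not probesets:
        raise ValidationError("rank_mis requires at least one probeset")
    X = np.asarray(normalized_values, dtype=float)
    y = np.asarray(y, dtype=bool)
    m = X.shape[1]
    if k is None:
        k = default_k(m)
    k = min(k, m)
    index = {p: i for i, p in enumerate(probe_ids)}
    ranked = []
    for ps in probesets:
        rows = [index[p] for p in ps.probes]
        model = cluster_samples(X[rows].T, y, k, mis_id=ps.mis_id, probes=ps.probes)
        ranked.append((ps.mis_id, mis_entropy(model), model))
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked
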