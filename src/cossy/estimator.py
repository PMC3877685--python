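"""Scikit-learn-style estimator wrapping the full train/predict pipeline.

``COSSYClassifier`` takes a pre-computed network partition (a list of MISs —
the partition depends only on the interaction network, never on expression
data) plus a molecule→probe map, and learns everything expression-dependent
in ``fit``: normalisation, differential-expression scores, representative
probesets, overlap merging, per-MIS clustering and the entropy ranking.
``predict`` classifies new samples by weighted voting of the top-G MISs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import features, prediction, ranking
from .network_io import MIS, ExpressionDataset, ProbeMap, ValidationError

__all__ = ["COSSYClassifier"]


class COSSYClassifier(BaseEstimator, ClassifierMixin):
    """Entropy-ranked subnetwork voting classifier for two-phenotype data.

    Parameters
    ----------
    mis_list : list of MIS
        Network partition (e.g. from :func:`cossy.partition.generate_mis`).
    probe_map : ProbeMap
        Molecule → probe mapping.
    probe_ids : list of str, optional
        Column names of X when X is a bare array; inferred from DataFrame
        columns otherwise.
    probeset_size : int, default 5
        Number of representative probes per MIS (R); MISs mapping to fewer
        unique probes are dropped.
    overlap_threshold : float, default 0.6
        Minimum probeset overlap at which two MISs are merged.
    n_clusters : int, optional
        Clusters per MIS; default is the rule of thumb round(sqrt(M/2)).
    n_voters : int, default 15
        G, the number of top-ranked MISs that vote.
    s0_policy : "median" | "none" | float, default "median"
        Variance-offset policy for the t-score.
    positive_label : optional
        Which class value is the positive context; defaults to the larger of
        the two class values (deterministic, independent of sample order).

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class values.
    normalization_ : NormalizationModel
    t_scores_ : dict probe -> float
    probesets_ : list of RepresentativeProbeset (post-merge)
    merged_mis_ : list of MIS (post-merge)
    ranked_ : list of (mis_id, entropy, MISClusterModel), ascending entropy
    g_ : int, effective number of voters (min(n_voters, len(ranked_)))
    """

    def __init__(
        self,
        mis_list=None,
        probe_map=None,
        probe_ids=None,
        probeset_size=5,
        overlap_threshold=0.6,
        n_clusters=None,
        n_voters=15,
        s0_policy="median",
        positive_label=None,
    ):
        self.mis_list = mis_list
        self.probe_map = probe_map
        self.probe_ids = probe_ids
        self.probeset_size = probeset_size
        self.overlap_threshold = overlap_threshold
        self.n_clusters = n_clusters
        self.n_voters = n_voters
        self.s0_policy = s0_policy
        self.positive_label = positive_label

    # -- helpers -------------------------------------------------------------

    def _resolve_probes(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (samples x probes)")
        if self.probe_ids is not None:
            if len(self.probe_ids) != X.shape[1]:
                raise ValidationError(
                    f"{len(self.probe_ids)} probe_ids for {X.shape[1]} columns"
                )
            return X, [str(p) for p in self.probe_ids]
        return X, [str(i) for i in range(X.shape[1])]

    def _dataset(self, X, y) -> ExpressionDataset:
        values, probes = self._resolve_probes(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValidationError(f"need exactly two classes, got {list(classes)}")
        pos = self.positive_label if self.positive_label is not None else classes[-1]
        if pos not in classes:
            raise ValidationError(f"positive_label {pos!r} not among classes")
        samples = [f"s{i}" for i in range(values.shape[0])]
        return ExpressionDataset(
            probe_ids=probes,
            sample_ids=samples,
            values=values.T,
            labels={s: str(lbl) for s, lbl in zip(samples, y)},
            positive_label=str(pos),
        )

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y):
        """Fit normalisation, probesets, clustering and ranking on (X, y).

        X is (n_samples, n_probes); y holds exactly two class values.
        """
        if not self.mis_list:
            raise ValidationError("mis_list is required (run the network partition first)")
        probe_map = self.probe_map if self.probe_map is not None else ProbeMap()
        ds = self._dataset(X, y)
        y_arr = np.asarray(y)
        self.classes_ = np.unique(y_arr)
        self._positive = ds.positive_label
        self._negative = ds.negative_label

        self.normalization_ = ranking.fit_normalization(ds)
        X_norm = self.normalization_.transform(ds.values)
        s0 = features.resolve_s0(X_norm, ds.y, self.s0_policy)
        self.s0_ = s0
        self.t_scores_ = features.t_score_table(ds, s0=s0, values=X_norm)

        kept: list[features.RepresentativeProbeset] = []
        mis_index: dict[str, MIS] = {}
        for mis in self.mis_list:
            ps = features.representative_probeset(
                mis, ds, probe_map, R=self.probeset_size, t_scores=self.t_scores_
            )
            if ps is not None:
                kept.append(ps)
                mis_index[mis.mis_id] = mis
        if not kept:
            raise ValidationError(
                f"no MIS maps to >= {self.probeset_size} probes in the dataset"
            )
        self.n_dropped_mis_ = len(self.mis_list) - len(kept)
        self.merged_mis_, self.probesets_ = features.merge_overlapping(
            kept,
            mis_index,
            ds,
            probe_map,
            threshold=self.overlap_threshold,
            R=self.probeset_size,
            t_scores=self.t_scores_,
        )
        k = self.n_clusters
        if k is None:
            k = ranking.default_k(ds.n_samples)
        self.k_ = min(k, ds.n_samples)
        self.ranked_ = ranking.rank_mis(
            self.probesets_, X_norm, ds.probe_ids, ds.y, k=self.k_
        )
        self.g_ = min(self.n_voters, len(self.ranked_))
        self._probe_index = {p: i for i, p in enumerate(ds.probe_ids)}
        self._probesets_by_id = {ps.mis_id: ps for ps in self.probesets_}
        return self

    def _predict_one(self, vec_norm: np.ndarray, sample_id: str) -> prediction.Prediction:
        mis_vectors = {
            mis_id: vec_norm[[self._probe_index[p] for p in self._probesets_by_id[mis_id].probes]]
            for mis_id, _e, _m in self.ranked_[: self.g_]
        }
        return prediction.classify(sample_id, mis_vectors, self.ranked_, self.g_)

    def predict_records(self, X) -> list[prediction.Prediction]:
        """Full per-sample vote records (weights, mode, nearest clusters)."""
        check_is_fitted(self, "ranked_")
        values, probes = self._resolve_probes(X)
        if probes != self.normalization_.probe_ids:
            raise ValidationError("probe set/order differs from the training data")
        out = []
        for i in range(values.shape[0]):
            vec = self.normalization_.transform(values[i])
            out.append(self._predict_one(vec, f"s{i}"))
        return out

    def predict(self, X):
        recs = self.predict_records(X)
        labels = [
            self._positive if r.label == "positive" else self._negative for r in recs
        ]
        # return in the dtype of classes_
        lookup = {str(c): c for c in self.classes_}
        return np.array([lookup[l] for l in labels])

    def decision_function(self, X):
        """Continuous vote margin W_pos - W_neg per sample."""
        return np.array([r.margin for r in self.predict_records(X)])
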