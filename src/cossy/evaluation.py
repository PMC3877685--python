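"""Leave-one-out cross-validation and accuracy / ROC-AUC summaries.

The network partition depends only on the interaction network, so it is
computed once and reused across folds. Everything expression-dependent —
normalisation, t-scores, representative probesets, overlap merging,
clustering and ranking — is refit on the M-1 training samples of every fold,
so the held-out sample leaks into no training step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .estimator import COSSYClassifier
from .network_io import MIS, ExpressionDataset, ProbeMap, ValidationError

__all__ = ["LOOCVResult", "loocv", "loocv_curve", "roc_auc"]


@dataclass
class LOOCVResult:
    per_sample: list[tuple[str, str, str, float, float]]
    # (sample_id, true label, predicted label, W_pos, W_neg)
    accuracy: float
    auc: float
    fold_votes: list = None  # per-fold VoteRecord lists, rank-ordered

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: P(random positive outscores a random negative), ties half.

    ``labels`` is a boolean vector (True = positive). Equivalent to the
    Mann–Whitney statistic divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def loocv(
    dataset: ExpressionDataset,
    mis_list: list[MIS],
    probe_map: ProbeMap,
    probeset_size: int = 5,
    overlap_threshold: float = 0.6,
    n_clusters: int | None = None,
    n_voters: int = 15,
    s0_policy="median",
) -> LOOCVResult:
    """Leave-one-out cross-validation of the full pipeline.

    For each sample, the classifier is retrained from scratch on the other
    M-1 samples and predicts the held-out sample. The AUC is computed from
    the continuous vote margin W_pos - W_neg.
    """
    if dataset.n_samples < 4:
        raise ValidationError("LOOCV requires at least 4 samples")
    per_sample = []
    margins = []
    y_true = []
    fold_votes = []
    for sample_id in dataset.sample_ids:
        train_ids = [s for s in dataset.sample_ids if s != sample_id]
        train = dataset.subset_samples(train_ids)
        n_pos = int(train.y.sum())
        if n_pos < 2 or train.n_samples - n_pos < 2:
            raise ValidationError(
                f"fold holding out {sample_id!r} leaves < 2 samples in a class"
            )
        clf = COSSYClassifier(
            mis_list=mis_list,
            probe_map=probe_map,
            probe_ids=train.probe_ids,
            probeset_size=probeset_size,
            overlap_threshold=overlap_threshold,
            n_clusters=n_clusters,
            n_voters=n_voters,
            s0_policy=s0_policy,
            positive_label=dataset.positive_label,
        )
        clf.fit(train.values.T, [train.labels[s] for s in train_ids])
        rec = clf.predict_records(dataset.sample_vector(sample_id)[None, :])[0]
        predicted = (
            dataset.positive_label if rec.label == "positive" else dataset.negative_label
        )
        truth = dataset.labels[sample_id]
        per_sample.append((sample_id, truth, predicted, rec.W_pos, rec.W_neg))
        margins.append(rec.margin)
        y_true.append(truth == dataset.positive_label)
        fold_votes.append(rec.votes)

    correct = sum(1 for _s, t, p, _wp, _wn in per_sample if t == p)
    return LOOCVResult(
        per_sample=per_sample,
        accuracy=correct / len(per_sample),
        auc=roc_auc(margins, y_true),
        fold_votes=fold_votes,
    )


def loocv_curve(
    dataset: ExpressionDataset,
    mis_list: list[MIS],
    probe_map: ProbeMap,
    candidates: "list[int] | tuple[int, ...]" = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25),
    **kwargs,
) -> dict[int, LOOCVResult]:
    """LOOCV accuracy/AUC for every candidate G from one fit per fold.

    Each fold is trained once with G = max(candidates); the recorded votes are
    re-tallied for every smaller G (candidates exceeding the number of ranked
    MISs are evaluated with all of them, collapsing onto the same result).
    Supports the reported procedure of using the minimum G attaining the
    highest accuracy (see :func:`cossy.prediction.choose_g`).
    """
    from .prediction import tally_votes

    g_max = max(candidates)
    base = loocv(dataset, mis_list, probe_map, n_voters=g_max, **kwargs)
    # base carries only the final tallies; rerun tallying from the vote records
    # stored per fold
    results: dict[int, LOOCVResult] = {}
    votes_per_fold = base.fold_votes
    for g in sorted(set(candidates)):
        per_sample = []
        margins = []
        y_true = []
        for (sample_id, truth), votes in zip(
            [(s, t) for s, t, _p, _wp, _wn in base.per_sample], votes_per_fold
        ):
            g_eff = min(g, len(votes))
            pred = tally_votes(sample_id, votes, g_eff)
            predicted = (
                dataset.positive_label
                if pred.label == "positive"
                else dataset.negative_label
            )
            per_sample.append((sample_id, truth, predicted, pred.W_pos, pred.W_neg))
            margins.append(pred.margin)
            y_true.append(truth == dataset.positive_label)
        correct = sum(1 for _s, t, p, _wp, _wn in per_sample if t == p)
        results[g] = LOOCVResult(
            per_sample=per_sample,
            accuracy=correct / len(per_sample),
            auc=roc_auc(margins, y_true),
        )
    return results
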