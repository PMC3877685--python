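"""Feature selection: map MISs to probes and pick representative probesets.

Each MIS is mapped to the microarray probes of its molecules (every probe of
a multi-probe molecule is kept separately). An MIS survives only if it maps
to at least ``R`` unique probes present in the dataset; the ``R`` probes with
the largest absolute differential-expression score form its *representative
probeset*. Differential expression is scored with a variance-offset Welch
t-statistic

    t = (mean_pos - mean_neg) / sqrt(var_pos/M_pos + var_neg/M_neg + s0^2)

where ``s0`` regularises near-zero variances (default: 5% of the median
standard error across all probes of the training set; ``s0 = 0`` recovers the
classical Welch statistic). Finally, MISs whose representative probesets
overlap strongly are merged: the pair with the highest overlap (shared probes
/ R) is unioned at the molecule level and its probeset recomputed, repeatedly,
until every pairwise overlap falls below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network_io import MIS, ExpressionDataset, ProbeMap, ValidationError

__all__ = [
    "RepresentativeProbeset",
    "mis_probes",
    "welch_t",
    "compute_s0",
    "t_score_table",
    "representative_probeset",
    "overlap",
    "merge_overlapping",
]


@dataclass
class RepresentativeProbeset:
    """The fixed-size list of most differentially expressed probes of one MIS."""

    mis_id: str
    probes: list[str]  # ordered by decreasing |t|, ties by probe id

    def __post_init__(self) -> None:
        if len(set(self.probes)) != len(self.probes):
            raise ValidationError(f"duplicate probes in probeset {self.mis_id!r}")

    @property
    def size(self) -> int:
        return len(self.probes)


def mis_probes(
    mis: MIS, probe_map: ProbeMap, dataset: ExpressionDataset
) -> set[str]:
    """Probes measured for an MIS: union over molecules, restricted to the dataset."""
    mapped: set[str] = set()
    for mol in mis.molecules:
        mapped |= probe_map.probes_of(mol)
    return mapped & set(dataset.probe_ids)


def _class_stats(values: np.ndarray, y: np.ndarray):
    """Per-class means and unbiased variances along the sample axis."""
    pos = values[..., y]
    neg = values[..., ~y]
    if pos.shape[-1] < 2 or neg.shape[-1] < 2:
        raise ValidationError("each class needs >= 2 samples for the t-score")
    return (
        pos.mean(axis=-1),
        neg.mean(axis=-1),
        pos.var(axis=-1, ddof=1),
        neg.var(axis=-1, ddof=1),
        pos.shape[-1],
        neg.shape[-1],
    )


def welch_t(probe_row: np.ndarray, y: np.ndarray, s0: float = 0.0) -> float:
    """Variance-offset Welch t for one probe; positive = higher mean in positives."""
    mp, mn, vp, vn, np_, nn = _class_stats(np.asarray(probe_row, dtype=float), np.asarray(y, dtype=bool))
    return float((mp - mn) / np.sqrt(vp / np_ + vn / nn + s0 ** 2))


def _standard_errors(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    mp, mn, vp, vn, np_, nn = _class_stats(values, y)
    return np.sqrt(vp / np_ + vn / nn)


def compute_s0(values: np.ndarray, y: np.ndarray, fraction: float = 0.05) -> float:
    """Variance offset: ``fraction`` of the median per-probe standard error."""
    return float(fraction * np.median(_standard_errors(np.asarray(values, float), np.asarray(y, bool))))


def resolve_s0(values: np.ndarray, y: np.ndarray, policy: "str | float") -> float:
    """Turn an s0 policy ("median", "none", or a number) into a value."""
    if isinstance(policy, str):
        if policy == "median":
            return compute_s0(values, y)
        if policy in ("none", "0"):
            return 0.0
        raise ValidationError(f"unknown s0 policy {policy!r}")
    s0 = float(policy)
    if s0 < 0:
        raise ValidationError("s0 must be nonnegative")
    return s0


def t_score_table(
    dataset: ExpressionDataset, s0: float | None = None, values: np.ndarray | None = None
) -> dict[str, float]:
    """t-score per probe over the whole (training) dataset, vectorised.

    ``values`` overrides the dataset matrix (e.g. to score normalised data);
    ``s0 = None`` applies the default median policy.
    """
    X = dataset.values if values is None else np.asarray(values, float)
    y = dataset.y
    if s0 is None:
        s0 = compute_s0(X, y)
    mp, mn, vp, vn, np_, nn = _class_stats(X, y)
    t = (mp - mn) / np.sqrt(vp / np_ + vn / nn + s0 ** 2)
    return dict(zip(dataset.probe_ids, map(float, t)))


def representative_probeset(
    mis: MIS,
    dataset: ExpressionDataset,
    probe_map: ProbeMap,
    R: int = 5,
    t_scores: Mapping[str, float] | None = None,
) -> RepresentativeProbeset | None:
    """The R most differentially expressed probes of an MIS, or None.

    Returns ``None`` when the MIS maps to fewer than R unique probes in the
    dataset; such MISs are dropped from all downstream steps. Ordering is by
    decreasing |t|, ties broken by probe identifier.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    probes = mis_probes(mis, probe_map, dataset)
    if len(probes) < R:
        return None
    if t_scores is None:
        t_scores = t_score_table(dataset)
    ordered = sorted(probes, key=lambda p: (-abs(t_scores[p]), p))
    return RepresentativeProbeset(mis_id=mis.mis_id, probes=ordered[:R])


def overlap(a: RepresentativeProbeset, b: RepresentativeProbeset) -> float:
    """Fraction of shared probes between two equal-size representative probesets."""
    if a.size != b.size:
        raise ValidationError(
            f"probeset size mismatch: {a.mis_id} has {a.size}, {b.mis_id} has {b.size}"
        )
    return len(set(a.probes) & set(b.probes)) / a.size


def merge_overlapping(
    probesets: list[RepresentativeProbeset],
    mis_index: Mapping[str, MIS],
    dataset: ExpressionDataset,
    probe_map: ProbeMap,
    threshold: float = 0.6,
    R: int = 5,
    t_scores: Mapping[str, float] | None = None,
) -> tuple[list[MIS], list[RepresentativeProbeset]]:
    """Greedily merge MISs whose representative probesets overlap >= threshold.

    At each step the pair with the maximal overlap is replaced by the union of
    the two molecule sets and the merged MIS's probeset is recomputed from
    scratch, so the size-R contract holds throughout. Ties on the maximal
    overlap break on the lexicographically smallest (mis_id, mis_id) pair.
    Terminates because every merge reduces the MIS count by one; on return all
    pairwise overlaps are < threshold.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must be in (0, 1]")
    if t_scores is None:
        t_scores = t_score_table(dataset)
    current: dict[str, tuple[MIS, RepresentativeProbeset]] = {
        ps.mis_id: (mis_index[ps.mis_id], ps) for ps in probesets
    }

    while len(current) > 1:
        best = None  # (-overlap, id_a, id_b)
        ids = sorted(current)
        for i, a in enumerate(ids):
            pa = current[a][1]
            for b in ids[i + 1:]:
                ov = overlap(pa, current[b][1])
                key = (-ov, a, b)
                if best is None or key < best:
                    best = key
        ov = -best[0]
        if ov < threshold:
            break
        a, b = best[1], best[2]
        mis_a, mis_b = current[a][0], current[b][0]
        merged_id = "+".join(sorted(set(a.split("+")) | set(b.split("+"))))
        merged = MIS(
            mis_id=merged_id,
            molecules=mis_a.molecules | mis_b.molecules,
            nodes=mis_a.nodes | mis_b.nodes,
            provenance=mis_a.provenance
            + mis_b.provenance
            + [f"merged:{a}+{b}@{ov:.2f}"],
        )
        merged_ps = representative_probeset(
            merged, dataset, probe_map, R=R, t_scores=t_scores
        )
        if merged_ps is None:  # pragma: no cover - union has >= R probes
            raise RuntimeError("merged MIS lost probes")
        del current[a], current[b]
        current[merged_id] = (merged, merged_ps)

    ids = sorted(current)
    return [current[i][0] for i in ids], [current[i][1] for i in ids]
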