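"""Persist a fitted classifier as inspectable plain-text files.

A model directory holds:

* ``config.json`` — resolved hyperparameters, class labels, s0, k, G;
* ``normalization.tsv`` — per-probe mean/sd and the position-indexed
  reference quantiles;
* ``probesets.tsv`` — representative probeset of each surviving MIS;
* ``clusters.json`` — per-MIS centroids, class counts and entropy;
* ``ranking.tsv`` — ascending-entropy MIS order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import COSSYClassifier
from .features import RepresentativeProbeset
from .ranking import MISClusterModel, NormalizationModel

__all__ = ["save_model", "load_model"]


def save_model(clf: COSSYClassifier, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    norm = clf.normalization_
    pd.DataFrame(
        {
            "probe_id": norm.probe_ids,
            "probe_mean": norm.probe_mean,
            "probe_sd": norm.probe_sd,
            "reference_quantile": norm.reference_quantiles,
        }
    ).to_csv(d / "normalization.tsv", sep="\t", index=False)

    with open(d / "probesets.tsv", "w") as fh:
        fh.write("mis_id\tprobes\n")
        for ps in clf.probesets_:
            fh.write(f"{ps.mis_id}\t{','.join(ps.probes)}\n")

    clusters = {}
    with open(d / "ranking.tsv", "w") as fh:
        fh.write("rank\tmis_id\tentropy\n")
        for rank, (mis_id, entropy, model) in enumerate(clf.ranked_, start=1):
            fh.write(f"{rank}\t{mis_id}\t{entropy:.10f}\n")
            clusters[mis_id] = {
                "k": model.k,
                "probes": model.probes,
                "centroids": np.asarray(model.centroids).tolist(),
                "p_counts": np.asarray(model.p_counts).tolist(),
                "n_counts": np.asarray(model.n_counts).tolist(),
                "entropy": entropy,
            }
    with open(d / "clusters.json", "w") as fh:
        json.dump(clusters, fh, indent=1, sort_keys=True)

    with open(d / "config.json", "w") as fh:
        json.dump(
            {
                "probeset_size": clf.probeset_size,
                "overlap_threshold": clf.overlap_threshold,
                "n_voters": clf.n_voters,
                "g": clf.g_,
                "k": clf.k_,
                "s0": clf.s0_,
                "positive_label": clf._positive,
                "negative_label": clf._negative,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def load_model(directory) -> COSSYClassifier:
    d = Path(directory)
    with open(d / "config.json") as fh:
        cfg = json.load(fh)
    norm_df = pd.read_csv(d / "normalization.tsv", sep="\t", dtype={"probe_id": str})
    normalization = NormalizationModel(
        probe_ids=[str(p) for p in norm_df["probe_id"]],
        reference_quantiles=norm_df["reference_quantile"].to_numpy(float),
        probe_mean=norm_df["probe_mean"].to_numpy(float),
        probe_sd=norm_df["probe_sd"].to_numpy(float),
    )
    probesets = []
    ps_df = pd.read_csv(d / "probesets.tsv", sep="\t", dtype=str)
    for _i, row in ps_df.iterrows():
        probesets.append(
            RepresentativeProbeset(mis_id=row["mis_id"], probes=row["probes"].split(","))
        )
    with open(d / "clusters.json") as fh:
        clusters = json.load(fh)
    rank_df = pd.read_csv(d / "ranking.tsv", sep="\t", dtype={"mis_id": str})
    ranked = []
    for _i, row in rank_df.iterrows():
        c = clusters[row["mis_id"]]
        model = MISClusterModel(
            mis_id=row["mis_id"],
            k=int(c["k"]),
            probes=list(c["probes"]),
            centroids=np.asarray(c["centroids"], float),
            p_counts=np.asarray(c["p_counts"], int),
            n_counts=np.asarray(c["n_counts"], int),
            entropy=float(c["entropy"]),
        )
        ranked.append((row["mis_id"], float(row["entropy"]), model))

    clf = COSSYClassifier(
        probe_ids=normalization.probe_ids,
        probeset_size=int(cfg["probeset_size"]),
        overlap_threshold=float(cfg["overlap_threshold"]),
        n_voters=int(cfg["n_voters"]),
        positive_label=cfg["positive_label"],
    )
    clf.normalization_ = normalization
    clf.probesets_ = probesets
    clf.ranked_ = ranked
    clf.g_ = int(cfg["g"])
    clf.k_ = int(cfg["k"])
    clf.s0_ = float(cfg["s0"])
    clf._positive = cfg["positive_label"]
    clf._negative = cfg["negative_label"]
    clf.classes_ = np.array(sorted([cfg["positive_label"], cfg["negative_label"]]))
    clf._probe_index = {p: i for i, p in enumerate(normalization.probe_ids)}
    clf._probesets_by_id = {ps.mis_id: ps for ps in probesets}
    return clf
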