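"""Readers, writers and core containers for networks, probe maps and expression data.

All on-disk formats are plain tab-separated text:

* edge list — two columns, one undirected edge per line;
* node→molecule map — two columns ``node<TAB>molecule``, one pair per line
  (a node may carry several molecules, a molecule may sit in several nodes);
* molecule→probe map — two columns ``molecule<TAB>probe``;
* expression matrix — header row of sample identifiers, first column probe
  identifiers, numeric cells;
* labels — two columns ``sample<TAB>class`` with exactly two distinct classes;
* MIS sets — GMT lines ``mis_id<TAB>description<TAB>member<TAB>member...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "InteractionNetwork",
    "ProbeMap",
    "ExpressionDataset",
    "MIS",
    "read_network",
    "write_network",
    "read_probe_map",
    "write_probe_map",
    "read_expression",
    "write_expression",
    "read_mis_sets",
    "write_mis_sets",
    "write_ranking",
]


class ParseError(ValueError):
    """A malformed line in an input file."""


class ValidationError(ValueError):
    """Structurally valid input that violates a contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class InteractionNetwork:
    """Undirected simple molecular interaction graph.

    Each node carries a non-empty set of molecule identifiers: a node may
    represent a single protein (STRING-style) or a group of molecules
    (KEGG-style, where the same gene can also appear in several nodes).

    Parameters
    ----------
    edges : iterable of (node, node)
        Undirected edges. Self-loops and duplicates are dropped with a warning.
    molecules_of : mapping node -> set of molecule ids
        Must cover every node appearing in ``edges``; nodes present only here
        are kept as isolated nodes.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        molecules_of: Mapping[str, Iterable[str]],
    ) -> None:
        mols: dict[str, frozenset[str]] = {}
        for node, ms in molecules_of.items():
            ms = frozenset(ms)
            if not ms:
                raise ValidationError(f"node {node!r} has no mapped molecules")
            mols[str(node)] = ms

        g = nx.Graph()
        g.add_nodes_from(mols)
        missing: set[str] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                logger.warning("dropping self-loop at node %r", u)
                continue
            if g.has_edge(u, v):
                logger.warning("dropping duplicate edge (%r, %r)", u, v)
                continue
            for n in (u, v):
                if n not in mols:
                    missing.add(n)
            if not missing:
                g.add_edge(u, v)
        if missing:
            raise ValidationError(
                "edge-list nodes absent from node->molecule map: "
                + ", ".join(sorted(missing))
            )

        self._graph = g
        self._molecules = mols

    # -- basic views --------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self._graph.edges)

    @property
    def molecules_of(self) -> dict[str, frozenset[str]]:
        return dict(self._molecules)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self._graph.neighbors(node))

    def degree(self, node: str) -> int:
        return self._graph.degree(node)

    def molecules(self, node: str) -> frozenset[str]:
        return self._molecules[node]

    def as_networkx(self) -> nx.Graph:
        """A copy of the underlying graph (molecule sets as node attribute)."""
        g = self._graph.copy()
        nx.set_node_attributes(g, {n: set(m) for n, m in self._molecules.items()}, "molecules")
        return g

    def subnetwork(self, nodes: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on ``nodes`` (edges taken from this network)."""
        nodes = set(nodes)
        unknown = nodes - set(self._molecules)
        if unknown:
            raise ValidationError(f"unknown nodes: {sorted(unknown)}")
        sub = self._graph.subgraph(nodes)
        return InteractionNetwork(
            list(sub.edges), {n: self._molecules[n] for n in nodes}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self._molecules == other._molecules
        )

    def __repr__(self) -> str:
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


class ProbeMap:
    """Molecule → probe lookup; unmapped molecules yield the empty set."""

    def __init__(self, probes_of: Mapping[str, Iterable[str]] | None = None) -> None:
        self._map: dict[str, frozenset[str]] = {
            str(m): frozenset(ps) for m, ps in (probes_of or {}).items()
        }

    def probes_of(self, molecule: str) -> frozenset[str]:
        return self._map.get(molecule, frozenset())

    @property
    def molecules(self) -> frozenset[str]:
        return frozenset(self._map)

    def items(self):
        return self._map.items()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return self._map == other._map


@dataclass
class ExpressionDataset:
    """Probes × samples expression matrix with binary phenotype labels."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (P, M)
    labels: dict[str, str]  # sample -> class string
    positive_label: str

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            p, m = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at probe {self.probe_ids[p]!r}, "
                f"sample {self.sample_ids[m]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without labels: {missing}")
        classes = sorted({self.labels[s] for s in self.sample_ids})
        if len(classes) != 2:
            raise ValidationError(
                f"expected exactly two classes, found {classes}"
            )
        if self.positive_label not in classes:
            raise ValidationError(
                f"positive label {self.positive_label!r} not among classes {classes}"
            )

    # -- derived views ------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def negative_label(self) -> str:
        return next(
            c for c in sorted({self.labels[s] for s in self.sample_ids})
            if c != self.positive_label
        )

    @property
    def y(self) -> np.ndarray:
        """Boolean vector over samples; True = positive class."""
        return np.array(
            [self.labels[s] == self.positive_label for s in self.sample_ids]
        )

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionDataset":
        keep = list(keep)
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return ExpressionDataset(
            probe_ids=list(self.probe_ids),
            sample_ids=keep,
            values=self.values[:, cols].copy(),
            labels={s: self.labels[s] for s in keep},
            positive_label=self.positive_label,
        )

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class MIS:
    """Molecular Interaction Subnetwork: the unit of ranking and voting.

    ``molecules`` is the union of molecule sets over the subnetwork's nodes;
    ``nodes`` records the underlying graph nodes (empty for MISs created by
    overlap merging, where node identity is no longer unique); ``provenance``
    traces the partition path that produced the MIS.
    """

    mis_id: str
    molecules: frozenset[str]
    nodes: frozenset[str] = frozenset()
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.molecules = frozenset(self.molecules)
        self.nodes = frozenset(self.nodes)
        if not self.molecules:
            raise ValidationError(f"MIS {self.mis_id!r} has no molecules")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _two_columns(path: Path, what: str) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"{path}: malformed {what} line {lineno}: {line!r} "
                    "(expected two tab-separated columns)"
                )
            pairs.append((parts[0].strip(), parts[1].strip()))
    return pairs


def read_network(edge_list_path, node_molecule_map_path) -> InteractionNetwork:
    """Load an interaction network from a TSV edge list and node→molecule map.

    Duplicate edges and self-loops are dropped with a logged warning; nodes
    that appear only in the map are retained as isolated nodes. An edge
    endpoint missing from the map is a validation error.
    """
    mol_pairs = _two_columns(Path(node_molecule_map_path), "node-molecule")
    molecules: dict[str, set[str]] = {}
    for node, mol in mol_pairs:
        molecules.setdefault(node, set()).add(mol)
    edges = _two_columns(Path(edge_list_path), "edge")
    return InteractionNetwork(edges, molecules)


def write_network(network: InteractionNetwork, edge_list_path, node_molecule_map_path) -> None:
    with open(edge_list_path, "w") as fh:
        for e in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
    with open(node_molecule_map_path, "w") as fh:
        for node in sorted(network.nodes):
            for mol in sorted(network.molecules(node)):
                fh.write(f"{node}\t{mol}\n")


def read_probe_map(path) -> ProbeMap:
    pairs = _two_columns(Path(path), "molecule-probe")
    probes: dict[str, set[str]] = {}
    for mol, probe in pairs:
        probes.setdefault(mol, set()).add(probe)
    return ProbeMap(probes)


def write_probe_map(probe_map: ProbeMap, path) -> None:
    with open(path, "w") as fh:
        for mol in sorted(probe_map.molecules):
            for probe in sorted(probe_map.probes_of(mol)):
                fh.write(f"{mol}\t{probe}\n")


def read_expression(matrix_path, labels_path, positive_label: str) -> ExpressionDataset:
    """Load a probes × samples TSV matrix and a two-column labels file.

    ``positive_label`` designates which of the two class strings is treated
    as the positive context; it is never inferred from file order.
    """
    try:
        frame = pd.read_csv(
            matrix_path, sep="\t", index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{matrix_path}: cannot parse expression matrix: {exc}") from exc
    for col in frame.columns:
        bad = frame[col].apply(
            lambda v: not isinstance(v, (int, float, np.integer, np.floating))
        )
        if bad.any():
            probe = frame.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{matrix_path}: non-numeric value at probe {probe!r}, sample {col!r}"
            )
    label_pairs = _two_columns(Path(labels_path), "label")
    labels = {}
    for sample, cls in label_pairs:
        if sample in labels and labels[sample] != cls:
            raise ValidationError(f"conflicting labels for sample {sample!r}")
        labels[sample] = cls
    classes = sorted(set(labels.values()))
    if len(classes) > 2:
        raise ValidationError(f"more than two label values: {classes}")
    return ExpressionDataset(
        probe_ids=[str(p) for p in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=frame.to_numpy(dtype=float),
        labels=labels,
        positive_label=positive_label,
    )


def write_expression(dataset: ExpressionDataset, matrix_path, labels_path) -> None:
    # %.17g round-trips float64 exactly
    dataset.to_frame().to_csv(
        matrix_path, sep="\t", index_label="probe", float_format="%.17g"
    )
    with open(labels_path, "w") as fh:
        for s in dataset.sample_ids:
            fh.write(f"{s}\t{dataset.labels[s]}\n")


def write_mis_sets(mis_list: list[MIS], path) -> None:
    """Write MISs as GMT lines: id, provenance-as-description, molecule columns."""
    if not mis_list:
        raise ValidationError("refusing to write an empty MIS list")
    with open(path, "w") as fh:
        for mis in mis_list:
            desc = ";".join(mis.provenance) if mis.provenance else "na"
            fh.write("\t".join([mis.mis_id, desc, *sorted(mis.molecules)]) + "\n")


def read_mis_sets(path) -> list[MIS]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: malformed GMT line {lineno}")
            provenance = [] if parts[1] == "na" else parts[1].split(";")
            out.append(MIS(mis_id=parts[0], molecules=frozenset(parts[2:]), provenance=provenance))
    return out


def write_ranking(ranked, probesets_by_id, t_scores, path) -> None:
    """Write a ranked-MIS table: mis_id, entropy, probes, t-scores."""
    with open(path, "w") as fh:
        fh.write("mis_id\tentropy\tprobes\tt_scores\n")
        for mis_id, entropy, _model in ranked:
            probes = probesets_by_id[mis_id].probes
            ts = ",".join(f"{t_scores[p]:.6g}" for p in probes)
            fh.write(f"{mis_id}\t{entropy:.6f}\t{','.join(probes)}\t{ts}\n")
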