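"""Partition an interaction network into size-bounded subnetworks (MISs).

The pipeline is non-greedy: instead of growing subnetworks from seed nodes,
the whole network is divided first. Each connected component larger than the
appropriate size range is agglomerated into a community dendrogram by greedy
modularity maximisation (Clauset–Newman–Moore), the dendrogram is cut from
the top until each piece fits the range, branches that fall below the range
are dissolved and their nodes re-attached to the nearest surviving community
by hop distance, and any community pushed back above the range by that
re-attachment is re-partitioned recursively.

Modularity is the standard undirected, unweighted quantity

    Q = sum_i (e_ii - a_i^2)

where ``e_ii`` is the fraction of edges inside group *i* and ``a_i`` the
fraction of edge endpoints in group *i*. Merging adjacent groups *i*, *j*
changes Q by ``e_ij - 2 a_i a_j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network_io import MIS, InteractionNetwork, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AppropriateRange",
    "DendrogramNode",
    "CommunityDendrogram",
    "Community",
    "connected_components",
    "build_dendrogram",
    "extract_appropriate_communities",
    "merge_discarded_nodes",
    "generate_mis",
]

#: maximum hop distance examined when re-attaching a discarded node
H_MAX = 5


@dataclass(frozen=True)
class AppropriateRange:
    """Size window [min_range, max_range] a community must fit to become an MIS."""

    min_range: int = 5
    max_range: int = 15

    def __post_init__(self) -> None:
        if not (2 <= self.min_range <= self.max_range):
            raise ValidationError(
                f"require 2 <= min_range <= max_range, got "
                f"[{self.min_range}, {self.max_range}]"
            )

    def contains(self, size: int) -> bool:
        return self.min_range <= size <= self.max_range


@dataclass
class DendrogramNode:
    members: frozenset[str]
    left: Optional["DendrogramNode"] = None
    right: Optional["DendrogramNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CommunityDendrogram:
    """Merge tree from greedy modularity agglomeration of one connected component.

    ``merge_sequence`` lists (group_a_members, group_b_members, modularity
    after the merge) in merge order; the last entry leaves a single group
    containing every node. Cutting the tree top-down at any depth yields a
    disjoint, covering partition of the component.
    """

    root: DendrogramNode
    merge_sequence: list[tuple[frozenset[str], frozenset[str], float]] = field(
        default_factory=list
    )

    def cut(self, n_groups: int) -> list[frozenset[str]]:
        """Partition into ``n_groups`` by undoing the last merges (top cuts)."""
        groups: list[DendrogramNode] = [self.root]
        while len(groups) < n_groups:
            # split the internal node created latest = largest remaining merge
            splittable = [g for g in groups if not g.is_leaf]
            if not splittable:
                break
            order = {id(n): i for i, n in enumerate(self._internal_order())}
            target = max(splittable, key=lambda g: order[id(g)])
            groups.remove(target)
            groups.extend([target.left, target.right])
        return [g.members for g in groups]

    def _internal_order(self) -> list[DendrogramNode]:
        # internal nodes in creation (merge) order, reconstructed by size of
        # merge_sequence: walk the tree and match member sets
        index = {
            frozenset(a | b): i for i, (a, b, _q) in enumerate(self.merge_sequence)
        }
        nodes: list[tuple[int, DendrogramNode]] = []

        def walk(n: DendrogramNode) -> None:
            if n.is_leaf:
                return
            nodes.append((index[n.members], n))
            walk(n.left)
            walk(n.right)

        walk(self.root)
        nodes.sort(key=lambda t: t[0])
        return [n for _i, n in nodes]


@dataclass
class Community:
    members: frozenset[str]
    status: str = "appropriate"  # appropriate | discarded | oversized

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError("community with no members")


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------


def connected_components(network: InteractionNetwork) -> list[InteractionNetwork]:
    """Induced subgraphs, one per component, ordered by smallest member node."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(tuple(e) for e in network.edges)
    comps = sorted(nx.connected_components(g), key=min)
    return [network.subnetwork(c) for c in comps]


# ---------------------------------------------------------------------------
# greedy modularity dendrogram
# ---------------------------------------------------------------------------


def build_dendrogram(component: InteractionNetwork) -> CommunityDendrogram:
    """Agglomerate a connected component by greedy modularity maximisation.

    Starting from singleton groups, the adjacent pair of groups whose merge
    gives the largest modularity gain is merged until one group remains; ties
    are broken by the lexicographically smallest (group_a, group_b) pair of
    smallest member identifiers. The recorded modularity after each merge is
    the exact modularity of the partition at that step.
    """
    import networkx as nx

    nodes = sorted(component.nodes)
    if len(nodes) < 2 or component.n_edges < 1:
        raise ValidationError("dendrogram requires >= 2 nodes and >= 1 edge")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(tuple(e) for e in component.edges)
    if not nx.is_connected(g):
        raise ValidationError("build_dendrogram requires a connected component")

    m = g.number_of_edges()
    # group state: members via tree nodes, degree sums, internal edge counts,
    # inter-group edge counts
    tree: dict[int, DendrogramNode] = {}
    deg_sum: dict[int, int] = {}
    e_in: dict[int, int] = {}
    between: dict[int, dict[int, int]] = {}
    min_member: dict[int, str] = {}

    ids = {n: i for i, n in enumerate(nodes)}
    for n, i in ids.items():
        tree[i] = DendrogramNode(members=frozenset([n]))
        deg_sum[i] = g.degree(n)
        e_in[i] = 0
        between[i] = {}
        min_member[i] = n
    for u, v in g.edges:
        i, j = ids[u], ids[v]
        between[i][j] = between[i].get(j, 0) + 1
        between[j][i] = between[j].get(i, 0) + 1

    q = sum(-((d / (2 * m)) ** 2) for d in deg_sum.values())
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []
    next_id = len(nodes)
    active = set(tree)

    while len(active) > 1:
        best = None  # (gain, min_a, min_b, i, j)
        for i in active:
            ai = deg_sum[i] / (2 * m)
            for j, eij in between[i].items():
                if j <= i and j in active:
                    continue  # visit each unordered pair once via i < j
                gain = eij / m - 2 * ai * (deg_sum[j] / (2 * m))
                a, b = sorted((min_member[i], min_member[j]))
                key = (-gain, a, b)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:  # pragma: no cover - impossible on connected input
            raise RuntimeError("no adjacent pair to merge in a connected graph")
        _key, i, j = best
        gain = -_key[0]
        # create merged group
        k = next_id
        next_id += 1
        a_node, b_node = tree[i], tree[j]
        # record (a, b) ordered by smallest member
        if min(a_node.members) > min(b_node.members):
            a_node, b_node = b_node, a_node
        q += gain
        merges.append((a_node.members, b_node.members, q))
        tree[k] = DendrogramNode(
            members=a_node.members | b_node.members, left=a_node, right=b_node
        )
        deg_sum[k] = deg_sum[i] + deg_sum[j]
        e_in[k] = e_in[i] + e_in[j] + between[i].get(j, 0)
        min_member[k] = min(min_member[i], min_member[j])
        nb: dict[int, int] = {}
        for src in (i, j):
            for t, cnt in between[src].items():
                if t in (i, j):
                    continue
                nb[t] = nb.get(t, 0) + cnt
        between[k] = nb
        for t, cnt in nb.items():
            between[t].pop(i, None)
            between[t].pop(j, None)
            between[t][k] = cnt
        for dead in (i, j):
            active.discard(dead)
            del between[dead]
        active.add(k)

    return CommunityDendrogram(root=tree[next_id - 1], merge_sequence=merges)


# ---------------------------------------------------------------------------
# dendrogram cutting
# ---------------------------------------------------------------------------


def extract_appropriate_communities(
    dendrogram: CommunityDendrogram, size_range: AppropriateRange
) -> tuple[list[Community], set[str]]:
    """Cut the dendrogram top-down into communities within the size range.

    A group within the range is emitted as appropriate; one above the range
    is split at its top-most merge and both children are processed
    recursively; one below the range is discarded wholesale, its nodes
    collected for later re-attachment.
    """
    appropriate: list[Community] = []
    discarded: set[str] = set()

    def visit(node: DendrogramNode) -> None:
        n = node.size
        if size_range.contains(n):
            appropriate.append(Community(members=node.members, status="appropriate"))
        elif n > size_range.max_range:
            if node.is_leaf:  # pragma: no cover - leaves have size 1
                appropriate.append(Community(members=node.members, status="oversized"))
            else:
                visit(node.left)
                visit(node.right)
        else:
            discarded.update(node.members)

    visit(dendrogram.root)
    return appropriate, discarded


# ---------------------------------------------------------------------------
# discarded-node merging
# ---------------------------------------------------------------------------


def _hop_counts(
    network: InteractionNetwork, start: str, h: int, communities: list[set[str]],
    candidates: list[int],
) -> dict[int, int]:
    """Number of members of each candidate community within ``h`` hops of start."""
    seen = {start}
    frontier = {start}
    for _ in range(h):
        nxt = set()
        for u in frontier:
            nxt.update(network.neighbors(u))
        frontier = nxt - seen
        seen |= frontier
        if not frontier:
            break
    reach = seen - {start}
    return {c: len(reach & communities[c]) for c in candidates}


def merge_discarded_nodes(
    discarded: set[str],
    communities: list[Community],
    original: InteractionNetwork,
    seed: int,
) -> list[Community]:
    """Attach each discarded node to its closest appropriate community.

    Nodes are processed in waves: in each pass, every discarded node with a
    1-hop neighbour inside some community chooses the community with the most
    members within h hops, escalating h = 1, 2, ... (capped at ``H_MAX``) and
    restricting to the tied leaders at each escalation; a tie surviving at
    ``H_MAX`` is resolved uniformly at random with the supplied seed. Nodes
    with no path to any community are assigned at random among all
    communities (logged), which guarantees termination.
    """
    if not communities:
        raise ValidationError("merge_discarded_nodes requires >= 1 community")
    rng = np.random.default_rng(seed)
    members = [set(c.members) for c in communities]
    remaining = set(discarded)
    unknown = remaining - original.nodes
    if unknown:
        raise ValidationError(f"discarded nodes not in network: {sorted(unknown)}")

    while remaining:
        in_any = set().union(*members)
        frontier = {
            d for d in remaining if original.neighbors(d) & in_any
        }
        unreachable_pass = not frontier
        if unreachable_pass:
            # no remaining node touches a community: they are disconnected
            # from every community in the original graph
            frontier = set(remaining)
        assignments: dict[str, int] = {}
        for d in sorted(frontier):
            candidates = list(range(len(members)))
            chosen: int | None = None
            for h in range(1, H_MAX + 1):
                counts = _hop_counts(original, d, h, members, candidates)
                top = max(counts.values())
                leaders = sorted(c for c, v in counts.items() if v == top)
                if top > 0 and len(leaders) == 1:
                    chosen = leaders[0]
                    break
                if top > 0:
                    candidates = leaders
            if chosen is None:
                if unreachable_pass:
                    logger.warning(
                        "node %r has no path to any community; assigning at random", d
                    )
                chosen = int(rng.choice(sorted(candidates)))
            assignments[d] = chosen
        for d, c in assignments.items():
            members[c].add(d)
            remaining.discard(d)

    return [
        Community(members=frozenset(ms), status=communities[i].status)
        for i, ms in enumerate(members)
    ]


# ---------------------------------------------------------------------------
# top-level MIS generation
# ---------------------------------------------------------------------------


def _partition_component(
    component: InteractionNetwork,
    size_range: AppropriateRange,
    rng_seed: int,
) -> list[tuple[frozenset[str], str, list[str]]]:
    """Return (node set, status, provenance) triples partitioning the component."""
    n = component.n_nodes
    tag = f"component:{min(component.nodes)}(n={n})"
    if n <= size_range.max_range:
        status = "appropriate" if size_range.contains(n) else "undersized"
        return [(frozenset(component.nodes), status, [tag])]

    dendrogram = build_dendrogram(component)
    appropriate, discarded = extract_appropriate_communities(dendrogram, size_range)
    if not appropriate:
        # pathological topology: no cut of the dendrogram fits the range
        return [(frozenset(component.nodes), "oversized", [tag, "unsplittable"])]
    merged = merge_discarded_nodes(discarded, appropriate, component, rng_seed)

    out: list[tuple[frozenset[str], str, list[str]]] = []
    for idx, comm in enumerate(merged):
        prov = [tag, f"cut:{idx}"]
        if len(comm.members) <= size_range.max_range:
            status = "appropriate" if size_range.contains(len(comm.members)) else "undersized"
            out.append((comm.members, status, prov))
        elif comm.members == component.nodes:
            # re-attachment regrew the whole component: cannot be split further
            out.append((comm.members, "oversized", prov + ["unsplittable"]))
        else:
            sub = component.subnetwork(comm.members)
            for piece in connected_components(sub):
                for mem, status, sub_prov in _partition_component(
                    piece, size_range, rng_seed + 1
                ):
                    out.append((mem, status, prov + ["repartition"] + sub_prov))
    return out


def generate_mis(
    network: InteractionNetwork,
    size_range: AppropriateRange = AppropriateRange(),
    seed: int = 0,
) -> list[MIS]:
    """Partition a network into MISs whose sizes target the appropriate range.

    Every connected component is either emitted whole (when its size is at or
    below ``max_range`` — components below ``min_range`` are kept, since
    their probe count may still suffice downstream) or divided via the
    community dendrogram. Each node of the network lands in exactly one MIS;
    molecule sets may still overlap when a molecule sits in several nodes.
    Deterministic for a fixed seed.
    """
    mis_list: list[MIS] = []
    counter = 0
    for comp in connected_components(network):
        for members, status, provenance in _partition_component(
            comp, size_range, seed
        ):
            counter += 1
            molecules = frozenset().union(
                *(network.molecules(n) for n in members)
            )
            mis_list.append(
                MIS(
                    mis_id=f"MIS{counter:04d}",
                    molecules=molecules,
                    nodes=members,
                    provenance=provenance + [f"status:{status}"],
                )
            )
    return mis_list
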