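import itertools

import networkx as nx
import numpy as np
import pytest

from cossy.network_io import ValidationError
from cossy.partition import (
    AppropriateRange,
    Community,
    CommunityDendrogram,
    DendrogramNode,
    build_dendrogram,
    connected_components,
    extract_appropriate_communities,
    generate_mis,
    merge_discarded_nodes,
)
from cossy.synthetic import SyntheticSpec, make_network

from conftest import simple_network
from oracles import best_first_merge_gain, nx_modularity, random_connected_graph


def to_nx(network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(tuple(e) for e in network.edges)
    return g


def from_nx(g: nx.Graph):
    return simple_network(
        list(g.edges), {n: {f"g{n}"} for n in g.nodes}
    )


def replay_merge_modularities(network, dendrogram: CommunityDendrogram):
    """Recompute the partition modularity after every merge via networkx."""
    g = to_nx(network)
    groups = {frozenset([n]) for n in network.nodes}
    recomputed = []
    for a, b, _q in dendrogram.merge_sequence:
        groups.discard(frozenset(a))
        groups.discard(frozenset(b))
        groups.add(frozenset(a) | frozenset(b))
        recomputed.append(nx_modularity(g, [set(s) for s in groups]))
    return recomputed


class TestConnectedComponents:
    def test_two_disjoint_triangles(self):
        net = simple_network(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        comps = connected_components(net)
        assert [sorted(c.nodes) for c in comps] == [["a", "b", "c"], ["x", "y", "z"]]

    def test_isolated_node_is_its_own_component(self):
        net = simple_network([("a", "b")], {"a": {"g1"}, "b": {"g2"}, "c": {"g3"}})
        comps = connected_components(net)
        assert [sorted(c.nodes) for c in comps] == [["a", "b"], ["c"]]

    def test_planted_communities_without_crosslinks(self):
        spec = SyntheticSpec(n_communities=5, community_size=8, p_in=1.0, p_out=0.0, seed=4)
        net, truth = make_network(spec)
        comps = connected_components(net)
        assert len(comps) == 5
        planted = {}
        for node, c in truth.community_of.items():
            planted.setdefault(c, set()).add(node)
        assert {frozenset(c.nodes) for c in comps} == {
            frozenset(m) for m in planted.values()
        }


class TestBuildDendrogram:
    def test_two_cliques_with_bridge_top_cut(self):
        left = [f"a{i}" for i in range(4)]
        right = [f"b{i}" for i in range(4)]
        edges = (
            list(itertools.combinations(left, 2))
            + list(itertools.combinations(right, 2))
            + [("a0", "b0")]
        )
        net = simple_network(edges)
        dendro = build_dendrogram(net)
        top = {dendro.root.left.members, dendro.root.right.members}
        assert top == {frozenset(left), frozenset(right)}
        # exhaustive oracle: the top cut is the best 2-partition by modularity
        g = to_nx(net)
        nodes = sorted(net.nodes)
        best_q, best_split = -np.inf, None
        for mask in range(1, 2 ** (len(nodes) - 1)):
            part_a = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
            part_b = set(nodes) - part_a
            q = nx_modularity(g, [part_a, part_b])
            if q > best_q:
                best_q, best_split = q, {frozenset(part_a), frozenset(part_b)}
        assert top == best_split

    def test_triangle_merges_to_single_group(self):
        net = simple_network([("a", "b"), ("b", "c"), ("a", "c")])
        dendro = build_dendrogram(net)
        assert dendro.root.members == {"a", "b", "c"}
        recorded = [q for _a, _b, q in dendro.merge_sequence]
        assert recorded == pytest.approx(replay_merge_modularities(net, dendro), abs=1e-9)

    def test_planted_partition_recovered_at_three_groups(self):
        spec = SyntheticSpec(n_communities=3, community_size=10, p_in=0.8, p_out=0.05, seed=2)
        net, truth = make_network(spec)
        comps = connected_components(net)
        assert len(comps) == 1  # p_out joins the communities at this seed
        dendro = build_dendrogram(comps[0])
        cut = dendro.cut(3)
        planted = {}
        for node, c in truth.community_of.items():
            planted.setdefault(c, set()).add(node)
        assert {frozenset(c) for c in cut} == {frozenset(m) for m in planted.values()}

    def test_recorded_modularities_match_recomputation(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_max=9)
            net = from_nx(g)
            dendro = build_dendrogram(net)
            recorded = [q for _a, _b, q in dendro.merge_sequence]
            assert recorded == pytest.approx(
                replay_merge_modularities(net, dendro), abs=1e-9
            )

    def test_first_merge_is_brute_force_optimal(self, rng):
        for _ in range(25):
            g = random_connected_graph(rng, n_max=10)
            if g.number_of_nodes() < 2:
                continue
            net = from_nx(g)
            dendro = build_dendrogram(net)
            a, b, q_first = dendro.merge_sequence[0]
            assert len(a) == 1 and len(b) == 1
            assert q_first >= best_first_merge_gain(g) - 1e-12

    def test_cut_is_a_partition_at_every_depth(self, rng):
        g = random_connected_graph(rng, n_max=8)
        net = from_nx(g)
        dendro = build_dendrogram(net)
        for depth in range(1, net.n_nodes + 1):
            cut = dendro.cut(depth)
            assert len(cut) == depth
            flat = [n for grp in cut for n in grp]
            assert len(flat) == net.n_nodes and set(flat) == net.nodes

    def test_disconnected_input_rejected(self):
        net = simple_network([("a", "b"), ("c", "d")])
        with pytest.raises(ValidationError):
            build_dendrogram(net)


def chain_dendrogram(sizes):
    """Hand-built dendrogram whose top splits follow the given nested sizes.

    ``sizes`` is a nested tuple, e.g. ((12, 10), (9, 9)) for a 40-leaf tree
    whose top split is 22+18.
    """
    counter = itertools.count()

    def build(spec) -> DendrogramNode:
        if isinstance(spec, int):
            leaves = [DendrogramNode(frozenset([f"n{next(counter):03d}"])) for _ in range(spec)]
            while len(leaves) > 1:
                a, b = leaves.pop(0), leaves.pop(0)
                leaves.append(DendrogramNode(a.members | b.members, a, b))
            return leaves[0]
        left, right = (build(s) for s in spec)
        return DendrogramNode(left.members | right.members, left, right)

    root = build(sizes)
    return CommunityDendrogram(root=root, merge_sequence=[])


class TestExtractAppropriateCommunities:
    def test_recursive_splitting_hand_trace(self):
        dendro = chain_dendrogram(((12, 10), (9, 9)))
        assert dendro.root.size == 40
        appropriate, discarded = extract_appropriate_communities(
            dendro, AppropriateRange(5, 15)
        )
        assert sorted(len(c.members) for c in appropriate) == [9, 9, 10, 12]
        assert discarded == set()

    def test_group_below_range_fully_discarded(self):
        dendro = chain_dendrogram(4)
        appropriate, discarded = extract_appropriate_communities(
            dendro, AppropriateRange(5, 15)
        )
        assert appropriate == [] and len(discarded) == 4

    def test_group_in_range_emitted_without_recursion(self):
        dendro = chain_dendrogram(10)
        appropriate, discarded = extract_appropriate_communities(
            dendro, AppropriateRange(5, 15)
        )
        assert len(appropriate) == 1
        assert appropriate[0].members == dendro.root.members
        assert discarded == set()


class TestMergeDiscardedNodes:
    def test_majority_neighbor_community_wins_at_one_hop(self):
        # d touches two nodes of A but only one of B
        net = simple_network(
            [("a1", "a2"), ("b1", "b2"), ("d", "a1"), ("d", "a2"), ("d", "b1")]
        )
        out = merge_discarded_nodes(
            {"d"},
            [Community({"a1", "a2"}), Community({"b1", "b2"})],
            net,
            seed=0,
        )
        assert out[0].members == {"a1", "a2", "d"}
        assert out[1].members == {"b1", "b2"}

    def test_tie_at_one_hop_resolved_at_two_hops(self):
        # d touches one node of each community; A has more members within 2 hops
        net = simple_network(
            [
                ("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                ("b1", "b2"),
                ("d", "a1"), ("d", "b1"),
            ]
        )
        out = merge_discarded_nodes(
            {"d"},
            [Community({"a1", "a2", "a3"}), Community({"b1", "b2"})],
            net,
            seed=0,
        )
        assert "d" in out[0].members

    def test_isolated_node_assignment_is_seeded_and_reproducible(self):
        net = simple_network(
            [("a1", "a2"), ("b1", "b2")],
            {"a1": {"g1"}, "a2": {"g2"}, "b1": {"g3"}, "b2": {"g4"}, "d": {"g5"}},
        )
        comms = [Community({"a1", "a2"}), Community({"b1", "b2"})]
        runs = [
            merge_discarded_nodes({"d"}, comms, net, seed=42) for _ in range(3)
        ]
        memberships = [tuple(tuple(sorted(c.members)) for c in r) for r in runs]
        assert len(set(memberships)) == 1  # identical across runs
        assert any("d" in c.members for c in runs[0])


class TestGenerateMIS:
    def test_single_in_range_component_is_one_mis(self):
        spec = SyntheticSpec(n_communities=1, community_size=10, p_in=0.9, seed=1)
        net, _ = make_network(spec)
        mis = generate_mis(net, AppropriateRange(5, 15), seed=1)
        assert len(mis) == 1
        assert mis[0].nodes == net.nodes
        assert mis[0].molecules == frozenset().union(
            *(net.molecules(n) for n in net.nodes)
        )

    def test_below_range_component_is_kept(self):
        net = simple_network([("a", "b"), ("b", "c"), ("c", "d")])
        mis = generate_mis(net, AppropriateRange(5, 15), seed=0)
        assert len(mis) == 1 and len(mis[0].nodes) == 4

    def test_star_component_emitted_as_one_oversized_mis(self):
        hub = "n00"
        edges = [(hub, f"n{i:02d}") for i in range(1, 30)]
        net = simple_network(edges)
        mis = generate_mis(net, AppropriateRange(5, 15), seed=0)
        assert len(mis) == 1
        assert len(mis[0].nodes) == 30
        assert "status:oversized" in mis[0].provenance[-1]

    def test_every_node_in_exactly_one_mis(self):
        spec = SyntheticSpec(n_communities=4, community_size=12, p_in=0.6, p_out=0.05, seed=9)
        net, _ = make_network(spec)
        mis = generate_mis(net, AppropriateRange(5, 15), seed=9)
        counts = {}
        for m in mis:
            for n in m.nodes:
                counts[n] = counts.get(n, 0) + 1
        assert set(counts) == set(net.nodes)
        assert set(counts.values()) == {1}

    def test_fixed_seed_is_bit_reproducible(self):
        spec = SyntheticSpec(n_communities=3, community_size=10, p_in=0.7, p_out=0.08, seed=6)
        net, _ = make_network(spec)
        a = generate_mis(net, AppropriateRange(5, 15), seed=123)
        b = generate_mis(net, AppropriateRange(5, 15), seed=123)
        assert [(m.mis_id, m.nodes, m.molecules, m.provenance) for m in a] == [
            (m.mis_id, m.nodes, m.molecules, m.provenance) for m in b
        ]

    def test_size_discipline_on_non_pathological_graphs(self):
        # most MISs from an Erdos-Renyi and a planted-partition graph of 200
        # nodes should land inside the appropriate range
        rng = np.random.default_rng(13)
        g = nx.gnp_random_graph(200, 0.03, seed=13)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
        nets = [from_nx(g)]
        spec = SyntheticSpec(n_communities=10, community_size=20, p_in=0.4, p_out=0.01, seed=13)
        nets.append(make_network(spec)[0])
        for net in nets:
            mis = generate_mis(net, AppropriateRange(5, 15), seed=13)
            sizes = [len(m.nodes) for m in mis]
            in_range = sum(1 for s in sizes if 5 <= s <= 15)
            assert in_range / len(sizes) >= 0.6


def test_appropriate_range_validation():
    with pytest.raises(ValidationError):
        AppropriateRange(1, 15)
    with pytest.raises(ValidationError):
        AppropriateRange(10, 5)
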