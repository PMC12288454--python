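"""Network construction, communities, and suboptimal-path enumeration."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from allosterik.correlation import dcc
from allosterik.exceptions import DegenerateNetworkError, NoPathError
from allosterik.network import (
    PathEnsemble,
    PathQuery,
    build_network,
    detect_communities,
    path_statistics,
    suboptimal_paths,
)
from allosterik.trajectory import Trajectory


def brute_force_paths(G, sources, sinks, delta):
    """Independent oracle: exhaustive simple-path enumeration + weight filter."""
    def pw(p):
        return sum(G[a][b]["weight"] for a, b in zip(p, p[1:]))

    l_opt = math.inf
    for s in sources:
        for t in sinks:
            try:
                l_opt = min(l_opt, nx.dijkstra_path_length(G, s, t))
            except nx.NetworkXNoPath:
                continue
    paths = set()
    for s in sources:
        for t in sinks:
            for p in nx.all_simple_paths(G, s, t):
                if pw(p) <= l_opt + delta + 1e-9:
                    paths.add(tuple(p))
    return l_opt, paths


def toy_graph():
    G = nx.Graph()
    for a, b, w in [("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 1.5), ("b", "t", 1.0), ("s", "t", 3.0)]:
        G.add_edge(a, b, weight=w)
    return G


def _controlled_corr_traj():
    """Three in-contact residues whose pairwise DCC is known exactly.

    Residue displacements (x only): b = a (C=1); c built as 0.5·a + √0.75·u
    with u ⊥ a and ‖u‖ = ‖a‖, so C(a,c) = 0.5 exactly.
    """
    a = np.array([1.0, -1.0, 1.0, -1.0])
    u = np.array([1.0, 1.0, -1.0, -1.0])
    c = 0.5 * a + math.sqrt(0.75) * u
    coords = np.zeros((4, 3, 3))
    coords[:, 0, 0] = 0.0 + 0.001 * a
    coords[:, 1, 0] = 4.0 + 0.001 * a
    coords[:, 2, 0] = 8.0 + 0.001 * c
    atoms = pd.DataFrame(
        {
            "serial": [1, 2, 3],
            "atom_name": "CA",
            "resid": [1, 3, 5],
            "resname": "GLY",
            "chain": "A",
            "domain": ["DBD", "linker", "EO"],
        }
    )
    return Trajectory(atoms, coords)


class TestBuildNetwork:
    def test_edge_weights_are_minus_log_correlation(self):
        traj = _controlled_corr_traj()
        net = build_network(traj, dcc(traj), contact_cutoff=8.5, occupancy_min=0.75)
        w12 = net.graph[("A", 1)][("A", 3)]["weight"]
        w23 = net.graph[("A", 3)][("A", 5)]["weight"]
        assert w12 == pytest.approx(0.0, abs=1e-9)  # |C| = 1
        assert w23 == pytest.approx(-math.log(0.5), abs=1e-9)
        for _, _, d in net.graph.edges(data=True):
            assert d["weight"] == pytest.approx(-math.log(min(abs(d["corr"]), 1.0)), abs=1e-12)

    def test_low_occupancy_pair_excluded(self):
        """A pair in contact for only half the frames gets no edge at o_min=0.75."""
        coords = np.zeros((4, 3, 3))
        coords[:, 0, 0] = [0.001, -0.001, 0.001, -0.001]
        coords[:, 1, 0] = 4.0 + np.array([0.001, -0.001, 0.001, -0.001])
        coords[:, 2, 0] = [8.0, 20.0, 8.0, 20.0]  # near atom 2 in half the frames
        traj = Trajectory(_controlled_corr_traj().atoms, coords)
        net = build_network(traj, dcc(traj), contact_cutoff=8.5, occupancy_min=0.75)
        assert not net.graph.has_edge(("A", 3), ("A", 5))
        assert not net.graph.has_edge(("A", 1), ("A", 5))

    def test_empty_network_rejected(self):
        traj = _controlled_corr_traj()
        with pytest.raises(DegenerateNetworkError):
            build_network(traj, dcc(traj), contact_cutoff=0.5)

    def test_enm_network_basic_shape(self, superposed):
        net = build_network(superposed, dcc(superposed))
        assert net.n_nodes == superposed.n_atoms
        assert net.n_edges > 0
        occ = [d["occupancy"] for _, _, d in net.graph.edges(data=True)]
        assert min(occ) >= 0.75


class TestCommunities:
    def test_two_cliques_with_bridge(self):
        G = nx.Graph()
        left = [("A", i) for i in range(1, 5)]
        right = [("B", i) for i in range(1, 5)]
        for grp in (left, right):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    G.add_edge(u, v, weight=0.2)
        G.add_edge(left[0], right[0], weight=2.0)
        part = detect_communities(G)
        assert part.n_communities == 2
        assert part.membership[left[0]] != part.membership[right[0]]
        assert {part.membership[u] for u in left} != {part.membership[u] for u in right}

    def test_uniform_clique_is_one_community(self):
        G = nx.complete_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        part = detect_communities(G)
        assert part.n_communities == 1

    def test_partition_covers_all_nodes(self, superposed):
        net = build_network(superposed, dcc(superposed))
        part = detect_communities(net)
        assert set(part.membership) == set(net.graph.nodes)
        comms = part.communities()
        assert all(c for c in comms)
        assert sum(len(c) for c in comms) == net.n_nodes

    def test_membership_invariant_to_node_relabelling(self):
        G = nx.Graph()
        left = [("A", i) for i in range(1, 5)]
        right = [("B", i) for i in range(1, 5)]
        for grp in (left, right):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    G.add_edge(u, v, weight=0.2)
        G.add_edge(left[1], right[2], weight=2.0)
        part1 = detect_communities(G)
        H = nx.Graph()
        for u, v, d in reversed(list(G.edges(data=True))):
            H.add_edge(v, u, **d)
        part2 = detect_communities(H)
        groups1 = {frozenset(c) for c in part1.communities()}
        groups2 = {frozenset(c) for c in part2.communities()}
        assert groups1 == groups2


class TestSuboptimalPaths:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (0.0, {("s", "a", "t")}),
            (0.5, {("s", "a", "t"), ("s", "b", "t")}),
            (1.0, {("s", "a", "t"), ("s", "b", "t"), ("s", "t")}),
        ],
    )
    def test_toy_graph_enumeration(self, delta, expected):
        ens = suboptimal_paths(toy_graph(), PathQuery(["s"], ["t"], delta=delta))
        assert ens.l_opt == pytest.approx(2.0)
        assert {nodes for _, nodes in ens.paths} == expected

    def test_single_edge(self):
        G = nx.Graph()
        G.add_edge("s", "t", weight=1.0)
        for delta in (0.0, 10.0):
            ens = suboptimal_paths(G, PathQuery(["s"], ["t"], delta=delta))
            assert ens.n_paths == 1

    def test_count_nondecreasing_in_delta(self):
        G = nx.gnm_random_graph(10, 22, seed=3)
        rng = np.random.default_rng(3)
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        counts = [
            suboptimal_paths(G, PathQuery([0], [9], delta=d)).n_paths
            for d in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_weights_resummed_and_sorted(self):
        G = toy_graph()
        ens = suboptimal_paths(G, PathQuery(["s"], ["t"], delta=5.0))
        ws = [w for w, _ in ens.paths]
        assert ws == sorted(ws)
        for w, nodes in ens.paths:
            resum = sum(G[a][b]["weight"] for a, b in zip(nodes, nodes[1:]))
            assert abs(resum - w) < 1e-9
            assert w <= ens.l_opt + ens.delta + 1e-9

    def test_truncation_flagged(self):
        ens = suboptimal_paths(toy_graph(), PathQuery(["s"], ["t"], delta=5.0, max_paths=2))
        assert ens.truncated and ens.n_paths == 2

    def test_no_connectivity_raises(self):
        G = nx.Graph()
        G.add_edge("s", "a", weight=1.0)
        G.add_node("t")
        with pytest.raises(NoPathError):
            suboptimal_paths(G, PathQuery(["s"], ["t"]))

    def test_overlapping_sources_sinks_rejected(self):
        with pytest.raises(ValueError):
            PathQuery(["s"], ["s"])

    def test_matches_brute_force_on_random_graphs(self):
        """Branch-and-bound equals exhaustive enumeration (multi-source/sink)."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 11))
            G = nx.gnm_random_graph(n, int(2.2 * n), seed=seed + 100)
            if not nx.is_connected(G):
                G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
            for u, v in G.edges:
                G[u][v]["weight"] = float(rng.uniform(0.05, 1.5))
            nodes = sorted(G.nodes)
            sources, sinks = nodes[:2], nodes[-2:]
            if set(sources) & set(sinks):
                continue
            l_ref, expected = brute_force_paths(G, sources, sinks, 0.6)
            ens = suboptimal_paths(G, PathQuery(sources, sinks, delta=0.6))
            assert ens.l_opt == pytest.approx(l_ref)
            assert {nodes_ for _, nodes_ in ens.paths} == expected

    def test_edge_removal_never_shortens_l_opt(self):
        G = toy_graph()
        base = suboptimal_paths(G, PathQuery(["s"], ["t"], delta=0.0)).l_opt
        for u, v in list(G.edges):
            H = G.copy()
            H.remove_edge(u, v)
            try:
                l2 = suboptimal_paths(H, PathQuery(["s"], ["t"], delta=0.0)).l_opt
            except NoPathError:
                continue
            assert l2 >= base - 1e-12


class TestPathStatistics:
    def _ens(self, weights, l_opt=None):
        paths = sorted((float(w), ("s", f"m{i}", "t")) for i, w in enumerate(weights))
        lo = min(weights) if l_opt is None else l_opt
        return PathEnsemble(paths, float(lo), delta=float(max(weights) - lo))

    def test_identical_ensembles_no_shift(self):
        a = self._ens([1.0, 1.2, 1.4])
        comp = path_statistics({"x": a, "y": self._ens([1.0, 1.2, 1.4])})
        assert comp.shifts[("x", "y")] == "none"
        assert comp.table.n_paths.nunique() == 1

    def test_uniform_weight_increase_is_right_shift(self):
        a = self._ens([1.0, 1.2, 1.4])
        b = self._ens([1.5, 1.7, 1.9])
        comp = path_statistics({"a": a, "b": b})
        assert comp.shifts[("a", "b")] == "right"
        assert comp.shifts[("b", "a")] == "left"

    def test_ranking_by_count(self):
        comp = path_statistics({"big": self._ens([1, 1.1, 1.2, 1.3]), "small": self._ens([1.0])})
        assert comp.ranking[0] == "big"

    def test_histogram_origin_at_l_opt(self):
        ens = self._ens([2.0, 2.5, 3.0])
        counts, edges = ens.histogram()
        assert edges[0] == pytest.approx(2.0)
        assert counts.sum() == 3
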