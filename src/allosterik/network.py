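"""Correlation-weighted residue networks, communities, and suboptimal paths.

Nodes are residues; an edge joins residues that stay in Cα contact for a
minimum fraction of frames, weighted by w = −ln|C_ij| so that strongly
correlated pairs are "short".  Allosteric communication between the
DNA-binding (DBD) and effector-binding (EO) domains is then summarised by
the ensemble of suboptimal paths: every simple source→sink path whose total
weight is within δ of the optimal path weight.  Path counts and length
distributions index how many routes a signal can take and how fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .correlation import CorrelationMatrix
from .exceptions import DegenerateNetworkError, NoPathError
from .trajectory import Trajectory

_W_FLOOR = 1e-6  # floor on w when converting to affinity 1/w


@dataclass
class DynamicalNetwork:
    """Weighted residue graph; nodes are (chain, resid) tuples."""

    graph: nx.Graph
    contact_cutoff: float
    occupancy_min: float
    corr_min: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (f"{u[0]}{u[1]}", f"{v[0]}{v[1]}", d["weight"], d["occupancy"], d["corr"])
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["i", "j", "weight", "occupancy", "C"]).to_csv(
            path, sep="\t", index=False
        )

    def to_graphml(self, path: str | Path) -> None:
        G = nx.relabel_nodes(self.graph, {n: f"{n[0]}{n[1]}" for n in self.graph})
        nx.write_graphml(G, str(path))


def build_network(
    traj: Trajectory,
    cmat: CorrelationMatrix,
    contact_cutoff: float = 8.0,
    occupancy_min: float = 0.75,
    corr_min: float = 0.01,
    exclude_bonded: bool = True,
) -> DynamicalNetwork:
    """Build the dynamical network from a superposed trajectory and its DCC.

    Edge (i, j) exists iff the Cα pair is within ``contact_cutoff`` Å in at
    least ``occupancy_min`` of frames and |C_ij| ≥ ``corr_min``; its weight is
    −ln|C_ij|.  ``exclude_bonded`` drops sequence-adjacent pairs within a
    chain, whose trivially high correlation would otherwise dominate paths.
    """
    if traj.residues != cmat.residues:
        raise ValueError("trajectory and correlation matrix residue order differ")
    n = traj.n_atoms
    occ = np.zeros((n * (n - 1)) // 2)
    for f in range(traj.n_frames):
        occ += pdist(traj.coords[f]) <= contact_cutoff
    occ = squareform(occ / traj.n_frames)

    residues = traj.residues
    domains = list(traj.atoms["domain"])
    G = nx.Graph()
    for node, dom in zip(residues, domains):
        G.add_node(node, domain=dom)
    absC = np.abs(cmat.C)
    for i in range(n):
        ci, ri = residues[i]
        for j in range(i + 1, n):
            cj, rj = residues[j]
            if exclude_bonded and ci == cj and abs(ri - rj) == 1:
                continue
            if occ[i, j] < occupancy_min or absC[i, j] < corr_min:
                continue
            w = -math.log(min(absC[i, j], 1.0)) if absC[i, j] < 1.0 else 0.0
            G.add_edge(
                residues[i],
                residues[j],
                weight=w,
                occupancy=float(occ[i, j]),
                corr=float(cmat.C[i, j]),
                affinity=1.0 / max(w, _W_FLOOR),
            )
    if G.number_of_edges() == 0:
        raise DegenerateNetworkError(
            "no edges survive the contact/occupancy/correlation cutoffs"
        )
    return DynamicalNetwork(G, contact_cutoff, occupancy_min, corr_min)


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    """Node→community assignment maximising weighted modularity."""

    membership: dict
    n_communities: int
    modularity: float

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


def detect_communities(
    net: DynamicalNetwork | nx.Graph, max_communities: int | None = None
) -> CommunityPartition:
    """Girvan–Newman divisive clustering, keeping the max-modularity level.

    Edge betweenness uses w as a distance; modularity uses the affinity 1/w
    (w floored at 1e-6).  The trivial one-community partition competes, so a
    structureless graph returns a single community.  Community ids are
    assigned by the lexicographically smallest member, making the labelling
    deterministic.
    """
    G = net.graph if isinstance(net, DynamicalNetwork) else net
    for u, v, d in G.edges(data=True):
        d.setdefault("weight", 1.0)
        d.setdefault("affinity", 1.0 / max(d["weight"], _W_FLOOR))
    if max_communities is None:
        max_communities = min(G.number_of_nodes(), 25)

    def most_valuable_edge(g):
        bw = nx.edge_betweenness_centrality(g, weight="weight")
        return max(sorted(bw), key=lambda e: (bw[e], e))

    base = [set(c) for c in nx.connected_components(G)]
    candidates = [base]
    gn = nx.community.girvan_newman(G, most_valuable_edge=most_valuable_edge)
    for level in gn:
        candidates.append([set(c) for c in level])
        if len(level) >= max_communities:
            break

    def q(part):
        return nx.community.modularity(G, part, weight="affinity")

    best = max(candidates, key=lambda p: (q(p), -len(p)))
    ordered = sorted(best, key=lambda c: min(c))
    membership = {node: cid for cid, comm in enumerate(ordered) for node in comm}
    return CommunityPartition(membership, len(ordered), float(q(best)))


# ---------------------------------------------------------------------------
# Suboptimal paths
# ---------------------------------------------------------------------------

@dataclass
class PathQuery:
    sources: list
    sinks: list
    delta: float | None = None  # None → 0.2 × L_opt
    max_paths: int = 100_000

    def __post_init__(self):
        if set(self.sources) & set(self.sinks):
            raise ValueError("sources and sinks must be disjoint")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be ≥ 0")


@dataclass
class PathEnsemble:
    """All simple source→sink paths with weight ≤ L_opt + delta."""

    paths: list  # [(weight, (node, ...)), ...] sorted by weight
    l_opt: float
    delta: float
    truncated: bool = False

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.paths])

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Path-length histogram with fixed origin at L_opt, 20 equal bins."""
        w = self.weights
        hi = w.max() if len(w) else self.l_opt
        if hi <= self.l_opt:
            hi = self.l_opt + 1e-9
        edges = np.linspace(self.l_opt, hi, bins + 1)
        counts, edges = np.histogram(w, bins=edges)
        return counts, edges

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (rank, w, "-".join(f"{c}{r}" for c, r in nodes))
            for rank, (w, nodes) in enumerate(self.paths, start=1)
        ]
        pd.DataFrame(rows, columns=["rank", "weight", "path"]).to_csv(
            path, sep="\t", index=False
        )


def suboptimal_paths(
    net: DynamicalNetwork | nx.Graph, query: PathQuery
) -> PathEnsemble:
    """Enumerate every simple source→sink path within δ of the optimum.

    L_opt is the minimum shortest-path weight over all source–sink pairs
    (Dijkstra).  Enumeration is depth-first branch and bound: a partial path
    is pruned when its weight plus the exact remaining distance to the
    nearest sink (multi-source Dijkstra lower bound) exceeds L_opt + δ.
    Hitting ``max_paths`` sets the ``truncated`` flag rather than failing
    silently.
    """
    G = net.graph if isinstance(net, DynamicalNetwork) else net
    sources = [s for s in query.sources if s in G]
    sinks = [t for t in query.sinks if t in G]
    if not sources or not sinks:
        raise NoPathError("no source/sink nodes present in the network")
    dist_to_sink = nx.multi_source_dijkstra_path_length(G, sinks, weight="weight")
    reachable = [s for s in sources if s in dist_to_sink]
    if not reachable:
        raise NoPathError("no source is connected to any sink")
    l_opt = min(dist_to_sink[s] for s in reachable)
    delta = 0.2 * l_opt if query.delta is None else query.delta
    bound = l_opt + delta + 1e-9

    sink_set = set(sinks)
    results: list[tuple[float, tuple]] = []
    truncated = False

    def dfs(node, w, path, on_path):
        nonlocal truncated
        if truncated:
            return
        if node in sink_set:
            results.append((w, tuple(path)))
            if len(results) >= query.max_paths:
                truncated = True
                return
        for nbr, d in G.adj[node].items():
            if nbr in on_path:
                continue
            w2 = w + d["weight"]
            if w2 + dist_to_sink.get(nbr, math.inf) > bound:
                continue
            path.append(nbr)
            on_path.add(nbr)
            dfs(nbr, w2, path, on_path)
            on_path.discard(nbr)
            path.pop()
            if truncated:
                return

    for s in sorted(reachable):
        if dist_to_sink[s] > bound:
            continue
        dfs(s, 0.0, [s], {s})
        if truncated:
            break

    results.sort(key=lambda t: (t[0], t[1]))
    return PathEnsemble(results, float(l_opt), float(delta), truncated)


# ---------------------------------------------------------------------------
# Cross-state comparison
# ---------------------------------------------------------------------------

@dataclass
class PathComparison:
    table: pd.DataFrame
    shifts: dict  # (key_a, key_b) → "right" | "left" | "none"
    ranking: list  # keys sorted by path count, descending

    def to_json(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "shifts": {f"{a}|{b}": s for (a, b), s in self.shifts.items()},
            "ranking": [str(k) for k in self.ranking],
        }


def path_statistics(
    ensembles: dict, shift_tol: float = 1e-6
) -> PathComparison:
    """Compare path ensembles across states/variants.

    Reports per ensemble the path count, L_opt and mean/median path weight,
    classifies each ordered pair as right-/left-shifted by the difference of
    median weights (|Δmedian| ≤ ``shift_tol`` → "none"), and ranks ensembles
    by path count.  Right-shifted (longer) distributions indicate delayed
    signal transmission; left-shifted ones faster communication.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least two ensembles to compare")
    rows = []
    medians = {}
    for key, ens in ensembles.items():
        w = ens.weights
        medians[key] = float(np.median(w)) if len(w) else math.nan
        rows.append(
            {
                "key": str(key),
                "n_paths": ens.n_paths,
                "l_opt": ens.l_opt,
                "mean_weight": float(w.mean()) if len(w) else math.nan,
                "median_weight": medians[key],
                "truncated": ens.truncated,
            }
        )
    table = pd.DataFrame(rows)
    shifts = {}
    keys = list(ensembles)
    for a in keys:
        for b in keys:
            if a == b:
                continue
            d = medians[b] - medians[a]
            if math.isnan(d) or abs(d) <= shift_tol:
                shifts[(a, b)] = "none"
            else:
                shifts[(a, b)] = "right" if d > 0 else "left"
    ranking = sorted(keys, key=lambda k: (-ensembles[k].n_paths, str(k)))
    return PathComparison(table, shifts, ranking)
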