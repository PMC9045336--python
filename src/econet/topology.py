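"""Topological indices and module detection.

All distance-based metrics operate on the unweighted, unsigned skeleton of
the network, so edge weights and signs never affect path lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import EcoNetwork, powerlaw_fit

__all__ = [
    "ModulePartition",
    "TopologySummary",
    "detect_modules",
    "large_modules",
    "connectedness",
    "geodesic_efficiency",
    "harmonic_geodesic_distance",
    "stress_centrality",
    "centralization_stress",
    "betweenness",
    "eigenvector_centrality",
    "summarize",
    "key_nodes",
    "node_table",
]


@dataclass
class ModulePartition:
    """node -> module id assignment plus Newman-Girvan modularity Q."""

    assignment: dict
    modularity_q: float

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def sizes(self) -> dict:
        sizes: dict = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module_id) -> list:
        return [n for n, m in self.assignment.items() if m == module_id]


@dataclass
class TopologySummary:
    n_nodes: int
    n_links: int
    avg_degree: float
    connectedness: float
    geodesic_efficiency: float
    harmonic_geodesic_distance: float
    modularity: float
    n_modules: int
    centralization_stress: float
    powerlaw_r2: float
    negative_link_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def detect_modules(net: EcoNetwork, seed: int | None = None) -> ModulePartition:
    """Greedy (CNM-style) modularity maximization on the unsigned skeleton.

    Module ids are assigned by decreasing size with lexicographic
    tie-breaking on the smallest member, so the labelling is deterministic.
    The ``seed`` argument is accepted for interface symmetry; the greedy
    algorithm itself is deterministic.
    """
    g = net.skeleton()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        communities = [frozenset([n]) for n in g.nodes]
    else:
        communities = list(nx.community.greedy_modularity_communities(g))
    communities.sort(key=lambda c: (-len(c), str(min(c, key=str))))
    assignment = {n: i for i, c in enumerate(communities) for n in c}
    q = nx.community.modularity(g, communities) if g.number_of_edges() else 0.0
    return ModulePartition(assignment, float(q))


def large_modules(part: ModulePartition, min_size: int = 5) -> pd.DataFrame:
    """Modules with >= ``min_size`` nodes, size-descending, labelled M1, M2...

    Returns a DataFrame with columns ``label``, ``module_id``, ``size``.
    """
    sizes = part.sizes()
    big = sorted(
        [(m, s) for m, s in sizes.items() if s >= min_size],
        key=lambda t: (-t[1], t[0]),
    )
    return pd.DataFrame(
        [
            {"label": f"M{i + 1}", "module_id": m, "size": s}
            for i, (m, s) in enumerate(big)
        ],
        columns=["label", "module_id", "size"],
    )


def connectedness(net: EcoNetwork) -> float:
    """Krackhardt connectedness: fraction of node pairs joined by a path."""
    g = net.skeleton()
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    reachable = sum(
        len(c) * (len(c) - 1) // 2 for c in nx.connected_components(g)
    )
    return reachable / (n * (n - 1) / 2)


def _distance_matrix(g: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        i = idx[src]
        for dst, dist in lengths.items():
            d[i, idx[dst]] = dist
    return nodes, d


def geodesic_efficiency(net: EcoNetwork) -> float:
    """Mean of 1/d(i, j) over unordered node pairs (0 for disconnected)."""
    g = net.skeleton()
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    _, d = _distance_matrix(g)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d[iu]), 1.0 / d[iu], 0.0)
    return float(inv.mean())


def harmonic_geodesic_distance(net: EcoNetwork) -> float:
    """Reciprocal of geodesic efficiency (inf for an edgeless network)."""
    eff = geodesic_efficiency(net)
    return float("inf") if eff == 0 else 1.0 / eff


def _shortest_path_counts(g: nx.Graph) -> tuple[list, np.ndarray, np.ndarray]:
    """BFS per source: distances and numbers of shortest paths."""
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = {u: list(g.neighbors(u)) for u in nodes}
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1.0
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    vi = idx[v]
                    if np.isinf(dist[si, vi]):
                        dist[si, vi] = depth
                        nxt.append(v)
                    if dist[si, vi] == depth:
                        sigma[si, vi] += sigma[si, idx[u]]
            frontier = nxt
    return nodes, dist, sigma


def stress_centrality(net: EcoNetwork) -> pd.Series:
    """Raw shortest-path counts through each node.

    stress(v) = number of shortest paths between pairs (s, t), s != t != v,
    that pass through v as an intermediate.
    """
    g = net.skeleton()
    nodes, dist, sigma = _shortest_path_counts(g)
    n = len(nodes)
    stress = np.zeros(n)
    for vi in range(n):
        through = dist[:, vi][:, None] + dist[vi, :][None, :]
        on_path = np.isfinite(dist) & (through == dist)
        counts = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        counts = np.where(on_path, counts, 0.0)
        counts[vi, :] = 0.0
        counts[:, vi] = 0.0
        np.fill_diagonal(counts, 0.0)
        stress[vi] = counts.sum() / 2.0  # unordered pairs
    return pd.Series(stress, index=nodes)


def centralization_stress(net: EcoNetwork) -> float:
    """Sum of (max stress - stress(v)) normalized by (n - 1) * max stress.

    0 when every node has the same stress centrality (including max = 0).
    """
    s = stress_centrality(net)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 nodes")
    mx = float(s.max())
    if mx == 0:
        return 0.0
    return float((mx - s).sum() / ((n - 1) * mx))


def betweenness(net: EcoNetwork) -> pd.Series:
    """Normalized shortest-path betweenness centrality."""
    g = net.skeleton()
    return pd.Series(nx.betweenness_centrality(g, normalized=True))


def eigenvector_centrality(net: EcoNetwork) -> pd.Series:
    """Principal-eigenvector centrality on the largest component.

    Nodes outside the largest component get 0; the vector is nonnegative
    with unit Euclidean norm.
    """
    g = net.skeleton()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    if sub.number_of_edges() == 0:
        vals = {n: 1.0 for n in comp}
    else:
        order = list(sub.nodes)
        adj = nx.to_numpy_array(sub, nodelist=order)
        w, v = np.linalg.eigh(adj)
        principal = np.abs(v[:, np.argmax(w)])
        vals = dict(zip(order, principal))
    out = pd.Series(0.0, index=list(g.nodes))
    for n, v in vals.items():
        out[n] = abs(v)
    norm = np.linalg.norm(out.to_numpy())
    return out / norm if norm > 0 else out


def summarize(net: EcoNetwork, part: ModulePartition | None = None) -> TopologySummary:
    """All topological indices in one record (shape of a per-network row)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if part is None:
        part = detect_modules(net)
    degrees = [d for _, d in net.skeleton().degree()]
    try:
        pr2 = powerlaw_fit(degrees)["r_squared"]
    except ValueError:
        pr2 = float("nan")
    return TopologySummary(
        n_nodes=net.n_nodes,
        n_links=net.n_links,
        avg_degree=2.0 * net.n_links / net.n_nodes,
        connectedness=connectedness(net),
        geodesic_efficiency=geodesic_efficiency(net),
        harmonic_geodesic_distance=harmonic_geodesic_distance(net),
        modularity=part.modularity_q,
        n_modules=part.n_modules,
        centralization_stress=centralization_stress(net) if net.n_nodes >= 3 else 0.0,
        powerlaw_r2=pr2,
        negative_link_fraction=(net.n_negative / net.n_links) if net.n_links else 0.0,
    )


def key_nodes(net: EcoNetwork) -> dict:
    """Argmax node per centrality metric (degree, betweenness, stress,
    eigenvector) -- the "key network node" report."""
    g = net.skeleton()
    deg = pd.Series(dict(g.degree()))
    return {
        "degree": deg.idxmax(),
        "betweenness": betweenness(net).idxmax(),
        "stress": stress_centrality(net).idxmax(),
        "eigenvector": eigenvector_centrality(net).idxmax(),
    }


def node_table(net: EcoNetwork, part: ModulePartition, min_large: int = 5) -> pd.DataFrame:
    """Per-node attribute table: degree, centralities, module membership."""
    g = net.skeleton()
    deg = pd.Series(dict(g.degree()))
    btw = betweenness(net)
    strs = stress_centrality(net)
    eig = eigenvector_centrality(net)
    sizes = part.sizes()
    rows = []
    for n in net.nodes:
        m = part.assignment[n]
        rows.append(
            {
                "otu_id": n,
                "degree": int(deg[n]),
                "betweenness": float(btw[n]),
                "stress": float(strs[n]),
                "eigenvector": float(eig[n]),
                "module": m,
                "is_large_module": sizes[m] >= min_large,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")
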