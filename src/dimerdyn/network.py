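"""Dynamical cross-correlation networks, communication paths, communities.

The DCCM entry for residues i, j is the normalized covariance of their Cα
displacement vectors, c_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)
(isotropic vector-dot convention).  A weighted graph keeps an edge where
|c_ij| exceeds a threshold (0.4 by default, strict), with path weight
w_ij = −ln|c_ij| so that strongly coupled residues are close; the signed
correlation is retained as an edge attribute.  Suboptimal paths are the k
shortest simple paths (Yen's algorithm) and communities come from a
random-walk agglomeration (walktrap) or Girvan–Newman betweenness
partitioning on the |c| > 0.5 graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from dimerdyn.core_io import SelectionMask, Trajectory
from dimerdyn.geometry import iterative_mean_structure

__all__ = [
    "CorrelationMatrix",
    "CorrelationNetwork",
    "PathSet",
    "CommunityPartition",
    "dccm",
    "build_network",
    "suboptimal_paths",
    "node_path_frequency",
    "detect_communities",
    "compare_networks",
]


@dataclass
class CorrelationMatrix:
    """Residue–residue cross-correlation matrix with node labels."""

    values: np.ndarray
    node_labels: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("correlation diagonal must be exactly 1")
        if np.any(np.abs(v) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        # snap tiny numerical excursions
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        if len(self.node_labels) != v.shape[0]:
            raise ValueError("one node label per residue required")


@dataclass
class CorrelationNetwork:
    """Thresholded weighted graph over residues."""

    graph: nx.Graph
    edge_threshold: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class PathSet:
    """k shortest simple paths between a source and a sink residue."""

    source: object
    sink: object
    paths: list[list]
    lengths: list[float]
    k_requested: int
    status: str = "ok"   # or "disconnected"

    def __post_init__(self):
        if any(l2 < l1 - 1e-12 for l1, l2 in zip(self.lengths, self.lengths[1:])):
            raise ValueError("path lengths must be non-decreasing")
        for p in self.paths:
            if len(set(p)) != len(p):
                raise ValueError("paths must be simple")


@dataclass
class CommunityPartition:
    """Node → community id, with the (weighted) modularity of the split."""

    assignment: dict
    modularity: float
    method: str
    community_threshold: float

    def communities(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return out

    def together(self, a, b) -> bool:
        return self.assignment[a] == self.assignment[b]


def dccm(
    traj: Trajectory,
    ca_mask: SelectionMask | None = None,
    superpose: bool = True,
    node_labels: list | None = None,
) -> CorrelationMatrix:
    """Cross-correlation matrix of Cα displacements over a trajectory.

    Frames are optionally superposed onto their iterated mean structure
    before deviations are taken.  A residue with zero positional variance
    gets zero off-diagonal correlation (with a warning) rather than NaN.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least two frames")
    sub = ca_mask.apply(traj.coords) if ca_mask is not None else traj.coords
    if superpose:
        fitted, mean = iterative_mean_structure(sub)
    else:
        fitted, mean = sub, sub.mean(axis=0)
    dev = fitted - fitted.mean(axis=0)
    cov = np.einsum("fid,fjd->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 1e-15
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} residue(s) with zero variance; correlations zeroed",
            stacklevel=2,
        )
        var[zero] = 1.0
    c = cov / np.sqrt(var[:, None] * var[None, :])
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    if node_labels is None:
        node_labels = list(range(c.shape[0]))
    return CorrelationMatrix(values=c, node_labels=node_labels)


def build_network(c: CorrelationMatrix, edge_threshold: float = 0.4) -> CorrelationNetwork:
    """Graph with an edge wherever |c_ij| strictly exceeds the threshold.

    Edge attributes: ``correlation`` (signed), ``weight`` = −ln|c_ij|
    (non-negative path length).  Isolated nodes are retained.
    """
    g = nx.Graph()
    g.add_nodes_from(c.node_labels)
    n = c.values.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            cij = c.values[i, j]
            if abs(cij) > edge_threshold:
                g.add_edge(
                    c.node_labels[i], c.node_labels[j],
                    correlation=float(cij),
                    weight=float(-np.log(abs(cij))),
                )
    return CorrelationNetwork(graph=g, edge_threshold=edge_threshold)


def suboptimal_paths(net: CorrelationNetwork, source, sink, k: int = 50) -> PathSet:
    """The k lowest-total-weight simple paths between source and sink.

    Yen's algorithm via networkx; ties in total length are broken
    lexicographically by node sequence.  Fewer than k paths are returned
    when the graph admits fewer; a disconnected pair yields an empty set
    with status "disconnected".
    """
    g = net.graph
    if source not in g or sink not in g:
        raise KeyError("source/sink not in network")
    if source == sink:
        return PathSet(source, sink, [[source]], [0.0], k)

    def plen(p):
        return float(sum(g[u][v]["weight"] for u, v in zip(p, p[1:])))

    try:
        gen = nx.shortest_simple_paths(g, source, sink, weight="weight")
        raw: list[tuple[float, list]] = []
        kth_len = None
        for p in gen:
            length = plen(p)
            if len(raw) < k:
                raw.append((length, p))
                kth_len = max(l for l, _ in raw)
            elif length <= kth_len + 1e-12:
                raw.append((length, p))  # collect ties of the kth length
            else:
                break
    except nx.NetworkXNoPath:
        return PathSet(source, sink, [], [], k, status="disconnected")
    raw.sort(key=lambda t: (t[0], t[1]))
    raw = raw[:k]
    return PathSet(source, sink, [p for _, p in raw], [l for l, _ in raw], k)


def node_path_frequency(paths: PathSet) -> dict:
    """Number of paths in which each residue occurs (endpoints counted)."""
    if not paths.paths:
        raise ValueError("empty path set")
    counts: dict = {}
    for p in paths.paths:
        for node in p:
            counts[node] = counts.get(node, 0) + 1
    return counts


def _walktrap(g: nx.Graph) -> list[set]:
    """Random-walk agglomerative communities via igraph's walktrap."""
    import igraph

    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [abs(g[u][v].get("correlation", 1.0)) for u, v in g.edges]
    ig = igraph.Graph(n=len(nodes), edges=edges)
    if edges:
        dendro = ig.community_walktrap(weights=weights, steps=4)
        clustering = dendro.as_clustering()
        membership = clustering.membership
    else:
        membership = list(range(len(nodes)))
    out: dict[int, set] = {}
    for n, cid in zip(nodes, membership):
        out.setdefault(cid, set()).add(n)
    return list(out.values())


def _girvan_newman(g: nx.Graph) -> list[set]:
    """Best-modularity cut of the Girvan–Newman betweenness dendrogram."""
    if g.number_of_edges() == 0:
        return [{n} for n in g.nodes]
    best, best_q = None, -np.inf
    components = [set(c) for c in nx.connected_components(g)]
    candidates = [components]
    for partition in nx.algorithms.community.girvan_newman(g):
        candidates.append([set(c) for c in partition])
        if len(candidates) > 60:   # dendrogram depth guard for large graphs
            break
    for part in candidates:
        q = nx.algorithms.community.modularity(g, part, weight=None)
        if q > best_q:
            best, best_q = part, q
    return best


def detect_communities(
    c: CorrelationMatrix,
    community_threshold: float = 0.5,
    method: str = "walktrap",
) -> CommunityPartition:
    """Community partition of the |c| > threshold correlation network.

    The network is rebuilt at ``community_threshold`` (0.5 by default,
    tighter than the 0.4 path network).  ``method`` is ``walktrap``
    (random-walk agglomeration, the default) or ``girvan_newman``.
    An empty edge set yields singleton communities with modularity 0.
    """
    net = build_network(c, edge_threshold=community_threshold)
    g = net.graph
    if method == "walktrap":
        parts = _walktrap(g)
    elif method == "girvan_newman":
        parts = _girvan_newman(g)
    else:
        raise ValueError(f"unknown community method {method!r}")
    # deterministic community ids: order by smallest member
    parts = sorted(parts, key=lambda s: sorted(map(str, s)))
    assignment = {}
    for cid, members in enumerate(parts):
        for n in members:
            assignment[n] = cid
    if g.number_of_edges() == 0:
        q = 0.0
    else:
        q = float(nx.algorithms.community.modularity(g, parts, weight=None))
    return CommunityPartition(
        assignment=assignment, modularity=q,
        method=method, community_threshold=community_threshold,
    )


@dataclass
class NetworkComparison:
    """Differences between apo and holo correlation networks."""

    gained_edges: list
    lost_edges: list
    delta_correlation: dict
    pairs_split: list      # together in apo, apart in holo
    pairs_joined: list     # apart in apo, together in holo

    @property
    def is_empty(self) -> bool:
        return not (self.gained_edges or self.lost_edges
                    or self.pairs_split or self.pairs_joined)


def compare_networks(
    apo_net: CorrelationNetwork,
    holo_net: CorrelationNetwork,
    apo_comm: CommunityPartition | None = None,
    holo_comm: CommunityPartition | None = None,
    apo_c: CorrelationMatrix | None = None,
    holo_c: CorrelationMatrix | None = None,
) -> NetworkComparison:
    """Edge gains/losses, per-pair Δc and community co-membership changes."""
    if set(apo_net.graph.nodes) != set(holo_net.graph.nodes):
        raise ValueError("apo and holo networks must share their node set")
    apo_edges = {tuple(sorted(e, key=str)) for e in apo_net.graph.edges}
    holo_edges = {tuple(sorted(e, key=str)) for e in holo_net.graph.edges}
    gained = sorted(holo_edges - apo_edges, key=str)
    lost = sorted(apo_edges - holo_edges, key=str)
    delta_c = {}
    if apo_c is not None and holo_c is not None:
        if apo_c.node_labels != holo_c.node_labels:
            raise ValueError("correlation matrices must share node labels")
        d = holo_c.values - apo_c.values
        labels = apo_c.node_labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if d[i, j] != 0.0:
                    delta_c[(labels[i], labels[j])] = float(d[i, j])
    split, joined = [], []
    if apo_comm is not None and holo_comm is not None:
        nodes = sorted(apo_comm.assignment, key=str)
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                u, v = nodes[a], nodes[b]
                t_apo = apo_comm.together(u, v)
                t_holo = holo_comm.together(u, v)
                if t_apo and not t_holo:
                    split.append((u, v))
                elif t_holo and not t_apo:
                    joined.append((u, v))
    return NetworkComparison(
        gained_edges=gained, lost_edges=lost, delta_correlation=delta_c,
        pairs_split=split, pairs_joined=joined,
    )
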