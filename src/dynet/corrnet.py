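"""Fluctuation-correlation matrices and contact-gated correlation networks.

The normalized cross-correlation between nodes i and j is

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2> <dr_j^2>),   dr_i(t) = r_i(t) - <r_i>

with r_i(t) the representative position of node i (Calpha for amino
acids, heavy-atom center for ligands) and <.> the time average over the
analysis window.  An edge joins two nodes without a covalent bond whose
heavy atoms come within a distance cutoff (default 4.5 A) in at least a
threshold fraction of frames (default 75 %).  Edge strength is |C_ij|;
for shortest-path searches each edge carries the length -log|C_ij|, so
strongly correlated contacts are short and weakly correlated ones long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .structure import NodeMap, Trajectory

DEFAULT_CONTACT_CUTOFF = 4.5   # Angstrom, heavy-atom contact distance
DEFAULT_OCC_THRESHOLD = 0.75   # fraction of frames a contact must persist
DEGREE_REPORT_CUTOFF = 10      # "hub" degree threshold reported in summaries


@dataclass
class CorrelationMatrix:
    """Normalized N x N fluctuation-correlation matrix of one replicate."""

    values: np.ndarray
    n_frames: int
    replicate_id: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.values = v


@dataclass
class OccupancyMatrix:
    """Fraction of frames each node pair spends in heavy-atom contact."""

    values: np.ndarray
    cutoff: float
    n_frames: int
    replicate_id: int = 0


@dataclass
class CorrelationNetwork:
    """A contact-gated, correlation-weighted network over the node set.

    Wraps a :class:`networkx.Graph` whose nodes are node ids and whose
    edges carry ``weight`` (|C_ij|), ``length`` (-log|C_ij|) and
    ``occupancy`` attributes.
    """

    graph: nx.Graph
    node_map: NodeMap
    replicate_id: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def resolve(self, key) -> int:
        return self.node_map.resolve(key)

    def label(self, node_id: int) -> str:
        return self.node_map.nodes[node_id].label

    def copy(self) -> "CorrelationNetwork":
        return CorrelationNetwork(self.graph.copy(), self.node_map, self.replicate_id)

    def edge_table(self) -> pd.DataFrame:
        """TSV-ready edge list (node labels, weight, length, occupancy)."""
        rows = [
            {
                "node_i": self.label(u),
                "node_j": self.label(v),
                "weight": d["weight"],
                "length": d["length"],
                "occupancy": d.get("occupancy", np.nan),
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "length", "occupancy"])

    def write_graphml(self, path) -> None:
        g = nx.relabel_nodes(self.graph, {i: self.label(i) for i in self.graph}, copy=True)
        nx.write_graphml(g, path)


@dataclass
class NetworkSummary:
    """Headline topology parameters of one correlation network."""

    n_nodes: int
    n_edges: int
    max_degree: int
    avg_degree: float
    n_degree_above: int
    max_edge_betweenness: float
    max_node_betweenness: float
    degree_cutoff: int = DEGREE_REPORT_CUTOFF

    def as_dict(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "max_degree": self.max_degree,
            "avg_degree": self.avg_degree,
            f"nodes_degree_gt_{self.degree_cutoff}": self.n_degree_above,
            "max_edge_betweenness": self.max_edge_betweenness,
            "max_node_betweenness": self.max_node_betweenness,
        }


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlation_matrix(traj: Trajectory) -> CorrelationMatrix:
    """Pairwise fluctuation correlations of the representative positions.

    The three Cartesian components enter through the dot product, i.e.
    the correlation pools x, y and z displacements.  Zero-variance nodes
    get zero off-diagonal correlation (with a warning) instead of NaN.
    """
    if traj.n_frames < 2:
        raise ValueError("correlation needs at least 2 frames")
    pos = traj.rep_positions()
    delta = pos - pos.mean(axis=0)
    cov = np.tensordot(delta, delta, axes=([0, 2], [0, 2])) / traj.n_frames
    var = np.diag(cov).copy()
    silent = var <= 0.0
    if silent.any():
        warnings.warn(
            f"{int(silent.sum())} node(s) have zero fluctuation variance; "
            "their correlations are set to 0",
            stacklevel=2,
        )
        var[silent] = 1.0
    C = cov / np.sqrt(np.outer(var, var))
    C[silent, :] = 0.0
    C[:, silent] = 0.0
    np.fill_diagonal(C, 1.0)
    np.clip(C, -1.0, 1.0, out=C)
    return CorrelationMatrix(C, n_frames=traj.n_frames, replicate_id=traj.replicate_id)


# ---------------------------------------------------------------------------
# contact occupancy
# ---------------------------------------------------------------------------

def contact_occupancy(
    traj: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    *,
    chunk: int = 2000,
) -> OccupancyMatrix:
    """Fraction of frames in which the closest heavy-atom pair of nodes
    (i, j) is below ``cutoff``.

    Pairs whose bounding spheres (node centroid + maximal atom radius)
    never approach the cutoff are skipped, which keeps the exact
    all-atom-pair scan tractable.
    """
    nm = traj.node_map
    n = nm.n_nodes
    F = traj.n_frames
    heavy = [node.heavy_atoms for node in nm.nodes]

    centroids = np.stack(
        [traj.coords[:, h].mean(axis=1) for h in heavy], axis=1
    )  # (F, n, 3)
    radii = np.array(
        [
            np.linalg.norm(traj.coords[:, h] - centroids[:, i, None, :], axis=-1).max()
            for i, h in enumerate(heavy)
        ]
    )
    occ = np.zeros((n, n))
    # minimal centroid distance over frames, for the bounding-sphere filter
    min_cdist = np.full((n, n), np.inf)
    for f0 in range(0, F, chunk):
        c = centroids[f0: f0 + chunk]
        d = np.linalg.norm(c[:, :, None, :] - c[:, None, :, :], axis=-1).min(axis=0)
        np.minimum(min_cdist, d, out=min_cdist)

    for i in range(n):
        for j in range(i + 1, n):
            if min_cdist[i, j] - radii[i] - radii[j] >= cutoff:
                continue
            ai, aj = heavy[i], heavy[j]
            hits = 0
            for f0 in range(0, F, chunk):
                block_i = traj.coords[f0: f0 + chunk, ai]
                block_j = traj.coords[f0: f0 + chunk, aj]
                d = np.linalg.norm(
                    block_i[:, :, None, :] - block_j[:, None, :, :], axis=-1
                )
                hits += int((d.reshape(d.shape[0], -1).min(axis=1) < cutoff).sum())
            occ[i, j] = occ[j, i] = hits / F
    return OccupancyMatrix(occ, cutoff=cutoff, n_frames=F, replicate_id=traj.replicate_id)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def build_network(
    corr: CorrelationMatrix,
    occ: OccupancyMatrix,
    node_map: NodeMap,
    *,
    occ_threshold: float = DEFAULT_OCC_THRESHOLD,
    exclusions: "set[tuple[int, int]] | None" = None,
) -> CorrelationNetwork:
    """Gate node pairs by contact occupancy and weight them by |C_ij|.

    ``exclusions`` defaults to the covalently bonded node pairs
    (peptide-bonded chain neighbours); occupancy is compared inclusively
    (>= threshold).  Edges with |C_ij| = 0 have no defined length and
    are dropped with a warning.
    """
    C = corr.values
    O = occ.values
    n = node_map.n_nodes
    if C.shape != (n, n) or O.shape != (n, n):
        raise ValueError("matrix shapes do not match the node set")
    if exclusions is None:
        exclusions = node_map.covalent_pairs()
    g = nx.Graph()
    for node in node_map.nodes:
        g.add_node(node.node_id, label=node.label, role=node.role)
    dropped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if O[i, j] < occ_threshold or (i, j) in exclusions:
                continue
            w = abs(float(C[i, j]))
            if w == 0.0:
                dropped += 1
                continue
            g.add_edge(i, j, weight=w, length=float(-np.log(w)), occupancy=float(O[i, j]))
    if dropped:
        warnings.warn(
            f"dropped {dropped} zero-correlation contact(s): length undefined",
            stacklevel=2,
        )
    return CorrelationNetwork(g, node_map, replicate_id=corr.replicate_id)


def consensus_network(nets: "list[CorrelationNetwork]") -> CorrelationNetwork:
    """Majority-vote consensus over replicate networks.

    An edge survives when present in more than half of the replicates;
    its weight (and occupancy) is the mean over the replicates that have
    it, and its length is recomputed from the mean weight.
    """
    if not nets:
        raise ValueError("need at least one replicate network")
    node_map = nets[0].node_map
    count: dict[tuple[int, int], int] = {}
    wsum: dict[tuple[int, int], float] = {}
    osum: dict[tuple[int, int], float] = {}
    for net in nets:
        if net.node_map.n_nodes != node_map.n_nodes:
            raise ValueError("replicate networks disagree on the node set")
        for u, v, d in net.graph.edges(data=True):
            key = (u, v) if u < v else (v, u)
            count[key] = count.get(key, 0) + 1
            wsum[key] = wsum.get(key, 0.0) + d["weight"]
            osum[key] = osum.get(key, 0.0) + d.get("occupancy", np.nan)
    g = nx.Graph()
    for node in node_map.nodes:
        g.add_node(node.node_id, label=node.label, role=node.role)
    need = len(nets) // 2 + 1
    for key, c in count.items():
        if c < need:
            continue
        w = wsum[key] / c
        g.add_edge(
            *key,
            weight=w,
            length=float(-np.log(w)),
            occupancy=osum[key] / c,
            support=c / len(nets),
        )
    return CorrelationNetwork(g, node_map, replicate_id=-1)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def weighted_degrees(net: CorrelationNetwork) -> pd.DataFrame:
    """Per-node degree and correlation-weighted degree (sum of incident
    edge strengths)."""
    g = net.graph
    rows = [
        {
            "node": net.label(i),
            "degree": g.degree(i),
            "weighted_degree": sum(d["weight"] for _, _, d in g.edges(i, data=True)),
        }
        for i in g.nodes
    ]
    return pd.DataFrame(rows, columns=["node", "degree", "weighted_degree"])


def network_summary(
    net: CorrelationNetwork,
    *,
    degree_cutoff: int = DEGREE_REPORT_CUTOFF,
    weighted_betweenness: bool = True,
) -> NetworkSummary:
    """Node/edge counts, degree statistics, and the maxima of normalized
    node and edge betweenness (shortest paths on edge lengths)."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if e == 0:
        warnings.warn("network has no edges; summary is all zeros", stacklevel=2)
        return NetworkSummary(n, 0, 0, 0.0, 0, 0.0, 0.0, degree_cutoff)
    degrees = np.array([d for _, d in g.degree()])
    weight = "length" if weighted_betweenness else None
    node_bc = nx.betweenness_centrality(g, weight=weight, normalized=True)
    edge_bc = nx.edge_betweenness_centrality(g, weight=weight, normalized=True)
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        max_degree=int(degrees.max()),
        avg_degree=float(2.0 * e / n),
        n_degree_above=int((degrees > degree_cutoff).sum()),
        max_edge_betweenness=float(max(edge_bc.values())),
        max_node_betweenness=float(max(node_bc.values())),
        degree_cutoff=degree_cutoff,
    )
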