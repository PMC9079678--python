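"""Community structure, regulation pathways, and information-transfer
efficiency on correlation networks.

Communities come from the Girvan-Newman procedure: repeatedly remove
the edge with the highest betweenness (computed on the -log|C| edge
lengths) and keep the partition along the removal sequence that
maximizes Newman modularity (on the |C| edge weights).  Regulation
pathways are Dijkstra shortest paths from a source node (a ligand) to
the nearest member of a sink region (the effector / nanobody face);
their summed edge length is the shortest-path length (SPL).  Replicate
networks give an SPL mean +- sd and a consensus pathway.  Deleting all
edges incident to a ligand ("weakening") simulates loss of ligand
coupling, and the efficiency of information transfer compares summed
pathway SPLs between systems:

    efficiency(system) = 100 * sum(SPL_reference) / sum(SPL_system)  [%]

so the reference scores 100 % and systems with longer pathways score
proportionally less.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .corrnet import CorrelationNetwork


@dataclass
class CommunityPartition:
    """Girvan-Newman partition of a correlation network."""

    membership: dict[int, int]            # node id -> community id
    communities: list[set[int]]           # indexed by community id
    modularity: float
    n_isolated: int
    meta_network: nx.Graph                # communities as super-nodes

    @property
    def n_communities(self) -> int:
        return len(self.communities)


@dataclass
class RegulationPath:
    """One source -> sink shortest path."""

    nodes: list[int]
    labels: list[str]
    total_length: float
    reachable: bool = True

    @property
    def n_intermediate(self) -> int:
        """Nodes strictly between source and sink."""
        if not self.reachable:
            raise ValueError("path is unreachable; no intermediate count")
        return max(len(self.nodes) - 2, 0)


@dataclass
class SPLSummary:
    """Replicate statistics of the source -> sink shortest-path length."""

    lengths: list[float]                  # one per replicate (inf if unreachable)
    mean: float
    sd: float
    consensus_path: "RegulationPath | None" = None

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.mean)


@dataclass
class EfficiencyReport:
    """Transfer-efficiency percentages of systems against a reference."""

    reference: str
    spl_sums: dict[str, float]            # system label -> sum of pathway SPLs
    efficiency_pct: dict[str, float]      # system label -> 100 * ref / system


# ---------------------------------------------------------------------------
# Girvan-Newman communities
# ---------------------------------------------------------------------------

def _most_valuable_edge(g: nx.Graph) -> tuple[int, int]:
    """Highest-betweenness edge; ties broken by the smallest sorted node
    pair so repeated runs are reproducible."""
    bc = nx.edge_betweenness_centrality(g, weight="length")
    items = sorted(
        ((tuple(sorted(e)), b) for e, b in bc.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return items[0][0]


def girvan_newman(net: CorrelationNetwork) -> CommunityPartition:
    """Split the network by iterative max-betweenness edge removal and
    return the modularity-optimal partition along the dendrogram.

    Connected components are never merged; on a graph with no edges the
    partition is all singletons with modularity 0.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    base = [set(c) for c in nx.connected_components(g)]
    if g.number_of_edges() == 0:
        return _finish_partition(net, base, 0.0)
    best = base
    best_q = nx.community.modularity(g, base, weight="weight")
    for level in nx.community.girvan_newman(g, most_valuable_edge=_most_valuable_edge):
        part = [set(c) for c in level]
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q + 1e-12:
            best, best_q = part, q
    return _finish_partition(net, best, best_q)


def _finish_partition(
    net: CorrelationNetwork, communities: list[set[int]], modularity: float
) -> CommunityPartition:
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    membership = {node: cid for cid, comm in enumerate(communities) for node in comm}
    meta = nx.Graph()
    meta.add_nodes_from(range(len(communities)))
    for u, v, d in net.graph.edges(data=True):
        cu, cv = membership[u], membership[v]
        if cu == cv:
            continue
        w = meta[cu][cv]["weight"] + d["weight"] if meta.has_edge(cu, cv) else d["weight"]
        meta.add_edge(cu, cv, weight=w)
    part = CommunityPartition(
        membership=membership,
        communities=communities,
        modularity=modularity,
        n_isolated=0,
        meta_network=meta,
    )
    part.n_isolated = count_isolated(part, net)
    return part


def count_isolated(partition: CommunityPartition, net: CorrelationNetwork) -> int:
    """Connected components with no edge to the component holding the
    largest community -- clusters cut off from the main information flow."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    if len(comps) <= 1:
        return 0
    largest = max(
        partition.communities, key=lambda c: (len(c), -min(c))
    )
    anchor = next(iter(largest))
    main = next(c for c in comps if anchor in c)
    return sum(1 for c in comps if c is not main)


# ---------------------------------------------------------------------------
# shortest paths
# ---------------------------------------------------------------------------

def _resolve_many(net: CorrelationNetwork, keys) -> list[int]:
    if isinstance(keys, (int, str)):
        keys = [keys]
    return [net.resolve(k) for k in keys]


def shortest_path(
    net: CorrelationNetwork,
    source,
    sink_set,
    *,
    tol: float = 1e-9,
) -> RegulationPath:
    """Dijkstra shortest path (on edge lengths) from ``source`` to the
    nearest member of ``sink_set``.

    Exact ties are broken deterministically: among all minimum-length
    paths the lexicographically smallest node-id sequence is returned
    (the tie tolerance absorbs float round-off).  An unreachable sink
    yields ``reachable=False`` rather than an exception.
    """
    src = net.resolve(source)
    sinks = _resolve_many(net, sink_set)
    if not sinks:
        raise ValueError("sink set is empty")
    g = net.graph
    dist_s = nx.single_source_dijkstra_path_length(g, src, weight="length")
    reachable = [t for t in sinks if t in dist_s]
    if not reachable:
        return RegulationPath([], [], math.inf, reachable=False)
    best = min(dist_s[t] for t in reachable)
    target = min(t for t in reachable if dist_s[t] <= best + tol)
    dist_t = nx.single_source_dijkstra_path_length(g, target, weight="length")
    total = dist_s[target]
    eps = tol * (1.0 + abs(total))
    # greedy walk over the shortest-path DAG, smallest node id first
    path = [src]
    node = src
    while node != target:
        nxt = None
        for nbr in sorted(g.neighbors(node)):
            edge_len = g[node][nbr]["length"]
            if nbr not in dist_t:
                continue
            if abs(dist_s[node] + edge_len + dist_t[nbr] - total) <= eps:
                nxt = nbr
                break
        if nxt is None:  # pragma: no cover - defensive; DAG walk cannot dead-end
            raise RuntimeError("shortest-path reconstruction failed")
        path.append(nxt)
        node = nxt
    return RegulationPath(
        nodes=path,
        labels=[net.label(i) for i in path],
        total_length=float(total),
        reachable=True,
    )


def average_spl(
    nets: Sequence[CorrelationNetwork],
    source,
    sink_set,
    *,
    consensus: "CorrelationNetwork | None" = None,
) -> SPLSummary:
    """Per-replicate SPLs with mean +- sd and the consensus-network path.

    The mean and sd are over the replicates in which the sink is
    reachable (sd uses n-1 weighting, 0 for a single replicate); if no
    replicate reaches the sink the summary is unreachable.
    """
    if not nets:
        raise ValueError("need at least one replicate network")
    lengths = [shortest_path(net, source, sink_set).total_length for net in nets]
    finite = [x for x in lengths if math.isfinite(x)]
    if finite:
        mean = float(np.mean(finite))
        sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    else:
        mean, sd = math.inf, 0.0
    cpath = None
    if consensus is not None:
        cpath = shortest_path(consensus, source, sink_set)
    return SPLSummary(lengths=lengths, mean=mean, sd=sd, consensus_path=cpath)


def count_path_nodes(path: "RegulationPath | Sequence[str]") -> int:
    """Number of nodes strictly between source and sink."""
    if isinstance(path, RegulationPath):
        return path.n_intermediate
    return max(len(list(path)) - 2, 0)


def parse_pathway(text: str) -> list[str]:
    """Split a printed pathway string like ``"IXO-V111-F396-L114-Y440-Nb9"``
    into its node labels (labels themselves must not contain hyphens)."""
    labels = [t for t in text.strip().split("-") if t]
    if len(labels) < 2:
        raise ValueError(f"not a pathway string: {text!r}")
    return labels


# ---------------------------------------------------------------------------
# perturbation and efficiency
# ---------------------------------------------------------------------------

def weaken_ligand(net: CorrelationNetwork, ligand_nodes) -> CorrelationNetwork:
    """Delete every edge incident to the given ligand node(s), keeping
    the node set unchanged (the in-silico loss of ligand coupling)."""
    out = net.copy()
    for nid in _resolve_many(net, ligand_nodes):
        out.graph.remove_edges_from(list(out.graph.edges(nid)))
    return out


def transfer_efficiency(
    reference_spls: Iterable[float],
    system_spls: Iterable[float],
) -> float:
    """Efficiency of information transfer of a system against a
    reference, in percent: ``100 * sum(reference) / sum(system)``."""
    ref = [float(x) for x in reference_spls]
    sys_ = [float(x) for x in system_spls]
    if not ref or not sys_:
        raise ValueError("SPL lists must be non-empty")
    if not all(math.isfinite(x) for x in ref + sys_):
        raise ValueError("SPLs must be finite")
    denom = sum(sys_)
    if denom == 0:
        raise ValueError("system SPL sum is zero")
    return 100.0 * sum(ref) / denom


def efficiency_report(
    reference: str, system_spls: "dict[str, Sequence[float]]"
) -> EfficiencyReport:
    """Score every system's transfer efficiency against the reference."""
    if reference not in system_spls:
        raise KeyError(f"reference {reference!r} not among the systems")
    sums = {label: float(sum(spls)) for label, spls in system_spls.items()}
    ref_spls = list(system_spls[reference])
    eff = {
        label: transfer_efficiency(ref_spls, spls)
        for label, spls in system_spls.items()
    }
    return EfficiencyReport(reference=reference, spl_sums=sums, efficiency_pct=eff)
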