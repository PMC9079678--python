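"""Shared test helpers: bead systems, random graphs, and independent
brute-force oracles (kept free of the code paths they check)."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from dynet.structure import Node, NodeMap, Trajectory


def bead_node_map(
    n_nodes: int,
    *,
    resnames: "list[str] | None" = None,
    atom_names: "list[list[str]] | None" = None,
    elements: "list[list[str]] | None" = None,
    roles: "list[str] | None" = None,
    chain: str = "A",
) -> NodeMap:
    """A minimal node map: by default one CA bead per node."""
    resnames = resnames or ["GLY"] * n_nodes
    atom_names = atom_names or [["CA"] for _ in range(n_nodes)]
    elements = elements or [
        [n[0] if not n[0].isdigit() else "H" for n in names] for names in atom_names
    ]
    from dynet.structure import PROTEIN_RESNAMES

    roles = roles or [
        "amino-acid" if rn in PROTEIN_RESNAMES else "ligand" for rn in resnames
    ]
    nodes = []
    flat_names: list[str] = []
    flat_elems: list[str] = []
    flat_node_ids: list[int] = []
    cursor = 0
    for i in range(n_nodes):
        names = atom_names[i]
        elems = elements[i]
        idx = np.arange(cursor, cursor + len(names))
        heavy = idx[[e != "H" for e in elems]]
        rep = "CA" if "CA" in names and roles[i] != "ligand" else None
        nodes.append(
            Node(
                node_id=i,
                chain=chain,
                resid=i + 1,
                resname=resnames[i],
                role=roles[i],
                rep_atom=rep,
                heavy_atoms=np.asarray(heavy, dtype=int),
                atoms=idx.copy(),
            )
        )
        flat_names.extend(names)
        flat_elems.extend(elems)
        flat_node_ids.extend([i] * len(names))
        cursor += len(names)
    return NodeMap(
        nodes=nodes,
        atom_names=np.array(flat_names),
        atom_elements=np.array(flat_elems),
        atom_node_ids=np.array(flat_node_ids, dtype=int),
        source_indices=np.arange(cursor),
    )


def bead_trajectory(positions: np.ndarray, node_map: "NodeMap | None" = None) -> Trajectory:
    """Trajectory from (frames, nodes, 3) single-bead positions."""
    positions = np.asarray(positions, dtype=float)
    nm = node_map or bead_node_map(positions.shape[1])
    return Trajectory(positions, nm)


def graph_network(g: nx.Graph):
    """Wrap a weight-annotated graph as a CorrelationNetwork.

    Edges may carry ``weight`` in (0, 1]; ``length`` is derived when
    missing.  Nodes must be 0..n-1.
    """
    from dynet.corrnet import CorrelationNetwork

    nm = bead_node_map(g.number_of_nodes())
    for u, v, d in g.edges(data=True):
        d.setdefault("weight", 0.5)
        d.setdefault("length", float(-math.log(d["weight"])))
        d.setdefault("occupancy", 1.0)
    for i in g.nodes:
        g.nodes[i].setdefault("label", nm.nodes[i].label)
        g.nodes[i].setdefault("role", nm.nodes[i].role)
    return CorrelationNetwork(g, nm)


def random_length_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """Random connected-ish graph with random positive edge lengths."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.55:
                w = float(rng.uniform(0.05, 0.95))
                g.add_edge(i, j, weight=w, length=float(-math.log(w)))
    return g


def brute_force_shortest(g: nx.Graph, source: int, target: int):
    """Exhaustive enumeration over all simple paths (the oracle)."""
    best_len, best_path = math.inf, None
    for path in nx.all_simple_paths(g, source, target):
        total = sum(g[u][v]["length"] for u, v in zip(path, path[1:]))
        if total < best_len - 1e-12:
            best_len, best_path = total, path
    return best_len, best_path


def planted_block_graph(rng: np.random.Generator):
    """Abstract weighted block network with a ligand node bridging the
    first two blocks (for perturbation monotonicity checks).

    Intra-block edges are dense and strong; adjacent blocks share one
    weak bridge; the ligand connects into two blocks.
    """
    k = int(rng.integers(3, 6))
    sizes = rng.integers(4, 8, size=k)
    g = nx.Graph()
    blocks, start = [], 0
    for size in sizes:
        blk = list(range(start, start + int(size)))
        blocks.append(blk)
        start += int(size)
        for u, v in itertools.combinations(blk, 2):
            if rng.random() < 0.85:
                w = float(rng.uniform(0.6, 0.95))
                g.add_edge(u, v, weight=w, length=float(-math.log(w)))
    for a, b in zip(blocks, blocks[1:]):
        u = int(rng.choice(a))
        v = int(rng.choice(b))
        w = float(rng.uniform(0.03, 0.10))
        g.add_edge(u, v, weight=w, length=float(-math.log(w)))
    ligand = start
    g.add_node(ligand)
    for blk in blocks[:2]:
        v = int(rng.choice(blk))
        w = float(rng.uniform(0.2, 0.9))
        g.add_edge(ligand, v, weight=w, length=float(-math.log(w)))
    return g, ligand, blocks
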