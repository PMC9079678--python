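"""Synthetic bead trajectories with a planted correlation-block structure.

This is a statistical stand-in for all-atom MD, not a force field: each
node is a small rigid cluster of pseudo-atoms, and node displacements
are drawn from a zero-mean multivariate Gaussian whose correlation
matrix is planted explicitly.  The generator guarantees, by
construction and by post-hoc numerical verification,

* a block structure (the planted communities) with uniform intra-block
  correlation ``rho_intra`` over a ``rho_inter`` background,
* an ordered source-to-sink pathway whose consecutive nodes are in
  physical contact, are never chain neighbours (so the pathway survives
  the covalent-bond edge exclusion), and, across block boundaries,
  correlate at ``pathway_rho``,
* a contact geometry in which exactly the declared pairs can satisfy
  the 4.5-Angstrom / 75 %-occupancy edge criterion.

Layout.  Each block occupies its own chain and consists of a ring of
beads (ring chord 3.8 A) plus an entry and an exit relay anchored on
the 135- and 45-degree faces; blocks are strung left to right with
exit and entry relays of adjacent blocks in direct contact.  The
planted pathway runs ligand -> ring short arc -> exit relay -> next
entry relay -> ... -> sink.  One weak "decoy" bridge per adjacent
block pair (closed through aimed satellite beads, correlating only at
the background level) gives the shortest-path search a genuine wrong
alternative.  Ring positions hold the chain sequence in a strided
order so geometric neighbours are never sequence neighbours.

The planted correlation matrix is realised through a latent factor
model (one global factor, one per block, one per cross-block pathway
edge) and is therefore positive semi-definite by construction whenever
the per-node loadings are feasible.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .structure import Node, NodeMap, Trajectory, write_pdb


class PlantedSpecError(ValueError):
    """Raised when a planted specification is internally inconsistent."""


class GenerationError(RuntimeError):
    """Raised when no clash-free geometry satisfying the contacts exists."""


# geometry constants (Angstrom)
RING_CHORD = 3.8        # center distance of adjacent beads on a block ring
ATTACH_DIST = 4.0       # relay / ligand / sink anchor distance
BOND_LENGTH = 1.6       # satellite pseudo-atom bond length
CLASH_MIN = 1.5         # hard lower bound on any interatomic distance
CONTACT_MAX = 4.1       # planted contacts must be at least this close
NONCONTACT_MIN = 4.9    # all other node pairs must stay at least this far
_MIN_ROUTED_BLOCK = 7   # smallest block that supports pathway routing


def _key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def _ring_order(m: int) -> list[int]:
    """Order of ring members around the circle such that geometric
    neighbours differ in sequence by at least 2 (stride coprime to m)."""
    for stride in (3, 2, 5, 7):
        s = stride % m
        if s >= 2 and m - s >= 2 and np.gcd(s, m) == 1:
            return [(j * s) % m for j in range(m)]
    if m == 6:  # no valid stride exists; hand-checked order
        return [0, 2, 4, 1, 5, 3]
    # tiny rings: identity fallback; missing ring edges are acceptable there
    return list(range(m))


def _entry_anchor_pos(m: int) -> int:
    """Ring position index (angle 2*pi*j/m) anchoring the entry relay."""
    return max(2, int(round(3 * m / 8)))


@dataclass
class PlantedSpec:
    """Ground-truth description of one synthetic system.

    Defaults define the reference study conditions: 40 nodes in 4
    equal blocks (ligand source in block 1, effector sink in block 4),
    intra-block correlation 0.8 over a 0.05 background, cross-block
    pathway correlation 0.12, and 25 000 frames for each of 5
    replicates with 0.3 A per-axis displacement amplitude.

    ``pathway_rho`` is bounded by positive semi-definiteness: a node
    carrying one cross-block pathway edge needs
    ``rho_intra + (pathway_rho - rho_inter) <= 1`` shared variance
    (two edges double the last term), i.e. ``pathway_rho <= 0.15`` at
    the default 0.8 / 0.05 block levels.

    Pass ``pathway=[]`` / ``extra_contacts=[]`` explicitly to disable
    the pathway or the decoy bridges; ``None`` (default) derives them
    from the block layout.
    """

    n_nodes: int = 40
    blocks: list[list[int]] | None = None
    rho_intra: float = 0.8
    rho_inter: float = 0.05
    pathway: list[int] | None = None
    pathway_rho: float = 0.12
    extra_contacts: list[tuple[int, int]] | None = None
    n_frames: int = 25_000
    n_replicates: int = 5
    amplitude: float = 0.3  # per-axis displacement std, Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blocks is None:
            if self.n_nodes % 4:
                raise PlantedSpecError("default layout needs n_nodes divisible by 4")
            size = self.n_nodes // 4
            self.blocks = [list(range(b * size, (b + 1) * size)) for b in range(4)]
        if self.pathway is None:
            self.pathway = self._default_pathway()
        if self.extra_contacts is None:
            self.extra_contacts = [
                (self.blocks[b][1], self.blocks[b + 1][1 + _ring_order(len(self.blocks[b + 1]) - 2)[(len(self.blocks[b + 1]) - 2) // 2]])
                for b in range(len(self.blocks) - 1)
                if min(len(self.blocks[b]), len(self.blocks[b + 1])) >= _MIN_ROUTED_BLOCK
            ]
        self.extra_contacts = [tuple(p) for p in self.extra_contacts]
        self.validate()

    def _default_pathway(self) -> list[int]:
        if any(len(blk) < _MIN_ROUTED_BLOCK for blk in self.blocks):
            return []
        path: list[int] = []
        for blk in self.blocks:
            ring = blk[1:-1]
            order = _ring_order(len(ring))
            k = _entry_anchor_pos(len(ring))
            path.append(blk[0])
            path.extend(ring[order[j]] for j in range(k, 0, -1))
            path.append(blk[-1])
        return path

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        flat = sorted(i for blk in self.blocks for i in blk)
        if flat != list(range(self.n_nodes)):
            raise PlantedSpecError("blocks must partition the node set")
        if not 0.0 <= self.rho_inter < self.rho_intra <= 1.0:
            raise PlantedSpecError("need 0 <= rho_inter < rho_intra <= 1")
        if not self.pathway_rho > self.rho_inter:
            raise PlantedSpecError("pathway_rho must exceed rho_inter")
        if len(self.pathway) != len(set(self.pathway)):
            raise PlantedSpecError("pathway must not repeat nodes")
        bo = self.block_of
        for u, v in zip(self.pathway, self.pathway[1:]):
            if bo[u] == bo[v] and abs(u - v) == 1:
                raise PlantedSpecError(
                    f"pathway step {u}-{v} joins chain neighbours; such an "
                    "edge is excluded by the covalent-bond rule"
                )
        if self.n_frames < 2 or self.n_replicates < 1:
            raise PlantedSpecError("need n_frames >= 2 and n_replicates >= 1")
        if self.amplitude <= 0:
            raise PlantedSpecError("amplitude must be positive")
        if np.any(self._residual_variances() < -1e-12):
            raise PlantedSpecError(
                "planted correlations are infeasible: reduce pathway_rho or "
                "rho_intra (per-node shared variance exceeds 1)"
            )

    # -- derived structure ---------------------------------------------
    @property
    def block_of(self) -> dict[int, int]:
        return {i: b for b, blk in enumerate(self.blocks) for i in blk}

    @property
    def source(self) -> int:
        if not self.pathway:
            raise PlantedSpecError("spec has no pathway")
        return self.pathway[0]

    @property
    def sink(self) -> int:
        if not self.pathway:
            raise PlantedSpecError("spec has no pathway")
        return self.pathway[-1]

    def cross_block_pathway_edges(self) -> list[tuple[int, int]]:
        bo = self.block_of
        return [
            (u, v)
            for u, v in zip(self.pathway, self.pathway[1:])
            if bo[u] != bo[v]
        ]

    def _residual_variances(self) -> np.ndarray:
        lam2 = np.full(self.n_nodes, self.rho_intra)  # global + block loadings
        for u, v in self.cross_block_pathway_edges():
            lam2[u] += self.pathway_rho - self.rho_inter
            lam2[v] += self.pathway_rho - self.rho_inter
        return 1.0 - lam2

    def correlation_matrix(self) -> np.ndarray:
        """The planted node-displacement correlation matrix (PSD)."""
        C = np.full((self.n_nodes, self.n_nodes), self.rho_inter)
        for blk in self.blocks:
            C[np.ix_(blk, blk)] = self.rho_intra
        for u, v in self.cross_block_pathway_edges():
            C[u, v] = C[v, u] = self.pathway_rho
        np.fill_diagonal(C, 1.0)
        eig_min = float(np.linalg.eigvalsh(C).min())
        if eig_min < -1e-10:
            warnings.warn(
                f"planted matrix not PSD (min eigenvalue {eig_min:.3g}); "
                "projecting to the nearest PSD matrix",
                stacklevel=2,
            )
            w, V = np.linalg.eigh(C)
            C = (V * np.clip(w, 0.0, None)) @ V.T
            d = np.sqrt(np.diag(C))
            C = C / np.outer(d, d)
        return C

    def planted_contacts(self) -> set[tuple[int, int]]:
        """All node pairs placed in physical contact (< 4.5 A heavy atoms)."""
        contacts: set[tuple[int, int]] = set()
        for blk in self.blocks:
            if len(blk) >= _MIN_ROUTED_BLOCK:
                ring = blk[1:-1]
                order = _ring_order(len(ring))
                m = len(ring)
                for j in range(m):
                    contacts.add(_key(ring[order[j]], ring[order[(j + 1) % m]]))
                k = _entry_anchor_pos(m)
                contacts.add(_key(blk[0], ring[order[k]]))    # entry anchor
                contacts.add(_key(blk[-1], ring[order[1]]))   # exit anchor
            else:
                for a, b in zip(blk, blk[1:]):
                    contacts.add(_key(a, b))
                if len(blk) >= 3:  # circular small-block layout wraps around
                    contacts.add(_key(blk[0], blk[-1]))
        for u, v in zip(self.pathway, self.pathway[1:]):
            contacts.add(_key(u, v))
        for u, v in self.extra_contacts:
            contacts.add(_key(u, v))
        return contacts

    def to_json(self) -> dict:
        d = asdict(self)
        d["planted_contacts"] = sorted(self.planted_contacts())
        d["cross_block_pathway_edges"] = self.cross_block_pathway_edges()
        return d


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class Geometry:
    """Reference coordinates plus the node map for a planted spec."""

    node_map: NodeMap
    coords: np.ndarray  # (atoms, 3) reference structure
    spec: PlantedSpec


def _satellite_frame(aim: np.ndarray | None) -> np.ndarray:
    """Two unit vectors for the satellite beads of one node.

    Satellites point out of the block plane (+z/-z) so they never close
    unplanned contacts; a node participating in a declared long-range
    contact instead aims its first satellite at the partner."""
    z = np.array([0.0, 0.0, 1.0])
    if aim is None:
        return np.stack([z, -z])
    a = aim / np.linalg.norm(aim)
    return np.stack([a, -z if a @ z < 0.9 else np.array([1.0, 0.0, 0.0])])


def build_geometry(spec: PlantedSpec) -> Geometry:
    """Place the nodes so exactly the planted contacts are in range.

    See the module docstring for the layout.  The construction is
    verified numerically: planted contacts closer than 4.1 A, all other
    node pairs beyond 4.9 A, no two atoms within 1.5 A; a violation
    raises :class:`GenerationError`.
    """
    n = spec.n_nodes
    centers = np.zeros((n, 3))
    routed = [len(blk) >= _MIN_ROUTED_BLOCK for blk in spec.blocks]
    if spec.pathway and not all(routed):
        raise GenerationError(
            f"pathway routing needs every block to have >= {_MIN_ROUTED_BLOCK} nodes"
        )

    radii: list[float] = []
    for blk in spec.blocks:
        m = len(blk) - 2 if len(blk) >= _MIN_ROUTED_BLOCK else len(blk)
        radii.append(
            RING_CHORD / (2.0 * np.sin(np.pi / max(m, 3))) if m >= 3 else RING_CHORD / 2
        )

    # block centers strung along x; relays of adjacent routed blocks touch
    block_x = [0.0]
    for b in range(1, len(spec.blocks)):
        ra, rb = radii[b - 1], radii[b]
        if routed[b - 1] and routed[b]:
            dy2 = 0.5 * (rb - ra) ** 2
            gap = (ra + rb + 2 * ATTACH_DIST) / np.sqrt(2.0) + np.sqrt(
                max(RING_CHORD ** 2 - dy2, 1.0)
            )
        else:
            gap = ra + rb + 4 * NONCONTACT_MIN  # unrouted blocks: far apart
        block_x.append(block_x[-1] + gap)

    for b, blk in enumerate(spec.blocks):
        cx = block_x[b]
        if not routed[b]:
            # compact layout for small blocks: ring (or pair / point)
            m = len(blk)
            if m == 1:
                centers[blk[0]] = (cx, 0.0, 0.0)
            elif m == 2:
                centers[blk[0]] = (cx - RING_CHORD / 2, 0.0, 0.0)
                centers[blk[1]] = (cx + RING_CHORD / 2, 0.0, 0.0)
            else:
                R = radii[b]
                for j, node in enumerate(blk):
                    th = 2 * np.pi * j / m
                    centers[node] = (cx + R * np.cos(th), R * np.sin(th), 0.0)
            continue
        ring = blk[1:-1]
        order = _ring_order(len(ring))
        m = len(ring)
        R = radii[b]
        for j in range(m):
            th = 2 * np.pi * j / m
            centers[ring[order[j]]] = (cx + R * np.cos(th), R * np.sin(th), 0.0)
        k = _entry_anchor_pos(m)
        for slot, th in ((blk[0], 2 * np.pi * k / m), (blk[-1], 2 * np.pi / m)):
            centers[slot] = (
                cx + (R + ATTACH_DIST) * np.cos(th),
                (R + ATTACH_DIST) * np.sin(th),
                0.0,
            )

    # only declared long-range contacts aim a satellite at their partner
    aims: dict[int, np.ndarray] = {}
    for u, v in spec.extra_contacts:
        if np.linalg.norm(centers[v] - centers[u]) > CONTACT_MAX:
            aims[u] = centers[v] - centers[u]
            aims[v] = centers[u] - centers[v]

    coords = np.empty((n * 3, 3))
    names: list[str] = []
    for i in range(n):
        sats = _satellite_frame(aims.get(i))
        coords[3 * i] = centers[i]
        coords[3 * i + 1: 3 * i + 3] = centers[i] + BOND_LENGTH * sats
        names.extend(["CA", "CB", "CG"])

    node_map = _make_node_map(spec, names)
    geometry = Geometry(node_map=node_map, coords=coords, spec=spec)
    _verify_geometry(geometry)
    return geometry


def _make_node_map(spec: PlantedSpec, atom_names: list[str]) -> NodeMap:
    chains = (string.ascii_uppercase * 4)[: len(spec.blocks)]
    chain_of: dict[int, str] = {}
    resid_of: dict[int, int] = {}
    for b, blk in enumerate(spec.blocks):
        for node in blk:
            chain_of[node] = chains[b]
            resid_of[node] = node + 1  # global numbering keeps labels unique
    source = spec.pathway[0] if spec.pathway else None
    sink = spec.pathway[-1] if spec.pathway else None
    nodes = []
    for i in range(spec.n_nodes):
        atoms = np.arange(3 * i, 3 * i + 3)
        if i == source:
            role, resname, rep = "ligand", "LIG", None
        elif i == sink:
            role, resname, rep = "effector-region", "SYN", "CA"
        else:
            role, resname, rep = "amino-acid", "SYN", "CA"
        nodes.append(
            Node(
                node_id=i,
                chain=chain_of[i],
                resid=resid_of[i],
                resname=resname,
                role=role,
                rep_atom=rep,
                heavy_atoms=atoms.copy(),
                atoms=atoms.copy(),
            )
        )
    n_atoms = 3 * spec.n_nodes
    return NodeMap(
        nodes=nodes,
        atom_names=np.array(atom_names),
        atom_elements=np.array(["C"] * n_atoms),
        atom_node_ids=np.repeat(np.arange(spec.n_nodes), 3),
        source_indices=np.arange(n_atoms),
    )


def min_atom_distances(geometry: Geometry) -> np.ndarray:
    """(n, n) matrix of minimal interatomic distances between nodes."""
    n = geometry.spec.n_nodes
    pts = geometry.coords.reshape(n, 3, 3)
    diff = pts[:, None, :, None, :] - pts[None, :, None, :, :]
    d = np.sqrt((diff ** 2).sum(-1)).reshape(n, n, 9).min(-1)
    np.fill_diagonal(d, np.inf)
    return d


def _verify_geometry(geometry: Geometry) -> None:
    spec = geometry.spec
    flat = geometry.coords
    pair = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
    np.fill_diagonal(pair, np.inf)
    if pair.min() < CLASH_MIN:
        raise GenerationError(f"atom clash at {pair.min():.2f} A")
    dmin = min_atom_distances(geometry)
    contacts = spec.planted_contacts()
    for i, j in contacts:
        if dmin[i, j] > CONTACT_MAX:
            raise GenerationError(
                f"planted contact ({i},{j}) too far: {dmin[i, j]:.2f} A"
            )
    mask = np.triu(np.ones_like(dmin, dtype=bool), 1)
    for i, j in contacts:
        mask[i, j] = False
    if np.any(dmin[mask] < NONCONTACT_MIN):
        masked = np.where(mask, dmin, np.inf)
        bad = np.unravel_index(int(np.argmin(masked)), dmin.shape)
        raise GenerationError(
            f"unplanned near-contact {bad}: {dmin[bad]:.2f} A"
        )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_trajectory(spec: PlantedSpec, geometry: Geometry) -> list[Trajectory]:
    """Draw ``n_replicates`` independent trajectories.

    Per axis and per frame, node displacements follow the planted
    correlation matrix (isotropic: the same structure on x, y and z,
    independently); all four beads of a node translate rigidly with it.
    Replicate streams are spawned from the single spec seed, so equal
    specs give bit-identical output.
    """
    resid_var = spec._residual_variances()
    if np.any(resid_var < -1e-12):
        raise PlantedSpecError("planted correlation model is not PSD-feasible")
    resid_sd = np.sqrt(np.clip(resid_var, 0.0, None))
    block_idx = np.array([spec.block_of[i] for i in range(spec.n_nodes)])
    edges = spec.cross_block_pathway_edges()
    lam_g = np.sqrt(spec.rho_inter)
    lam_b = np.sqrt(spec.rho_intra - spec.rho_inter)
    lam_e = np.sqrt(spec.pathway_rho - spec.rho_inter)

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    out = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        T, n = spec.n_frames, spec.n_nodes
        disp = np.empty((T, n, 3))
        for ax in range(3):
            g = rng.standard_normal(T)
            fb = rng.standard_normal((T, len(spec.blocks)))
            fe = rng.standard_normal((T, len(edges))) if edges else None
            x = lam_g * g[:, None] + lam_b * fb[:, block_idx]
            for k, (u, v) in enumerate(edges):
                x[:, u] += lam_e * fe[:, k]
                x[:, v] += lam_e * fe[:, k]
            x += rng.standard_normal((T, n)) * resid_sd
            disp[:, :, ax] = x
        disp *= spec.amplitude
        coords = geometry.coords[None, :, :] + np.repeat(disp, 3, axis=1)
        out.append(
            Trajectory(coords, geometry.node_map, replicate_id=rep, dt=1.0)
        )
    return out


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixture(spec: PlantedSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write topology + replicate trajectories as multi-model PDB files,
    plus a JSON sidecar with the full ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = build_geometry(spec)
    trajectories = sample_trajectory(spec, geometry)
    paths: dict[str, Path] = {}
    top = out_dir / "topology.pdb"
    write_pdb(geometry.node_map, geometry.coords, top)
    paths["topology"] = top
    for traj in trajectories:
        p = out_dir / f"replicate_{traj.replicate_id}.pdb"
        write_pdb(geometry.node_map, traj.coords, p)
        paths[f"replicate_{traj.replicate_id}"] = p
    truth = spec.to_json()
    truth["planted_correlation"] = spec.correlation_matrix().round(6).tolist()
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["ground_truth"] = truth_path
    return paths
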