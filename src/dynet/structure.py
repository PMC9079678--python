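"""Topology and trajectory handling for residue-level network analysis.

A *node* is one amino acid or one ligand; everything downstream
(correlation matrices, contact occupancies, networks) operates on the
node set defined here.  Waters, ions and lipids are excluded; hydrogens
are retained in the coordinate arrays (hydrogen-bond analysis needs
them) but never counted as heavy atoms.

Coordinates are Angstrom throughout.  Residue numbering follows the
source topology (1-based); node ids are contiguous 0-based internal
indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.analysis.align import rotation_matrix as _mda_rotation_matrix


class TopologyError(ValueError):
    """Raised when a topology file cannot be mapped onto a node set."""


class GeometryError(ValueError):
    """Raised when a geometric operation is ill-posed (e.g. too few fit atoms)."""


#: residue names treated as protein residues (one node each).  ``SYN`` is the
#: bead residue written by the synthetic-data generator.
PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
    TYR VAL HID HIE HIP HSD HSE HSP CYX CYM ASH GLH LYN SEC PYL MSE SYN""".split()
)

#: solvent / ion / lipid residue names dropped from the node set.
EXCLUDED_RESNAMES = frozenset(
    """HOH WAT TIP TIP3 TIP4 T3P T4P SPC SOL
    NA CL K CS MG ZN MN FE CU SOD CLA POT CAL CES LIT NA+ CL- K+
    POPC POPE POPS POPG POPA DPPC DMPC DOPC DOPE CHL1 CHOL PLM OL PA PC PE""".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HID": "H", "HIE": "H", "HIP": "H", "HSD": "H", "HSE": "H",
    "HSP": "H", "CYX": "C", "MSE": "M",
}

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "NA": 22.990,
    "K": 39.098, "CA": 40.078,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "SE", "FE", "ZN", "MG", "NA"}


def element_from_name(name: str) -> str:
    """Guess the chemical element from a PDB atom name.

    Follows the usual heuristic: strip digits/primes, recognise common
    two-letter elements, map names like ``1HG1``/``HB2`` to hydrogen,
    otherwise take the first letter.
    """
    stripped = name.strip().upper()
    core = stripped.lstrip("0123456789")
    if not core:
        raise TopologyError(f"cannot infer element from atom name {name!r}")
    if core[:2] in _TWO_LETTER_ELEMENTS:
        return core[:2]
    return core[0]


@dataclass(frozen=True)
class Node:
    """One network node: an amino acid or a ligand."""

    node_id: int
    chain: str
    resid: int
    resname: str
    role: str  # 'amino-acid' | 'ligand' | 'effector-region'
    rep_atom: str | None  # atom name, or None for heavy-atom center of geometry
    heavy_atoms: np.ndarray  # indices into the NodeMap atom arrays
    atoms: np.ndarray  # all atom indices (heavy + hydrogens)

    @property
    def label(self) -> str:
        """Short label, e.g. ``Y403`` for TYR 403 or the residue name for ligands."""
        if self.role == "ligand":
            return self.resname
        one = THREE_TO_ONE.get(self.resname)
        return f"{one}{self.resid}" if one else f"{self.resname}{self.resid}"


@dataclass
class NodeMap:
    """Partition of the retained atoms into nodes.

    ``source_indices`` records, for each retained atom, its index in the
    original topology file so trajectory frames can be subset consistently.
    """

    nodes: list[Node]
    atom_names: np.ndarray
    atom_elements: np.ndarray
    atom_node_ids: np.ndarray
    source_indices: np.ndarray
    atom_masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.atom_masses is None:
            self.atom_masses = np.array(
                [_ELEMENT_MASSES.get(e, 12.0) for e in self.atom_elements]
            )
        self.validate()

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def node_by_label(self, label: str) -> Node:
        hits = [node for node in self.nodes if node.label == label]
        if not hits:
            raise KeyError(f"no node labelled {label!r}")
        if len(hits) > 1:
            raise KeyError(
                f"label {label!r} is ambiguous ({len(hits)} nodes); "
                "use the node id instead"
            )
        return hits[0]

    def resolve(self, key: "int | str | Node") -> int:
        """Map a node id, label or Node to its node id."""
        if isinstance(key, Node):
            return key.node_id
        if isinstance(key, (int, np.integer)):
            if not 0 <= key < self.n_nodes:
                raise KeyError(f"node id {key} out of range")
            return int(key)
        return self.node_by_label(key).node_id

    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def heavy_atom_indices(self) -> np.ndarray:
        return np.concatenate([n.heavy_atoms for n in self.nodes])

    def ligand_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.role == "ligand"]

    def rep_atom_index(self, node: Node) -> int | None:
        """Index of the representative atom, or None when the node uses its
        heavy-atom center of geometry (ligands)."""
        if node.rep_atom is None:
            return None
        names = self.atom_names[node.heavy_atoms]
        hits = node.heavy_atoms[names == node.rep_atom]
        if len(hits) == 0:
            return None
        return int(hits[0])

    def covalent_pairs(self) -> set[tuple[int, int]]:
        """Node pairs joined by a covalent bond.

        In a polypeptide the only inter-node covalent links are backbone
        peptide bonds, i.e. chain-sequence neighbours; ligands are assumed
        non-covalently bound.
        """
        pairs: set[tuple[int, int]] = set()
        by_chain: dict[str, list[Node]] = {}
        for node in self.nodes:
            if node.role != "ligand":
                by_chain.setdefault(node.chain, []).append(node)
        for chain_nodes in by_chain.values():
            chain_nodes.sort(key=lambda n: n.resid)
            for a, b in zip(chain_nodes, chain_nodes[1:]):
                if b.resid - a.resid == 1:
                    pairs.add((min(a.node_id, b.node_id), max(a.node_id, b.node_id)))
        return pairs

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if ids != list(range(len(ids))):
            raise TopologyError("node ids must be contiguous and 0-based")
        seen = np.zeros(self.n_atoms, dtype=int)
        for node in self.nodes:
            if len(node.heavy_atoms) == 0:
                raise TopologyError(
                    f"residue {node.resname} {node.resid} (chain {node.chain}) "
                    "has no heavy atoms"
                )
            seen[node.atoms] += 1
        if not np.all(seen == 1):
            raise TopologyError("atoms must belong to exactly one node")


@dataclass
class Trajectory:
    """Frame-indexed coordinates for all retained atoms of one replicate."""

    coords: np.ndarray  # (frames, atoms, 3), Angstrom
    node_map: NodeMap
    replicate_id: int = 0
    dt: float = 1.0  # ps between retained frames

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.node_map.n_atoms:
            raise TopologyError(
                f"trajectory has {self.coords.shape[1]} atoms but topology "
                f"defines {self.node_map.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def rep_positions(self) -> np.ndarray:
        """(frames, nodes, 3) positions of the representative point per node.

        Amino acids use their Calpha atom; ligands (and nodes whose
        representative atom is missing) use the heavy-atom center of
        geometry.
        """
        nm = self.node_map
        out = np.empty((self.n_frames, nm.n_nodes, 3))
        for node in nm.nodes:
            idx = nm.rep_atom_index(node)
            if idx is None:
                out[:, node.node_id] = self.coords[:, node.heavy_atoms].mean(axis=1)
            else:
                out[:, node.node_id] = self.coords[:, idx]
        return out

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(coords, self.node_map, self.replicate_id, self.dt)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _universe(topology: str | Path, trajectory: str | Path | None = None):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory is None:
                return mda.Universe(str(topology))
            return mda.Universe(str(topology), str(trajectory))
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise TopologyError(f"cannot parse {topology}: {exc}") from exc


def read_topology(path: str | Path) -> NodeMap:
    """Build the node set from a PDB file.

    One node per protein residue and per ligand HETATM group; water, ion
    and lipid residues are excluded; hydrogens are kept in the atom
    arrays but dropped from each node's heavy-atom list.
    """
    u = _universe(path)
    nodes: list[Node] = []
    atom_names: list[str] = []
    atom_elements: list[str] = []
    atom_node_ids: list[int] = []
    source_indices: list[int] = []

    for res in u.residues:
        resname = res.resname.strip().upper()
        if resname in EXCLUDED_RESNAMES:
            continue
        role = "amino-acid" if resname in PROTEIN_RESNAMES else "ligand"
        heavy: list[int] = []
        atoms: list[int] = []
        for atom in res.atoms:
            element = element_from_name(atom.name)
            local = len(atom_names)
            atom_names.append(atom.name.strip())
            atom_elements.append(element)
            atom_node_ids.append(len(nodes))
            source_indices.append(int(atom.ix))
            atoms.append(local)
            if element != "H":
                heavy.append(local)
        if not atoms:
            continue
        if not heavy:
            raise TopologyError(
                f"residue {resname} {int(res.resid)} has no heavy atoms"
            )
        chain = ""
        try:
            chain = str(res.segment.segid).strip()
        except Exception:  # pragma: no cover - topologies without segments
            chain = ""
        if not chain and hasattr(res.atoms, "chainIDs"):
            ids = {c for c in res.atoms.chainIDs if str(c).strip()}
            if ids:
                chain = sorted(ids)[0]
        rep = "CA" if role == "amino-acid" else None
        if rep is not None and rep not in {atom_names[i] for i in heavy}:
            rep = None  # fall back to the center of geometry
        nodes.append(
            Node(
                node_id=len(nodes),
                chain=chain or "A",
                resid=int(res.resid),
                resname=resname,
                role=role,
                rep_atom=rep,
                heavy_atoms=np.array(heavy, dtype=int),
                atoms=np.array(atoms, dtype=int),
            )
        )
    if not nodes:
        raise TopologyError(f"{path}: no protein or ligand residues found")
    return NodeMap(
        nodes=nodes,
        atom_names=np.array(atom_names),
        atom_elements=np.array(atom_elements),
        atom_node_ids=np.array(atom_node_ids, dtype=int),
        source_indices=np.array(source_indices, dtype=int),
    )


def _window_slice(n_frames: int, window, stride: int) -> np.ndarray:
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if window is None:
        start, stop = 0, n_frames
    elif isinstance(window, float):
        if not 0.0 < window <= 1.0:
            raise ValueError("fractional window must be in (0, 1]")
        start, stop = n_frames - max(1, int(round(window * n_frames))), n_frames
    else:
        start, stop = window
        if start < 0:
            start += n_frames
        if stop <= 0:
            stop += n_frames
        stop = min(stop, n_frames)
    frames = np.arange(start, stop)[::stride]
    if len(frames) == 0:
        raise ValueError(f"empty frame window {window!r} for {n_frames} frames")
    return frames


def read_trajectory(
    paths: Sequence[str | Path] | str | Path,
    node_map: NodeMap,
    *,
    topology: str | Path | None = None,
    stride: int = 1,
    window: "tuple[int, int] | float | None" = None,
    dt: float = 1.0,
) -> list[Trajectory]:
    """Read one :class:`Trajectory` per input file (= per replicate).

    ``window`` selects frames before striding: either a 0-based
    half-open ``(start, stop)`` frame range (negative values count from
    the end) or a float ``f`` meaning the last fraction ``f`` of frames
    (the usual "last 50 ns" equilibrated-window convention).  Multi-model
    PDB files are self-describing; binary formats such as DCD need
    ``topology``.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    trajectories: list[Trajectory] = []
    for replicate_id, path in enumerate(paths):
        path = Path(path)
        top = topology if topology is not None else path
        u = _universe(top, path)
        if u.atoms.n_atoms <= node_map.source_indices.max():
            raise TopologyError(
                f"{path}: frame has {u.atoms.n_atoms} atoms, topology expects "
                f"at least {int(node_map.source_indices.max()) + 1}"
            )
        frames = _window_slice(len(u.trajectory), window, stride)
        coords = np.empty((len(frames), node_map.n_atoms, 3))
        for k, fi in enumerate(frames):
            ts = u.trajectory[int(fi)]
            coords[k] = ts.positions[node_map.source_indices]
        trajectories.append(
            Trajectory(coords, node_map, replicate_id=replicate_id, dt=dt * stride)
        )
    return trajectories


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _fit_frame(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (both (n,3)).

    Returns the rotation matrix plus the two centroids.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    R, _ = _mda_rotation_matrix(mobile - mob_c, reference - ref_c)
    return np.asarray(R), mob_c, ref_c


def superpose(
    traj: Trajectory,
    reference: "int | np.ndarray | str" = "mean",
) -> Trajectory:
    """Rigid-body least-squares fit of every frame onto a reference.

    The fit is computed on the representative points (Calpha / ligand
    centers) and applied to all atoms.  ``reference`` is a frame index,
    an explicit (nodes, 3) array, or ``"mean"`` for the time-mean
    representative structure of the window.
    """
    rep = traj.rep_positions()
    if rep.shape[1] < 3:
        raise GeometryError("superposition needs at least 3 representative atoms")
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError(f"unknown reference {reference!r}")
        # iterate fit-to-mean until the mean structure is a fixed point,
        # so superposing an already-superposed trajectory is a no-op
        ref = rep.mean(axis=0)
        work = rep.copy()
        for _ in range(100):
            for f in range(work.shape[0]):
                R, mob_c, ref_c = _fit_frame(work[f], ref)
                work[f] = (work[f] - mob_c) @ R.T + ref_c
            new_ref = work.mean(axis=0)
            if np.abs(new_ref - ref).max() < 1e-12:
                ref = new_ref
                break
            ref = new_ref
    elif isinstance(reference, (int, np.integer)):
        ref = rep[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != rep.shape[1:]:
            raise GeometryError(
                f"reference shape {ref.shape} does not match node count {rep.shape[1]}"
            )
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        R, mob_c, ref_c = _fit_frame(rep[f], ref)
        out[f] = (traj.coords[f] - mob_c) @ R.T + ref_c
    return traj.with_coords(out)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the trajectory as a (multi-model) PDB file.

    Ligand atoms are emitted as HETATM records so the node roles survive
    a round trip through :func:`read_topology`.
    """
    write_pdb(traj.node_map, traj.coords, path)


def write_pdb(node_map: NodeMap, coords: np.ndarray, path: str | Path) -> None:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = node_map.n_atoms
    resindex = node_map.atom_node_ids
    u = mda.Universe.empty(
        n_atoms,
        n_residues=node_map.n_nodes,
        n_segments=len({n.chain for n in node_map.nodes}),
        atom_resindex=resindex,
        residue_segindex=[
            sorted({n.chain for n in node_map.nodes}).index(n.chain)
            for n in node_map.nodes
        ],
        trajectory=True,
    )
    u.add_TopologyAttr("names", node_map.atom_names)
    u.add_TopologyAttr("elements", node_map.atom_elements)
    u.add_TopologyAttr("resnames", [n.resname for n in node_map.nodes])
    u.add_TopologyAttr("resids", [n.resid for n in node_map.nodes])
    u.add_TopologyAttr("segids", sorted({n.chain for n in node_map.nodes}))
    u.add_TopologyAttr("chainIDs", [node_map.nodes[i].chain for i in resindex])
    u.add_TopologyAttr(
        "record_types",
        [
            "HETATM" if node_map.nodes[i].role == "ligand" else "ATOM"
            for i in resindex
        ],
    )
    u.add_TopologyAttr("occupancies", np.ones(n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(n_atoms))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=coords.shape[0] > 1) as w:
            for frame in coords:
                u.atoms.positions = frame
                w.write(u.atoms)
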