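"""Residue- and ligand-interaction fingerprints over a trajectory.

Three geometric criteria, each scored as a per-pair *population* (the
fraction of frames in which the criterion holds):

* hydrophobic  -- side-chain (or ligand) mass centers closer than 6.5 A;
* electrostatic -- side-chain mass centers of two charged residues (or a
  charged residue and a ligand) closer than 11 A;
* hydrogen bond -- donor-acceptor heavy-atom distance below 3.5 A with a
  donor-hydrogen-acceptor angle above 120 degrees.

Glycine has no side chain, so its Calpha stands in for the side-chain
center.  When the input carries no hydrogens, an ideal-geometry hydrogen
is placed along the donor's valence direction (approximate, flagged in
the record).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import Trajectory

HYDROPHOBIC_CUTOFF = 6.5   # A, side-chain mass-center distance
ELECTROSTATIC_CUTOFF = 11.0  # A, charged side-chain mass-center distance
HBOND_DISTANCE = 3.5       # A, donor-acceptor heavy-atom distance
HBOND_ANGLE = 120.0        # degrees, donor-hydrogen-acceptor
STRONG_POPULATION = 0.4    # reporting threshold for "strong" interactions

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

NEGATIVE_RESIDUES = frozenset({"ASP", "GLU", "ASH", "GLH"})
POSITIVE_RESIDUES = frozenset({"ARG", "LYS", "HIS", "HID", "HIE", "HIP", "LYN"})

#: polar heavy atoms that can donate a hydrogen, by atom name
DONOR_ATOMS = frozenset(
    "N NE NH1 NH2 NZ ND1 NE2 ND2 NE1 OG OG1 OH SG OW".split()
)
#: heavy atoms that can accept a hydrogen bond
ACCEPTOR_ATOMS = frozenset(
    "O OXT OD1 OD2 OE1 OE2 OG OG1 OH ND1 NE2 SD OW".split()
)


@dataclass
class InteractionRecord:
    """One node pair scored under one interaction criterion."""

    node_i: int
    node_j: int
    label_i: str
    label_j: str
    kind: str                 # 'hydrophobic' | 'electrostatic' | 'hbond'
    population: float         # fraction of frames in [0, 1]
    mean_distance: float      # A, over the frames satisfying the criterion
    mean_angle: float | None = None  # degrees, hbond only
    approximate_hydrogens: bool = False


def records_table(records: "list[InteractionRecord]") -> pd.DataFrame:
    rows = [
        {
            "node_i": r.label_i,
            "node_j": r.label_j,
            "type": r.kind,
            "population": r.population,
            "mean_distance": r.mean_distance,
            "mean_angle": r.mean_angle,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["node_i", "node_j", "type", "population", "mean_distance", "mean_angle"]
    )


def filter_strong(
    records: "list[InteractionRecord]", min_population: float = STRONG_POPULATION
) -> "list[InteractionRecord]":
    """Pure population filter; the returned list is a subset of the input."""
    return [r for r in records if r.population >= min_population]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sidechain_centers(traj: Trajectory) -> np.ndarray:
    """(frames, nodes, 3) side-chain mass centers; ligands use all heavy
    atoms, glycine (or any residue without side-chain atoms) its Calpha."""
    nm = traj.node_map
    out = np.empty((traj.n_frames, nm.n_nodes, 3))
    for node in nm.nodes:
        if node.role == "ligand":
            idx = node.heavy_atoms
        else:
            names = nm.atom_names[node.heavy_atoms]
            idx = node.heavy_atoms[~np.isin(names, list(BACKBONE_ATOMS))]
            if len(idx) == 0:
                ca = node.heavy_atoms[names == "CA"]
                idx = ca if len(ca) else node.heavy_atoms
        masses = nm.atom_masses[idx]
        out[:, node.node_id] = (
            traj.coords[:, idx] * masses[None, :, None]
        ).sum(axis=1) / masses.sum()
    return out


def _center_records(
    traj: Trajectory,
    cutoff: float,
    kind: str,
    eligible: "np.ndarray",
) -> "list[InteractionRecord]":
    centers = _sidechain_centers(traj)
    nm = traj.node_map
    records = []
    idx = np.flatnonzero(eligible)
    for a, i in enumerate(idx):
        for j in idx[a + 1:]:
            d = np.linalg.norm(centers[:, i] - centers[:, j], axis=1)
            hits = d < cutoff
            if not hits.any():
                continue
            records.append(
                InteractionRecord(
                    node_i=int(i),
                    node_j=int(j),
                    label_i=nm.nodes[i].label,
                    label_j=nm.nodes[j].label,
                    kind=kind,
                    population=float(hits.mean()),
                    mean_distance=float(d[hits].mean()),
                )
            )
    return records


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def hydrophobic_contacts(
    traj: Trajectory, cutoff: float = HYDROPHOBIC_CUTOFF
) -> "list[InteractionRecord]":
    """All node pairs whose side-chain/ligand mass centers come within
    the hydrophobic cutoff in at least one frame."""
    eligible = np.ones(traj.node_map.n_nodes, dtype=bool)
    return _center_records(traj, cutoff, "hydrophobic", eligible)


def electrostatic_contacts(
    traj: Trajectory,
    cutoff: float = ELECTROSTATIC_CUTOFF,
    *,
    include_his: bool = True,
    include_ligands: bool = False,
) -> "list[InteractionRecord]":
    """Charge-charge contacts between charged side chains.

    The charged set is Asp/Glu (negative) and Arg/Lys (positive), plus
    His when ``include_his`` (protonation-state agnostic default).
    """
    nm = traj.node_map
    positive = set(POSITIVE_RESIDUES)
    if not include_his:
        positive -= {"HIS", "HID", "HIE", "HIP"}
    eligible = np.array(
        [
            n.resname in NEGATIVE_RESIDUES
            or n.resname in positive
            or (include_ligands and n.role == "ligand")
            for n in nm.nodes
        ]
    )
    return _center_records(traj, cutoff, "electrostatic", eligible)


def _donor_hydrogens(traj: Trajectory, donor: int) -> tuple[np.ndarray, bool]:
    """(frames, n_H, 3) hydrogen positions for one donor heavy atom.

    Prefers explicit hydrogens bonded to the donor (within 1.25 A in the
    first frame); otherwise places one ideal hydrogen 1.0 A along the
    donor valence, i.e. away from the centroid of the donor's bonded
    heavy neighbours.  Returns the positions and an approximate flag.
    """
    nm = traj.node_map
    node = nm.nodes[nm.atom_node_ids[donor]]
    ref = traj.coords[0]
    hyd = [
        a for a in node.atoms
        if nm.atom_elements[a] == "H"
        and np.linalg.norm(ref[a] - ref[donor]) < 1.25
    ]
    if hyd:
        return traj.coords[:, hyd], False
    neigh = [
        a for a in node.heavy_atoms
        if a != donor and np.linalg.norm(ref[a] - ref[donor]) < 1.75
    ]
    if not neigh:
        return np.empty((traj.n_frames, 0, 3)), True
    centroid = traj.coords[:, neigh].mean(axis=1)
    direction = traj.coords[:, donor] - centroid
    norm = np.linalg.norm(direction, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    pos = traj.coords[:, donor] + direction / norm
    return pos[:, None, :], True


def hydrogen_bonds(
    traj: Trajectory,
    distance_cutoff: float = HBOND_DISTANCE,
    angle_cutoff: float = HBOND_ANGLE,
) -> "list[InteractionRecord]":
    """Donor-acceptor contacts satisfying both the distance and the
    donor-hydrogen-acceptor angle criterion, aggregated per node pair
    (a frame counts when any donor/acceptor combination qualifies)."""
    nm = traj.node_map
    donors: list[int] = []
    acceptors: list[int] = []
    for node in nm.nodes:
        for a in node.heavy_atoms:
            name = nm.atom_names[a]
            if name in DONOR_ATOMS:
                donors.append(a)
            if name in ACCEPTOR_ATOMS:
                acceptors.append(a)
    per_pair_hits: dict[tuple[int, int], np.ndarray] = {}
    per_pair_dist: dict[tuple[int, int], np.ndarray] = {}
    per_pair_ang: dict[tuple[int, int], np.ndarray] = {}
    approx_any = False
    skipped = 0
    for d_atom in donors:
        h_pos, approx = _donor_hydrogens(traj, d_atom)
        if h_pos.shape[1] == 0:
            skipped += 1
            continue
        approx_any = approx_any or approx
        d_node = int(nm.atom_node_ids[d_atom])
        d_xyz = traj.coords[:, d_atom]
        for a_atom in acceptors:
            a_node = int(nm.atom_node_ids[a_atom])
            if a_node == d_node:
                continue
            a_xyz = traj.coords[:, a_atom]
            dist = np.linalg.norm(d_xyz - a_xyz, axis=1)
            close = dist < distance_cutoff
            if not close.any():
                continue
            # angle at the hydrogen: donor-H-acceptor, best over hydrogens
            v1 = d_xyz[:, None, :] - h_pos
            v2 = a_xyz[:, None, :] - h_pos
            cosang = (v1 * v2).sum(-1) / (
                np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1) + 1e-12
            )
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))).max(axis=1)
            hits = close & (angle > angle_cutoff)
            if not hits.any():
                continue
            key = (min(d_node, a_node), max(d_node, a_node))
            if key not in per_pair_hits:
                per_pair_hits[key] = np.zeros(traj.n_frames, dtype=bool)
                per_pair_dist[key] = np.full(traj.n_frames, np.inf)
                per_pair_ang[key] = np.zeros(traj.n_frames)
            per_pair_hits[key] |= hits
            better = hits & (dist < per_pair_dist[key])
            per_pair_dist[key] = np.where(better, dist, per_pair_dist[key])
            per_pair_ang[key] = np.where(better, angle, per_pair_ang[key])
    if skipped:
        warnings.warn(
            f"{skipped} donor(s) had no resolvable hydrogen and were skipped",
            stacklevel=2,
        )
    records = []
    for (i, j), hits in sorted(per_pair_hits.items()):
        dists = per_pair_dist[(i, j)][hits]
        angles = per_pair_ang[(i, j)][hits]
        records.append(
            InteractionRecord(
                node_i=i,
                node_j=j,
                label_i=nm.nodes[i].label,
                label_j=nm.nodes[j].label,
                kind="hbond",
                population=float(hits.mean()),
                mean_distance=float(dists.mean()),
                mean_angle=float(angles.mean()),
                approximate_hydrogens=approx_any,
            )
        )
    return records


def all_interactions(traj: Trajectory, **kwargs) -> "list[InteractionRecord]":
    """Hydrophobic + electrostatic + hydrogen-bond records, concatenated."""
    return (
        hydrophobic_contacts(traj)
        + electrostatic_contacts(traj, **kwargs)
        + hydrogen_bonds(traj)
    )
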