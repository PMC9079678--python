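"""Trajectory stability metrics: RMSD series, RMSF profiles, pairwise
distance-difference maps, and PCA of node fluctuations.

All metrics operate on the representative node positions (Calpha for
amino acids, heavy-atom centers for ligands), matching the residue
level of the network analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import GeometryError, Trajectory, _fit_frame


@dataclass
class FluctuationProfile:
    """Per-node root-mean-square fluctuation about the time mean (A)."""

    values: np.ndarray
    node_ids: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSF values cannot be negative")


@dataclass
class PCAModes:
    """Leading eigenmodes of the 3N x 3N node-coordinate covariance."""

    modes: np.ndarray              # (k, 3N), rows orthonormal
    variance_fractions: np.ndarray  # all 3N fractions, descending, sum 1
    eigenvalues: np.ndarray        # all 3N, descending


def rmsd_series(
    traj: Trajectory,
    reference: "int | np.ndarray" = 0,
    *,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (A) of the representative atoms to a reference.

    With ``fit=True`` (default) each frame is rigid-body fitted to the
    reference before measuring, the usual Calpha-RMSD convention.
    """
    pos = traj.rep_positions()
    if isinstance(reference, (int, np.integer)):
        ref = pos[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != pos.shape[1:]:
            raise GeometryError("reference does not match the node count")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = pos[f]
        if fit:
            if pos.shape[1] < 3:
                raise GeometryError("fitting needs at least 3 nodes")
            R, mob_c, ref_c = _fit_frame(frame, ref)
            frame = (frame - mob_c) @ R.T + ref_c
        out[f] = np.sqrt(((frame - ref) ** 2).sum(axis=1).mean())
    return out


def rmsf(traj: Trajectory) -> FluctuationProfile:
    """RMSF_i = sqrt(<|r_i - <r_i>|^2>) per node.

    Assumes the trajectory is already superposed; a single global fit to
    the window mean (not per-frame-pair fits) is the intended protocol.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    pos = traj.rep_positions()
    delta = pos - pos.mean(axis=0)
    values = np.sqrt((delta ** 2).sum(axis=2).mean(axis=0))
    return FluctuationProfile(
        values=values,
        node_ids=np.arange(pos.shape[1]),
        n_frames=traj.n_frames,
    )


def distance_difference(traj_a: Trajectory, traj_b: Trajectory) -> np.ndarray:
    """D_ij = <d_ij>_A - <d_ij>_B on representative atoms.

    Antisymmetric under swapping the two trajectories, zero diagonal.
    Positive entries mean the pair sits further apart in A than in B.
    """
    if traj_a.node_map.n_nodes != traj_b.node_map.n_nodes:
        raise ValueError("trajectories must share a node set")

    def mean_distances(traj: Trajectory) -> np.ndarray:
        pos = traj.rep_positions()
        acc = np.zeros((pos.shape[1], pos.shape[1]))
        for f in range(pos.shape[0]):
            diff = pos[f, :, None, :] - pos[f, None, :, :]
            acc += np.sqrt((diff ** 2).sum(-1))
        return acc / pos.shape[0]

    return mean_distances(traj_a) - mean_distances(traj_b)


def pca_modes(traj: Trajectory, k: int = 3) -> PCAModes:
    """Eigen-decomposition of the 3N x 3N covariance of representative
    coordinates; fractions are eigenvalue shares of the total variance."""
    pos = traj.rep_positions()
    F, N, _ = pos.shape
    if k > 3 * N:
        raise ValueError(f"k={k} exceeds the 3N={3 * N} coordinate dimensions")
    if F <= 3 * N:
        warnings.warn(
            f"only {F} frames for {3 * N} coordinates; covariance is rank-deficient",
            stacklevel=2,
        )
    X = pos.reshape(F, 3 * N)
    X = X - X.mean(axis=0)
    cov = X.T @ X / F
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAModes(
        modes=eigvecs[:, :k].T.copy(),
        variance_fractions=fractions,
        eigenvalues=eigvals,
    )
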