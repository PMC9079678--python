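import numpy as np
import pytest

from dynet.synth import PlantedSpec, build_geometry, sample_trajectory


@pytest.fixture(scope="session")
def small_spec() -> PlantedSpec:
    """Default 40-node planted system at a fast frame count."""
    return PlantedSpec(n_frames=1500, n_replicates=3, seed=11)


@pytest.fixture(scope="session")
def small_system(small_spec):
    geometry = build_geometry(small_spec)
    trajectories = sample_trajectory(small_spec, geometry)
    return small_spec, geometry, trajectories


@pytest.fixture(scope="session")
def small_networks(small_system):
    from dynet.corrnet import build_network, contact_occupancy, correlation_matrix

    spec, geometry, trajectories = small_system
    nets = []
    for traj in trajectories:
        corr = correlation_matrix(traj)
        occ = contact_occupancy(traj)
        nets.append(build_network(corr, occ, geometry.node_map))
    return nets


def pdb_line(record, serial, name, resname, chain, resseq, xyz, element):
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {name_field:<4} {resname:<4}{chain}{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


@pytest.fixture()
def tiny_pdb(tmp_path):
    """3-residue peptide + 1 ligand + water + lipid, hand-written."""
    rng = np.random.default_rng(3)
    lines = []
    serial = 1
    for resseq, resname in enumerate(["ALA", "GLY", "SER"], start=1):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            xyz = rng.normal(scale=5.0, size=3) + resseq * 4.0
            lines.append(pdb_line("ATOM", serial, name, resname, "A", resseq, xyz, element))
            serial += 1
    for name, element in (("C1", "C"), ("N1", "N")):
        lines.append(pdb_line("HETATM", serial, name, "LIG", "A", 4, rng.normal(size=3), element))
        serial += 1
    lines.append(pdb_line("HETATM", serial, "O", "HOH", "A", 5, rng.normal(size=3), "O"))
    serial += 1
    lines.append(pdb_line("ATOM", serial, "P", "POPC", "B", 1, rng.normal(size=3), "P"))
    lines.append("END")
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
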