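"""Shared fixtures: tiny hand-built topologies and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from cationsite.trajectory import AtomRecord, Topology, Trajectory

AMINO3 = ["GLY", "ALA", "ASP", "LYS", "PRO", "SER", "LEU", "GLU"]
ATOM_NAMES = ["N", "CA", "C", "O", "CB", "OD1", "OD2", "NZ"]


def make_topology(rng: np.random.Generator, n_residues: int = 5,
                  atoms_per_residue: int = 4, n_na: int = 1,
                  n_k: int = 1) -> Topology:
    """A random but well-formed protein-plus-ions topology."""
    atoms = []
    serial = 1
    for r in range(n_residues):
        resname = AMINO3[int(rng.integers(len(AMINO3)))]
        for a in range(atoms_per_residue):
            name = ATOM_NAMES[a % len(ATOM_NAMES)]
            atoms.append(AtomRecord(serial=serial, name=name,
                                    element=name[0], residue_name=resname,
                                    residue_seq=r + 1, chain="A"))
            serial += 1
    ion_sets: dict[str, list[int]] = {}
    for sp, resn, count in (("Na", "NA", n_na), ("K", "K", n_k)):
        for _ in range(count):
            ion_sets.setdefault(sp, []).append(len(atoms))
            atoms.append(AtomRecord(serial=serial, name=resn, element=sp,
                                    residue_name=resn, residue_seq=900 + serial,
                                    chain="I"))
            serial += 1
    return Topology(atoms=atoms, ion_sets=ion_sets)


def make_trajectory(rng: np.random.Generator, topology: Topology,
                    n_frames: int = 20, box=None,
                    spread: float = 15.0) -> Trajectory:
    coords = rng.random((n_frames, topology.n_atoms, 3)) * spread
    return Trajectory(topology=topology, coords=coords, box=box)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def single_ion_residue_traj(distances, cutoff_atom=(0.0, 0.0, 0.0)):
    """One single-atom residue at the origin and one Na ion placed at the
    given distance from it in each frame."""
    atoms = [
        AtomRecord(serial=1, name="CA", element="C", residue_name="GLY",
                   residue_seq=1, chain="A"),
        AtomRecord(serial=2, name="NA", element="Na", residue_name="NA",
                   residue_seq=901, chain="I"),
    ]
    top = Topology(atoms=atoms, ion_sets={"Na": [1]})
    coords = np.zeros((len(distances), 2, 3))
    coords[:, 0, :] = cutoff_atom
    for f, d in enumerate(distances):
        coords[f, 1, :] = (d, 0.0, 0.0)
    return Trajectory(topology=top, coords=coords)
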