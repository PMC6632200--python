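"""Topology/trajectory I/O round-trips and minimum-image distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cationsite.errors import (EmptyInputError, FrameMismatchError, ParseError)
from cationsite.trajectory import (
    Selection, distance, distance_array, read_frames, read_topology,
    write_frames_table, write_pdb, write_topology_table, write_xyz)

from conftest import make_topology, make_trajectory

PDB_4ATOM = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  O   GLY A   1       2.100   1.100   0.000  1.00  0.00           O
HETATM    4 NA    NA A 900       5.000   5.000   5.000  1.00  0.00          NA
END
"""


def test_pdb_topology_parses_atoms_and_detects_ions(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(PDB_4ATOM)
    top = read_topology(p)
    assert top.n_atoms == 4
    assert top.ion_sets == {"Na": [3]}
    assert top.atoms[1].name == "CA"
    assert top.atoms[3].residue_seq == 900  # author numbering preserved


def test_pdb_without_cryst1_yields_box_free_trajectory(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(PDB_4ATOM)
    top = read_topology(p)
    traj = read_frames(p, top)
    assert traj.box is None
    # non-periodic distances: ion to N atom straight Euclidean
    d = distance(traj.coords[0, 0], traj.coords[0, 3])
    assert d == pytest.approx(np.sqrt(75.0))


def test_malformed_pdb_record_reports_line_number(tmp_path):
    bad = PDB_4ATOM.replace("   1.450", "   xxx.4", 1)
    p = tmp_path / "bad.pdb"
    p.write_text(bad)
    top = read_topology(p)  # serial/name fields are fine
    with pytest.raises(ParseError, match="line 2"):
        read_frames(p, top)


def test_empty_pdb_raises_empty_input(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("END\n")
    with pytest.raises(EmptyInputError):
        read_topology(p)


def test_triclinic_box_is_rejected(tmp_path):
    lines = ("CRYST1   60.000   60.000   60.000  90.00  90.00  60.00 P 1\n"
             + PDB_4ATOM)
    p = tmp_path / "tric.pdb"
    p.write_text(lines)
    top = read_topology(p)
    with pytest.raises(ParseError, match="triclinic"):
        read_frames(p, top)


@pytest.mark.parametrize("fmt", ["pdb", "table"])
def test_topology_roundtrip_is_lossless(tmp_path, rng, fmt):
    top = make_topology(rng, n_residues=12, atoms_per_residue=4, n_na=1, n_k=1)
    assert top.n_atoms == 50
    path = tmp_path / f"topo.{'pdb' if fmt == 'pdb' else 'tsv'}"
    if fmt == "pdb":
        write_pdb(path, top, np.zeros((top.n_atoms, 3)))
    else:
        write_topology_table(path, top)
    back = read_topology(path, format=fmt)
    for a, b in zip(top.atoms, back.atoms):
        assert (a.serial, a.name, a.residue_name, a.residue_seq, a.chain) == \
            (b.serial, b.name, b.residue_name, b.residue_seq, b.chain)
    assert back.ion_sets == top.ion_sets


@pytest.mark.parametrize("fmt,decimals", [("pdb", 3), ("xyz", 5), ("table", 5)])
def test_frames_roundtrip_preserves_coordinates(tmp_path, rng, fmt, decimals):
    top = make_topology(rng, n_residues=3)
    traj = make_trajectory(rng, top, n_frames=4, spread=40.0)
    path = tmp_path / f"frames.{ {'pdb': 'pdb', 'xyz': 'xyz', 'table': 'tsv'}[fmt] }"
    if fmt == "pdb":
        write_pdb(path, top, traj.coords)
    elif fmt == "xyz":
        write_xyz(path, top, traj.coords)
    else:
        write_frames_table(path, top, traj.coords)
    back = read_frames(path, top, format=fmt)
    assert back.n_frames == 4
    np.testing.assert_allclose(back.coords, traj.coords, atol=10**-decimals / 2)


def test_multimodel_pdb_gives_sequential_frame_indices(tmp_path, rng):
    top = make_topology(rng, n_residues=2)
    traj = make_trajectory(rng, top, n_frames=3)
    p = tmp_path / "multi.pdb"
    write_pdb(p, top, traj.coords, box=(50.0, 50.0, 50.0))
    back = read_frames(p, top)
    assert [f.index for f in back.frames()] == [0, 1, 2]
    np.testing.assert_allclose(back.box, [50.0, 50.0, 50.0])


def test_xyz_atom_count_mismatch_names_frame(tmp_path, rng):
    top = make_topology(rng, n_residues=1, atoms_per_residue=4, n_na=0, n_k=0)
    lines = "5\nframe 0\n" + "\n".join("C 0 0 0" for _ in range(5)) + "\n"
    p = tmp_path / "bad.xyz"
    p.write_text(lines)
    with pytest.raises(FrameMismatchError, match="frame 0"):
        read_frames(p, top, format="xyz")


def test_distance_simple_and_minimum_image():
    assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
    assert distance((1, 0, 0), (9, 0, 0), box=(10, 10, 10)) == pytest.approx(2.0)


def test_distance_rejects_non_finite():
    with pytest.raises(Exception, match="non-finite"):
        distance((0, 0, np.nan), (1, 1, 1))


def brute_force_min_image(a, b, box):
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float)
    return min(np.linalg.norm(np.asarray(b) + s * np.asarray(box) - np.asarray(a))
               for s in shifts)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(-30, 30), min_size=6, max_size=6))
def test_minimum_image_equals_image_enumeration(values):
    box = np.array([7.0, 9.0, 11.0])
    # wrap into the primary cell: the 27-shift enumeration is exhaustive there
    a, b = np.array(values[:3]) % box, np.array(values[3:]) % box
    d = distance(a, b, box)
    assert d == pytest.approx(brute_force_min_image(a, b, box), abs=1e-9)
    # properties: symmetry, non-negativity, never longer than non-periodic
    assert d == pytest.approx(distance(b, a, box))
    assert 0 <= d <= distance(a, b) + 1e-12


def test_distance_array_matches_scalar(rng):
    a = rng.random((6, 3)) * 20
    b = rng.random((6, 3)) * 20
    box = np.array([8.0, 9.0, 10.0])
    vec = distance_array(a, b, box)
    for i in range(6):
        assert vec[i] == pytest.approx(distance(a[i], b[i], box))


def test_selection_resolution_is_stable_and_ordered(rng):
    top = make_topology(rng, n_residues=6)
    sel = Selection.of(residue_seq={2, 4}, heavy_only=True)
    first = sel.resolve(top)
    second = sel.resolve(top)
    np.testing.assert_array_equal(first, second)
    assert np.all(np.diff(first) > 0)


def test_mdanalysis_agrees_on_pdb_distances(tmp_path, rng):
    """Independent reader cross-check on a written multi-model PDB."""
    MDAnalysis = pytest.importorskip("MDAnalysis")
    top = make_topology(rng, n_residues=3)
    traj = make_trajectory(rng, top, n_frames=2, spread=30.0)
    p = tmp_path / "x.pdb"
    write_pdb(p, top, traj.coords)
    u = MDAnalysis.Universe(str(p))
    ours = read_frames(p, top)
    for f, ts in enumerate(u.trajectory):
        np.testing.assert_allclose(ts.positions, ours.coords[f], atol=1e-3)
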