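"""Topologies, multi-frame coordinate sets, atom selections and distances.

Conventions used throughout the package:

* coordinates are in Angstrom (Å), frames are 0-based;
* residue numbering is the author numbering of the input file and is never
  renumbered ("P71" means ``residue_seq == 71``);
* periodic boxes are orthorhombic; distances under a box use the minimum
  image convention. Triclinic boxes are rejected.

Supported formats: PDB (ATOM/HETATM/MODEL/ENDMDL/CRYST1), XYZ
(count + comment + ``element x y z``), and a tabular trajectory format
(TSV with columns ``frame, atom_serial, x, y, z``; topology TSV with
columns ``serial, name, element, residue_name, residue_seq, chain``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CationSiteError,
    ConfigurationError,
    EmptyInputError,
    FrameMismatchError,
    ParseError,
)

#: Residue-name aliases for monatomic ions, mapping to canonical species
#: labels. CHARMM names (SOD/POT/CLA) are included; the table can be
#: extended by passing ``ion_aliases`` to the readers.
ION_ALIASES: dict[str, str] = {
    "NA": "Na",
    "SOD": "Na",
    "K": "K",
    "POT": "K",
    "CL": "Cl",
    "CLA": "Cl",
}

_ELEMENTS_2 = {
    "NA", "CL", "MG", "CA", "ZN", "FE", "MN", "BR", "SE",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology; field values are kept exactly as read."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str = "A"
    is_hydrogen: bool = False


@dataclass
class Topology:
    """An ordered atom list with derived residue grouping and ion sets."""

    atoms: list[AtomRecord]
    ion_sets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ConfigurationError("atom serials are not unique within the topology")
        for a in self.atoms:
            if not a.element:
                raise ConfigurationError(f"atom serial {a.serial} has an empty element")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Group atom indices by (chain, residue_seq, residue_name), in order."""
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault((a.chain, a.residue_seq, a.residue_name), []).append(i)
        return groups

    def protein_residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Residue groups excluding declared ion atoms and water."""
        ion_idx = {i for idx in self.ion_sets.values() for i in idx}
        out: dict[tuple[str, int, str], list[int]] = {}
        for key, idx in self.residues().items():
            if key[2] in ("HOH", "WAT", "TIP3"):
                continue
            members = [i for i in idx if i not in ion_idx]
            if members:
                out[key] = members
        return out

    def ion_indices(self, species: str | None = None) -> list[int]:
        if species is not None:
            return list(self.ion_sets.get(species, []))
        return [i for idx in self.ion_sets.values() for i in idx]

    def species_of(self, atom_index: int) -> str | None:
        for sp, idx in self.ion_sets.items():
            if atom_index in idx:
                return sp
        return None


@dataclass
class Frame:
    """Coordinates of all atoms at one time point (Å)."""

    index: int
    coords: np.ndarray
    time: float | None = None  # ps
    box: np.ndarray | None = None  # orthorhombic lengths (Å)


@dataclass
class Trajectory:
    """A topology plus stacked per-frame coordinates.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``. An optional shared
    orthorhombic ``box`` applies to every frame.
    """

    topology: Topology
    coords: np.ndarray
    box: np.ndarray | None = None
    times: np.ndarray | None = None
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConfigurationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("a trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FrameMismatchError(
                f"coordinate array has {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        t = None if self.times is None else float(self.times[i])
        return Frame(index=i, coords=self.coords[i], time=t, box=self.box)

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass(frozen=True)
class Selection:
    """A declarative atom predicate resolving to a stable ordered index list.

    ``heavy_only`` defaults to True: cation coordination and salt bridges
    act through O/N heavy atoms, and hydrogens are often absent anyway.
    """

    chain: str | None = None
    residue_seq: frozenset[int] | None = None
    residue_name: frozenset[str] | None = None
    atom_name: frozenset[str] | None = None
    heavy_only: bool = True

    @staticmethod
    def of(chain=None, residue_seq=None, residue_name=None, atom_name=None,
           heavy_only=True) -> "Selection":
        fs = lambda x: None if x is None else frozenset(x)
        return Selection(chain, fs(residue_seq), fs(residue_name), fs(atom_name),
                         heavy_only)

    def matches(self, a: AtomRecord) -> bool:
        if self.heavy_only and a.is_hydrogen:
            return False
        if self.chain is not None and a.chain != self.chain:
            return False
        if self.residue_seq is not None and a.residue_seq not in self.residue_seq:
            return False
        if self.residue_name is not None and a.residue_name not in self.residue_name:
            return False
        if self.atom_name is not None and a.name not in self.atom_name:
            return False
        return True

    def resolve(self, topology: Topology) -> np.ndarray:
        idx = [i for i, a in enumerate(topology.atoms) if self.matches(a)]
        return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# distances

def _check_box(box) -> np.ndarray | None:
    if box is None:
        return None
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or not np.all(box > 0):
        raise ConfigurationError("box must be three positive orthorhombic lengths")
    return box


def distance(a, b, box=None) -> float:
    """Euclidean distance in Å; minimum-image under an orthorhombic box."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise CationSiteError("non-finite coordinates in distance()")
    box = _check_box(box)
    d = b - a
    if box is not None:
        d -= box * np.round(d / box)
    return float(np.sqrt(np.sum(d * d)))


def distance_array(a: np.ndarray, b: np.ndarray, box=None) -> np.ndarray:
    """Broadcasted distances between coordinate arrays of shape (..., 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = _check_box(box)
    d = b - a
    if box is not None:
        d = d - box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def min_distance_per_frame(traj: Trajectory, idx_a: np.ndarray,
                           idx_b: np.ndarray) -> np.ndarray:
    """Per-frame minimum distance between two atom index groups.

    Returns an array of length ``n_frames``.
    """
    ca = traj.coords[:, np.asarray(idx_a, dtype=int), :]
    cb = traj.coords[:, np.asarray(idx_b, dtype=int), :]
    d = distance_array(ca[:, :, None, :], cb[:, None, :, :], traj.box)
    return d.min(axis=(1, 2))


# ---------------------------------------------------------------------------
# PDB I/O

def _guess_element(name: str, resname: str) -> str:
    """Element from atom name, with ion residue names taking precedence."""
    stripped = name.strip()
    alias = ION_ALIASES.get(resname.strip().upper())
    if alias is not None:
        return alias
    two = stripped[:2].upper()
    if two in _ELEMENTS_2 and two == resname.strip().upper()[:2]:
        return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return stripped or "X"


def _canonical_species(resname: str, aliases: dict[str, str]) -> str | None:
    return aliases.get(resname.strip().upper())


def _parse_pdb_atom_line(line: str, lineno: int, path: str) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip() or line[17:21].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record: {exc}", lineno, path) from exc
    if not element:
        element = _guess_element(name, resname)
    element = element.capitalize() if len(element) > 1 else element.upper()
    hyd = element.upper() == "H"
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_seq=resseq, chain=chain,
                      is_hydrogen=hyd)


def _parse_pdb_coords(line: str, lineno: int, path: str) -> tuple[float, float, float]:
    try:
        return (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed coordinate fields: {exc}", lineno, path) from exc


def _parse_cryst1(line: str, lineno: int, path: str) -> np.ndarray:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed CRYST1 record: {exc}", lineno, path) from exc
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise ParseError(
            "triclinic box (angles != 90°) is not supported; only orthorhombic "
            "boxes are handled", lineno, path)
    return np.array([a, b, c], dtype=float)


def read_topology(path, format: str | None = None,
                  ion_aliases: dict[str, str] | None = None) -> Topology:
    """Read a topology from a PDB, XYZ or topology-TSV file.

    Ions are auto-detected from the residue name via :data:`ION_ALIASES`
    (extensible through ``ion_aliases``) and collected into
    ``Topology.ion_sets`` under canonical species labels.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    aliases = dict(ION_ALIASES)
    if ion_aliases:
        aliases.update({k.upper(): v for k, v in ion_aliases.items()})

    if fmt == "pdb":
        atoms = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                rec = line[:6]
                if rec in ("ATOM  ", "HETATM"):
                    atoms.append(_parse_pdb_atom_line(line, lineno, str(path)))
                elif rec.startswith("ENDMDL"):
                    break  # topology from first model only
    elif fmt == "xyz":
        atoms = []
        with open(path) as fh:
            lines = fh.readlines()
        if not lines:
            raise EmptyInputError(f"{path} is empty")
        try:
            n = int(lines[0].split()[0])
        except (ValueError, IndexError) as exc:
            raise ParseError("XYZ atom count expected", 1, str(path)) from exc
        for i in range(n):
            lineno = 3 + i
            if lineno - 1 >= len(lines):
                raise ParseError("truncated XYZ frame", lineno, str(path))
            parts = lines[lineno - 1].split()
            if len(parts) < 4:
                raise ParseError("XYZ line needs 'element x y z'", lineno, str(path))
            el = parts[0]
            elem = el.capitalize() if len(el) > 1 else el.upper()
            atoms.append(AtomRecord(
                serial=i + 1, name=el, element=elem,
                residue_name=el.upper(), residue_seq=i + 1, chain="A",
                is_hydrogen=elem.upper() == "H"))
    elif fmt == "table":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", keep_default_na=False)  # "NA" is an ion
        required = {"serial", "name", "element", "residue_name", "residue_seq", "chain"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"topology table missing columns {sorted(missing)}",
                             1, str(path))
        atoms = [AtomRecord(serial=int(r.serial), name=str(r.name),
                            element=str(r.element), residue_name=str(r.residue_name),
                            residue_seq=int(r.residue_seq), chain=str(r.chain),
                            is_hydrogen=str(r.element).upper() == "H")
                 for r in df.itertuples(index=False)]
    else:
        raise ConfigurationError(f"unknown topology format {fmt!r}")

    if not atoms:
        raise EmptyInputError(f"no atoms found in {path}")

    ion_sets: dict[str, list[int]] = {}
    residues: dict[tuple, list[int]] = {}
    for i, a in enumerate(atoms):
        residues.setdefault((a.chain, a.residue_seq, a.residue_name), []).append(i)
    for key, idx in residues.items():
        sp = _canonical_species(key[2], aliases)
        if sp is not None and len(idx) == 1:
            ion_sets.setdefault(sp, []).append(idx[0])
    return Topology(atoms=atoms, ion_sets=ion_sets)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    if suffix in (".tsv", ".txt", ".table"):
        return "table"
    raise ConfigurationError(f"cannot infer format from suffix {suffix!r}")


def read_frames(path, topology: Topology, format: str | None = None,
                replicate_id: str = "rep1") -> Trajectory:
    """Read a multi-frame coordinate set against an existing topology."""
    path = Path(path)
    fmt = format or _infer_format(path)
    n_atoms = topology.n_atoms

    frames: list[np.ndarray] = []
    box = None
    if fmt == "pdb":
        current: list[tuple[float, float, float]] = []
        saw_model = False
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                rec = line[:6]
                if rec.startswith("CRYST1"):
                    box = _parse_cryst1(line, lineno, str(path))
                elif rec.startswith("MODEL"):
                    saw_model = True
                    current = []
                elif rec in ("ATOM  ", "HETATM"):
                    current.append(_parse_pdb_coords(line, lineno, str(path)))
                elif rec.startswith("ENDMDL"):
                    _append_frame(frames, current, n_atoms)
                    current = []
        if current or (not saw_model and not frames):
            if not current:
                raise EmptyInputError(f"no coordinates found in {path}")
            _append_frame(frames, current, n_atoms)
    elif fmt == "xyz":
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].split()[0])
            except (ValueError, IndexError) as exc:
                raise ParseError("XYZ atom count expected", i + 1, str(path)) from exc
            block = lines[i + 2:i + 2 + n]
            if len(block) < n:
                raise ParseError("truncated XYZ frame", i + 1, str(path))
            coords = []
            for j, line in enumerate(block):
                parts = line.split()
                if len(parts) < 4:
                    raise ParseError("XYZ line needs 'element x y z'",
                                     i + 3 + j, str(path))
                coords.append(tuple(float(v) for v in parts[1:4]))
            _append_frame(frames, coords, n_atoms)
            i += 2 + n
    elif fmt == "table":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"frame", "atom_serial", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"trajectory table missing columns {sorted(missing)}",
                             1, str(path))
        serial_order = {a.serial: i for i, a in enumerate(topology.atoms)}
        for f_idx, (fval, grp) in enumerate(df.groupby("frame", sort=True)):
            if len(grp) != n_atoms:
                raise FrameMismatchError(
                    f"frame {fval} has {len(grp)} atoms, topology has {n_atoms}",
                    frame=f_idx)
            arr = np.empty((n_atoms, 3), dtype=float)
            for r in grp.itertuples(index=False):
                arr[serial_order[int(r.atom_serial)]] = (r.x, r.y, r.z)
            frames.append(arr)
    else:
        raise ConfigurationError(f"unknown trajectory format {fmt!r}")

    if not frames:
        raise EmptyInputError(f"no frames found in {path}")
    return Trajectory(topology=topology, coords=np.stack(frames), box=box,
                      replicate_id=replicate_id)


def _append_frame(frames: list, coords: list, n_atoms: int) -> None:
    if len(coords) != n_atoms:
        raise FrameMismatchError(
            f"frame has {len(coords)} atoms, topology has {n_atoms}",
            frame=len(frames))
    frames.append(np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)

def write_pdb(path, topology: Topology, coords: np.ndarray | None = None,
              box: np.ndarray | None = None) -> None:
    """Write a (multi-model) PDB. ``coords`` may be (N,3) or (F,N,3)."""
    path = Path(path)
    if coords is None:
        coords = np.zeros((1, topology.n_atoms, 3))
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        if box is not None:
            a, b, c = np.asarray(box, dtype=float)
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}"
                     f"{90.0:7.2f} P 1           1\n")
        multi = coords.shape[0] > 1
        for f in range(coords.shape[0]):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            for atom, xyz in zip(topology.atoms, coords[f]):
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{_record_type(topology, atom)}{atom.serial:5d} {name:<4s}"
                    f" {atom.residue_name:<3s} {atom.chain[:1]}{atom.residue_seq:4d}"
                    f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{atom.element.upper():>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _record_type(topology: Topology, atom: AtomRecord) -> str:
    return ("HETATM" if atom.residue_name.upper() in ION_ALIASES
            or atom.residue_name in ("HOH", "WAT") else "ATOM  ")


def write_xyz(path, topology: Topology, coords: np.ndarray) -> None:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for atom, xyz in zip(topology.atoms, coords[f]):
                fh.write(f"{atom.element:<3s} {xyz[0]:15.6f} {xyz[1]:15.6f} "
                         f"{xyz[2]:15.6f}\n")


def write_topology_table(path, topology: Topology) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [dataclasses.asdict(a) for a in topology.atoms],
        columns=["serial", "name", "element", "residue_name", "residue_seq",
                 "chain", "is_hydrogen"],
    )
    df.drop(columns=["is_hydrogen"]).to_csv(path, sep="\t", index=False)


def write_frames_table(path, topology: Topology, coords: np.ndarray) -> None:
    import pandas as pd

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    rows = []
    for f in range(coords.shape[0]):
        for atom, xyz in zip(topology.atoms, coords[f]):
            rows.append((f, atom.serial, xyz[0], xyz[1], xyz[2]))
    pd.DataFrame(rows, columns=["frame", "atom_serial", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
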