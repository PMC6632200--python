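"""Species-resolved ion-residue contact frequency tables.

A contact is counted when the minimum distance from an ion to any heavy
atom of a residue is within the cutoff (4.0 Å by default, boundary
inclusive). Two counting conventions are provided:

* ``ion_frame_pairs`` (default) — every (ion, frame) pair within the
  cutoff contributes one count, so two simultaneous ions count twice;
* ``any_ion_per_frame`` — a residue counts at most once per frame,
  regardless of how many ions of the species are nearby.

Relative frequencies are ``absolute / n_frames x 100`` in both
conventions; under ``ion_frame_pairs`` they can therefore exceed 100%
in principle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MergeError
from .events import SiteDefinition
from .trajectory import Selection, Topology, Trajectory, distance_array

COUNTING_MODES = ("ion_frame_pairs", "any_ion_per_frame")


@dataclass(frozen=True)
class ContactParameters:
    cutoff: float = 4.0
    heavy_only: bool = True
    counting: str = "ion_frame_pairs"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")
        if self.counting not in COUNTING_MODES:
            raise ConfigurationError(
                f"counting must be one of {COUNTING_MODES}, got {self.counting!r}")


@dataclass
class ContactTable:
    """Per-residue, per-species contact counts over one or more replicates.

    ``counts`` is indexed by (chain, residue_seq, residue_name) with one
    integer column per species; ``combined`` (filled by
    :func:`combine_species`) is the across-species sum.
    """

    counts: pd.DataFrame
    n_frames: int
    params: ContactParameters
    replicate_ids: tuple[str, ...] = ("rep1",)
    combined: pd.Series | None = None

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    def relative(self) -> pd.DataFrame:
        """Relative frequencies in percent of frames (full precision)."""
        return self.counts / self.n_frames * 100.0

    def combined_relative(self) -> pd.Series | None:
        if self.combined is None:
            return None
        return self.combined / self.n_frames * 100.0

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Flat output table (TSV layout); relative columns rounded."""
        rel = self.relative()
        out = pd.DataFrame(index=self.counts.index)
        for sp in self.species:
            out[f"{sp.lower()}_abs"] = self.counts[sp]
            out[f"{sp.lower()}_rel"] = rel[sp].round(decimals)
        if self.combined is not None:
            out["sum_abs"] = self.combined
            out["sum_rel"] = self.combined_relative().round(decimals)
        out["n_frames"] = self.n_frames
        return out.reset_index()


def count_contacts(traj: Trajectory, params: ContactParameters | None = None,
                   residues: Selection | None = None) -> ContactTable:
    """Count ion-residue contacts for every (residue, species) pair.

    ``residues`` restricts the table; by default all non-ion, non-water
    residues of the topology are profiled.
    """
    params = params or ContactParameters()
    top = traj.topology
    if not top.ion_sets:
        raise ConfigurationError("trajectory declares no ions")

    groups = top.protein_residues()
    if residues is not None:
        keep = set(residues.resolve(top).tolist())
        groups = {k: [i for i in idx if i in keep] for k, idx in groups.items()}
        groups = {k: idx for k, idx in groups.items() if idx}
        if not groups:
            raise ConfigurationError("residue selection resolved to no atoms")

    heavy = top.heavy_mask
    species = sorted(top.ion_sets)
    rows = {}
    for key, idx in groups.items():
        atom_idx = np.array([i for i in idx if not params.heavy_only or heavy[i]],
                            dtype=int)
        if atom_idx.size == 0:
            continue
        res_xyz = traj.coords[:, atom_idx, :]          # (F, m, 3)
        counts = {}
        for sp in species:
            ion_idx = np.array(top.ion_sets[sp], dtype=int)
            ion_xyz = traj.coords[:, ion_idx, :]       # (F, I, 3)
            d = distance_array(ion_xyz[:, :, None, :], res_xyz[:, None, :, :],
                               traj.box)
            dmin = d.min(axis=2)                       # (F, I) min over atoms
            within = dmin <= params.cutoff
            if params.counting == "ion_frame_pairs":
                counts[sp] = int(within.sum())
            else:
                counts[sp] = int(within.any(axis=1).sum())
        rows[key] = counts

    index = pd.MultiIndex.from_tuples(rows.keys(),
                                      names=["chain", "residue_seq", "residue_name"])
    counts_df = pd.DataFrame([rows[k] for k in rows], index=index,
                             columns=species).astype(int)
    return ContactTable(counts=counts_df, n_frames=traj.n_frames, params=params,
                        replicate_ids=(traj.replicate_id,))


def merge_replicates(tables: list[ContactTable]) -> ContactTable:
    """Pool counts and frame totals over replicate runs.

    Relative frequencies are recomputed from the merged totals, which is
    exactly equivalent to recounting over the concatenated trajectories.
    """
    if not tables:
        raise MergeError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.params != first.params:
            raise MergeError("tables were computed with different parameters")
        if tuple(t.counts.columns) != tuple(first.counts.columns):
            raise MergeError("tables have different species sets")
        if not t.counts.index.equals(first.counts.index):
            only_a = first.counts.index.difference(t.counts.index).tolist()
            only_b = t.counts.index.difference(first.counts.index).tolist()
            raise MergeError(
                f"residue keys differ between tables: only in first {only_a}, "
                f"only in other {only_b}")
    counts = first.counts.copy()
    for t in tables[1:]:
        counts = counts + t.counts
    merged = ContactTable(
        counts=counts.astype(int),
        n_frames=sum(t.n_frames for t in tables),
        params=first.params,
        replicate_ids=tuple(r for t in tables for r in t.replicate_ids),
    )
    if all(t.combined is not None for t in tables):
        merged = combine_species(merged)
    return merged


def combine_species(table: ContactTable) -> ContactTable:
    """Fill the across-species sum column (the 'all cations' column)."""
    if len(table.species) < 1:
        raise ConfigurationError("table has no species columns")
    return replace(table, combined=table.counts.sum(axis=1).astype(int))


def identify_candidate_sites(table: ContactTable, topology: Topology,
                             reference_coords: np.ndarray,
                             rel_threshold: float = 1.0,
                             link_cutoff: float = 8.0,
                             box: np.ndarray | None = None,
                             cutoff: float | None = None) -> list[SiteDefinition]:
    """Group high-contact residues into candidate coordination sites.

    Residues whose combined relative frequency is at or above
    ``rel_threshold`` (percent) are clustered by single linkage on the
    minimum heavy-atom inter-residue distance in ``reference_coords``;
    clusters closer than ``link_cutoff`` merge. Each cluster becomes one
    :class:`SiteDefinition` named by its member residues.
    """
    t = table if table.combined is not None else combine_species(table)
    rel = t.combined_relative()
    passing = [key for key, v in rel.items() if v >= rel_threshold]
    if not passing:
        return []

    groups = topology.protein_residues()
    heavy = topology.heavy_mask
    members = {key: np.array([i for i in groups[key] if heavy[i]], dtype=int)
               for key in passing}

    # single-linkage clustering on min inter-residue heavy-atom distance
    n = len(passing)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a = reference_coords[members[passing[i]]]
            b = reference_coords[members[passing[j]]]
            dmin = distance_array(a[:, None, :], b[None, :, :], box).min()
            if dmin <= link_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list] = {}
    for i, key in enumerate(passing):
        clusters.setdefault(find(i), []).append(key)

    sites = []
    for keys in clusters.values():
        keys = sorted(keys, key=lambda k: (k[0], k[1]))
        name = "-".join(f"{_one_letter(k[2])}{k[1]}" for k in keys)
        sel = Selection.of(residue_seq={k[1] for k in keys}, heavy_only=True)
        sites.append(SiteDefinition(name=name, members=sel,
                                    cutoff=cutoff or t.params.cutoff))
    sites.sort(key=lambda s: s.name)
    return sites


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "HSD": "H", "HSE": "H",
}


def _one_letter(residue_name: str) -> str:
    return _THREE_TO_ONE.get(residue_name.upper(), "X")
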