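"""Ion-atom distance series and in-site coordination statistics.

Identifies which electronegative atoms (carbonyl/carboxylate oxygens)
actually coordinate a cation while it sits in the site: statistics are
restricted to in-site frames, and an atom is called coordinating when
the ion spends a sufficient fraction of those frames inside a
species-specific first-shell proximity threshold (defaults: Na 2.6 Å,
K 3.0 Å — typical first-shell cation-oxygen distances; a single 2.5 Å
threshold would reject genuine K+ coordination at 2.6-2.9 Å).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import _one_letter
from .errors import ConfigurationError
from .events import OccupancyMask
from .trajectory import Selection, Trajectory, distance_array

#: Default first-shell proximity thresholds (Å) per cation species.
PROXIMITY_DEFAULTS = {"Na": 2.6, "K": 3.0}


@dataclass
class AtomPairSeries:
    """Distance from one ion to one atom, for every frame (Å)."""

    ion_index: int
    species: str | None
    atom_index: int
    atom_label: str  # e.g. "P71:O", "D75:OD1", "K504:NZ"
    distances: np.ndarray


@dataclass
class CoordinationStats:
    atom_label: str
    species: str | None
    mean_distance: float
    sd_distance: float
    n_frames_used: int
    fraction_below_proximity: float
    proximity: float


@dataclass(frozen=True)
class CoordinationCall:
    atom_label: str
    species: str | None
    is_coordinating: bool
    proximity: float
    occupancy_fraction: float
    fraction_below_proximity: float
    positively_charged: bool = False


def atom_label(traj_or_top, atom_index: int) -> str:
    top = getattr(traj_or_top, "topology", traj_or_top)
    a = top.atoms[atom_index]
    return f"{_one_letter(a.residue_name)}{a.residue_seq}:{a.name}"


def distance_series(traj: Trajectory, ion: int,
                    atoms: Selection | np.ndarray) -> list[AtomPairSeries]:
    """One full-length, periodic-aware distance series per selected atom."""
    idx = atoms.resolve(traj.topology) if isinstance(atoms, Selection) \
        else np.asarray(atoms, dtype=int)
    if idx.size == 0:
        raise ConfigurationError("atom selection resolved to no atoms")
    if ion in idx.tolist():
        raise ConfigurationError("atom selection includes the ion itself")
    species = traj.topology.species_of(ion)
    ion_xyz = traj.coords[:, ion, :]
    out = []
    for i in idx.tolist():
        d = distance_array(ion_xyz, traj.coords[:, i, :], traj.box)
        out.append(AtomPairSeries(ion_index=ion, species=species, atom_index=i,
                                  atom_label=atom_label(traj, i), distances=d))
    return out


def in_site_stats(series: AtomPairSeries, mask: OccupancyMask,
                  proximity: float | None = None,
                  sample_sd: bool = False) -> CoordinationStats | None:
    """Mean/SD of the ion-atom distance over in-site frames only.

    SD is the population standard deviation by default (``ddof=0``);
    pass ``sample_sd=True`` for the n-1 convention. Returns None (with a
    warning) when the mask has no in-site frames.
    """
    if series.distances.size != mask.n_frames:
        raise ConfigurationError("series and mask have different lengths")
    d = series.distances[mask.mask]
    if d.size == 0:
        warnings.warn(f"no in-site frames for {series.atom_label}; stats withheld")
        return None
    prox = proximity if proximity is not None else \
        PROXIMITY_DEFAULTS.get(series.species or "", 2.6)
    return CoordinationStats(
        atom_label=series.atom_label,
        species=series.species,
        mean_distance=float(d.mean()),
        sd_distance=float(d.std(ddof=1 if sample_sd else 0)),
        n_frames_used=int(d.size),
        fraction_below_proximity=float((d < prox).mean()),
        proximity=prox,
    )


def coordination_call(stats: CoordinationStats, species: str | None = None,
                      occupancy_fraction: float = 0.25,
                      min_frames: int = 50,
                      positively_charged: bool = False) -> CoordinationCall | None:
    """Call an atom coordinating when the in-proximity fraction is large enough.

    The criterion is inclusive (``>=``). Positively charged atoms (Lys/Arg
    nitrogens) are still reported, flagged by ``positively_charged``; they
    normally fail the criterion because like charges repel. Calls are
    withheld (None) below ``min_frames`` in-site frames.
    """
    if stats.n_frames_used < min_frames:
        warnings.warn(
            f"{stats.atom_label}: only {stats.n_frames_used} in-site frames "
            f"(< {min_frames}); coordination call withheld")
        return None
    return CoordinationCall(
        atom_label=stats.atom_label,
        species=species if species is not None else stats.species,
        is_coordinating=stats.fraction_below_proximity >= occupancy_fraction,
        proximity=stats.proximity,
        occupancy_fraction=occupancy_fraction,
        fraction_below_proximity=stats.fraction_below_proximity,
        positively_charged=positively_charged,
    )


def stats_table(stats: list[CoordinationStats | None],
                calls: list[CoordinationCall | None] | None = None) -> pd.DataFrame:
    rows = []
    calls = calls or [None] * len(stats)
    for s, c in zip(stats, calls):
        if s is None:
            continue
        row = {"atom": s.atom_label, "species": s.species,
               "mean_A": s.mean_distance, "sd_A": s.sd_distance,
               "n_frames": s.n_frames_used,
               "fraction_below_proximity": s.fraction_below_proximity,
               "proximity_A": s.proximity}
        if c is not None:
            row["is_coordinating"] = c.is_coordinating
        rows.append(row)
    return pd.DataFrame(rows)
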