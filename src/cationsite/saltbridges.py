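"""Salt-bridge distance series, occupancy and orientation statistics.

A salt bridge between a basic nitrogen (e.g. lysine NZ) and a
carboxylate is considered *possible* when the nitrogen-oxygen distance
is below 4.0 Å and *formed* below 3.2 Å (both strict ``<``). With two
carboxylate oxygens (OD1/OD2, OE1/OE2) the per-frame minimum is used
and the nearer oxygen is recorded as the "oriented" one; per-oxygen
medians are computed over the frames where that oxygen is oriented,
since the two oxygens of an aspartate can alternate in facing the
nitrogen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import atom_label
from .trajectory import Selection, Trajectory, distance_array


@dataclass(frozen=True)
class SaltBridgePair:
    """Basic-side and acidic-side selections (1-2 acidic oxygens)."""

    basic: Selection
    acidic: Selection
    label: str = ""


@dataclass
class BridgeSeries:
    """Per-frame N-O distances for one basic atom against 1-2 oxygens."""

    basic_label: str
    oxygen_labels: list[str]
    per_oxygen: np.ndarray      # (F, n_ox)
    min_dist: np.ndarray        # (F,)
    oriented: np.ndarray        # (F,) index into oxygen_labels (argmin, tie -> lower)


@dataclass
class BridgeStats:
    label: str
    occupancy_formed_pct: float    # % frames min distance < formed cutoff
    occupancy_possible_pct: float  # % frames min distance < possible cutoff
    median_min: float
    quartiles_min: tuple[float, float, float]  # Q1, median, Q3 of the min series
    per_oxygen_median_oriented: dict[str, float]
    per_oxygen_occupancy_formed_pct: dict[str, float]
    oriented_fraction: dict[str, float]
    formed_cutoff: float
    possible_cutoff: float


def bridge_series(traj: Trajectory, pair: SaltBridgePair) -> list[BridgeSeries]:
    """One series per basic atom. Oriented oxygen = per-frame argmin
    (ties resolved to the lower atom index)."""
    basic_idx = pair.basic.resolve(traj.topology)
    acid_idx = pair.acidic.resolve(traj.topology)
    if basic_idx.size == 0 or acid_idx.size == 0:
        raise ConfigurationError("salt-bridge selections resolve to no atoms")
    acid_idx = np.sort(acid_idx)
    out = []
    for b in basic_idx.tolist():
        d = distance_array(traj.coords[:, b, None, :],
                           traj.coords[:, acid_idx, :], traj.box)  # (F, n_ox)
        out.append(BridgeSeries(
            basic_label=atom_label(traj, b),
            oxygen_labels=[atom_label(traj, i) for i in acid_idx.tolist()],
            per_oxygen=d,
            min_dist=d.min(axis=1),
            oriented=d.argmin(axis=1),  # np.argmin takes first (lowest index) on ties
        ))
    return out


def bridge_stats(series: BridgeSeries, formed_cutoff: float = 3.2,
                 possible_cutoff: float = 4.0) -> BridgeStats:
    """Occupancies (strict thresholds), medians and orientation breakdown.

    Medians use the standard convention: middle value for odd n, mean of
    the two middle values for even n (numpy's default).
    """
    if series.min_dist.size == 0:
        raise ConfigurationError("empty bridge series")
    mn = series.min_dist
    n = mn.size
    q1, med, q3 = np.percentile(mn, [25, 50, 75])
    per_ox_median = {}
    per_ox_formed = {}
    oriented_frac = {}
    for k, lab in enumerate(series.oxygen_labels):
        sel = series.oriented == k
        per_ox_median[lab] = float(np.median(series.per_oxygen[sel, k])) \
            if sel.any() else float("nan")
        per_ox_formed[lab] = 100.0 * float((series.per_oxygen[:, k]
                                            < formed_cutoff).mean())
        oriented_frac[lab] = float(sel.mean())
    return BridgeStats(
        label=series.basic_label + "~" + "/".join(series.oxygen_labels),
        occupancy_formed_pct=100.0 * float((mn < formed_cutoff).sum()) / n,
        occupancy_possible_pct=100.0 * float((mn < possible_cutoff).sum()) / n,
        median_min=float(med),
        quartiles_min=(float(q1), float(med), float(q3)),
        per_oxygen_median_oriented=per_ox_median,
        per_oxygen_occupancy_formed_pct=per_ox_formed,
        oriented_fraction=oriented_frac,
        formed_cutoff=formed_cutoff,
        possible_cutoff=possible_cutoff,
    )


def stats_table(stats: list[BridgeStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {"bridge": s.label,
               "occupancy_formed_pct": s.occupancy_formed_pct,
               "occupancy_possible_pct": s.occupancy_possible_pct,
               "median_min_A": s.median_min,
               "q1_A": s.quartiles_min[0], "q3_A": s.quartiles_min[2],
               "formed_cutoff_A": s.formed_cutoff,
               "possible_cutoff_A": s.possible_cutoff}
        for lab, v in s.per_oxygen_median_oriented.items():
            row[f"median_oriented[{lab}]"] = v
        for lab, v in s.oriented_fraction.items():
            row[f"oriented_fraction[{lab}]"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def series_table(series: BridgeSeries) -> pd.DataFrame:
    df = pd.DataFrame(series.per_oxygen, columns=series.oxygen_labels)
    df.insert(0, "frame", np.arange(series.per_oxygen.shape[0]))
    df["min_A"] = series.min_dist
    df["oriented"] = [series.oxygen_labels[k] for k in series.oriented]
    return df
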