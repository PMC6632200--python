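"""Synthetic data with exact, closed-form ground truth.

Two generators:

* :func:`simulate_trajectory` — Na+/K+ ions around a static 12-atom toy
  pocket (four residues labelled P71/D75/D501/K504, atom names matching
  real carbonyl/carboxylate/amine chemistry). Each ion follows an
  independent two-state Markov chain (bulk -> site with entry
  probability ``a``, site -> site with stay probability ``s``); in-site
  frames are placed inside a shell around a site atom, bulk frames
  uniformly in the box with an exclusion zone around the pocket. The
  chain gives exact closed forms: stationary occupancy ``a/(a+1-s)``
  and mean dwell ``1/(1-s)`` frames. Ions teleport rather than diffuse —
  this trades path realism for exact event statistics; an
  Ornstein-Uhlenbeck tether smooths in-site motion when a coordination
  target is set.

* :func:`simulate_recordings` — stepped-voltage current sweeps with a
  linear IV, solution-dependent reversal potential and exponential
  partial deactivation:
  ``I(t) = g (V - V_rev) [(1-f) + f e^(-t/tau)]`` at deactivating
  voltages, plus white Gaussian noise.

Both are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .tevc import (CurrentSweep, Recording, STANDARD_SOLUTIONS, SweepProtocol)
from .trajectory import AtomRecord, Topology, Trajectory

# ---------------------------------------------------------------------------
# toy pocket

#: (name, element, residue_name, residue_seq, x, y, z, is_site_atom)
#: A compact 4-residue pocket: coordinating oxygens ~2.4 Å from the site
#: center, backbone carbons further out. All heavy-atom inter-residue
#: minimum distances are well below 8 Å, so the four residues cluster
#: into a single candidate site.
_POCKET_ATOMS = [
    ("CA", "C", "PRO", 71, 25.5, 30.0, 30.0, False),
    ("O",  "O", "PRO", 71, 27.6, 30.0, 30.0, True),
    ("CA", "C", "ASP", 75, 30.0, 25.2, 30.0, False),
    ("CB", "C", "ASP", 75, 30.4, 26.3, 30.4, False),
    ("OD1", "O", "ASP", 75, 30.0, 27.6, 30.0, True),
    ("OD2", "O", "ASP", 75, 31.2, 26.8, 31.5, True),
    ("CA", "C", "ASP", 501, 34.8, 30.0, 30.2, False),
    ("CB", "C", "ASP", 501, 33.6, 29.8, 30.1, False),
    ("OD1", "O", "ASP", 501, 32.4, 30.0, 30.0, True),
    ("OD2", "O", "ASP", 501, 30.0, 30.0, 32.4, True),
    ("CA", "C", "LYS", 504, 30.0, 34.8, 30.3, False),
    ("NZ", "N", "LYS", 504, 30.0, 32.4, 30.0, True),
]


def toy_pocket_topology(n_na: int = 6, n_k: int = 6) -> tuple[Topology, np.ndarray,
                                                              np.ndarray]:
    """The 12-atom pocket plus ion atoms.

    Returns (topology, protein_coords (12,3), site_atom_indices).
    """
    atoms = []
    coords = []
    site_idx = []
    for i, (name, el, resn, resseq, x, y, z, is_site) in enumerate(_POCKET_ATOMS):
        atoms.append(AtomRecord(serial=i + 1, name=name, element=el,
                                residue_name=resn, residue_seq=resseq, chain="A"))
        coords.append((x, y, z))
        if is_site:
            site_idx.append(i)
    serial = len(atoms) + 1
    ion_sets: dict[str, list[int]] = {"Na": [], "K": []}
    for sp, resn, count in (("Na", "NA", n_na), ("K", "K", n_k)):
        for j in range(count):
            ion_sets[sp].append(len(atoms))
            atoms.append(AtomRecord(serial=serial, name=resn, element=sp,
                                    residue_name=resn, residue_seq=1000 + serial,
                                    chain="I"))
            serial += 1
    top = Topology(atoms=atoms, ion_sets={k: v for k, v in ion_sets.items() if v})
    return top, np.array(coords, dtype=float), np.array(site_idx, dtype=int)


# ---------------------------------------------------------------------------
# ion-trajectory generator

@dataclass(frozen=True)
class TrajSimConfig:
    """Study conditions for the synthetic ion trajectory.

    Defaults mirror the simulated system the analyses were designed for:
    six ions of each species around one pocket, entry probability
    ``a = 0.02`` per bulk frame and stay probability ``s = 0.9`` per
    in-site frame (stationary occupancy 1/6, mean dwell 10 frames).
    """

    box: tuple[float, float, float] = (60.0, 60.0, 60.0)
    n_frames: int = 5000
    n_na: int = 6
    n_k: int = 6
    entry_prob: float = 0.02
    stay_prob: float = 0.9
    site_shell: tuple[float, float] = (2.0, 3.5)   # Å around a site atom
    bulk_exclusion: float = 6.0                    # Å from any pocket atom
    coordination: dict[str, tuple[float, float]] | None = None
    # atom label -> (mu, sigma) Å: in-site placement at Gaussian radius
    # from that atom instead of the uniform shell
    ou_tether: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        r_min, r_max = self.site_shell
        if not (0 < r_min <= r_max):
            raise ConfigurationError("site_shell needs 0 < r_min <= r_max")
        if not (0 < self.entry_prob < 1 and 0 < self.stay_prob < 1):
            raise ConfigurationError("probabilities must lie in (0, 1)")
        if r_max > min(self.box) / 2:
            raise ConfigurationError("site shell does not fit inside the box")


@dataclass
class TrajGroundTruth:
    """True per-ion occupancy plus the chain's closed-form expectations."""

    masks: dict[int, np.ndarray]          # ion atom index -> bool per frame
    entry_prob: float
    stay_prob: float
    site_atom_labels: list[str] = field(default_factory=list)
    coordinating_atom: dict[int, str] = field(default_factory=dict)

    @property
    def stationary_occupancy(self) -> float:
        a, s = self.entry_prob, self.stay_prob
        return a / (a + 1.0 - s)

    @property
    def mean_dwell_frames(self) -> float:
        return 1.0 / (1.0 - self.stay_prob)

    def expected_approaches(self, n_frames: int) -> float:
        """Expected maximal-run count per ion (stationary start)."""
        pi = self.stationary_occupancy
        return pi + (n_frames - 1) * (1.0 - pi) * self.entry_prob


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_trajectory(config: TrajSimConfig) -> tuple[Trajectory, TrajGroundTruth]:
    """Generate a trajectory whose true occupancy equals the geometric mask.

    In-site frames are guaranteed within the site shell (<= r_max) of a
    site atom; bulk frames are rejected until farther than
    ``bulk_exclusion`` from every pocket atom. With ``r_max`` at or
    below the intended contact cutoff and ``bulk_exclusion`` above it,
    the generated mask and the distance-based mask coincide exactly.
    """
    rng = np.random.default_rng(config.seed)
    top, prot_xyz, site_idx = toy_pocket_topology(config.n_na, config.n_k)
    from .geometry import atom_label  # local import avoids a cycle

    site_labels = [atom_label(top, i) for i in site_idx.tolist()]
    label_to_xyz = {atom_label(top, i): prot_xyz[i] for i in site_idx.tolist()}
    box = np.array(config.box, dtype=float)
    n_ions = config.n_na + config.n_k
    ion_atom_idx = top.ion_indices()
    F = config.n_frames

    coords = np.empty((F, top.n_atoms, 3), dtype=float)
    coords[:, :prot_xyz.shape[0], :] = prot_xyz[None, :, :]

    a, s = config.entry_prob, config.stay_prob
    pi = a / (a + 1.0 - s)
    masks: dict[int, np.ndarray] = {}
    coordinating: dict[int, str] = {}

    coord_labels = list(config.coordination) if config.coordination else []
    for k, ion_idx in enumerate(ion_atom_idx):
        state = np.empty(F, dtype=bool)
        state[0] = rng.random() < pi
        u = rng.random(F - 1)
        for f in range(1, F):
            state[f] = (u[f - 1] < s) if state[f - 1] else (u[f - 1] < a)
        masks[ion_idx] = state

        xyz = np.empty((F, 3), dtype=float)
        in_idx = np.flatnonzero(state)
        if coord_labels:
            lab = coord_labels[k % len(coord_labels)]
            coordinating[ion_idx] = lab
            mu, sigma = config.coordination[lab]
            center = label_to_xyz.get(lab)
            if center is None:
                raise ConfigurationError(f"unknown coordination atom {lab!r}")
            if config.ou_tether and in_idx.size:
                r = _ou_radii(rng, in_idx, mu, sigma)
            else:
                r = np.abs(rng.normal(mu, sigma, size=in_idx.size))
            xyz[in_idx] = center + _uniform_sphere(rng, in_idx.size) * r[:, None]
        elif in_idx.size:
            which = rng.integers(0, site_idx.size, size=in_idx.size)
            r_min, r_max = config.site_shell
            # uniform in the shell volume
            r = (rng.random(in_idx.size) * (r_max**3 - r_min**3) + r_min**3) ** (1 / 3)
            centers = prot_xyz[site_idx[which]]
            xyz[in_idx] = centers + _uniform_sphere(rng, in_idx.size) * r[:, None]

        out_idx = np.flatnonzero(~state)
        need = out_idx.size
        placed = np.empty((0, 3))
        while placed.shape[0] < need:
            cand = rng.random((max(64, 2 * need), 3)) * box
            d = np.linalg.norm(cand[:, None, :] - prot_xyz[None, :, :], axis=2)
            ok = cand[d.min(axis=1) > config.bulk_exclusion]
            placed = np.vstack([placed, ok])
        xyz[out_idx] = placed[:need]
        coords[:, ion_idx, :] = xyz

    traj = Trajectory(topology=top, coords=coords, box=box,
                      replicate_id=f"sim-seed{config.seed}")
    truth = TrajGroundTruth(masks=masks, entry_prob=a, stay_prob=s,
                            site_atom_labels=site_labels,
                            coordinating_atom=coordinating)
    return traj, truth


def _ou_radii(rng: np.random.Generator, in_idx: np.ndarray, mu: float,
              sigma: float, theta: float = 0.3) -> np.ndarray:
    """Mean-reverting radius sequence with stationary N(mu, sigma)."""
    n = in_idx.size
    r = np.empty(n)
    r[0] = rng.normal(mu, sigma)
    innov = sigma * np.sqrt(1 - (1 - theta) ** 2)
    for i in range(1, n):
        fresh = in_idx[i] != in_idx[i - 1] + 1  # new visit: resample
        if fresh:
            r[i] = rng.normal(mu, sigma)
        else:
            r[i] = mu + (1 - theta) * (r[i - 1] - mu) + rng.normal(0, innov)
    return np.abs(r)


# ---------------------------------------------------------------------------
# TEVC generator

@dataclass(frozen=True)
class SolutionSim:
    """Per-solution generator parameters."""

    conductance: float          # µA per mV (chord conductance)
    vrev: float                 # mV
    deact_fraction: float = 0.0  # f in [0, 1): steady-state loss fraction
    tau: float = 0.2            # s
    noise_sd: float = 0.01      # µA

    def __post_init__(self) -> None:
        if not 0 <= self.deact_fraction < 1:
            raise ConfigurationError("deactivating fraction must be in [0, 1)")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")


@dataclass(frozen=True)
class TevcSimConfig:
    protocol: SweepProtocol = SweepProtocol()
    solutions: dict[str, SolutionSim] = None  # label -> parameters
    sample_rate: float = 2000.0               # Hz
    n_cells: int = 3
    cell_gain_sd: float = 0.1                 # lognormal-ish gain spread
    deact_threshold: float | None = None      # mV; None -> each solution's V_rev
    seed: int = 0

    def __post_init__(self) -> None:
        if self.solutions is None:
            object.__setattr__(self, "solutions", default_solution_presets())


def _exp_window_means(tau: float, settle: float, window: float, pulse: float,
                      sample_rate: float | None) -> tuple[float, float]:
    """Means of ``e^(-t/tau)`` over the begin and end analysis windows.

    With ``sample_rate`` the mean is taken over exactly the sample grid
    the measurement uses (same boolean selection as ``window_currents``);
    without it, the continuous-time integral mean.
    """
    if sample_rate is None:
        cont = lambda t0, t1: tau / (t1 - t0) * (np.exp(-t0 / tau)
                                                 - np.exp(-t1 / tau))
        return cont(settle, settle + window), cont(pulse - window, pulse)
    n = int(round(pulse * sample_rate))
    t = np.arange(n) / sample_rate
    ex = np.exp(-t / tau)
    begin = (t >= settle) & (t < settle + window)
    end = t >= pulse - window
    return float(ex[begin].mean()), float(ex[end].mean())


def analytic_deactivation_pct(f: float, tau: float, settle: float = 0.025,
                              window: float = 0.025, pulse: float = 1.0,
                              sample_rate: float | None = None) -> float:
    """Closed-form percent reduction between the begin and end window means
    of ``(1-f) + f e^(-t/tau)``."""
    mb, me = _exp_window_means(tau, settle, window, pulse, sample_rate)
    b = (1.0 - f) + f * mb
    e = (1.0 - f) + f * me
    return (b - e) / b * 100.0


def deact_fraction_for_reduction(reduction_pct: float, tau: float = 0.2,
                                 settle: float = 0.025, window: float = 0.025,
                                 pulse: float = 1.0,
                                 sample_rate: float | None = 2000.0) -> float:
    """Invert :func:`analytic_deactivation_pct` for the model fraction f.

    The published observable is the measured begin-to-end reduction; the
    generator parameter f is derived from it so that the simulated
    observable equals the stated one at the default analysis windows.
    """
    p = reduction_pct / 100.0
    mb, me = _exp_window_means(tau, settle, window, pulse, sample_rate)
    return p / (mb - me + p * (1.0 - mb))


#: Measured begin-to-end current reductions (%) the presets reproduce.
WT_DEACTIVATION_PCT = {"Na30K0": 12.0, "Na30K1": 10.7, "Na30K30": 3.2}


def default_solution_presets() -> dict[str, SolutionSim]:
    """Wild-type-like presets for the seven standard bath solutions.

    Conductances scale ~5x over the 0.3 -> 30 mM Na range and nearly
    double with 1 mM K; V_rev values are anchored at about -45 mV for
    Na30K1 (the zero-current holding level) and spaced
    semilogarithmically in Na. Deactivating fractions reproduce the
    measured reductions in :data:`WT_DEACTIVATION_PCT`.
    """
    f = {k: deact_fraction_for_reduction(v) for k, v in WT_DEACTIVATION_PCT.items()}
    return {
        "Na03K0": SolutionSim(conductance=0.006, vrev=-95.0),
        "Na03K1": SolutionSim(conductance=0.011, vrev=-90.0),
        "Na30K0": SolutionSim(conductance=0.030, vrev=-50.0,
                              deact_fraction=f["Na30K0"]),
        "Na30K1": SolutionSim(conductance=0.055, vrev=-45.0,
                              deact_fraction=f["Na30K1"]),
        "Na30K30": SolutionSim(conductance=0.032, vrev=-25.0,
                               deact_fraction=f["Na30K30"]),
        "Na0K1": SolutionSim(conductance=0.0015, vrev=-30.0),
        "Na0K30": SolutionSim(conductance=0.0020, vrev=-15.0),
    }


def simulate_recordings(config: TevcSimConfig) -> tuple[list[Recording], dict]:
    """Generate recordings for every (cell, solution) pair plus ground truth."""
    rng = np.random.default_rng(config.seed)
    proto = config.protocol
    n_samp = int(round(proto.pulse_duration * config.sample_rate))
    t = np.arange(n_samp) / config.sample_rate
    recordings = []
    for c in range(config.n_cells):
        gain = float(np.exp(rng.normal(0.0, config.cell_gain_sd))) \
            if config.cell_gain_sd > 0 else 1.0
        for label, sol in config.solutions.items():
            na_mm, k_mm = STANDARD_SOLUTIONS.get(label, (np.nan, np.nan))
            sweeps = {}
            for v in proto.voltages:
                i_peak = gain * sol.conductance * (v - sol.vrev)
                thr = config.deact_threshold if config.deact_threshold is not None \
                    else sol.vrev
                if sol.deact_fraction > 0 and v < thr:
                    factor = (1.0 - sol.deact_fraction) \
                        + sol.deact_fraction * np.exp(-t / sol.tau)
                else:
                    factor = np.ones_like(t)
                trace = i_peak * factor
                if sol.noise_sd > 0:
                    trace = trace + rng.normal(0.0, sol.noise_sd, size=n_samp)
                sweeps[float(v)] = CurrentSweep(step_voltage=float(v),
                                                samples=trace,
                                                sample_rate=config.sample_rate)
            recordings.append(Recording(solution=label, na_mm=na_mm, k_mm=k_mm,
                                        sweeps=sweeps, cell_id=f"cell{c + 1}"))
    truth = {
        label: {"conductance": sol.conductance, "vrev": sol.vrev,
                "deact_fraction": sol.deact_fraction, "tau": sol.tau,
                "analytic_deactivation_pct": analytic_deactivation_pct(
                    sol.deact_fraction, sol.tau, pulse=proto.pulse_duration)}
        for label, sol in config.solutions.items()
    }
    return recordings, truth
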