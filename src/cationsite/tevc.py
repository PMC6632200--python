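"""Two-electrode voltage-clamp (TEVC) current-trace analysis.

Covers the standard oocyte workflow for a stepped-voltage protocol
(+20 to -160 mV in -15 mV decrements, 1 s pulses by default):

* window currents at the beginning/end of the pulse and the pulse
  average (short window means are used rather than single samples for
  noise robustness);
* percent deactivation, ``(|I_begin| - |I_end|) / |I_begin| x 100``;
* IV-curve assembly with per-cell normalization to a reference
  (solution, voltage) point, means and SDs across cells;
* reversal potential by linear interpolation of the zero-current
  crossing;
* semilogarithmic fit of V_rev against ion concentration, reported next
  to the ideal Nernst slope ``(RT/F) ln 10`` at the configured
  temperature (58.6 mV/decade at 22 °C).

Units: current µA, voltage mV, concentration mM, time s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, NormalizationError

R_GAS = 8.314462618      # J / (mol K)
FARADAY = 96485.33212    # C / mol

#: Standard bath solutions: label -> (Na mM, K mM).
STANDARD_SOLUTIONS: dict[str, tuple[float, float]] = {
    "Na0K1": (0.0, 1.0), "Na0K30": (0.0, 30.0),
    "Na03K0": (0.3, 0.0), "Na03K1": (0.3, 1.0),
    "Na30K0": (30.0, 0.0), "Na30K1": (30.0, 1.0), "Na30K30": (30.0, 30.0),
}


def nernst_slope(temperature_c: float = 22.0) -> float:
    """Ideal slope (mV per decade of concentration) at the given T (°C)."""
    return R_GAS * (temperature_c + 273.15) / FARADAY * np.log(10.0) * 1000.0


@dataclass(frozen=True)
class SweepProtocol:
    start_voltage: float = 20.0      # mV
    decrement: float = -15.0         # mV
    n_steps: int = 13
    pulse_duration: float = 1.0      # s
    inter_pulse: float = 1.5         # s

    @property
    def voltages(self) -> np.ndarray:
        return self.start_voltage + self.decrement * np.arange(self.n_steps)


@dataclass
class CurrentSweep:
    """Samples (µA) covering one voltage pulse at a fixed sample rate."""

    step_voltage: float
    samples: np.ndarray
    sample_rate: float               # Hz
    pulse_window: tuple[int, int] | None = None  # sample slice [i0, i1)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.pulse_window is None:
            self.pulse_window = (0, self.samples.size)
        i0, i1 = self.pulse_window
        if not (0 <= i0 < i1 <= self.samples.size):
            raise ConfigurationError("pulse window outside the sample range")

    @property
    def pulse_duration(self) -> float:
        i0, i1 = self.pulse_window
        return (i1 - i0) / self.sample_rate


@dataclass
class Recording:
    """All sweeps of one protocol run on one cell in one solution."""

    solution: str
    na_mm: float
    k_mm: float
    sweeps: dict[float, CurrentSweep]
    cell_id: str = "cell1"
    date: str = ""

    def sweep_at(self, voltage: float) -> CurrentSweep:
        for v, s in self.sweeps.items():
            if abs(v - voltage) < 1e-6:
                return s
        raise ConfigurationError(
            f"no sweep at {voltage} mV in recording {self.cell_id}/{self.solution}")


def window_currents(sweep: CurrentSweep, settle: float = 0.025,
                    window: float = 0.025) -> tuple[float, float, float]:
    """(I_begin, I_end, I_avg) window means in µA.

    I_begin averages ``[settle, settle+window)`` after pulse onset
    (skipping the capacitive transient), I_end the last ``window``
    seconds of the pulse, I_avg everything from ``settle`` to pulse end.
    """
    i0, i1 = sweep.pulse_window
    dur = sweep.pulse_duration
    if settle + window > dur + 1e-12:
        raise ConfigurationError("settle + window exceeds the pulse duration")
    t = (np.arange(i0, i1) - i0) / sweep.sample_rate
    pulse = sweep.samples[i0:i1]
    begin_sel = (t >= settle) & (t < settle + window)
    end_sel = t >= dur - window
    avg_sel = t >= settle
    for name, sel in (("begin", begin_sel), ("end", end_sel), ("avg", avg_sel)):
        if not sel.any():
            raise ConfigurationError(
                f"{name} window contains no samples at {sweep.sample_rate} Hz")
    return (float(pulse[begin_sel].mean()), float(pulse[end_sel].mean()),
            float(pulse[avg_sel].mean()))


def deactivation_pct(i_begin: float, i_end: float) -> float | None:
    """Percent current reduction from pulse start to end (via magnitudes).

    Undefined (None) when the initial current is zero.
    """
    if i_begin == 0:
        return None
    return (abs(i_begin) - abs(i_end)) / abs(i_begin) * 100.0


def deactivation_table(recordings: list[Recording], voltage: float = -145.0,
                       settle: float = 0.025, window: float = 0.025) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        ib, ie, ia = window_currents(rec.sweep_at(voltage), settle, window)
        rows.append({"cell": rec.cell_id, "solution": rec.solution,
                     "voltage_mV": voltage, "I_begin_uA": ib, "I_end_uA": ie,
                     "I_avg_uA": ia,
                     "deactivation_pct": deactivation_pct(ib, ie)})
    return pd.DataFrame(rows)


_STATISTICS = ("begin", "end", "avg")


def build_iv(recordings: list[Recording], statistic: str = "avg",
             normalize_to: tuple[str, float] | None = ("Na30K1", -145.0),
             settle: float = 0.025, window: float = 0.025) -> pd.DataFrame:
    """Per-solution IV curves: mean and SD of normalized currents across cells.

    Normalization is per cell: every current of a cell is divided by the
    magnitude of that cell's current at the reference (solution, voltage)
    point, so the result is invariant to a global gain on any one cell's
    recordings. Columns: solution, voltage_mV, mean, sd, n.
    """
    if statistic not in _STATISTICS:
        raise ConfigurationError(f"statistic must be one of {_STATISTICS}")
    pick = _STATISTICS.index(statistic)

    def stat(rec: Recording, v: float) -> float:
        return window_currents(rec.sweep_at(v), settle, window)[pick]

    by_cell: dict[str, list[Recording]] = {}
    for rec in recordings:
        by_cell.setdefault(rec.cell_id, []).append(rec)

    points: dict[tuple[str, float], list[float]] = {}
    for cell, recs in by_cell.items():
        scale = 1.0
        if normalize_to is not None:
            ref_sol, ref_v = normalize_to
            refs = [r for r in recs if r.solution == ref_sol]
            if not refs:
                raise NormalizationError(
                    f"cell {cell!r} has no recording in reference solution "
                    f"{ref_sol!r}")
            scale = abs(stat(refs[0], ref_v))
            if scale == 0:
                raise NormalizationError(
                    f"cell {cell!r}: reference current at {ref_v} mV is zero")
        for rec in recs:
            for v in sorted(rec.sweeps):
                points.setdefault((rec.solution, v), []).append(
                    stat(rec, v) / scale)

    rows = [{"solution": sol, "voltage_mV": v,
             "mean": float(np.mean(vals)),
             "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
             "n": len(vals)}
            for (sol, v), vals in sorted(points.items())]
    return pd.DataFrame(rows)


def estimate_vrev(voltages: np.ndarray, currents: np.ndarray) -> float | None:
    """Reversal potential (mV) by linear interpolation at the zero crossing.

    With several crossings the one at the least-negative voltage is
    returned (with a warning); returns None with a diagnostic warning
    when the IV never changes sign.
    """
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]

    crossings = []
    for k in range(v.size):
        if i[k] == 0.0:
            crossings.append(float(v[k]))
    for k in range(v.size - 1):
        if i[k] * i[k + 1] < 0:
            crossings.append(float(v[k] - i[k] * (v[k + 1] - v[k])
                                   / (i[k + 1] - i[k])))
    if not crossings:
        warnings.warn("IV curve has no zero crossing; V_rev undetermined")
        return None
    crossings = sorted(set(crossings))
    if len(crossings) > 1:
        warnings.warn(f"multiple zero crossings {crossings}; using the one at "
                      "the least-negative voltage")
    return crossings[-1]


@dataclass
class ReversalFit:
    slope: float            # mV / decade
    intercept: float        # mV
    residuals: np.ndarray   # mV
    temperature_c: float
    ideal_slope: float = field(init=False)

    def __post_init__(self) -> None:
        self.ideal_slope = nernst_slope(self.temperature_c)

    def predict(self, conc_mm) -> np.ndarray:
        return self.slope * np.log10(np.asarray(conc_mm, dtype=float)) \
            + self.intercept


def fit_vrev_semilog(points: list[tuple[float, float]],
                     temperature_c: float = 22.0) -> ReversalFit:
    """Least-squares fit of ``V_rev = slope * log10(c) + intercept``.

    ``points`` are (concentration mM, V_rev mV) pairs; all
    concentrations must be positive and at least two must be distinct.
    """
    conc = np.array([p[0] for p in points], dtype=float)
    vrev = np.array([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ConfigurationError("concentrations must be positive for a log fit")
    x = np.log10(conc)
    if np.unique(x).size < 2:
        raise ConfigurationError("need at least two distinct concentrations")
    res = sps.linregress(x, vrev)
    fitted = res.slope * x + res.intercept
    return ReversalFit(slope=float(res.slope), intercept=float(res.intercept),
                       residuals=vrev - fitted, temperature_c=temperature_c)


# ---------------------------------------------------------------------------
# CSV + manifest I/O

def write_recording(rec: Recording, directory, protocol: SweepProtocol) -> Path:
    """Write one CSV per sweep plus a manifest JSON; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for v in sorted(rec.sweeps, reverse=True):
        s = rec.sweeps[v]
        fname = f"{rec.cell_id}_{rec.solution}_{int(round(v)):+d}mV.csv"
        t = np.arange(s.samples.size) / s.sample_rate
        pd.DataFrame({"time_s": t, "current_uA": s.samples}).to_csv(
            directory / fname, index=False, float_format="%.6f")
        entries.append({"voltage_mV": v, "file": fname,
                        "sample_rate_hz": s.sample_rate,
                        "pulse_window": list(s.pulse_window)})
    manifest = {
        "solution": rec.solution, "na_mm": rec.na_mm, "k_mm": rec.k_mm,
        "cell_id": rec.cell_id, "date": rec.date,
        "protocol": {
            "start_voltage": protocol.start_voltage,
            "decrement": protocol.decrement, "n_steps": protocol.n_steps,
            "pulse_duration": protocol.pulse_duration,
            "inter_pulse": protocol.inter_pulse,
        },
        "sweeps": entries,
    }
    mpath = directory / f"{rec.cell_id}_{rec.solution}_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath


def read_recording(manifest_path) -> tuple[Recording, SweepProtocol]:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        m = json.load(fh)
    proto = SweepProtocol(**m["protocol"])
    sweeps = {}
    for e in m["sweeps"]:
        df = pd.read_csv(manifest_path.parent / e["file"])
        sweeps[float(e["voltage_mV"])] = CurrentSweep(
            step_voltage=float(e["voltage_mV"]),
            samples=df["current_uA"].to_numpy(),
            sample_rate=float(e["sample_rate_hz"]),
            pulse_window=tuple(e["pulse_window"]))
    rec = Recording(solution=m["solution"], na_mm=m["na_mm"], k_mm=m["k_mm"],
                    sweeps=sweeps, cell_id=m["cell_id"], date=m.get("date", ""))
    return rec, proto
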