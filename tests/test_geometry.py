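"""Ion-atom distance series, in-site statistics and coordination calls."""

import numpy as np
import pytest

from cationsite.errors import ConfigurationError
from cationsite.events import OccupancyMask
from cationsite.geometry import (
    CoordinationStats, coordination_call, distance_series, in_site_stats)
from cationsite.synthetic import TrajSimConfig, simulate_trajectory
from cationsite.trajectory import Selection, distance

from conftest import single_ion_residue_traj


def all_true_mask(n, ion=1):
    return OccupancyMask(ion_index=ion, site_name="s", mask=np.ones(n, dtype=bool))


def test_constant_separation_gives_constant_series():
    traj = single_ion_residue_traj([2.38] * 5)
    series = distance_series(traj, 1, Selection.of(residue_seq={1}))
    assert len(series) == 1
    np.testing.assert_allclose(series[0].distances, 2.38)
    assert series[0].species == "Na"
    assert series[0].atom_label == "G1:CA"


def test_series_rejects_the_ion_itself():
    traj = single_ion_residue_traj([3.0])
    with pytest.raises(ConfigurationError, match="ion itself"):
        distance_series(traj, 1, np.array([0, 1]))


def test_series_matches_per_frame_bruteforce(rng):
    traj, _ = simulate_trajectory(TrajSimConfig(n_frames=150, seed=2))
    ion = traj.topology.ion_sets["Na"][0]
    sel = Selection.of(atom_name={"O", "OD1", "OD2", "NZ"})
    for s in distance_series(traj, ion, sel):
        for f in (0, 17, 149):
            expected = distance(traj.coords[f, ion],
                                traj.coords[f, s.atom_index], traj.box)
            assert s.distances[f] == pytest.approx(expected)


def test_in_site_stats_population_and_sample_sd():
    traj = single_ion_residue_traj([2.0, 3.0])
    s = distance_series(traj, 1, Selection.of(residue_seq={1}))[0]
    stats = in_site_stats(s, all_true_mask(2))
    assert stats.mean_distance == pytest.approx(2.5)
    assert stats.sd_distance == pytest.approx(0.5)  # population convention
    sample = in_site_stats(s, all_true_mask(2), sample_sd=True)
    assert sample.sd_distance == pytest.approx(np.sqrt(0.5))


def test_constant_series_has_zero_sd():
    traj = single_ion_residue_traj([2.38] * 8)
    s = distance_series(traj, 1, Selection.of(residue_seq={1}))[0]
    stats = in_site_stats(s, all_true_mask(8))
    assert stats.mean_distance == pytest.approx(2.38)
    assert stats.sd_distance == 0.0


def test_no_in_site_frames_withholds_stats():
    traj = single_ion_residue_traj([2.0, 3.0])
    s = distance_series(traj, 1, Selection.of(residue_seq={1}))[0]
    empty = OccupancyMask(1, "s", np.zeros(2, dtype=bool))
    with pytest.warns(UserWarning, match="no in-site frames"):
        assert in_site_stats(s, empty) is None


def test_submask_never_uses_more_frames(rng):
    traj, truth = simulate_trajectory(TrajSimConfig(n_frames=500, seed=3))
    ion = traj.topology.ion_sets["Na"][0]
    s = distance_series(traj, ion, Selection.of(atom_name={"O"}))[0]
    full = OccupancyMask(ion, "s", np.ones(500, dtype=bool))
    sub = OccupancyMask(ion, "s", truth.masks[ion])
    n_sub = in_site_stats(s, sub).n_frames_used if truth.masks[ion].any() else 0
    assert n_sub <= in_site_stats(s, full).n_frames_used


def test_gaussian_coordination_distance_recovered():
    cfg = TrajSimConfig(n_frames=11000, n_na=1, n_k=0, entry_prob=0.5,
                        stay_prob=0.98, coordination={"P71:O": (2.4, 0.15)},
                        seed=101)
    traj, truth = simulate_trajectory(cfg)
    ion = traj.topology.ion_sets["Na"][0]
    mask = OccupancyMask(ion, "site", truth.masks[ion])
    assert mask.mask.sum() > 10000
    s = [x for x in distance_series(traj, ion, Selection.of(atom_name={"O"}))
         if x.atom_label == "P71:O"][0]
    stats = in_site_stats(s, mask)
    assert stats.mean_distance == pytest.approx(2.4, abs=0.01)
    assert stats.sd_distance == pytest.approx(0.15, rel=0.10)


def make_stats(fraction, n=1000, label="X:O", species="Na", proximity=2.6):
    return CoordinationStats(atom_label=label, species=species,
                             mean_distance=2.4, sd_distance=0.1,
                             n_frames_used=n, fraction_below_proximity=fraction,
                             proximity=proximity)


def test_coordination_call_thresholds():
    assert coordination_call(make_stats(0.9)).is_coordinating
    assert not coordination_call(make_stats(0.0, label="K504:NZ"),
                                 positively_charged=True).is_coordinating
    # boundary is inclusive
    assert coordination_call(make_stats(0.25)).is_coordinating
    assert not coordination_call(make_stats(0.2499999)).is_coordinating


def test_call_withheld_below_minimum_frames():
    with pytest.warns(UserWarning, match="withheld"):
        assert coordination_call(make_stats(0.9, n=10)) is None


@pytest.mark.parametrize("seed", range(20))
def test_planted_atom_called_spectator_rejected(seed):
    """Exactly the planted coordinating atom passes; a pocket atom ~5 Å
    away never does."""
    cfg = TrajSimConfig(n_frames=2500, n_na=1, n_k=0, entry_prob=0.5,
                        stay_prob=0.95, coordination={"P71:O": (2.4, 0.15)},
                        seed=1000 + seed)
    traj, truth = simulate_trajectory(cfg)
    ion = traj.topology.ion_sets["Na"][0]
    mask = OccupancyMask(ion, "site", truth.masks[ion])
    series = distance_series(traj, ion,
                             Selection.of(atom_name={"O", "OD1"}))
    calls = {}
    for s in series:
        st = in_site_stats(s, mask)
        calls[s.atom_label] = coordination_call(st).is_coordinating
    assert calls["P71:O"] is True
    assert calls["D501:OD1"] is False  # 4.8 Å from the planted center
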