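"""Contact-frequency tables: counting conventions, merging, site finding."""

import numpy as np
import pandas as pd
import pytest

from cationsite.contacts import (
    ContactParameters, combine_species, count_contacts, identify_candidate_sites,
    merge_replicates)
from cationsite.errors import ConfigurationError, MergeError
from cationsite.reference import reference_contact_counts
from cationsite.synthetic import TrajSimConfig, simulate_trajectory
from cationsite.trajectory import Trajectory, distance

from conftest import make_topology, make_trajectory, single_ion_residue_traj


def brute_force_contacts(traj, cutoff=4.0, counting="ion_frame_pairs",
                         heavy_only=True):
    """Independent all-pairs recount: plain loops over frames/ions/atoms."""
    top = traj.topology
    out = {}
    for key, idx in top.protein_residues().items():
        atoms = [i for i in idx if not heavy_only or not top.atoms[i].is_hydrogen]
        if not atoms:
            continue
        per_species = {}
        for sp, ions in top.ion_sets.items():
            n = 0
            for f in range(traj.n_frames):
                hits = 0
                for ion in ions:
                    dmin = min(distance(traj.coords[f, ion], traj.coords[f, a],
                                        traj.box) for a in atoms)
                    if dmin <= cutoff:
                        hits += 1
                n += hits if counting == "ion_frame_pairs" else (1 if hits else 0)
            per_species[sp] = n
        out[key] = per_species
    return out


def test_direct_count_with_inclusive_boundary():
    traj = single_ion_residue_traj([3.9, 4.1, 2.0])
    table = count_contacts(traj)
    key = ("A", 1, "GLY")
    assert table.counts.loc[key, "Na"] == 2
    assert table.relative().loc[key, "Na"] == pytest.approx(66.6667, abs=1e-3)


def test_ion_never_within_cutoff_gives_zero_row():
    traj = single_ion_residue_traj([8.0, 9.0, 10.0])
    table = count_contacts(traj)
    assert int(table.counts.sum().sum()) == 0
    assert float(table.relative().sum().sum()) == 0.0


def test_no_ions_is_a_configuration_error(rng):
    top = make_topology(rng, n_na=0, n_k=0)
    traj = make_trajectory(rng, top)
    with pytest.raises(ConfigurationError, match="no ions"):
        count_contacts(traj)


@pytest.mark.parametrize("counting", ["ion_frame_pairs", "any_ion_per_frame"])
@pytest.mark.parametrize("boxed", [False, True])
def test_counts_match_allpairs_bruteforce(rng, counting, boxed):
    for _ in range(4):
        top = make_topology(rng, n_residues=int(rng.integers(2, 6)),
                            n_na=2, n_k=2)
        box = np.array([12.0, 14.0, 16.0]) if boxed else None
        traj = make_trajectory(rng, top, n_frames=int(rng.integers(5, 40)),
                               box=box, spread=18.0)
        params = ContactParameters(cutoff=4.0, counting=counting)
        table = count_contacts(traj, params)
        oracle = brute_force_contacts(traj, counting=counting)
        for key, per_species in oracle.items():
            for sp, n in per_species.items():
                assert table.counts.loc[key, sp] == n, (key, sp)


def test_count_monotone_in_cutoff(rng):
    top = make_topology(rng)
    traj = make_trajectory(rng, top, n_frames=30)
    small = count_contacts(traj, ContactParameters(cutoff=3.0))
    large = count_contacts(traj, ContactParameters(cutoff=6.0))
    assert (large.counts.values >= small.counts.values).all()


def test_merge_sums_counts_and_recomputes_relatives():
    t1 = single_ion_residue_traj([2.0] * 10 + [9.0] * 90)
    tables = [count_contacts(t1) for _ in range(3)]
    merged = merge_replicates(tables)
    key = ("A", 1, "GLY")
    assert merged.counts.loc[key, "Na"] == 30
    assert merged.n_frames == 300
    assert merged.relative().loc[key, "Na"] == pytest.approx(10.0)
    # merging a single table is the identity
    alone = merge_replicates([tables[0]])
    pd.testing.assert_frame_equal(alone.counts, tables[0].counts)


def test_merge_equals_recount_over_concatenated_trajectories(rng):
    top = make_topology(rng)
    t1 = make_trajectory(rng, top, n_frames=25)
    t2 = make_trajectory(rng, top, n_frames=35)
    merged = merge_replicates([count_contacts(t1), count_contacts(t2)])
    concat = Trajectory(topology=top,
                        coords=np.concatenate([t1.coords, t2.coords]))
    recount = count_contacts(concat)
    pd.testing.assert_frame_equal(merged.counts, recount.counts)
    assert merged.n_frames == recount.n_frames


def test_merge_rejects_mismatched_residue_keys(rng):
    top_a = make_topology(rng, n_residues=3)
    top_b = make_topology(rng, n_residues=4)
    ta = count_contacts(make_trajectory(rng, top_a))
    tb = count_contacts(make_trajectory(rng, top_b))
    with pytest.raises(MergeError, match="residue keys differ"):
        merge_replicates([ta, tb])


def test_combined_species_column_reproduces_published_sums():
    table, published = reference_contact_counts()
    combined = combine_species(table)
    assert (combined.combined == published["sum_abs"]).all()
    # relative arithmetic at printed precision: rounded Na% + rounded K%
    rel = combined.relative().round(2)
    assert (rel["Na"] + rel["K"]).round(2).equals(published["sum_rel"])
    # spot rows
    assert combined.combined.loc[("A", 69, "PHE")] == 76
    assert combined.combined.loc[("A", 70, "LYS")] == 579


def test_combine_single_species_equals_that_species():
    traj = single_ion_residue_traj([2.0, 9.0])
    t = combine_species(count_contacts(traj))
    assert (t.combined == t.counts["Na"]).all()


def test_combine_and_merge_commute(rng):
    top = make_topology(rng)
    tables = [count_contacts(make_trajectory(rng, top, n_frames=15))
              for _ in range(2)]
    a = combine_species(merge_replicates(tables))
    b = merge_replicates([combine_species(t) for t in tables])
    assert a.combined.equals(b.combined)


def test_candidate_site_recovery_from_planted_attractor():
    traj, truth = simulate_trajectory(TrajSimConfig(n_frames=3000, seed=11))
    table = combine_species(count_contacts(traj))
    sites = identify_candidate_sites(table, traj.topology, traj.coords[0],
                                     rel_threshold=1.0, link_cutoff=8.0,
                                     box=traj.box)
    assert len(sites) == 1
    assert sites[0].name == "P71-D75-D501-K504"


def test_distant_clusters_stay_separate_sites(rng):
    # two 2-residue clusters 30 Å apart, both above threshold
    from cationsite.contacts import ContactTable
    from cationsite.trajectory import AtomRecord, Topology

    atoms, coords = [], []
    for r, (seq, base) in enumerate([(1, 0.0), (2, 4.0), (10, 30.0), (11, 34.0)]):
        atoms.append(AtomRecord(serial=r + 1, name="CA", element="C",
                                residue_name="GLY", residue_seq=seq, chain="A"))
        coords.append((base, 0.0, 0.0))
    top = Topology(atoms=atoms, ion_sets={})
    index = pd.MultiIndex.from_tuples(
        [("A", 1, "GLY"), ("A", 2, "GLY"), ("A", 10, "GLY"), ("A", 11, "GLY")],
        names=["chain", "residue_seq", "residue_name"])
    table = ContactTable(counts=pd.DataFrame({"Na": [50, 40, 60, 30]}, index=index),
                         n_frames=1000, params=ContactParameters())
    sites = identify_candidate_sites(table, top, np.array(coords),
                                     rel_threshold=1.0, link_cutoff=8.0)
    assert sorted(s.name for s in sites) == ["G1-G2", "G10-G11"]
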