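# Methods

This note documents the models, conventions and numerical choices behind
`cationsite`, in the spirit of a simulator/analysis package's model
documentation. Nothing here states a result the tests or
`scripts/acceptance.py` do not themselves compute.

## Coordinates, numbering, distances

All coordinates are in Å, frames 0-based, residue numbering exactly as
in the input file (author numbering; "P71" means residue_seq 71).
Periodic distances use the orthorhombic minimum-image convention,
`d = Δ − L·round(Δ/L)` per axis; triclinic boxes are rejected with a
clear error because every analysis here targets rectangular solvent
boxes. Hydrogens are detected from the element column, falling back to
the first alphabetic character of the atom name; selections default to
heavy atoms only, since cation coordination and salt bridges act
through O/N atoms and many structure files carry no hydrogens anyway.
Monatomic-ion residue names (NA, K, and the CHARMM aliases SOD, POT,
CLA) map to canonical species labels; the alias table is extensible.

## Contact frequencies

A residue–ion contact in a frame means the minimum distance from the
ion to any heavy atom of the residue is **≤ cutoff** (default 4.0 Å,
boundary inclusive — a stated, measurable convention; tests use strict
interior/exterior points where exactness matters). Two counting
conventions exist because "frames in which an ion was within 4 Å" is
ambiguous when two ions visit simultaneously:

- `ion_frame_pairs` (default): every (ion, frame) pair counts, so
  column sums can exceed the frame count. Chosen as default because the
  companion dwell analysis reports per-ion approaches, implying per-ion
  bookkeeping.
- `any_ion_per_frame`: a residue counts at most once per frame.

Relative frequency is `absolute / n_frames × 100` in both conventions.
Replicate tables merge by summing counts and frame totals, which is
identical to recounting over concatenated trajectories. Output TSVs
round relatives to 2 decimals; internal values are full precision.

Candidate sites are residues whose combined (across-species) relative
frequency reaches `rel_threshold` (default 1.0 %), grouped by single
linkage on minimum heavy-atom inter-residue distance with
`link_cutoff = 8 Å` — wide enough that a pocket whose residues sit a
few Cα–Cα distances apart clusters as one site, narrow enough that
pockets tens of Å apart stay separate. Both are configurable.

## Approach events and dwell statistics

An ion occupies a site in a frame when its minimum distance to any
member atom is ≤ the site cutoff. Events are maximal occupied runs;
`debounce_gap` (default 0) fuses runs separated by at most that many
unoccupied frames, counting the gap toward the fused duration. The
default 0 means a single-frame exit ends an approach — no operational
definition of an "approach" is standard, and counts are stride-
sensitive, so the parameter is exposed and recorded in output.

Species dwell percentage defaults to the mean over that species' ions
of the per-ion occupied fraction; a union convention ("any ion of the
species in the site") is also provided since per-simulation totals can
reasonably mean either. Mean dwell is total dwell frames over approach
count and is reported absent when there are no approaches. Replicates
are summarized separately plus pooled.

## Coordination geometry

In-site statistics (mean, SD, fraction below proximity) are computed
over occupied frames only. SD is the population convention (divide by
n), configurable to sample SD. An atom is called coordinating when the
fraction of in-site frames with distance strictly below the
species-specific proximity threshold is ≥ 0.25 (inclusive). Proximity
defaults are Na 2.6 Å and K 3.0 Å — typical first-shell cation–oxygen
separations; a single 2.5 Å criterion appropriate for Na⁺ would reject
genuine K⁺ coordination, whose first-shell distances run 2.6–2.9 Å.
Calls are withheld below 50 in-site frames. Carboxylate oxygen pairs
(OD1/OD2, OE1/OE2) are analyzed as separate atoms because the two
oxygens of an aspartate can behave differently (one coordinating, one
averted). Positively charged nitrogens are reported but flagged; they
fail the criterion because like charges repel.

## Salt bridges

Thresholds are strict: *formed* < 3.2 Å, *possible* < 4.0 Å. With two
acidic oxygens the per-frame minimum is used and the nearer oxygen is
the "oriented" one (ties break to the lower atom index — measure zero
on continuous data). Orientation by nearest-oxygen is an approximation
of a visual criterion and is recorded as such in output metadata.
Per-oxygen medians restricted to oriented frames are reported alongside
full-series medians and quartiles; no outlier trimming is applied.
Medians use the standard middle-value / mean-of-two-middles convention.

## Conservation

Identity percentage at a column is matches-to-reference over all
sequences; gaps count as mismatches by default (conservative), with an
ignore-gaps option. Charge classes default to negative = {D, E},
positive = {K, R, H}. Reference positions are 1-based ungapped indices
mapped through the alignment. Phylogenetic rate-based conservation
grades are *not* reimplemented — a grade is not a function of the
percentage alone — so externally computed grades are passed through for
display only.

The packaged 20-sequence family alignment is a **synthetic stand-in**
(`synthetic_family_alignment`): real family sequences are not bundled,
so a scaffold alignment is constructed whose columns at positions
71/75/501/504 carry exactly the documented family compositions
(P 90 %/K 5 %/S 5 %; D 100 %; D 60 %/E 15 %/N 10 %/P 5 %/K 5 %/W 5 %;
K 100 %), with insertion columns so that reference positions and
alignment columns differ. It validates the mapping and percentage
arithmetic at realistic compositions; it says nothing about any real
alignment's content, which is aligner-dependent.

## Voltage-clamp analysis

The default protocol steps 1 s pulses from +20 to −160 mV in −15 mV
decrements with 1.5 s rests. Begin/end currents are 25 ms window means
after a 25 ms settle (skipping the capacitive transient) — windows
rather than instantaneous samples for noise robustness; both are
configurable and recorded in output. The IV statistic defaults to the
pulse average, with begin/end selectable. Normalization is per cell:
all of a cell's currents are divided by |I| at the reference point
(default Na30K1, −145 mV, protocol step 11) of that cell's reference
recording, making the result invariant to per-cell gain. Leak
subtraction is off by default (comparison against uninjected controls
is the usual practice); a control-subtraction option exists. Reversal
potentials come from linear interpolation at the zero crossing; with
multiple crossings the least-negative one is used, with a warning. The
semilog fit is least squares of V_rev on log₁₀(concentration), reported
next to the ideal Nernst slope (R·T/F)·ln 10 at a configurable
temperature, default 22 °C (room-temperature oocyte recording). Units:
µA, mV, mM, s.

## Synthetic generators

**Ion trajectories.** Ions teleport under an independent two-state
Markov chain per ion (bulk→site entry probability `a`, site→site stay
probability `s`), initialized from the stationary distribution. This
deliberately sacrifices path realism (no diffusion, no inertia) for
exact ground truth: stationary occupancy `a/(a+1−s)`, mean dwell
`1/(1−s)` frames, expected run count `π + (F−1)(1−π)a`. In-site frames
are placed uniformly in a 2.0–3.5 Å shell around a randomly chosen site
atom (or at a Gaussian radius from an assigned coordinating atom, with
an optional mean-reverting Ornstein–Uhlenbeck radius for smoother
in-visit motion); bulk frames are uniform in the box, rejected within
6 Å of any pocket atom. Because the shell radius stays at or below the
4 Å contact cutoff and the exclusion zone above it, the generated mask
*equals* the geometric mask, making event tests exact. The toy pocket
is 12 atoms in four residues labelled P71/D75/D501/K504 with real atom
names (O, OD1/OD2, NZ), coordinating oxygens ≈ 2.4 Å from the site
center, so downstream reports read like real site tables. Defaults
`a = 0.02`, `s = 0.9`, six ions per species, 60 Å box are the study
conditions used throughout the tests. What passing tests show: the
statistics are computed correctly on data satisfying the model's
assumptions; they do not show robustness to diffusive recrossing noise,
which the debounce parameter exists to handle on real data.

**Recordings.** Sweeps follow
`I(t) = g·(V−V_rev)·[(1−f) + f·e^(−t/τ)]` at deactivating voltages
(below the solution's V_rev by default) and are flat otherwise, plus
white Gaussian noise (σ default 0.01 µA) and an optional lognormal
per-cell gain (σ 0.1) that the per-cell IV normalization must cancel.
No drift or seal-leak modelling. The closed-form window mean of the
exponential factor — continuous, or evaluated exactly on the discrete
sample grid — is the oracle for deactivation recovery.

The wild-type solution presets encode the documented observables: the
begin-to-end current reductions of 12.0 % (Na30K0), 10.7 % (Na30K1) and
3.2 % (Na30K30). Since the observable is the *measured* reduction, not
the model parameter, each preset's `f` is obtained by inverting the
analytic window-mean reduction at the default windows and sample rate
(e.g. reduction 12.0 % ⇒ f ≈ 0.142 at τ = 0.2 s). V_rev presets anchor
Na30K1 at −45 mV (the zero-current holding level) and space the others
semilogarithmically in Na with sub-Nernstian slope; conductances scale
≈ 5× over 0.3→30 mM Na and nearly double with 1 mM K. τ = 0.2 s gives
visibly settling decay within the 1 s pulse.

## Reference data

`reference.py` carries the wild-type contact-frequency table for the 17
residues around the coordination site (per-species absolute counts,
plus the published combined columns kept separately so the
across-species arithmetic is recomputed, never copied). The pooled
frame total behind the table was not stated; 60,700 frames is inferred
from the absolute/relative ratios and reproduces every 2-decimal
relative frequency in the table.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes chosen to give
tight statistical power at interactive cost: 100 random ≤ 50-atom
systems for the brute-force contact oracle, 100,000-frame chains (×
several seeds) for dwell statistics, 10⁴-sample Gaussian series for
medians, 5 synthetic cells for electrophysiology. The dwell tolerance
uses the exact asymptotic standard error of a two-state chain's
occupied fraction — binomial variance inflated by the autocorrelation
factor (1+λ)/(1−λ), λ = s−a — since frames of a Markov chain are not
independent. All randomness flows through explicit seeds; identical
config and seed reproduce artifacts byte-for-byte.

## Known limitations

- The trajectory generator's teleporting ions make residence statistics
  exact but cannot exercise debounce-sensitive recrossing behaviour.
- Orientation of carboxylate oxygens is inferred from proximity alone,
  not from side-chain dihedral geometry.
- The conservation module reports percentages of whatever alignment it
  is given; reproducing any particular published percentage from raw
  sequences depends on the upstream aligner.
- DCD/XTC binary trajectories, RMSD fitting, hydrogen-bond angle
  criteria, GHK permeability decomposition and free-energy estimates
  are out of scope.
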