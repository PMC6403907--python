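# Methods

`dendromd` simulates isolated silicon-containing dendrimers in vacuum
and measures their intramolecular mobility.  This note records the
model, the estimators, the defaults and the design choices, in the
order data flows through the package.

## Dendrimer families and topology generation

Four chemistries are built as rooted trees of branching Si atoms:

| family | core | spacer | terminal segments |
|--------|------|--------|-------------------|
| `s`  | trifunctional Si-(CH3) | `-O-` | trimethylsilyl (3 CH3) |
| `l`  | trifunctional Si-(CH3) | `-O-Si(CH3)2-O-` | trimethylsilyl |
| `c3` | trifunctional Si | `-(CH2)3-` | 2 butyl `-(CH2)3-CH3` + 1 CH3 |
| `c4` | tetrafunctional Si | `-(CH2)3-` | as `c3` |

Branch multiplicity is 2 everywhere (trifunctional branching Si: one
incoming, two outgoing skeleton bonds), configurable up to 3.  Layer
`i` therefore holds `f * 2^(i-1)` branching Si, `f` the core
functionality; this closed form is asserted against graph traversal for
every family and generation 1-7.

Assumptions where the chemistry is not fully determined by the family
description: carbosilane branching Si carry one methyl substituent to
complete the Si valence; the outermost carbosilane Si carries two butyl
segments (the two branching slots) plus one methyl.  Layer labels on
non-skeleton atoms follow the segment they belong to; terminal-segment
atoms are labelled `G+1`, and the *terminal tracking atoms* — the atoms
whose motion represents the terminal groups in every analysis — are the
outermost (layer-`G`) branching Si.

Both a united-atom representation (CH2/CH3 as single sites; the
default, ~3x cheaper) and an explicit all-atom representation are
available.  All analyses track Si positions and skeleton torsions, so
the choice does not affect the analysis layer.  Partial charges are
assigned by bond increments (Si->O 0.2 e, Si->C 0.05 e), which makes
every molecule exactly neutral.

## Energy model

Class-I functional forms, energies in kcal/mol, lengths in angstrom,
time in ps:

* bonds `k (r - r0)^2`, angles `k (theta - theta0)^2`;
* torsions: cosine series `sum V/2 (1 + cos(n phi - gamma))` on
  carbosilane skeletons only (siloxane rotational states are weakly
  defined and are modelled torsion-free); the series amplitude is
  divided by the number of quadruples sharing a central bond;
* Lennard-Jones with Lorentz-Berthelot mixing, cutoff 1.05 nm,
  energy-shifted to zero at the cutoff;
* screened Coulomb
  `U_q = K q_i q_j / r * (1 - r/R_q)^2` for `r < R_q`, zero beyond,
  with the screening radius equal to the LJ cutoff — the potential and
  its derivative vanish continuously at `R_q`, so the model has no
  long-range part at all;
* non-bonded exclusions: 1-2 and 1-3 excluded, 1-4 full strength.

The shipped numeric parameters are *editable defaults* in the
PCFF/AMBER style (a YAML override hook is provided).  Every claim the
package tests is structural or symmetry-level, chosen to be robust to
reasonable parameter values.  Forces are the exact analytic negative
gradient; the test suite holds them to a central-difference oracle at
relative error 1e-5.

## Initial embedding

Conformations are grown from the core in BFS order using internal
coordinates (equilibrium bonds and angles; dihedral candidates at
staggered positions with +-0.5 rad jitter, scored by the distance to
the nearest already-placed atom, best candidate wins).  The grown
structure is relaxed by L-BFGS on the full force field, then polished
with 20-400x stiffened bonded terms until the embedding contract holds:
no non-bonded pair closer than the clash distance (default 1.5 A),
bonds within 2% and angles within 5 degrees of equilibrium.  Up to
three growth attempts with derived seeds are made before an embedding
error naming the worst colliding pair is raised.  Embedding is
deterministic per seed.

## Integration and thermostat

Velocity Verlet with the 0.002 ps elementary step.  Temperature control
is a collisional thermostat: per atom, collisions arrive at rate
`collision_rate` (default 10 ps^-1); at a collision the atom exchanges
momentum elastically with a Maxwell-distributed virtual bath particle,

    v' = ((m - m0) v + 2 m0 u) / (m + m0),  u ~ N(0, kT/m0).

The default bath mass is 1 amu — each collision is a small impulse, so
the target temperature is maintained (long-run kinetic temperature
within 3% in the tests) without overdamping conformational motion.
`bath_mass=None` selects the full velocity re-draw variant, which is
maximally ergodic per collision but Brownian-overdamped for collective
rearrangements; it is not the default for exactly that reason.

Two frame streams are saved from one run: a coarse stream for
positional statistics (10 ps in the full-study preset) and an optional
fine stream (0.1 ps) for torsion analysis — the 0.4 ps dwell criterion
is unresolvable at coarse spacing, and the transition counter refuses
spacings above half the dwell threshold.

Non-bonded pairs come from a Verlet neighbour list (2 A skin, rebuild
at half-skin displacement) above 220 atoms, and a static all-pair list
below.  The pair loop is JIT-compiled with numba when available;
a pure-numpy path produces identical results and serves as the
reference implementation.

NVE mode (thermostat off after optional thermostatted equilibration)
conserves the net total energy to well under 1% of the mean kinetic
energy over 10 ps at the default step; the bounded Verlet energy
oscillation shrinks as dt^2, which the suite checks by timestep
halving.

## Mobility decomposition

For every tracked Si atom: `R(t)` is the distance to the core atom, and
`Omega(t)` the angle between the core-to-atom vector and the vector
from the core to the mass-weighted centre of mass of the atom's dendron
(all dendron atoms included).  Both are functions of internal vectors
only and are therefore exactly invariant under rigid-body motion of the
molecule — asserted to 1e-8 under per-frame random rotations and
translations.  Frames where either vector degenerates to zero length
are flagged, excluded from angular statistics and counted.

Layer statistics (mean, root of dispersion, max-minus-min range, for R
and Omega) pool all atoms of a layer across frames and replicas; the
pooled convention was chosen over averaging per-atom means because the
range plots only make sense on the pooled sample.  A brute-force
concatenate-everything oracle pins the pooled dispersion in the tests.

The *mixing time* of a layer is the smallest averaging window after
which atoms of the layer become statistically indistinguishable: the
between-atom standard deviation of window means must fall below a
tolerance fraction (default 0.2) of the pooled dispersion for both R
and Omega; `None` means "not mixed on this trajectory".

## Relaxation spectra

The autocorrelation function of a per-atom signal X is

    A(t) = <dX(t') dX(t'+t)> / <dX^2>,   dX = X - <X>,

estimated over all overlapping origins with the biased (divide-by-N)
normalisation via FFT, so `A(0) = 1` exactly; a double-loop oracle
matches to 1e-12.  The maximum lag defaults to 10% of the series
length.  The relaxation time `tau` is the first 1/e crossing of the raw
ACF, linearly interpolated between bracketing lags — chosen as primary
over the exponential-fit time constant, which is computed alongside and
reported with its relative deviation as a QC column.  ACFs that never
reach 1/e within the max lag are *censored*: carried with a lower bound
equal to the max lag, excluded from means and dispersions, counted in
the tables.

Layer spectra pool per-atom, per-replica `tau` samples; histograms use
30 log-spaced bins over the observed range.  On exact-discretisation OU
signals the ensemble-mean estimate recovers the generator's `tau`
within 10% at series length 200 tau (per-seed crossing noise at that
length is ~10-15%, which bounds what any estimator can promise
per-realisation).

## Torsion dynamics

Dihedrals follow the IUPAC sign convention with trans at +-180 deg.
The angular space is split into three equal 120-degree sectors centred
on 180 (t), +60 (g+) and -60 (g-); boundary frames tie-break to the
earlier-listed centre (so +-120 belongs to trans).  A sector change
counts as a transition only if the new sector persists *strictly
longer* than the dwell threshold (0.4 ps); a shorter excursion is
erased and the bond is deemed to have remained in its previous state
throughout (the alternative — latching to the excursion — was
rejected as inconsistent with a "remains in the new state" criterion).
An independent run-length-encoding oracle reproduces the counts exactly
on random sequences.

Frequencies (transitions per ns) are averaged over all bonds at the
same topological bond count from the core; terminal butyl torsions are
indexed beyond the last branching layer so terminal mobility is visible
at the right end of the profile.  For siloxanes, whose rotational
minima are shallow, the same three-sector dwell-filtered counter is
reported as the frequency of "transitions through 120 degrees" — the
sector-crossing interpretation, noted as an interpretation; the
alternative (cumulative 120-degree rotation) was not implemented.

## Dendron geometry

Per frame, the angles between all pairs of core-to-dendron-COM unit
vectors: 3 for trifunctional, 6 for tetrafunctional cores.  For
tetrafunctional cores the two pairs with the largest time-mean angles
are labelled "big", the rest "small" — an interpretation (the split is
not otherwise defined) that is invariant under dendron relabelling and
selects the disjoint dendron pairs for tetrahedral-like geometries.
Product-moment correlations between the angle time series are labelled
in-phase/anti-phase by sign only; which structural pairs should move in
phase is left to the data.

## Synthetic ground truth

Every analysis operation is validated without MD:

* OU series use the exact conditional update
  `x_{n+1} = rho x_n + sqrt(1-rho^2) xi`, `rho = exp(-dt/tau)`, so the
  analytic ACF `exp(-t/tau)` holds with no discretisation bias;
* telegraph signals draw exponential dwell times (truncated at one
  frame), emit sector-centre angles with bounded uniform jitter, and
  return their own dwell-filtered transition count via independent
  bookkeeping;
* rigid composites apply an independent random rotation+translation to
  every frame of a base trajectory, preserving internal geometry to
  isometry precision.

What the generators do *not* emulate: coupling between radial and
angular motion, non-exponential relaxation, correlated transitions of
neighbouring torsions, and force-field physics in general.  Passing the
generator-based tests therefore demonstrates the correctness of the
estimators, not the realism of the force field; the simulator-based
tests cover structure- and symmetry-level physics only.

## Problem sizes and study presets

The full study design — 8 replicas x 30 ns production after 6 ns
equilibration at 600 K, temperatures 300 and 600 K, generations 4-7 —
is expressible in `StudyConfig` but is cluster-scale.  The desk preset
caps generation at 4 and production at 2 ns.  The package's own
validation runs use: a G2 carbosilane (10 ps, both streams) for
invariance and round-trip checks; a G1 siloxane for NVE/NVT checks; and
a G4 carbosilane at 600 K (100 ps equilibration + 250-300 ps
production, 0.5 ps frames, 3 replicas in the acceptance script) for the
inter-dendron-angle symmetry check.  At these spans the time-averaged
trifunctional inter-dendron angle comes out 10-15% below the ideal 120
degrees: individual dendron pairs still interpenetrate for stretches
comparable to the trajectory length, a finite-sampling effect that full
100 ns trajectories average out.

## Known limitations

* No solvent, periodic boundaries, Ewald electrostatics or pressure
  coupling — the model is an isolated molecule in vacuum by design.
* Force-field numbers are literature-style defaults, not a validated
  parameter set; quantitative observables (absolute <R>, tau values)
  depend on them, structural/symmetry observables much less so.
* Relaxation times of real dendrimer layers are nanoseconds;
  desk-scale trajectories censor most of them.  The estimators handle
  censoring explicitly, but quantitative spectra need long runs.
* The all-atom representation uses the same 0.002 ps default step;
  C-H stretching is marginally resolved at that step, so NVE work in
  the all-atom representation should reduce the timestep.
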