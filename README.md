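# dendromd

Vacuum molecular dynamics and intramolecular-mobility analysis for
siloxane and carbosilane dendrimers.

Dendrimers are regularly branched tree-like macromolecules grown in
generations around a central core.  How mobile their interior is — how
far each branching atom strays radially and angularly, how fast those
motions relax, how often backbone bonds hop between rotational isomers
— controls melt viscosity, NMR lineshapes and the anomalous
liquid-to-solid transitions seen in high-generation melts.  This
package is for polymer-simulation researchers who want to generate and
analyse such single-molecule trajectories end to end: it builds the
molecular graph for four silicon-dendrimer families (two siloxane, two
carbosilane), runs vacuum MD with a screened Coulomb potential and a
collisional thermostat, and computes the bespoke mobility statistics
that characterise intramolecular dynamics.

## The model and the observables

The energy model is class-I: harmonic bonds and angles, a cosine
torsion series on carbosilane skeletons, Lennard-Jones with a 1.05 nm
cutoff, and a screened Coulomb potential

    U_q(r) = q_i q_j / r * W_q(r),  W_q(r) = (1 - r/R_q)^2  (r < R_q),

with the screening radius R_q equal to the LJ cutoff, so electrostatics
vanishes smoothly at the cutoff.  Integration is velocity Verlet at
0.002 ps with a collisional thermostat (stochastic impulses from
virtual Maxwell-distributed bath particles).

For every branching Si atom the motion is decomposed into:

* **R(t)** — distance to the core atom;
* **Ω(t)** — angle between the core→atom vector and the core→dendron
  centre-of-mass vector, which excludes overall molecular rotation by
  construction.

Per topological layer the package reports ⟨R⟩, ⟨Ω⟩, the dispersion
roots D_R and D_Ω, and the ranges R_max−R_min, Ω_max−Ω_min.  Relaxation
is measured through the autocorrelation function

    A(t) = ⟨δX(t′) δX(t′+t)⟩ / ⟨δX²⟩,  δX = X − ⟨X⟩,

whose first 1/e crossing defines the relaxation time τ; per-layer τ
distributions pool atoms and replicas.  Rotational isomerism is
quantified by dividing each dihedral's angular space into three
120-degree sectors (trans at 180°, gauche at ±60°) and counting sector
changes that persist longer than a 0.4 ps dwell threshold, averaged
over all bonds at the same topological distance from the core.
Inter-dendron angles (3 for trifunctional, 6 for tetrafunctional cores)
and their cross-correlations complete the picture.

See `docs/methods.md` for estimator details, defaults and limitations.

## Worked example

Build a generation-2 carbosilane dendrimer, run 20 ps of thermostatted
vacuum MD at 600 K, and compute the layer statistics:

```python
from dendromd import (DendrimerRecipe, SimulationConfig, build_topology,
                      initial_coordinates, integrate, dendron_angles)
from dendromd.mobility import layer_table, mobility_series_set

recipe = DendrimerRecipe(family="c3", generation=2, seed=5)
topology = build_topology(recipe)
print(f"{recipe.family} G{recipe.generation}: {topology.n_atoms} united-atom sites")

x0 = initial_coordinates(topology, seed=5)
config = SimulationConfig(temperature=600.0, equilibration_ps=5.0,
                          production_ps=20.0, coarse_save_ps=0.2, seed=5)
result = integrate(topology, x0, config)

series = mobility_series_set(result.coarse)
print(layer_table(series, topology).round(2).to_string(index=False))
print(dendron_angles(result.coarse).summary().round(1).to_string(index=False))
```

Output:

```
c3 G2: 95 united-atom sites
 layer  mean_R  D_R  R_range  mean_Omega  D_Omega  Omega_range  n_samples
     1    5.53 0.32     1.77       18.82     9.39        44.51        303
     2    8.89 1.53     6.55       27.88     9.69        50.24        606
 dendron_i  dendron_j  mean_deg  deviation_deg  range_deg class
         1          2      58.9           10.0       38.3
         1          3      96.1           15.8       60.9
         2          3     129.6           14.6       62.2
```

Layer-2 Si atoms sit on average 8.9 Å from the core and wander over a
6.5 Å corridor, with a mean angular displacement of 28° from their
dendron axis — the outward stretch and per-layer mobility growth
typical of these molecules.  The three inter-dendron angles fluctuate
asymmetrically on this short trajectory; their pair-and-time average
approaches the symmetric 120° only over much longer runs.

The same workflow is available from the shell:

```sh
dendro simulate --family c3 --generation 2 --production 20 -o g2.xyz
dendro analyze mobility g2.xyz --family c3 --generation 2
dendro analyze dendrons g2.xyz --family c3 --generation 2
```

and `dendro run --config study.yaml` orchestrates a full multi-recipe,
multi-replica study with per-stage resume and a reproducibility
manifest.

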