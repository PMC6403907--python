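"""Energy model: screened Coulomb form, gradients, cutoffs, errors."""

import numpy as np
import pytest

from dendromd import (
    DendrimerRecipe,
    ForceFieldParams,
    ParameterizationError,
    build_topology,
    initial_coordinates,
    minimize_energy,
    screened_coulomb_energy,
    total_energy_forces,
)
from dendromd.forcefield import CompiledForceField
from dendromd.units import COULOMB_K

from conftest import make_star_topology


class TestScreenedCoulomb:
    def test_vanishes_at_screening_radius(self):
        assert screened_coulomb_energy(0.3, -0.3, 10.5, r_q=10.5) == 0.0
        assert screened_coulomb_energy(0.3, -0.3, 12.0, r_q=10.5) == 0.0

    def test_half_radius_gives_quarter_screening(self):
        r_q = 10.5
        r = r_q / 2
        bare = COULOMB_K * 0.2 * 0.4 / r
        assert screened_coulomb_energy(0.2, 0.4, r, r_q=r_q) == pytest.approx(bare * 0.25)

    def test_approaches_bare_coulomb_at_short_range(self):
        r = 1e-4
        ratio = screened_coulomb_energy(0.2, 0.2, r, r_q=10.5) / (COULOMB_K * 0.04 / r)
        assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_zero_distance_is_singular(self):
        with pytest.raises(ValueError):
            screened_coulomb_energy(0.1, 0.1, 0.0)

    def test_energy_and_force_continuous_at_screening_radius(self):
        """Both U and dU/dr go to zero continuously at r = R_q."""
        r_q = 10.5
        eps = 1e-7
        below = screened_coulomb_energy(0.3, 0.3, r_q - eps, r_q=r_q)
        assert abs(below) < 1e-12
        # numerical derivative just inside the radius is also ~0
        d = (
            screened_coulomb_energy(0.3, 0.3, r_q - eps, r_q=r_q)
            - screened_coulomb_energy(0.3, 0.3, r_q - 2 * eps, r_q=r_q)
        ) / eps
        assert abs(d) < 1e-5


class TestEnergyForces:
    def test_bonded_pair_at_equilibrium_has_zero_energy_and_force(self):
        topo = make_star_topology(functionality=1, per_dendron=1)
        params = ForceFieldParams(
            bonds={("Si", "Si"): (200.0, 2.0)},
            angles={},
            lj={"Si": (0.0, 3.8)},
            torsions={},
            include_torsions=False,
            coulomb=False,
        )
        x = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        e, f, comp = total_energy_forces(topo, x, params)
        assert e == pytest.approx(0.0, abs=1e-20)
        assert np.abs(f).max() < 1e-12

    def test_lj_pair_beyond_cutoff_contributes_nothing(self):
        topo = make_star_topology(functionality=2, per_dendron=2)
        params = ForceFieldParams(
            bonds={("Si", "Si"): (200.0, 2.0)},
            angles={("Si", "Si", "Si"): (0.0, 109.47)},
            lj={"Si": (0.4, 3.8)},
            torsions={},
            include_torsions=False,
            coulomb=False,
        )
        # the two non-bonded dendron tips sit 22 A apart, beyond 10.5 A
        x = np.array([[0.0, 0, 0], [9.0, 0, 0], [11.0, 0, 0], [-9.0, 0, 0], [-11.0, 0, 0]])
        e, f, comp = total_energy_forces(topo, x, params)
        assert comp["lj"] == 0.0
        assert comp["coulomb"] == 0.0

    def test_missing_parameter_names_the_type(self):
        topo = build_topology(DendrimerRecipe("s", 1))
        params = ForceFieldParams(bonds={("C", "C"): (310.0, 1.53)})
        with pytest.raises(ParameterizationError, match="Si"):
            total_energy_forces(topo, initial_coordinates(topo, seed=1), params)

    def test_torsion_terms_only_for_carbosilanes(self):
        assert ForceFieldParams.for_family("c3").include_torsions
        assert not ForceFieldParams.for_family("s").include_torsions
        topo = build_topology(DendrimerRecipe("s", 1))
        compiled = CompiledForceField(topo, ForceFieldParams.for_family("s"))
        assert len(compiled.tor_ijkl) == 0

    def test_net_force_vanishes(self):
        """Translation invariance: per-atom forces sum to zero."""
        topo = build_topology(DendrimerRecipe("c3", 1, seed=2))
        x = initial_coordinates(topo, seed=2)
        _, f, _ = total_energy_forces(topo, x)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_forces_match_finite_differences(self):
        """Analytic forces equal the central-difference gradient (all terms)."""
        topo = build_topology(DendrimerRecipe("c3", 1, seed=3))
        params = ForceFieldParams.for_family("c3")
        compiled = CompiledForceField(topo, params)
        x = minimize_energy(topo, initial_coordinates(topo, seed=3), params, max_steps=500)
        rng = np.random.default_rng(0)
        x = x + rng.normal(0.0, 0.02, x.shape)
        _, f, _ = compiled.energy_forces(x)
        h = 1e-5
        g = np.zeros_like(x)
        for i in range(topo.n_atoms):
            for k in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                g[i, k] = (compiled.energy_forces(xp)[0] - compiled.energy_forces(xm)[0]) / (2 * h)
        assert np.linalg.norm(g + f) / np.linalg.norm(f) < 1e-5

    def test_numba_and_numpy_paths_agree(self):
        import dendromd.forcefield as ff

        if not ff.HAVE_NUMBA:
            pytest.skip("numba not available; single path only")
        topo = build_topology(DendrimerRecipe("c3", 2, seed=4))
        x = initial_coordinates(topo, seed=4)
        params = ForceFieldParams.for_family("c3")
        e1, f1, _ = CompiledForceField(topo, params).energy_forces(x)
        ff.HAVE_NUMBA = False
        try:
            e2, f2, _ = CompiledForceField(topo, params).energy_forces(x)
        finally:
            ff.HAVE_NUMBA = True
        assert e1 == pytest.approx(e2, rel=1e-12)
        assert np.abs(f1 - f2).max() < 1e-9


def test_yaml_override_roundtrip(tmp_path):
    cfg = tmp_path / "ff.yaml"
    cfg.write_text(
        "bonds:\n  Si|O: [400.0, 1.60]\ncutoff: 9.0\ninclude_torsions: false\n"
    )
    params = ForceFieldParams.from_yaml(cfg)
    assert params.bond_params("Si", "O") == (400.0, 1.60)
    assert params.cutoff == 9.0
    assert not params.include_torsions


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterizationError):
        ForceFieldParams(bonds={("Si", "O"): (-1.0, 1.6)})
    with pytest.raises(ParameterizationError):
        ForceFieldParams(cutoff=-1.0)
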