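"""Velocity-Verlet vacuum MD with a collisional thermostat.

The thermostat models stochastic collisions with virtual bath
particles: each atom suffers collisions at exponentially distributed
times (rate = ``collision_rate``); at a collision the atom exchanges
momentum elastically with a Maxwell-distributed bath particle of mass
``bath_mass`` at the target temperature,

    v' = ((m - m0) v + 2 m0 u) / (m + m0),    u ~ Maxwell(T).

The default bath particle is light (1 amu), the standard choice for
this thermostat: each collision delivers a small impulse, so the
temperature is controlled without overdamping the conformational
dynamics.  ``bath_mass=None`` makes the bath particle carry the atom's
own mass, turning every collision into a full velocity re-draw — the
strongest (Andersen-like) variant.

Two frame streams can be saved from one run: a coarse stream for
positional statistics (default 10 ps) and a fine stream (default off;
0.1 ps in the torsion pipeline) resolving the 0.4 ps dwell criterion of
the trans-gauche transition counter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DivergedTrajectoryError
from .forcefield import CompiledForceField, ForceFieldParams
from .topology import DendrimerTopology
from .trajectory import Trajectory
from .units import KB, KCAL_PER_MOL_TO_AKMA

_ALL_PAIRS_MAX_ATOMS = 220
_COORD_LIMIT = 1.0e5  # A; beyond this the trajectory is declared diverged


@dataclass
class SimulationConfig:
    """Integration settings; spans in ps, temperatures in K.

    ``mode`` is ``"NVT"`` (thermostat on) or ``"NVE"`` (thermostat off
    during production; an equilibration span, if any, still uses the
    thermostat to prepare velocities at the target temperature).
    """

    timestep: float = 0.002
    temperature: float = 600.0
    mode: str = "NVT"
    collision_rate: float = 10.0  # ps^-1
    bath_mass: float | None = 1.0  # amu; None = full velocity re-draw
    equilibration_ps: float = 0.0
    production_ps: float = 10.0
    coarse_save_ps: float = 10.0
    fine_save_ps: float | None = None
    seed: int = 0
    neighbor_skin: float = 2.0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.mode not in ("NVT", "NVE"):
            raise ValueError("mode must be NVT or NVE")
        for name in ("coarse_save_ps", "fine_save_ps"):
            val = getattr(self, name)
            if val is None:
                continue
            steps = val / self.timestep
            if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
                raise ValueError(f"{name}={val} is not a positive multiple of the timestep")


@dataclass
class MDResult:
    """Output bundle of :func:`integrate`."""

    coarse: Trajectory
    fine: Trajectory | None
    energies: pd.DataFrame
    final_coordinates: np.ndarray
    final_velocities: np.ndarray

    @property
    def trajectory(self) -> Trajectory:
        return self.coarse


class _PairProvider:
    """Static all-pair list for small systems, Verlet neighbour list otherwise."""

    def __init__(self, compiled: CompiledForceField, skin: float):
        self.compiled = compiled
        self.skin = skin
        self.n = compiled.topology.n_atoms
        self.static = compiled.all_pairs() if self.n <= _ALL_PAIRS_MAX_ATOMS else None
        self._ref = None
        self._pairs = None

    def pairs(self, x: np.ndarray) -> np.ndarray:
        if self.static is not None:
            return self.static
        if self._ref is not None:
            disp = np.max(np.linalg.norm(x - self._ref, axis=1))
            if disp < 0.5 * self.skin:
                return self._pairs
        tree = cKDTree(x)
        raw = tree.query_pairs(self.compiled.cutoff + self.skin, output_type="ndarray")
        self._pairs = self.compiled.filter_excluded(raw.astype(np.int64))
        self._ref = x.copy()
        return self._pairs


def maxwell_velocities(masses: np.ndarray, temperature: float, rng) -> np.ndarray:
    sigma = np.sqrt(KB * temperature * KCAL_PER_MOL_TO_AKMA / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Kinetic energy, kcal/mol."""
    return 0.5 * float(np.sum(masses[:, None] * velocities**2)) / KCAL_PER_MOL_TO_AKMA


def kinetic_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    return 2.0 * kinetic_energy(masses, velocities) / (3.0 * len(masses) * KB)


def integrate(
    topology: DendrimerTopology,
    start_coordinates: np.ndarray,
    config: SimulationConfig,
    params: ForceFieldParams | None = None,
    velocities: np.ndarray | None = None,
) -> MDResult:
    """Run equilibration + production; deterministic for a fixed seed.

    Frames are saved during production only, at the configured coarse
    (and optionally fine) intervals, starting with the first production
    frame.  Raises :class:`DivergedTrajectoryError` on numerical
    blow-up, reporting the last stable coarse frame index.
    """
    if params is None:
        params = ForceFieldParams.for_family(topology.recipe.family)
    compiled = CompiledForceField(topology, params)
    provider = _PairProvider(compiled, config.neighbor_skin)
    rng = np.random.default_rng(int(config.seed))
    dt = config.timestep
    masses = topology.masses
    inv_m = (KCAL_PER_MOL_TO_AKMA / masses)[:, None]

    x = np.array(start_coordinates, dtype=np.float64)
    v = maxwell_velocities(masses, config.temperature, rng) if velocities is None else np.array(velocities, dtype=np.float64)

    p_coll = 1.0 - np.exp(-config.collision_rate * dt)
    m0 = masses if config.bath_mass is None else np.full_like(masses, float(config.bath_mass))
    sig_bath = np.sqrt(KB * config.temperature * KCAL_PER_MOL_TO_AKMA / m0)

    def thermostat(v):
        hit = rng.random(len(masses)) < p_coll
        if np.any(hit):
            u = rng.normal(size=(int(hit.sum()), 3)) * sig_bath[hit, None]
            mm, bb = masses[hit, None], m0[hit, None]
            v[hit] = ((mm - bb) * v[hit] + 2.0 * bb * u) / (mm + bb)
        return v

    e, f, _ = compiled.energy_forces(x, provider.pairs(x))

    n_eq = int(round(config.equilibration_ps / dt))
    n_prod = int(round(config.production_ps / dt))
    every_c = int(round(config.coarse_save_ps / dt))
    every_f = int(round(config.fine_save_ps / dt)) if config.fine_save_ps else None

    coarse_frames, fine_frames, elog = [], [], []

    def step(x, v, f, thermo):
        v = v + (0.5 * dt) * f * inv_m
        x = x + dt * v
        e, f, _ = compiled.energy_forces(x, provider.pairs(x))
        v = v + (0.5 * dt) * f * inv_m
        if thermo:
            v = thermostat(v)
        return x, v, e, f

    thermo_eq = True
    for _ in range(n_eq):
        x, v, e, f = step(x, v, f, thermo_eq)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _COORD_LIMIT:
            raise DivergedTrajectoryError("trajectory diverged during equilibration", last_stable_frame=-1)

    thermo_prod = config.mode == "NVT"
    for s in range(n_prod + 1):
        if s % every_c == 0:
            coarse_frames.append(x.copy())
            ke = kinetic_energy(masses, v)
            elog.append(
                {
                    "time_ps": s * dt,
                    "potential": e,
                    "kinetic": ke,
                    "total": e + ke,
                    "temperature": kinetic_temperature(masses, v),
                }
            )
        if every_f and s % every_f == 0:
            fine_frames.append(x.copy())
        if s == n_prod:
            break
        x, v, e, f = step(x, v, f, thermo_prod)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _COORD_LIMIT:
            raise DivergedTrajectoryError(
                f"trajectory diverged at production step {s + 1}",
                last_stable_frame=len(coarse_frames) - 1,
            )

    coarse = Trajectory(np.asarray(coarse_frames), spacing=config.coarse_save_ps, topology=topology)
    fine = (
        Trajectory(np.asarray(fine_frames), spacing=config.fine_save_ps, topology=topology)
        if every_f
        else None
    )
    return MDResult(
        coarse=coarse,
        fine=fine,
        energies=pd.DataFrame(elog),
        final_coordinates=x,
        final_velocities=v,
    )


def minimize_energy(
    topology: DendrimerTopology,
    coordinates: np.ndarray,
    params: ForceFieldParams | None = None,
    max_steps: int = 500,
    f_tol: float = 1.0,
) -> np.ndarray:
    """Steepest descent with backtracking until max |F| < ``f_tol`` kcal/mol/A."""
    if params is None:
        params = ForceFieldParams.for_family(topology.recipe.family)
    compiled = CompiledForceField(topology, params)
    provider = _PairProvider(compiled, 2.0)
    x = np.array(coordinates, dtype=np.float64)
    e, f, _ = compiled.energy_forces(x, provider.pairs(x))
    step = 1.0e-4
    for _ in range(max_steps):
        fmax = np.max(np.abs(f))
        if fmax < f_tol:
            break
        x_new = x + min(step, 0.2 / fmax) * f
        e_new, f_new, _ = compiled.energy_forces(x_new, provider.pairs(x_new))
        if e_new < e:
            x, e, f = x_new, e_new, f_new
            step = min(step * 1.2, 1.0e-2)
        else:
            step *= 0.5
            if step < 1e-10:
                break
    return x
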