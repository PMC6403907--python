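"""Stochastic signal generators with known ground truth.

Every analysis operation in the package can be validated without MD on
signals from this module:

* :func:`generate_ou` — a stationary Gauss-Markov (Ornstein-Uhlenbeck)
  series with prescribed mean, variance and exponential autocorrelation
  ``exp(-t/tau)``.  The exact discrete-time conditional update is used,
  so the analytic ACF holds with no discretisation bias.
* :func:`generate_telegraph` — a three-state (t/g+/g-) dihedral
  telegraph signal with exponential dwell times (truncated at one frame)
  and bounded emission jitter, returning the ground-truth accepted
  transition count under a stated dwell threshold.
* :func:`generate_rigid_composite` — a per-frame random rigid
  rotation+translation applied to a base trajectory: internal geometry
  is untouched, so any rigid-motion-invariant observable must be
  bitwise-stable.

Generators emit the same containers as the trajectory store, so
analysers cannot tell synthetic from simulated input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .torsion import DEFAULT_SECTOR_CENTERS, wrap_angles
from .trajectory import Trajectory


@dataclass
class OUSpec:
    mean: float = 0.0
    variance: float = 1.0
    tau: float = 50.0          # ps
    spacing: float = 1.0       # ps
    length: int = 10000        # frames
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.length < 1 or self.spacing <= 0:
            raise ValueError("need positive length and spacing")
        if self.variance > 0 and self.spacing >= self.tau / 5.0:
            raise ValueError("spacing must be < tau/5 for a resolvable decay")


@dataclass
class TelegraphSpec:
    dwell_means: tuple = (5.0, 5.0, 5.0)   # ps per state (t, g+, g-)
    jitter: float = 10.0                   # deg, uniform half-width
    spacing: float = 0.1                   # ps
    length: int = 10000                    # frames
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.dwell_means):
            raise ValueError("dwell means must be positive")
        if not (0 <= self.jitter < 60.0):
            raise ValueError("jitter must stay within the 120-deg sector")
        if self.length < 1 or self.spacing <= 0:
            raise ValueError("need positive length and spacing")


def generate_ou(spec: OUSpec) -> np.ndarray:
    """Exact-discretisation OU series; ACF(t) = variance * exp(-t/tau)."""
    rng = np.random.default_rng(int(spec.seed))
    n = spec.length
    if spec.variance == 0:
        return np.full(n, spec.mean)
    rho = np.exp(-spec.spacing / spec.tau)
    sig = np.sqrt(spec.variance)
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, 1.0, size=n - 1) * np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return spec.mean + sig * x


def generate_telegraph(spec: TelegraphSpec, dwell_threshold: float = 0.4):
    """Three-state telegraph dihedral signal with ground truth.

    Returns ``(angles, true_states, true_count)`` where ``true_count``
    is the number of transitions accepted under ``dwell_threshold``
    applied to the realised discrete state sequence (same strictly-
    greater-than rule as the analyser).
    """
    rng = np.random.default_rng(int(spec.seed))
    n = spec.length
    states = np.empty(n, dtype=np.int64)
    pos = 0
    cur = int(rng.integers(0, 3))
    while pos < n:
        dwell = rng.exponential(spec.dwell_means[cur])
        frames = max(1, int(round(dwell / spec.spacing)))
        end = min(n, pos + frames)
        states[pos:end] = cur
        pos = end
        nxt = int(rng.integers(0, 2))
        cur = [s for s in range(3) if s != cur][nxt]
    centers = np.asarray(DEFAULT_SECTOR_CENTERS)
    jit = rng.uniform(-spec.jitter, spec.jitter, size=n) if spec.jitter > 0 else np.zeros(n)
    angles = wrap_angles(centers[states] + jit)
    true_count = _accepted_count(states, spec.spacing, dwell_threshold)
    return angles, states, true_count


def _accepted_count(states, spacing, dwell_threshold):
    """Generator-side bookkeeping of the dwell rule (independent of the analyser)."""
    count = 0
    cur = int(states[0])
    i = 1
    n = len(states)
    while i < n:
        if states[i] == cur:
            i += 1
            continue
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        if (j - i) * spacing > dwell_threshold + 1e-12:
            count += 1
            cur = int(states[i])
        i = j
    return count


def generate_rigid_composite(
    base: Trajectory, seed: int = 0, identity_first_frame: bool = False
) -> Trajectory:
    """Apply an independent random rotation+translation to every frame."""
    rng = np.random.RandomState(int(seed) % 2**32)
    coords = base.coordinates.copy()
    out = np.empty_like(coords)
    for f in range(base.n_frames):
        if identity_first_frame and f == 0:
            out[f] = coords[f]
            continue
        rot = Rotation.random(random_state=rng)
        shift = rng.uniform(-50.0, 50.0, size=3)
        out[f] = rot.apply(coords[f]) + shift
    return Trajectory(out, spacing=base.spacing, origin=base.origin, topology=base.topology)
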