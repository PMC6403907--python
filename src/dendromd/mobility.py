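"""Radial/angular decomposition of branching-Si motion and layer statistics.

The motion of every tracked Si atom is split into a radial part — the
distance ``R`` from the atom to the core atom — and an angular part —
the angle ``Omega`` between the core-to-atom vector and the vector from
the core to the centre of mass of the atom's dendron.  Both observables
are built from internal vectors only, so they are exactly invariant
under any rigid-body motion of the whole molecule: global rotation and
translation cancel by construction.

Layer statistics pool samples over all atoms of a layer, all frames and
(when several trajectories are supplied) all replicas: mean, the square
root of the dispersion, and the max-minus-min range, for both R and
Omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyLayerError
from .topology import DendrimerTopology, layer_members
from .trajectory import Trajectory


@dataclass
class MobilitySeries:
    """Per-atom R(t) (A) and Omega(t) (deg) over one trajectory."""

    atom_id: int
    r: np.ndarray
    omega: np.ndarray
    layer: int
    dendron: int
    valid: np.ndarray = None  # frames where Omega is well defined

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(len(self.r), dtype=bool)


@dataclass
class LayerStats:
    layer: int
    mean_r: float
    d_r: float
    r_range: float
    mean_omega: float
    d_omega: float
    omega_range: float
    n_samples: int


def _core_frames(trajectory: Trajectory):
    topo = trajectory.topology
    if topo is None:
        raise ValueError("trajectory must be linked to a topology")
    return trajectory.coordinates[:, topo.core_atom_id, :]


def radial_series(trajectory: Trajectory, atom_id: int) -> np.ndarray:
    """Distance from the core atom to ``atom_id`` per frame (A)."""
    topo = trajectory.topology
    if not topo.is_branching_si[atom_id]:
        raise ValueError(f"atom {atom_id} is not a tracked Si")
    d = trajectory.coordinates[:, atom_id, :] - _core_frames(trajectory)
    return np.linalg.norm(d, axis=1)


def _dendron_com(trajectory: Trajectory, dendron: int) -> np.ndarray:
    """Mass-weighted centre of mass of one dendron, per frame."""
    topo = trajectory.topology
    members = topo.dendron_members(dendron)
    m = topo.masses[members]
    xyz = trajectory.coordinates[:, members, :]
    return np.einsum("fad,a->fd", xyz, m) / m.sum()


def omega_series(
    trajectory: Trajectory, atom_id: int, return_valid: bool = False
):
    """Angle (deg) between core->atom and core->dendron-COM per frame.

    Frames where either vector degenerates to zero length are flagged
    invalid (NaN in the series) rather than raising; they are excluded
    from layer statistics and counted in the QC report.
    """
    topo = trajectory.topology
    if not topo.is_branching_si[atom_id] or atom_id == topo.core_atom_id:
        raise ValueError(f"atom {atom_id} is not a tracked non-core Si")
    core = _core_frames(trajectory)
    u = trajectory.coordinates[:, atom_id, :] - core
    v = _dendron_com(trajectory, int(topo.dendron[atom_id])) - core
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    valid = (ru > 1e-10) & (rv > 1e-10)
    cosw = np.full(len(u), np.nan)
    np.divide(
        np.einsum("ij,ij->i", u, v), ru * rv, out=cosw, where=valid
    )
    omega = np.degrees(np.arccos(np.clip(cosw, -1.0, 1.0)))
    if return_valid:
        return omega, valid
    return omega


def mobility_series_set(trajectory: Trajectory) -> list[MobilitySeries]:
    """R and Omega series for every tracked Si of the trajectory."""
    topo = trajectory.topology
    out = []
    com_cache = {}
    core = _core_frames(trajectory)
    for a in topo.tracked_si:
        a = int(a)
        den = int(topo.dendron[a])
        if den not in com_cache:
            com_cache[den] = _dendron_com(trajectory, den)
        u = trajectory.coordinates[:, a, :] - core
        v = com_cache[den] - core
        ru = np.linalg.norm(u, axis=1)
        rv = np.linalg.norm(v, axis=1)
        valid = (ru > 1e-10) & (rv > 1e-10)
        cosw = np.full(len(u), np.nan)
        np.divide(np.einsum("ij,ij->i", u, v), ru * rv, out=cosw, where=valid)
        omega = np.degrees(np.arccos(np.clip(cosw, -1.0, 1.0)))
        out.append(
            MobilitySeries(atom_id=a, r=ru, omega=omega, layer=int(topo.layer[a]),
                           dendron=den, valid=valid)
        )
    return out


def layer_statistics(series_set: list[MobilitySeries], layer: int) -> LayerStats:
    """Pooled layer statistics over atoms x frames (x replicas).

    Supply the concatenation of the series sets of several replicas to
    pool over replicas as well.  Degenerate (invalid) frames are
    excluded from the Omega sample.
    """
    rs, ws = [], []
    for s in series_set:
        if s.layer != layer:
            continue
        rs.append(s.r)
        ws.append(s.omega[s.valid])
    if not rs:
        raise EmptyLayerError(f"no tracked atoms in layer {layer}")
    r = np.concatenate(rs)
    w = np.concatenate(ws)
    return LayerStats(
        layer=layer,
        mean_r=float(r.mean()),
        d_r=float(r.std()),
        r_range=float(r.max() - r.min()),
        mean_omega=float(w.mean()) if len(w) else float("nan"),
        d_omega=float(w.std()) if len(w) else float("nan"),
        omega_range=float(w.max() - w.min()) if len(w) else float("nan"),
        n_samples=int(len(r)),
    )


def layer_table(series_set: list[MobilitySeries], topology: DendrimerTopology) -> pd.DataFrame:
    """One row per layer (1..G), mirroring the layer-profile plots."""
    rows = []
    for layer in range(1, topology.generation + 1):
        st = layer_statistics(series_set, layer)
        rows.append(
            {
                "layer": layer,
                "mean_R": st.mean_r,
                "D_R": st.d_r,
                "R_range": st.r_range,
                "mean_Omega": st.mean_omega,
                "D_Omega": st.d_omega,
                "Omega_range": st.omega_range,
                "n_samples": st.n_samples,
            }
        )
    return pd.DataFrame(rows)


def mixing_time(
    series_set: list[MobilitySeries],
    layer: int,
    tolerance: float = 0.2,
    spacing: float | None = None,
) -> float | None:
    """Smallest averaging window after which layer atoms look alike.

    For window length ``T`` the per-atom averages of R (and Omega) over
    the first ``T`` of the trajectory are compared across atoms; the
    mixing time is the smallest ``T`` for which the between-atom standard
    deviation of those window means drops below ``tolerance`` times the
    pooled dispersion, for both observables.  Returns ``None`` ("not
    mixed") if no window achieves it.  ``spacing`` (ps per frame)
    converts the result to ps; 1.0 if omitted.
    """
    members = [s for s in series_set if s.layer == layer]
    if len(members) < 2:
        raise EmptyLayerError(f"mixing time needs >= 2 atoms in layer {layer}")
    spacing = 1.0 if spacing is None else float(spacing)
    r = np.array([s.r for s in members])          # (atoms, frames)
    w = np.array([np.where(s.valid, s.omega, np.nan) for s in members])
    pooled_dr = float(r.std())
    pooled_dw = float(np.nanstd(w))
    cum_r = np.cumsum(r, axis=1)
    cum_w = np.nancumsum(np.nan_to_num(w), axis=1)
    nf = r.shape[1]
    counts = np.arange(1, nf + 1)
    mean_r = cum_r / counts
    mean_w = cum_w / counts
    spread_r = mean_r.std(axis=0)
    spread_w = mean_w.std(axis=0)
    ok_r = spread_r <= tolerance * max(pooled_dr, 1e-300)
    ok_w = spread_w <= tolerance * max(pooled_dw, 1e-300)
    ok = ok_r & ok_w
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return None
    return float((idx[0] + 1) * spacing)


def gyration_and_shape(trajectory: Trajectory):
    """Mass-weighted radius of gyration and shape factor per frame.

    The shape factor is the ratio of the largest to the smallest
    eigenvalue of the gyration tensor (1 for a sphere-symmetric cloud).
    """
    topo = trajectory.topology
    m = topo.masses if topo is not None else np.ones(trajectory.n_atoms)
    xyz = trajectory.coordinates
    com = np.einsum("fad,a->fd", xyz, m) / m.sum()
    d = xyz - com[:, None, :]
    rg2 = np.einsum("fad,fad,a->f", d, d, m) / m.sum()
    gyr = np.einsum("fai,faj,a->fij", d, d, m) / m.sum()
    eig = np.linalg.eigvalsh(gyr)
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = np.where(eig[:, 0] > 1e-12, eig[:, 2] / np.maximum(eig[:, 0], 1e-300), np.inf)
        shape = np.where(rg2 < 1e-12, 1.0, shape)
    return np.sqrt(rg2), shape
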