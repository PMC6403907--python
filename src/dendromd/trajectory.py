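"""Trajectory container and file I/O (XYZ and PDB+DCD).

A :class:`Trajectory` is an ordered stack of coordinate frames with a
uniform time spacing, optionally linked to a
:class:`~dendromd.topology.DendrimerTopology` so analysis code can look
up layers, dendrons and masses.  Coordinates are stored and written in
angstrom, times in ps.

The XYZ dialect written here is the plain one: an atom-count line, a
comment line carrying ``t=<ps>``, then ``element x y z`` records.  DCD
frames are read and written through MDAnalysis; the frame spacing is
carried in the DCD header where the format supports it and validated
against ``expected_spacing`` on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import TrajectoryMismatchError

_XYZ_FMT = "{:2s} {: .8f} {: .8f} {: .8f}\n"


@dataclass
class Trajectory:
    """Frames (n_frames, n_atoms, 3) in A at uniform spacing (ps)."""

    coordinates: np.ndarray
    spacing: float
    origin: float = 0.0
    topology: object = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryMismatchError("coordinates must have shape (frames, atoms, 3)")
        if self.n_frames < 1:
            raise TrajectoryMismatchError("a trajectory needs at least one frame")
        if self.spacing <= 0:
            raise TrajectoryMismatchError("frame spacing must be positive")
        if self.topology is not None and self.topology.n_atoms != self.n_atoms:
            raise TrajectoryMismatchError(
                f"topology has {self.topology.n_atoms} atoms, trajectory has {self.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.origin + self.spacing * np.arange(self.n_frames)

    def slice(self, start: int = 0, stop: int | None = None, step: int = 1) -> "Trajectory":
        sub = self.coordinates[start:stop:step]
        return Trajectory(
            sub,
            spacing=self.spacing * step,
            origin=self.origin + self.spacing * start,
            topology=self.topology,
        )

    def _elements(self):
        if self.topology is not None:
            return self.topology.elements
        return ["C"] * self.n_atoms


def write_trajectory(
    trajectory: Trajectory,
    path,
    format: str | None = None,
    overwrite: bool = True,
    append: bool = False,
) -> None:
    """Write a trajectory; format inferred from the extension if omitted.

    ``append`` (XYZ only) adds frames to an existing file, so chunked
    writes produce byte-identical output to a one-shot write.  With
    ``overwrite=False`` an existing file raises :class:`FileExistsError`.
    """
    path = str(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if not overwrite and os.path.exists(path) and not append:
        raise FileExistsError(path)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    if fmt == "xyz":
        _write_xyz(trajectory, path, append)
    elif fmt == "dcd":
        _write_dcd(trajectory, path)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")


def read_trajectory(
    path,
    topology=None,
    expected_spacing: float | None = None,
    format: str | None = None,
) -> Trajectory:
    """Read XYZ or DCD frames in file order.

    The spacing recorded in the file (XYZ ``t=`` comments, DCD header)
    is validated against ``expected_spacing`` when both are present;
    an atom-count mismatch with ``topology`` raises
    :class:`TrajectoryMismatchError`.
    """
    path = str(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt == "xyz":
        coords, origin, spacing = _read_xyz(path)
    elif fmt == "dcd":
        coords, origin, spacing = _read_dcd(path)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")
    if spacing is not None and expected_spacing is not None:
        if not np.isclose(spacing, expected_spacing, rtol=1e-6, atol=1e-9):
            raise TrajectoryMismatchError(
                f"file spacing {spacing} ps does not match expected {expected_spacing} ps"
            )
    final = spacing if spacing is not None else expected_spacing
    if final is None:
        final = 1.0
    if topology is not None and topology.n_atoms != coords.shape[1]:
        raise TrajectoryMismatchError(
            f"topology has {topology.n_atoms} atoms, file has {coords.shape[1]}"
        )
    return Trajectory(coords, spacing=float(final), origin=origin or 0.0, topology=topology)


# -- XYZ --------------------------------------------------------------------


def _write_xyz(trajectory, path, append):
    elements = trajectory._elements()
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for fi in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(f"t={trajectory.times[fi]:.6f} ps\n")
            for el, (x, y, z) in zip(elements, trajectory.coordinates[fi]):
                fh.write(_XYZ_FMT.format(el, x, y, z))


def _read_xyz(path):
    frames, times = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    fi = 0
    n_atoms = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryMismatchError(f"bad atom-count line at frame {fi}") from exc
        if n_atoms is None:
            n_atoms = n
        elif n != n_atoms:
            raise TrajectoryMismatchError(f"atom count changed at frame {fi}: {n} != {n_atoms}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = None
        for tok in comment.replace(",", " ").split():
            if tok.startswith("t="):
                try:
                    t = float(tok[2:])
                except ValueError:
                    pass
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise TrajectoryMismatchError(f"truncated frame {fi}: expected {n} atom lines")
        xyz = np.empty((n, 3))
        for a, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise TrajectoryMismatchError(f"unreadable atom line in frame {fi}, atom {a}")
            xyz[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(xyz)
        times.append(t)
        i += 2 + n
        fi += 1
    if not frames:
        raise TrajectoryMismatchError("no frames found")
    coords = np.asarray(frames)
    origin = times[0] if times[0] is not None else 0.0
    spacing = None
    if len(times) > 1 and times[0] is not None and times[1] is not None:
        spacing = times[1] - times[0]
    return coords, origin, spacing


# -- DCD (via MDAnalysis) ---------------------------------------------------


def _write_dcd(trajectory, path):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    u = mda.Universe.empty(trajectory.n_atoms, trajectory=True)
    u.load_new(
        trajectory.coordinates.astype(np.float32), format=MemoryReader, dt=trajectory.spacing
    )
    with mda.Writer(path, trajectory.n_atoms, dt=trajectory.spacing) as w:
        for ts in u.trajectory:
            w.write(u.atoms)


def _read_dcd(path):
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(path)
    coords = np.array([ts.positions.copy() for ts in reader], dtype=np.float64)
    spacing = None
    try:
        spacing = float(reader.ts.dt)
    except Exception:
        pass
    reader.close()
    return coords, 0.0, spacing
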