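"""Inter-dendron angles, their fluctuations and cross-correlations.

For each frame the angle between every pair of core-to-dendron-COM
vectors is computed: 3 angles for a trifunctional core, 6 for a
tetrafunctional one.  For tetrafunctional cores the six angles split
into two "big" and four "small" ones; the split is assigned per
trajectory by ranking the time-mean angles (the two largest are "big"),
which for tetrahedral-like geometries selects the two disjoint dendron
pairs and is invariant under dendron relabelling.

Cross-correlations between the angle time series (product-moment
coefficients) quantify the collective motion of dendrons; positive
pairs move in phase, negative pairs in anti-phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .trajectory import Trajectory


@dataclass
class DendronAngleSet:
    pairs: list                 # (dendron_i, dendron_j), 1-based
    angles: np.ndarray          # (frames, n_pairs), deg
    spacing: float              # ps
    classification: list        # "big" / "small" per pair (tetrafunctional), else ""

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def summary(self) -> pd.DataFrame:
        rows = []
        for p, (i, j) in enumerate(self.pairs):
            a = self.angles[:, p]
            rows.append(
                {
                    "dendron_i": i,
                    "dendron_j": j,
                    "mean_deg": float(a.mean()),
                    "deviation_deg": float(a.std()),
                    "range_deg": float(a.max() - a.min()),
                    "class": self.classification[p],
                }
            )
        return pd.DataFrame(rows)


def dendron_angles(trajectory: Trajectory) -> DendronAngleSet:
    """Per-frame pairwise angles between core->dendron-COM unit vectors."""
    topo = trajectory.topology
    f = topo.core_functionality
    if f < 2:
        raise ValueError("need at least two dendrons")
    core = trajectory.coordinates[:, topo.core_atom_id, :]
    vecs = []
    for d in range(1, f + 1):
        members = topo.dendron_members(d)
        m = topo.masses[members]
        com = np.einsum("fad,a->fd", trajectory.coordinates[:, members, :], m) / m.sum()
        v = com - core
        norm = np.linalg.norm(v, axis=1)
        if np.any(norm < 1e-10):
            raise ValueError(f"dendron {d} centre of mass degenerate at the core")
        vecs.append(v / norm[:, None])
    pairs = list(combinations(range(1, f + 1), 2))
    angles = np.empty((trajectory.n_frames, len(pairs)))
    for p, (i, j) in enumerate(pairs):
        c = np.einsum("fd,fd->f", vecs[i - 1], vecs[j - 1])
        angles[:, p] = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    classification = [""] * len(pairs)
    if f == 4:
        means = angles.mean(axis=0)
        big = set(np.argsort(means)[-2:])
        classification = ["big" if p in big else "small" for p in range(len(pairs))]
    return DendronAngleSet(
        pairs=pairs, angles=angles, spacing=trajectory.spacing, classification=classification
    )


def angle_correlations(angle_set: DendronAngleSet) -> pd.DataFrame:
    """Product-moment correlation matrix between all angle time series.

    Off-diagonal signs label pair motion: positive = in phase, negative
    = anti-phase.  Zero-variance series raise ValueError.
    """
    a = angle_set.angles
    if a.shape[0] < 2:
        raise ValueError("need at least two frames for correlations")
    if np.any(a.std(axis=0) == 0):
        raise ValueError("zero-variance angle series")
    corr = np.corrcoef(a.T)
    labels = [f"{i}-{j}" for i, j in angle_set.pairs]
    return pd.DataFrame(corr, index=labels, columns=labels)


def phase_labels(corr: pd.DataFrame) -> pd.DataFrame:
    """Long-form table of angle-pair correlations with in/anti-phase labels."""
    rows = []
    labels = list(corr.index)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            c = float(corr.iloc[a, b])
            rows.append(
                {
                    "pair_a": labels[a],
                    "pair_b": labels[b],
                    "correlation": c,
                    "phase": "in-phase" if c >= 0 else "anti-phase",
                }
            )
    return pd.DataFrame(rows)
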