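"""Energy model for vacuum dendrimer MD.

The functional forms are the standard class-I set: harmonic bond
stretching ``k (r - r0)^2``, harmonic angle bending ``k (theta -
theta0)^2``, a periodic cosine series for torsions (carbosilane
skeletons only), Lennard-Jones with a 1.05 nm cutoff (energy-shifted so
the potential is continuous at the cutoff) and a screened Coulomb
potential

    U_q(r) = K q_i q_j / r * W_q(r),    W_q(r) = (1 - r/R_q)^2  (r < R_q)

which, with the screening radius ``R_q`` set equal to the LJ cutoff,
vanishes together with its radial derivative at ``R_q`` — no long-range
part and no cutoff discontinuity.

Numeric parameter values shipped here are editable defaults in the
PCFF/AMBER style (the analyses in this package make structure- and
symmetry-level claims that are robust to reasonable choices); they can
be overridden wholesale from a YAML file via
:meth:`ForceFieldParams.from_yaml`.

Non-bonded exclusions follow the common convention: 1-2 and 1-3 pairs
excluded, 1-4 and beyond included at full strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ._kernels import HAVE_NUMBA, _nonbonded_kernel
from .errors import ParameterizationError
from .topology import DendrimerTopology, _base_type
from .units import COULOMB_K

DEFAULT_CUTOFF = 10.5  # A (1.05 nm)

# ---------------------------------------------------------------------------
# Editable default parameter tables (united-atom sites share elemental C
# bonded parameters; LJ is per explicit site type).

DEFAULT_BONDS = {  # (k kcal/mol/A^2, r0 A)
    ("Si", "O"): (350.0, 1.64),
    ("Si", "C"): (190.0, 1.87),
    ("C", "C"): (310.0, 1.53),
    ("C", "H"): (340.0, 1.09),
}

DEFAULT_ANGLES = {  # (k kcal/mol/rad^2, theta0 deg)
    ("O", "Si", "O"): (70.0, 109.47),
    ("O", "Si", "C"): (60.0, 109.47),
    ("C", "Si", "C"): (60.0, 109.47),
    ("Si", "O", "Si"): (35.0, 144.0),
    ("Si", "C", "C"): (60.0, 112.0),
    ("Si", "C", "H"): (45.0, 110.0),
    ("C", "C", "C"): (63.0, 112.7),
    ("C", "C", "H"): (50.0, 110.7),
    ("H", "C", "H"): (35.0, 107.8),
}

# Cosine series per central-bond type: list of (V kcal/mol, n, gamma deg);
# V is divided equally among the torsion quadruples sharing a central bond
# (the AMBER X-A-B-X convention), so the barrier per bond is ~V.
DEFAULT_TORSIONS = {
    ("C", "C"): [(1.4, 3, 0.0)],
    ("Si", "C"): [(0.9, 3, 0.0)],
}

DEFAULT_LJ = {  # site type -> (epsilon kcal/mol, sigma A)
    "Si": (0.40, 3.80),
    "O": (0.15, 3.00),
    "C": (0.066, 3.40),
    "H": (0.026, 2.47),
    "CH2": (0.118, 3.95),
    "CH3": (0.175, 3.75),
}


def _sym2(d, a, b):
    return d.get((a, b)) or d.get((b, a))


def _sym3(d, a, b, c):
    return d.get((a, b, c)) or d.get((c, b, a))


@dataclass
class ForceFieldParams:
    """Parameter set plus cutoff/screening settings.

    ``include_torsions`` controls whether the dihedral term is evaluated;
    carbosilane skeletons use it, the siloxane families are modelled
    torsion-free (their rotational states are much less sharply defined).
    """

    bonds: dict = field(default_factory=lambda: dict(DEFAULT_BONDS))
    angles: dict = field(default_factory=lambda: dict(DEFAULT_ANGLES))
    torsions: dict = field(default_factory=lambda: dict(DEFAULT_TORSIONS))
    lj: dict = field(default_factory=lambda: dict(DEFAULT_LJ))
    cutoff: float = DEFAULT_CUTOFF
    screening_radius: float = DEFAULT_CUTOFF
    include_torsions: bool = True
    coulomb: bool = True

    def __post_init__(self):
        if self.cutoff <= 0 or self.screening_radius <= 0:
            raise ParameterizationError("cutoff and screening radius must be positive")
        for key, (k, _) in self.bonds.items():
            if k <= 0:
                raise ParameterizationError(f"non-positive bond stiffness for {key}")
        for t, (eps, sig) in self.lj.items():
            if eps < 0 or sig <= 0:
                raise ParameterizationError(f"bad LJ parameters for type {t}")

    def bond_params(self, t1, t2):
        p = _sym2(self.bonds, _base_type(t1), _base_type(t2))
        if p is None:
            raise ParameterizationError(f"no bond parameters for type ({t1}, {t2})")
        return p

    def angle_params(self, t1, t2, t3):
        p = _sym3(self.angles, _base_type(t1), _base_type(t2), _base_type(t3))
        if p is None:
            raise ParameterizationError(f"no angle parameters for type ({t1}, {t2}, {t3})")
        return p

    def torsion_params(self, t2, t3):
        """Series for a central bond type, or None if the bond has no torsion term."""
        return _sym2(self.torsions, _base_type(t2), _base_type(t3))

    def lj_params(self, t):
        if t not in self.lj:
            raise ParameterizationError(f"no Lennard-Jones parameters for type {t}")
        return self.lj[t]

    @classmethod
    def for_family(cls, family: str) -> "ForceFieldParams":
        """Defaults for a dendrimer family: torsion term only for carbosilanes."""
        return cls(include_torsions=family in ("c3", "c4"))

    @classmethod
    def from_yaml(cls, path) -> "ForceFieldParams":
        """Load overrides from YAML (keys: bonds, angles, torsions, lj, cutoff...).

        Tuple-valued table keys are written as '|'-joined type names,
        e.g. ``"Si|O": [350.0, 1.64]``.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for name in ("bonds", "angles", "lj", "torsions"):
            if name in raw:
                table = {}
                for key, val in raw[name].items():
                    tkey = tuple(key.split("|")) if "|" in str(key) else key
                    if name == "torsions":
                        table[tkey] = [tuple(v) for v in val]
                    elif name == "lj":
                        table[key] = tuple(val)
                    else:
                        table[tkey] = tuple(val)
                kw[name] = table
        for name in ("cutoff", "screening_radius", "include_torsions", "coulomb"):
            if name in raw:
                kw[name] = raw[name]
        return cls(**kw)


def default_params(family: str = "c3") -> ForceFieldParams:
    return ForceFieldParams.for_family(family)


# ---------------------------------------------------------------------------
# Screened Coulomb


def screened_coulomb_energy(q_i: float, q_j: float, r, r_q: float = DEFAULT_CUTOFF):
    """Screened Coulomb pair energy, kcal/mol (charges in e, r in A).

    Zero for ``r >= r_q``; both the energy and its radial derivative are
    continuous at the screening radius.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("screened Coulomb potential is singular at r = 0")
    w = np.where(r < r_q, (1.0 - r / r_q) ** 2, 0.0)
    out = COULOMB_K * q_i * q_j / r * w
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Compiled per-topology parameter arrays


class CompiledForceField:
    """Parameter tables resolved to flat index arrays for one topology."""

    def __init__(self, topology: DendrimerTopology, params: ForceFieldParams):
        self.topology = topology
        self.params = params
        tps = topology.site_types
        n = topology.n_atoms

        bonds = topology.bonds
        bk = np.empty(len(bonds))
        br0 = np.empty(len(bonds))
        for m, (i, j) in enumerate(bonds):
            bk[m], br0[m] = params.bond_params(tps[i], tps[j])
        self.bond_ij = bonds
        self.bond_k = bk
        self.bond_r0 = br0

        angles = topology.angles
        ak = np.empty(len(angles))
        at0 = np.empty(len(angles))
        for m, (i, j, k) in enumerate(angles):
            kk, t0 = params.angle_params(tps[i], tps[j], tps[k])
            ak[m], at0[m] = kk, np.deg2rad(t0)
        self.angle_ijk = angles
        self.angle_k = ak
        self.angle_t0 = at0

        # torsions: expand the series, dividing V by the quadruple count
        # sharing each central bond
        tor_idx, tor_v, tor_n, tor_g = [], [], [], []
        if params.include_torsions and len(topology.torsions):
            quads = topology.torsions
            central = {}
            for (i, j, k, l) in quads:
                key = (min(j, k), max(j, k))
                central[key] = central.get(key, 0) + 1
            for (i, j, k, l) in quads:
                series = params.torsion_params(tps[j], tps[k])
                if not series:
                    continue
                mult = central[(min(j, k), max(j, k))]
                for (v, nn, g) in series:
                    tor_idx.append((i, j, k, l))
                    tor_v.append(v / mult)
                    tor_n.append(nn)
                    tor_g.append(np.deg2rad(g))
        self.tor_ijkl = np.asarray(tor_idx, dtype=np.int64).reshape(-1, 4)
        self.tor_v = np.asarray(tor_v)
        self.tor_n = np.asarray(tor_n, dtype=np.float64)
        self.tor_g = np.asarray(tor_g)

        # LJ mixing matrices over the site types present
        uniq = sorted(set(tps))
        tmap = {t: m for m, t in enumerate(uniq)}
        eps = np.array([params.lj_params(t)[0] for t in uniq])
        sig = np.array([params.lj_params(t)[1] for t in uniq])
        self.type_index = np.array([tmap[t] for t in tps], dtype=np.int64)
        self.eps_mat = np.sqrt(np.outer(eps, eps))
        self.sig_mat = 0.5 * (sig[:, None] + sig[None, :])
        self.charges = topology.charges.copy()

        self.cutoff = params.cutoff
        self.r_q = params.screening_radius

        # exclusions: 1-2 and 1-3
        excl = set()
        for i, j in bonds:
            excl.add(self._key(i, j, n))
        for i, j, k in angles:
            excl.add(self._key(i, k, n))
        self._n = n
        self.exclusions = excl
        self._pair_cache = None

    @staticmethod
    def _key(i, j, n):
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        return i * n + j

    def all_pairs(self) -> np.ndarray:
        """All non-excluded atom pairs (i < j); fine for small systems."""
        n = self._n
        iu, ju = np.triu_indices(n, k=1)
        keys = iu.astype(np.int64) * n + ju
        mask = ~np.isin(keys, np.fromiter(self.exclusions, dtype=np.int64, count=len(self.exclusions)))
        return np.column_stack([iu[mask], ju[mask]]).astype(np.int64)

    def filter_excluded(self, pairs: np.ndarray) -> np.ndarray:
        if len(pairs) == 0:
            return pairs.reshape(-1, 2)
        keys = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64) * self._n + np.maximum(
            pairs[:, 0], pairs[:, 1]
        )
        mask = ~np.isin(keys, np.fromiter(self.exclusions, dtype=np.int64, count=len(self.exclusions)))
        return pairs[mask]

    def _pair_tables(self, pairs: np.ndarray):
        """Per-pair LJ/charge parameters, cached per pair-list object.

        The neighbour list returns the same array object until it is
        rebuilt, so the gather cost is paid once per rebuild.
        """
        key = id(pairs)
        if self._pair_cache is not None and self._pair_cache[0] == key:
            return self._pair_cache[1]
        pi = np.ascontiguousarray(pairs[:, 0])
        pj = np.ascontiguousarray(pairs[:, 1])
        ti, tj = self.type_index[pi], self.type_index[pj]
        eps = self.eps_mat[ti, tj]
        sig = self.sig_mat[ti, tj]
        if self.params.coulomb:
            qq = COULOMB_K * self.charges[pi] * self.charges[pj]
        else:
            qq = np.zeros(len(pi))
        tab = (pi, pj, eps, sig, qq)
        self._pair_cache = (key, tab)
        return tab

    # -- energy/forces --------------------------------------------------

    def energy_forces(self, coords: np.ndarray, pairs: np.ndarray | None = None):
        """Total potential energy (kcal/mol) and per-atom forces (kcal/mol/A).

        ``pairs`` is a non-bonded pair list already purged of exclusions
        (e.g. from a neighbour list); ``None`` means all non-excluded
        pairs.  Returns ``(energy, forces, components)``.
        """
        x = np.asarray(coords, dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        f = np.zeros_like(x)
        comp = {}

        # bonds
        i, j = self.bond_ij[:, 0], self.bond_ij[:, 1]
        d = x[j] - x[i]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.bond_r0
        comp["bond"] = float(np.sum(self.bond_k * dr**2))
        fb = (2.0 * self.bond_k * dr / r)[:, None] * d  # dU/dx_j
        np.add.at(f, j, -fb)
        np.add.at(f, i, fb)

        # angles
        if len(self.angle_ijk):
            ai, aj, ak = self.angle_ijk.T
            u = x[ai] - x[aj]
            v = x[ak] - x[aj]
            ru = np.linalg.norm(u, axis=1)
            rv = np.linalg.norm(v, axis=1)
            c = np.einsum("ij,ij->i", u, v) / (ru * rv)
            c = np.clip(c, -1.0, 1.0)
            theta = np.arccos(c)
            s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
            dt = theta - self.angle_t0
            comp["angle"] = float(np.sum(self.angle_k * dt**2))
            dU = 2.0 * self.angle_k * dt
            # dtheta/dxi and dtheta/dxk
            gi = -(v / (ru * rv)[:, None] - (c / ru**2)[:, None] * u) / s[:, None]
            gk = -(u / (ru * rv)[:, None] - (c / rv**2)[:, None] * v) / s[:, None]
            np.add.at(f, ai, -dU[:, None] * gi)
            np.add.at(f, ak, -dU[:, None] * gk)
            np.add.at(f, aj, dU[:, None] * (gi + gk))
        else:
            comp["angle"] = 0.0

        # torsions
        if len(self.tor_ijkl):
            ti, tj, tk, tl = self.tor_ijkl.T
            b1 = x[tj] - x[ti]
            b2 = x[tk] - x[tj]
            b3 = x[tl] - x[tk]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            xx = np.einsum("ij,ij->i", n1, n2)
            yy = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2
            phi = np.arctan2(yy, xx)
            comp["torsion"] = float(
                np.sum(self.tor_v / 2.0 * (1.0 + np.cos(self.tor_n * phi - self.tor_g)))
            )
            dU = -0.5 * self.tor_v * self.tor_n * np.sin(self.tor_n * phi - self.tor_g)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            gi = -(nb2 / n1sq)[:, None] * n1
            gl = (nb2 / n2sq)[:, None] * n2
            d12 = np.einsum("ij,ij->i", b1, b2) / nb2**2
            d32 = np.einsum("ij,ij->i", b3, b2) / nb2**2
            gj = (-d12 - 1.0)[:, None] * gi + d32[:, None] * gl
            gk = (-d32 - 1.0)[:, None] * gl + d12[:, None] * gi
            np.add.at(f, ti, -dU[:, None] * gi)
            np.add.at(f, tj, -dU[:, None] * gj)
            np.add.at(f, tk, -dU[:, None] * gk)
            np.add.at(f, tl, -dU[:, None] * gl)
        else:
            comp["torsion"] = 0.0

        # non-bonded
        if pairs is None:
            pairs = self.all_pairs()
        e_lj = 0.0
        e_q = 0.0
        if len(pairs):
            pi, pj, eps, sig, qq = self._pair_tables(pairs)
            if HAVE_NUMBA:
                e_lj, e_q = _nonbonded_kernel(
                    x, pi, pj, eps, sig, qq, self.cutoff, self.r_q, f
                )
            else:
                d = x[pj] - x[pi]
                r2 = np.einsum("ij,ij->i", d, d)
                within = r2 < self.cutoff**2
                pi_, pj_, d, r2 = pi[within], pj[within], d[within], r2[within]
                eps_, sig_, qq_ = eps[within], sig[within], qq[within]
                if len(pi_):
                    r = np.sqrt(r2)
                    sr6 = (sig_**2 / r2) ** 3
                    sr12 = sr6 * sr6
                    src6 = (sig_ / self.cutoff) ** 6
                    e_lj = float(np.sum(4.0 * eps_ * (sr12 - sr6 - (src6 * src6 - src6))))
                    dU = 4.0 * eps_ * (-12.0 * sr12 + 6.0 * sr6) / r  # dU/dr
                    w = np.where(r < self.r_q, 1.0 - r / self.r_q, 0.0)
                    e_q = float(np.sum(qq_ / r * w**2))
                    dU = dU + qq_ * (-(w**2) / r2 - 2.0 * w / (r * self.r_q))
                    fp = (dU / r)[:, None] * d  # force on j is -dU/dx_j
                    nn = self._n
                    for c3 in range(3):
                        f[:, c3] -= np.bincount(pj_, weights=fp[:, c3], minlength=nn)
                        f[:, c3] += np.bincount(pi_, weights=fp[:, c3], minlength=nn)
        comp["lj"] = float(e_lj)
        comp["coulomb"] = float(e_q)

        energy = sum(comp.values())
        return energy, f, comp


def total_energy_forces(
    topology: DendrimerTopology,
    coordinates: np.ndarray,
    params: ForceFieldParams | None = None,
    pairs: np.ndarray | None = None,
):
    """One-shot energy/force evaluation.

    Convenience wrapper that compiles the parameter tables for this
    topology and evaluates; for repeated evaluation (integration,
    minimisation) build a :class:`CompiledForceField` once.
    Forces are the exact negative gradient of the energy.
    """
    if params is None:
        params = ForceFieldParams.for_family(topology.recipe.family)
    return CompiledForceField(topology, params).energy_forces(coordinates, pairs)
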