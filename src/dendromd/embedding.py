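"""Initial non-overlapping 3D embedding of a dendrimer topology.

Atoms are grown outward from the core in BFS order using internal
coordinates: every bond is placed at its equilibrium length, every
valence angle at its equilibrium value, and the dihedral around the
parent bond is chosen from a set of staggered-plus-jitter candidates by
an open-direction heuristic (maximise the minimum distance to already
placed atoms).  The grown structure is then relaxed by L-BFGS descent
on the full force field — the LJ repulsion resolves any steric clashes
that survive the growth in crowded high-generation peripheries — and
polished with stiffened bond/angle terms so the bonded geometry ends up
back at equilibrium.

The result satisfies, and :func:`initial_coordinates` verifies, the
embedding contract: no non-bonded pair (1-4 or further) closer than the
clash distance, bond lengths within 2% of equilibrium and valence
angles within 5 degrees of equilibrium.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmbeddingError
from .forcefield import ForceFieldParams
from .topology import DendrimerTopology

TETRAHEDRAL_DIRS = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)

N_CANDIDATES = 8


def _frame(axis: np.ndarray):
    """Two unit vectors orthogonal to ``axis``."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def initial_coordinates(
    topology: DendrimerTopology,
    seed: int | None = None,
    params: ForceFieldParams | None = None,
    clash_distance: float = 1.5,
    relax: bool = True,
    check: bool = True,
    max_retries: int = 3,
) -> np.ndarray:
    """Build an initial conformation (angstrom), deterministic per seed.

    Raises :class:`EmbeddingError` (naming the worst colliding pair) if a
    clash below ``clash_distance`` cannot be resolved.
    """
    if seed is None:
        seed = topology.recipe.seed
    if params is None:
        params = ForceFieldParams.for_family(topology.recipe.family)
    last_exc = None
    for attempt in range(max_retries):
        attempt_seed = int(seed) + 7919 * attempt
        x = _grow(topology, attempt_seed, params)
        if relax:
            x = _relax(topology, x, params, clash_distance)
        if not check:
            return x
        try:
            _verify(topology, x, params, clash_distance)
            return x
        except EmbeddingError as exc:
            last_exc = exc
    raise last_exc


def _grow(topology: DendrimerTopology, seed: int, params: ForceFieldParams) -> np.ndarray:
    """Internal-coordinate BFS growth (bonds/angles exact, dihedrals chosen)."""
    rng = np.random.default_rng(int(seed))
    tps = topology.site_types
    n = topology.n_atoms
    x = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)
    parent = topology.parent
    order = topology.bfs_order
    core = topology.core_atom_id

    # children grouped per parent, in BFS order
    children: list[list[int]] = [[] for _ in range(n)]
    for a in order[1:]:
        children[parent[a]].append(int(a))

    placed[core] = True
    # random global orientation for the core substituents
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(int(seed) % 2**32))
    core_dirs = rot.apply(TETRAHEDRAL_DIRS)
    for m, c in enumerate(children[core]):
        r0 = params.bond_params(tps[core], tps[c])[1]
        x[c] = x[core] + r0 * core_dirs[m % 4]
        placed[c] = True

    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=n)  # per-parent dihedral origin

    for p in order:
        p = int(p)
        if p == core or not children[p]:
            continue
        g = int(parent[p])
        axis = x[p] - x[g]
        axis /= np.linalg.norm(axis)
        e1, e2 = _frame(axis)
        placed_idx = np.flatnonzero(placed)
        # exclude only the parent and grandparent from scoring: their
        # distances to any candidate are fixed by the internal coordinates,
        # while already-placed siblings must repel later candidates
        near = {p, g}
        score_idx = np.array([a for a in placed_idx if a not in near], dtype=np.int64)
        for m, c in enumerate(children[p]):
            r0 = params.bond_params(tps[p], tps[c])[1]
            th0 = np.deg2rad(params.angle_params(tps[g], tps[p], tps[c])[1])
            base = phi0[p] + m * (2.0 * np.pi / 3.0)
            cand_phi = base + np.concatenate([[0.0], rng.uniform(-0.5, 0.5, N_CANDIDATES - 1)])
            best, best_score = None, -np.inf
            for phi in cand_phi:
                d = -np.cos(th0) * axis + np.sin(th0) * (np.cos(phi) * e1 + np.sin(phi) * e2)
                pos = x[p] + r0 * d
                if len(score_idx):
                    s = np.min(np.linalg.norm(x[score_idx] - pos, axis=1))
                else:
                    s = np.inf
                if s > best_score:
                    best, best_score = pos, s
            x[c] = best
            placed[c] = True
            score_idx = np.append(score_idx, c)

    return x


def _clash_pairs(topology, x, clash_distance):
    tree = cKDTree(x)
    pairs = np.asarray(sorted(tree.query_pairs(clash_distance)), dtype=np.int64).reshape(-1, 2)
    if len(pairs) == 0:
        return pairs
    excl = _excluded_set(topology)
    keys = pairs[:, 0] * topology.n_atoms + pairs[:, 1]
    mask = ~np.isin(keys, excl)
    return pairs[mask]


def _excluded_set(topology):
    n = topology.n_atoms
    keys = []
    for i, j in topology.bonds:
        i, j = (i, j) if i < j else (j, i)
        keys.append(i * n + j)
    for i, _, k in topology.angles:
        i, k = (i, k) if i < k else (k, i)
        keys.append(i * n + k)
    return np.unique(np.asarray(keys, dtype=np.int64))


def _relax(topology, x, params, clash_distance):
    """Two-stage L-BFGS relaxation of a freshly grown embedding.

    Stage one descends the full force field (LJ repulsion separates
    clashing subtrees far more effectively than any soft core); stage
    two polishes with 20x-stiffened bond/angle terms so the non-bonded
    pressure of crowded peripheries cannot hold the bonded geometry
    away from equilibrium.
    """
    from scipy.optimize import minimize as _spmin

    from .forcefield import CompiledForceField, ForceFieldParams

    def lbfgs(x, prm, maxiter):
        c = CompiledForceField(topology, prm)
        pairs = c.all_pairs()

        def fun(flat):
            e, f, _ = c.energy_forces(flat.reshape(-1, 3), pairs)
            return e, -f.ravel()

        res = _spmin(fun, x.ravel(), jac=True, method="L-BFGS-B",
                     options={"maxiter": maxiter})
        return res.x.reshape(-1, 3)

    x = lbfgs(x, params, 500)
    for mult in (20, 100, 400):
        stiff = ForceFieldParams(
            bonds={k: (kk * mult, r0) for k, (kk, r0) in params.bonds.items()},
            angles={k: (kk * mult, t0) for k, (kk, t0) in params.angles.items()},
            torsions={},
            include_torsions=False,
            coulomb=False,
            lj=params.lj,
            cutoff=params.cutoff,
            screening_radius=params.screening_radius,
        )
        x = lbfgs(x, stiff, 400)
        if _contract_ok(topology, x, params, clash_distance):
            break
    return x


def _contract_ok(topology, x, params, clash_distance):
    try:
        _verify(topology, x, params, clash_distance)
    except EmbeddingError:
        return False
    return True


def _verify(topology, x, params, clash_distance):
    pairs = _clash_pairs(topology, x, clash_distance)
    if len(pairs):
        d = np.linalg.norm(x[pairs[:, 1]] - x[pairs[:, 0]], axis=1)
        worst = pairs[np.argmin(d)]
        raise EmbeddingError(
            f"unresolved clash: atoms {int(worst[0])} and {int(worst[1])} at "
            f"{d.min():.2f} A < {clash_distance} A",
            clashing_pair=(int(worst[0]), int(worst[1])),
        )
    tps = topology.site_types
    for i, j in topology.bonds:
        r0 = params.bond_params(tps[i], tps[j])[1]
        r = np.linalg.norm(x[j] - x[i])
        if abs(r - r0) > 0.02 * r0:
            raise EmbeddingError(f"bond {i}-{j} off equilibrium: {r:.3f} vs {r0:.3f} A")
    for i, j, k in topology.angles:
        t0 = params.angle_params(tps[i], tps[j], tps[k])[1]
        u = x[i] - x[j]
        v = x[k] - x[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        th = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
        if abs(th - t0) > 5.0:
            raise EmbeddingError(f"angle {i}-{j}-{k} off equilibrium: {th:.1f} vs {t0:.1f} deg")
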