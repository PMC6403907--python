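"""Molecular-graph construction for the four dendrimer families.

Four chemistries are supported, named after the two siloxane and two
carbosilane homologue rows they represent:

* ``s``  — siloxane, trifunctional Si-(CH3) core, short ``-O-`` spacers,
  trimethylsilyl termini;
* ``l``  — siloxane, trifunctional Si-(CH3) core, long ``-O-Si(CH3)2-O-``
  spacers, trimethylsilyl termini;
* ``c3`` — carbosilane, trifunctional Si core, ``-(CH2)3-`` spacers,
  ``-(CH2)3-CH3`` (butyl) terminal segments;
* ``c4`` — carbosilane, tetrafunctional Si core, otherwise as ``c3``.

The skeleton is a rooted tree of branching Si atoms: layer 0 is the core,
layer ``i`` holds ``f * b**(i-1)`` branching Si (``f`` = core
functionality, ``b`` = branch multiplicity, 2 by default).  Every
non-core atom belongs to exactly one dendron (branch subtree of the
core).  Both a united-atom representation (CH2/CH3 as single sites) and
an explicit all-atom representation are available; all analyses track Si
positions and skeleton torsions, so they are representation-agnostic.

Layer labels on non-skeleton atoms follow the segment they belong to:
spacer atoms carry the layer of the branching Si they lead to, pendant
methyls carry their Si's layer, and terminal segments (beyond the
outermost branching Si) carry layer ``G+1``.  The "terminal tracking
atoms" of layer ``G+1`` are the outermost branching Si themselves — the
atoms whose radial/angular motion represents the terminal groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import yaml

from .errors import InvalidRecipeError
from .units import MASSES

FAMILIES = ("s", "l", "c3", "c4")
CORE_FUNCTIONALITY = {"s": 3, "l": 3, "c3": 3, "c4": 4}
REPRESENTATIONS = ("united-atom", "all-atom")

# Bond-increment partial charges (e): amount moved from the first-listed
# site to the second along each bond.  Only Si-O bonds are strongly polar
# in these chemistries; carbosilane skeletons are nearly apolar.
CHARGE_INCREMENTS = {
    ("Si", "O"): 0.200,
    ("Si", "C"): 0.050,
    ("C", "C"): 0.0,
    ("C", "H"): 0.0,
}


def _base_type(site_type: str) -> str:
    """Collapse united-atom carbon sites onto elemental carbon."""
    return "C" if site_type in ("CH2", "CH3", "C") else site_type


@dataclass(frozen=True)
class DendrimerRecipe:
    """Everything needed to build one dendrimer deterministically.

    Parameters
    ----------
    family:
        One of ``s``, ``l``, ``c3``, ``c4``.
    generation:
        Number of branching shells, 1-7.
    representation:
        ``united-atom`` (default; CH2/CH3 are single sites) or ``all-atom``.
    branch_multiplicity:
        Outgoing branches per branching Si (default 2; trifunctional
        branching atoms have one incoming and two outgoing skeleton bonds).
    seed:
        Seed for the initial 3D embedding only; the graph never depends
        on it.
    """

    family: str
    generation: int
    representation: str = "united-atom"
    branch_multiplicity: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidRecipeError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not (1 <= int(self.generation) <= 7):
            raise InvalidRecipeError(f"generation must be 1..7, got {self.generation}")
        if self.representation not in REPRESENTATIONS:
            raise InvalidRecipeError(f"representation must be one of {REPRESENTATIONS}")
        if not (1 <= int(self.branch_multiplicity) <= 3):
            raise InvalidRecipeError("branch_multiplicity must be 1..3 (Si valence limit)")

    @property
    def core_functionality(self) -> int:
        return CORE_FUNCTIONALITY[self.family]

    @property
    def is_carbosilane(self) -> bool:
        return self.family in ("c3", "c4")

    @classmethod
    def from_dict(cls, d: dict) -> "DendrimerRecipe":
        return cls(
            family=d["family"],
            generation=int(d["generation"]),
            representation=d.get("representation", "united-atom"),
            branch_multiplicity=int(d.get("branch_multiplicity", 2)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "DendrimerRecipe":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DendrimerTopology:
    """Molecular graph plus per-atom classification.

    Atom arrays are parallel over atom ids (0-based; the core atom is
    id 0).  ``layer`` runs 0 (core) .. G+1 (terminal segments),
    ``dendron`` is 1..core_functionality (0 for the core and its pendant
    methyl).  ``is_branching_si`` marks the Si skeleton including the
    core; ``is_terminal`` marks the outermost (layer-G) branching Si.
    """

    recipe: DendrimerRecipe
    elements: list
    site_types: list
    masses: np.ndarray
    charges: np.ndarray
    layer: np.ndarray
    dendron: np.ndarray
    is_branching_si: np.ndarray
    is_terminal: np.ndarray
    bonds: np.ndarray
    core_atom_id: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.site_types)

    @property
    def generation(self) -> int:
        return self.recipe.generation

    @property
    def core_functionality(self) -> int:
        return self.recipe.core_functionality

    @cached_property
    def neighbors(self) -> list:
        nbr = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            nbr[i].append(int(j))
            nbr[j].append(int(i))
        return nbr

    @cached_property
    def parent(self) -> np.ndarray:
        """Tree parent of every atom (-1 for the core); BFS from the core."""
        par = np.full(self.n_atoms, -1, dtype=np.int64)
        seen = np.zeros(self.n_atoms, dtype=bool)
        seen[self.core_atom_id] = True
        queue = [self.core_atom_id]
        while queue:
            nxt = []
            for a in queue:
                for b in self.neighbors[a]:
                    if not seen[b]:
                        seen[b] = True
                        par[b] = a
                        nxt.append(b)
            queue = nxt
        return par

    @cached_property
    def depth(self) -> np.ndarray:
        """Number of bonds from the core to each atom."""
        d = np.zeros(self.n_atoms, dtype=np.int64)
        order = self.bfs_order
        par = self.parent
        for a in order[1:]:
            d[a] = d[par[a]] + 1
        return d

    @cached_property
    def bfs_order(self) -> np.ndarray:
        order = [self.core_atom_id]
        seen = np.zeros(self.n_atoms, dtype=bool)
        seen[self.core_atom_id] = True
        head = 0
        while head < len(order):
            a = order[head]
            head += 1
            for b in self.neighbors[a]:
                if not seen[b]:
                    seen[b] = True
                    order.append(b)
        return np.asarray(order, dtype=np.int64)

    @cached_property
    def angles(self) -> np.ndarray:
        """All bonded triples (i, j, k), i and k neighbours of apex j."""
        out = []
        for j in range(self.n_atoms):
            nb = sorted(self.neighbors[j])
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    out.append((nb[a], j, nb[b]))
        return np.asarray(out, dtype=np.int64).reshape(-1, 3)

    @cached_property
    def torsions(self) -> np.ndarray:
        """All proper torsions (i, j, k, l) around each central bond j-k."""
        out = []
        for j, k in self.bonds:
            j, k = int(j), int(k)
            for i in self.neighbors[j]:
                if i == k:
                    continue
                for l in self.neighbors[k]:
                    if l == j or l == i:
                        continue
                    out.append((i, j, k, l))
        return np.asarray(out, dtype=np.int64).reshape(-1, 4)

    def bond_topological_index(self, i: int, j: int) -> int:
        """Count of skeleton bonds from the core to this bond (core bonds = 1)."""
        return int(max(self.depth[i], self.depth[j]))

    @property
    def tracked_si(self) -> np.ndarray:
        """Branching Si excluding the core — the atoms whose mobility is analysed."""
        mask = self.is_branching_si.copy()
        mask[self.core_atom_id] = False
        return np.flatnonzero(mask)

    def dendron_members(self, dendron: int) -> np.ndarray:
        return np.flatnonzero(self.dendron == dendron)

    # -- export ---------------------------------------------------------

    def to_pdb(self, path, coordinates=None) -> None:
        """Write a PDB file with CONECT records (coordinates in angstrom)."""
        xyz = np.zeros((self.n_atoms, 3)) if coordinates is None else np.asarray(coordinates)
        counts: dict = {}
        with open(path, "w") as fh:
            fh.write(f"TITLE     dendrimer {self.recipe.family} G{self.generation}\n")
            for i in range(self.n_atoms):
                el = self.elements[i]
                counts[el] = counts.get(el, 0) + 1
                name = f"{el}{counts[el] % 1000}"[:4]
                x, y, z = xyz[i]
                fh.write(
                    f"HETATM{i + 1:5d} {name:<4s} DND A   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
                )
            for i in range(self.n_atoms):
                nb = [j for j in self.neighbors[i] if j > i]
                for ofs in range(0, len(nb), 4):
                    rec = "".join(f"{j + 1:5d}" for j in nb[ofs:ofs + 4])
                    fh.write(f"CONECT{i + 1:5d}{rec}\n")
            fh.write("END\n")

    def labels_dict(self) -> dict:
        return {
            "family": self.recipe.family,
            "generation": self.generation,
            "representation": self.recipe.representation,
            "core_atom_id": self.core_atom_id,
            "site_types": list(self.site_types),
            "layer": self.layer.tolist(),
            "dendron": self.dendron.tolist(),
            "is_branching_si": self.is_branching_si.astype(int).tolist(),
            "is_terminal": self.is_terminal.astype(int).tolist(),
        }

    def to_labels_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.labels_dict(), fh)


class _Builder:
    def __init__(self, recipe: DendrimerRecipe):
        self.recipe = recipe
        self.site_types: list = []
        self.elements: list = []
        self.layer: list = []
        self.dendron: list = []
        self.branching: list = []
        self.terminal: list = []
        self.bonds: list = []

    def add(self, site_type, layer, dendron, parent=None, branching=False, terminal=False) -> int:
        """Add one site; in the all-atom representation CH2/CH3 expand to C + H."""
        allatom = self.recipe.representation == "all-atom"
        if allatom and site_type in ("CH2", "CH3"):
            cid = self._raw("C", "C", layer, dendron, parent, branching, terminal)
            for _ in range(2 if site_type == "CH2" else 3):
                self._raw("H", "H", layer, dendron, cid, False, False)
            return cid
        element = "C" if site_type in ("CH2", "CH3") else site_type
        return self._raw(site_type, element, layer, dendron, parent, branching, terminal)

    def _raw(self, site_type, element, layer, dendron, parent, branching, terminal) -> int:
        idx = len(self.site_types)
        self.site_types.append(site_type)
        self.elements.append(element)
        self.layer.append(layer)
        self.dendron.append(dendron)
        self.branching.append(branching)
        self.terminal.append(terminal)
        if parent is not None:
            self.bonds.append((parent, idx))
        return idx

    def finish(self) -> DendrimerTopology:
        masses = np.array([MASSES[t] for t in self.site_types], dtype=np.float64)
        bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        charges = np.zeros(len(self.site_types), dtype=np.float64)
        for i, j in bonds:
            bi, bj = _base_type(self.site_types[i]), _base_type(self.site_types[j])
            if (bi, bj) in CHARGE_INCREMENTS:
                q = CHARGE_INCREMENTS[(bi, bj)]
                charges[i] += q
                charges[j] -= q
            elif (bj, bi) in CHARGE_INCREMENTS:
                q = CHARGE_INCREMENTS[(bj, bi)]
                charges[j] += q
                charges[i] -= q
        return DendrimerTopology(
            recipe=self.recipe,
            elements=self.elements,
            site_types=self.site_types,
            masses=masses,
            charges=charges,
            layer=np.asarray(self.layer, dtype=np.int64),
            dendron=np.asarray(self.dendron, dtype=np.int64),
            is_branching_si=np.asarray(self.branching, dtype=bool),
            is_terminal=np.asarray(self.terminal, dtype=bool),
            bonds=bonds,
        )


def _add_spacer(b: _Builder, family: str, parent: int, layer: int, dendron: int) -> int:
    """Add one spacer segment; return the atom the next Si bonds to."""
    if family == "s":
        return b.add("O", layer, dendron, parent)
    if family == "l":
        o1 = b.add("O", layer, dendron, parent)
        si = b.add("Si", layer, dendron, o1)
        b.add("CH3", layer, dendron, si)
        b.add("CH3", layer, dendron, si)
        return b.add("O", layer, dendron, si)
    # carbosilane -(CH2)3-
    a = parent
    for _ in range(3):
        a = b.add("CH2", layer, dendron, a)
    return a


def _add_terminal_segments(b: _Builder, family: str, si: int, layer: int, dendron: int, n_slots: int):
    """Fill the outgoing slots of the outermost branching Si."""
    if family in ("s", "l"):
        for _ in range(n_slots):
            b.add("CH3", layer, dendron, si)
    else:
        bm = b.recipe.branch_multiplicity
        for k in range(n_slots):
            if k < bm:  # butyl -(CH2)3-CH3
                a = si
                for _ in range(3):
                    a = b.add("CH2", layer, dendron, a)
                b.add("CH3", layer, dendron, a)
            else:       # methyl completing the valence
                b.add("CH3", layer, dendron, si)


def build_topology(recipe: DendrimerRecipe) -> DendrimerTopology:
    """Build the molecular graph for ``recipe``.

    Deterministic for a fixed recipe; the recipe seed only enters the 3D
    embedding.  The returned graph is a tree (exactly one core, acyclic),
    branching-Si layer populations follow
    ``core_functionality * branch_multiplicity**(i-1)`` and Si/C/O
    valences are respected in the all-atom representation.
    """
    G = recipe.generation
    f = recipe.core_functionality
    bm = recipe.branch_multiplicity
    fam = recipe.family
    b = _Builder(recipe)

    core = b.add("Si", 0, 0, None, branching=True)
    if f == 3:  # trifunctional cores carry a pendant methyl
        b.add("CH3", 0, 0, core)

    def grow(parent_si: int, layer: int, dendron: int):
        """Attach one child branching Si (layer ``layer``) via a spacer."""
        tail = _add_spacer(b, fam, parent_si, layer, dendron)
        terminal = layer == G
        si = b.add("Si", layer, dendron, tail, branching=True, terminal=terminal)
        out_slots = 3  # Si valence 4 minus the incoming bond
        if terminal:
            _add_terminal_segments(b, fam, si, G + 1, dendron, out_slots)
        else:
            for _ in range(out_slots - bm):  # pendant methyls complete valence
                b.add("CH3", layer, dendron, si)
            for _ in range(bm):
                grow(si, layer + 1, dendron)

    for d in range(1, f + 1):
        grow(core, 1, d)
    return b.finish()


def layer_members(topology: DendrimerTopology, layer: int) -> np.ndarray:
    """Atom ids of the branching Si of ``layer``.

    Layer 0 is the core; layers 1..G are the branching shells; layer G+1
    returns the terminal-group tracking atoms, which for all four
    chemistries are the outermost (layer-G) branching Si.
    """
    G = topology.generation
    if not (0 <= layer <= G + 1):
        raise ValueError(f"layer {layer} out of range 0..{G + 1}")
    if layer == 0:
        return np.asarray([topology.core_atom_id], dtype=np.int64)
    if layer == G + 1:
        return np.flatnonzero(topology.is_terminal)
    return np.flatnonzero(topology.is_branching_si & (topology.layer == layer))
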