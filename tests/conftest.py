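import warnings

import numpy as np
import pytest

from dendromd import (
    DendrimerRecipe,
    ForceFieldParams,
    SimulationConfig,
    build_topology,
    initial_coordinates,
    integrate,
)
from dendromd.topology import DendrimerTopology

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def g1s_topology():
    return build_topology(DendrimerRecipe("s", 1, seed=1))


@pytest.fixture(scope="session")
def g1s_coords(g1s_topology):
    return initial_coordinates(g1s_topology, seed=1)


@pytest.fixture(scope="session")
def g2c3_md():
    """Short NVT run of a G2 carbosilane with both frame streams."""
    topo = build_topology(DendrimerRecipe("c3", 2, seed=5))
    x0 = initial_coordinates(topo, seed=5)
    cfg = SimulationConfig(
        temperature=600.0,
        equilibration_ps=2.0,
        production_ps=10.0,
        coarse_save_ps=0.2,
        fine_save_ps=0.1,
        seed=5,
    )
    return integrate(topo, x0, cfg, params=ForceFieldParams.for_family("c3"))


def make_star_topology(functionality=3, per_dendron=1):
    """Hand-built synthetic topology: a core Si with ``functionality``
    linear all-Si dendrons of ``per_dendron`` atoms each.

    Geometrically minimal stand-in for tests that place coordinates by
    hand; valences are not chemically meaningful and are not checked.
    """
    fam = "c4" if functionality == 4 else "c3"
    n = 1 + functionality * per_dendron
    site_types = ["Si"] * n
    elements = ["Si"] * n
    layer = [0]
    dendron = [0]
    bonds = []
    branching = [True] * n
    terminal = [False] * n
    idx = 1
    for d in range(1, functionality + 1):
        prev = 0
        for k in range(per_dendron):
            layer.append(k + 1)
            dendron.append(d)
            bonds.append((prev, idx))
            prev = idx
            idx += 1
    recipe = DendrimerRecipe(fam, max(per_dendron, 1))
    return DendrimerTopology(
        recipe=recipe,
        elements=elements,
        site_types=site_types,
        masses=np.full(n, 28.086),
        charges=np.zeros(n),
        layer=np.asarray(layer),
        dendron=np.asarray(dendron),
        is_branching_si=np.asarray(branching),
        is_terminal=np.asarray(terminal),
        bonds=np.asarray(bonds, dtype=np.int64),
    )
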