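"""Dihedral series, trans/gauche sectors, dwell-filtered transition counts."""

import numpy as np
import pytest

from dendromd import (
    ResolutionError,
    TelegraphSpec,
    angle_distribution,
    assign_states,
    count_transitions,
    crossing_frequency_120,
    frequency_profile,
    generate_telegraph,
)
from dendromd.torsion import (
    TransitionRecord,
    dihedral_angles,
    wrap_angles,
)


def chain_with_dihedral(phi_deg, theta_deg=112.0, r=1.53):
    """Four-atom chain with a prescribed dihedral angle."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    x = np.zeros((1, 4, 3))
    x[0, 1] = [r, 0, 0]
    x[0, 2] = x[0, 1] + r * np.array([np.cos(np.pi - th), np.sin(np.pi - th), 0.0])
    b2 = x[0, 2] - x[0, 1]
    b2u = b2 / np.linalg.norm(b2)
    n = np.cross(x[0, 1] - x[0, 0], b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2u)
    d3 = -np.cos(th) * b2u + np.sin(th) * (np.cos(ph) * m + np.sin(ph) * n)
    x[0, 3] = x[0, 2] + r * d3
    return x


@pytest.mark.parametrize("phi", [0.0, 180.0, 60.0, -60.0, 123.0])
def test_dihedral_angles_recover_construction(phi):
    """Planar cis -> 0, anti -> 180, staggered -> +-60 (signed, IUPAC)."""
    got = dihedral_angles(chain_with_dihedral(phi), (0, 1, 2, 3))[0]
    assert wrap_angles(got - phi) == pytest.approx(0.0, abs=1e-8)


def test_collinear_triple_flagged():
    x = np.zeros((1, 4, 3))
    x[0, 1] = [1, 0, 0]
    x[0, 2] = [2, 0, 0]  # 0-1-2 collinear
    x[0, 3] = [3, 1, 0]
    assert np.isnan(dihedral_angles(x, (0, 1, 2, 3))[0])


class TestAssignStates:
    def test_sector_membership(self):
        states = assign_states([179.0, -179.0, 60.0, -60.0, 10.0, -10.0])
        assert states.tolist() == [0, 0, 1, 2, 1, 2]

    def test_boundary_ties_go_to_earlier_center(self):
        # 120 is equidistant from 180 and 60 -> trans; 0 equidistant
        # from +-60 -> g+ (listed first)
        assert assign_states([120.0])[0] == 0
        assert assign_states([-120.0])[0] == 0
        assert assign_states([0.0])[0] == 1

    def test_nan_frames_get_sentinel(self):
        assert assign_states([np.nan])[0] == -1


class TestCountTransitions:
    def test_constant_state_no_transitions(self):
        rec = count_transitions(np.zeros(100, dtype=int), spacing=0.1)
        assert rec.n_transitions == 0

    def test_short_excursion_erased(self):
        """A 0.3 ps visit to g+ does not count against a 0.4 ps dwell."""
        states = np.array([0] * 20 + [1] * 3 + [0] * 20)  # 3 frames x 0.1 ps = 0.3 ps
        rec = count_transitions(states, spacing=0.1, dwell_threshold=0.4)
        assert rec.n_transitions == 0
        assert rec.state_sequence.tolist() == [0]

    def test_long_dwells_all_counted(self):
        """Five switches with 2 ps dwells -> five accepted transitions."""
        states = np.concatenate([[s] * 20 for s in (0, 1, 0, 2, 1, 0)])
        rec = count_transitions(states, spacing=0.1, dwell_threshold=0.4)
        assert rec.n_transitions == 5

    def test_exactly_threshold_dwell_rejected(self):
        # 4 frames x 0.1 ps = 0.4 ps is NOT strictly longer than 0.4 ps
        states = np.array([0] * 20 + [1] * 4 + [0] * 20)
        rec = count_transitions(states, spacing=0.1)
        assert rec.n_transitions == 0

    def test_spacing_too_coarse_rejected(self):
        with pytest.raises(ResolutionError):
            count_transitions(np.zeros(10, dtype=int), spacing=0.3, dwell_threshold=0.4)

    def test_dwell_monotonicity(self):
        rng = np.random.default_rng(5)
        states = rng.integers(0, 3, 2000)
        counts = [
            count_transitions(states, 0.1, dwell).n_transitions
            for dwell in (0.2, 0.4, 0.8, 1.6)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_rle_oracle_on_random_sequences(self):
        """Dwell filter agrees exactly with an independent RLE implementation."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(5, 300))
            states = rng.integers(0, 3, n)
            got = count_transitions(states, 0.1, 0.4).n_transitions
            assert got == rle_oracle(states, 0.1, 0.4)


def rle_oracle(states, spacing, dwell):
    """Reference implementation via explicit run-length encoding."""
    from itertools import groupby

    runs = [(s, len(list(g))) for s, g in groupby(states)]
    current = runs[0][0]
    count = 0
    for s, ln in runs[1:]:
        if s != current and ln * spacing > dwell + 1e-12:
            count += 1
            current = s
    return count


def test_frequency_invariant_under_angle_wrapping():
    angles, _, _ = generate_telegraph(TelegraphSpec(seed=3, length=4000))
    f0 = crossing_frequency_120(angles, 0.1)
    f1 = crossing_frequency_120(wrap_angles(angles + 720.0), 0.1)
    assert f0 == f1


class TestAngleDistribution:
    def test_delta_series_single_bin(self):
        edges, masses = angle_distribution(np.full(100, 63.0), bin_width=5.0)
        assert masses.sum() == pytest.approx(1.0)
        assert (masses > 0).sum() == 1
        assert masses.max() == pytest.approx(1.0)

    def test_balanced_trans_gauche_sectors(self):
        """50:50 trans/gauche generator gives equal sector masses."""
        spec = TelegraphSpec(dwell_means=(5.0, 2.5, 2.5), jitter=15.0, length=60000, seed=9)
        angles, states, _ = generate_telegraph(spec)
        edges, masses = angle_distribution(angles, bin_width=5.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        trans_mass = masses[np.abs(wrap_angles(centers - 180.0)) < 60].sum()
        p_trans = np.mean(states == 0)
        assert trans_mass == pytest.approx(p_trans, abs=0.02)

    def test_uniform_angles_flat(self):
        rng = np.random.default_rng(4)
        edges, masses = angle_distribution(rng.uniform(-180, 180, 200000), bin_width=10.0)
        assert masses.max() - masses.min() < 5.0 / np.sqrt(200000 / 36)  # loose band
        assert masses.sum() == pytest.approx(1.0)


class TestCrossing120:
    def test_constant_series_zero(self):
        assert crossing_frequency_120(np.full(100, 170.0), 0.1) == 0.0

    def test_slow_rotor_crosses_three_sectors(self):
        """One full 360 sweep crosses three sector boundaries."""
        t = np.linspace(0.0, 360.0, 2000, endpoint=False)
        angles = wrap_angles(t + 1.0)
        spacing = 0.1  # 200 ps sweep: each sector occupied for ~66 ps
        rec_count = crossing_frequency_120(angles, spacing) * (len(t) * spacing) / 1000.0
        assert round(rec_count) == 3

    def test_consistent_with_count_transitions(self):
        angles, _, _ = generate_telegraph(TelegraphSpec(seed=2, length=5000))
        states = assign_states(angles)
        rec = count_transitions(states, 0.1, 0.4)
        assert crossing_frequency_120(angles, 0.1, 0.4) == rec.frequency_ns


class TestFrequencyProfile:
    @staticmethod
    def _rec(bond_index, freq, cls="C-C"):
        n = int(round(freq))
        return TransitionRecord(
            torsion_id=(0, 1, 2, 3), bond_index=bond_index, bond_class=cls,
            state_sequence=np.zeros(1, dtype=int), dwell_times=np.zeros(1),
            n_transitions=n, span_ps=1000.0,
        )

    def test_identical_dynamics_flat_profile(self):
        recs = [self._rec(i, 50) for i in (1, 1, 2, 2, 3)]
        prof = frequency_profile(recs)
        assert np.allclose(prof.mean_frequency_ns, 50.0)

    def test_slow_si_bonds_alternate(self):
        """Si-adjacent bonds switching 3x slower produce an alternating profile."""
        recs = []
        for idx in range(1, 7):
            cls = "C-Si" if idx % 3 == 1 else "C-C"
            freq = 20 if cls == "C-Si" else 60
            recs.extend(self._rec(idx, freq, cls) for _ in range(3))
        prof = frequency_profile(recs).set_index("bond_index")
        slow = prof.loc[[1, 4], "mean_frequency_ns"]
        fast = prof.loc[[2, 3, 5, 6], "mean_frequency_ns"]
        assert slow.max() < fast.min()

    def test_single_class_returns_its_frequency(self):
        prof = frequency_profile([self._rec(2, 17)])
        assert prof.mean_frequency_ns.iloc[0] == pytest.approx(17.0)
        assert prof.n_bonds.iloc[0] == 1
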