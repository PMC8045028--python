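"""Radius of gyration, contacts, clusters, scattering, block averaging."""

import numpy as np
import pytest

import necklace as nk
from necklace.energy import SystemState
from necklace.mc import Trajectory, MCConfig
from necklace.observables import single_frame_scattering


def bare_state(coords, chain_id, bonds=(), charges=None, is_arg=None,
               is_ion=None, box=250.0):
    n = len(coords)
    return SystemState(
        coords=np.asarray(coords, float),
        radii=np.full(n, 2.0),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        epsilon=np.zeros(n),
        is_arg=np.zeros(n, bool) if is_arg is None else np.asarray(is_arg, bool),
        is_polyvalent_ion=np.zeros(n, bool) if is_ion is None else np.asarray(is_ion, bool),
        chain_id=np.asarray(chain_id, int),
        species=np.array(["X"] * n, dtype=object),
        bonds=np.array(bonds, int).reshape(-1, 2),
        box_length=box,
    )


def fake_traj(frames):
    return Trajectory(frames=frames, energies=np.zeros(len(frames)),
                      acceptance={}, config_echo=MCConfig(), final_state=frames[-1],
                      tuned_amplitudes={})


class TestRadiusOfGyration:
    def test_single_bead_is_zero(self):
        state = bare_state([[10, 10, 10]], [0])
        assert nk.radius_of_gyration(state, 0) == 0.0

    def test_two_beads_half_distance(self):
        state = bare_state([[0, 0, 0], [10, 0, 0]], [0, 0], bonds=[(0, 1)])
        assert nk.radius_of_gyration(state, 0) == pytest.approx(5.0)

    def test_straight_rod_closed_form(self):
        # N equally spaced beads: Rg = b·sqrt((N²−1)/12)
        n, b = 24, 4.1
        coords = [[i * b, 0, 0] for i in range(n)]
        state = bare_state(coords, [0] * n, bonds=[(i, i + 1) for i in range(n - 1)])
        expected = b * np.sqrt((n**2 - 1) / 12.0)
        assert nk.radius_of_gyration(state, 0) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_periodic_wrapping(self):
        n, b = 8, 4.1
        base = np.array([[i * b, 5.0, 5.0] for i in range(n)])
        state = bare_state(base + [240.0, 0, 0], [0] * n,
                           bonds=[(i, i + 1) for i in range(n - 1)])
        unwrapped = bare_state(base, [0] * n, bonds=[(i, i + 1) for i in range(n - 1)])
        assert nk.radius_of_gyration(state, 0) == pytest.approx(
            nk.radius_of_gyration(unwrapped, 0), rel=1e-10
        )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(100, 120, (12, 3))
        bonds = [(i, i + 1) for i in range(11)]
        state = bare_state(coords, [0] * 12, bonds=bonds)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=1).as_matrix()
        com = coords.mean(axis=0)
        rotated = bare_state((coords - com) @ R.T + com, [0] * 12, bonds=bonds)
        assert nk.radius_of_gyration(rotated, 0) == pytest.approx(
            nk.radius_of_gyration(state, 0), rel=1e-10
        )

    def test_unknown_chain_rejected(self):
        state = bare_state([[0, 0, 0]], [0])
        with pytest.raises(KeyError):
            nk.radius_of_gyration(state, 7)


class TestArgIonContacts:
    def test_no_ions_zero(self):
        state = bare_state([[0, 0, 0]], [0], is_arg=[True])
        assert nk.arg_ion_contacts(state) == 0

    def test_single_contact_within_cutoff(self):
        state = bare_state([[0, 0, 0], [4, 0, 0]], [0, -1],
                           charges=[1, -5], is_arg=[True, False],
                           is_ion=[False, True])
        assert nk.arg_ion_contacts(state, cutoff=4.5) == 1
        assert nk.arg_ion_contacts(state, cutoff=3.5) == 0

    def test_minimum_image_counted(self):
        state = bare_state([[1, 0, 0], [248, 0, 0]], [0, -1],
                           charges=[1, -5], is_arg=[True, False],
                           is_ion=[False, True], box=250.0)
        assert nk.arg_ion_contacts(state, cutoff=4.5) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        coords = rng.uniform(0, 50, (n, 3))
        is_arg = rng.random(n) < 0.3
        is_ion = ~is_arg & (rng.random(n) < 0.4)
        state = bare_state(coords, np.where(is_ion, -1, 0),
                           charges=np.where(is_ion, -5.0, 0.0),
                           is_arg=is_arg, is_ion=is_ion, box=50.0)
        cutoff = 6.0
        count = 0
        for i in np.flatnonzero(is_arg):
            for j in np.flatnonzero(is_ion):
                d = coords[j] - coords[i]
                d -= 50.0 * np.round(d / 50.0)
                if np.linalg.norm(d) <= cutoff:
                    count += 1
        assert nk.arg_ion_contacts(state, cutoff=cutoff) == count


class TestClusterSizes:
    def test_single_chain(self):
        state = bare_state([[0, 0, 0], [4.1, 0, 0]], [0, 0], bonds=[(0, 1)])
        assert dict(nk.cluster_sizes(state)) == {1: 1}

    def test_two_distant_chains(self):
        state = bare_state(
            [[0, 0, 0], [4.1, 0, 0], [100, 100, 100], [104.1, 100, 100]],
            [0, 0, 1, 1], bonds=[(0, 1), (2, 3)])
        assert dict(nk.cluster_sizes(state)) == {1: 2}

    def test_ion_bridge_joins_chains(self):
        # one ion within cutoff of beads from both chains
        state = bare_state(
            [[0, 0, 0], [4.1, 0, 0], [12.2, 0, 0], [16.3, 0, 0], [8.15, 0, 0]],
            [0, 0, 1, 1, -1], bonds=[(0, 1), (2, 3)],
            charges=[0, 0, 0, 0, -5], is_ion=[False] * 4 + [True])
        assert dict(nk.cluster_sizes(state, cutoff=4.5)) == {2: 1}

    def test_direct_contact_joins_chains(self):
        state = bare_state(
            [[0, 0, 0], [4.1, 0, 0], [8.2, 0, 0], [12.3, 0, 0]],
            [0, 0, 1, 1], bonds=[(0, 1), (2, 3)])
        assert dict(nk.cluster_sizes(state, cutoff=4.5)) == {2: 1}


class TestDebyeScattering:
    def test_single_bead_flat_unity(self):
        state = bare_state([[10, 10, 10]], [0])
        q = np.linspace(0.01, 0.5, 20)
        np.testing.assert_allclose(single_frame_scattering(state, q, 0), 1.0)

    def test_rigid_pair_closed_form(self):
        d = 10.0
        state = bare_state([[0, 0, 0], [d, 0, 0]], [0, 0], bonds=[(0, 1)])
        q = np.linspace(0.01, 0.8, 40)
        expected = 0.5 * (1 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(single_frame_scattering(state, q, 0), expected,
                                   rtol=1e-10)

    def test_guinier_fit_recovers_frame_rg(self, ff):
        # cross-module consistency: Debye curve of a frame → that frame's Rg
        wt = nk.hst5_wild_type()
        state = nk.gen_system([wt], {}, seed=3, ff=ff)
        rg_direct = nk.radius_of_gyration(state, 0)
        q = np.linspace(0.004, 1.0 / rg_direct, 200)
        curve = nk.debye_scattering(fake_traj([state]), q, chain=0)
        fit = nk.guinier_fit(curve)
        assert fit.rg == pytest.approx(rg_direct, rel=0.01)

    def test_monotone_on_guinier_window(self, ff):
        wt = nk.hst5_wild_type()
        state = nk.gen_system([wt], {}, seed=1, ff=ff)
        rg = nk.radius_of_gyration(state, 0)
        q = np.linspace(0.004, 0.8 / rg, 50)
        I = single_frame_scattering(state, q, 0)
        assert np.all(np.diff(I) < 0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            nk.debye_scattering(
                Trajectory(frames=[], energies=np.array([]), acceptance={},
                           config_echo=MCConfig(), final_state=None,
                           tuned_amplitudes={}),
                np.linspace(0.01, 0.1, 5))


class TestBlockAveraging:
    def test_mean_matches_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(3.0, 0.5, 1000)
        s = nk.block_series("x", vals)
        assert s.mean == pytest.approx(vals.mean())
        assert s.sem >= 0

    def test_white_noise_sem_matches_iid_formula(self):
        # uncorrelated series: block SEM ≈ σ/√n independent of block size
        rng = np.random.default_rng(2)
        vals = rng.normal(0.0, 1.0, 20_000)
        s = nk.block_series("x", vals, n_blocks=20)
        assert s.sem == pytest.approx(1.0 / np.sqrt(len(vals)), rel=0.35)

    def test_sem_shrinks_with_more_blocks(self):
        rng = np.random.default_rng(3)
        sems = []
        for n in (500, 5000, 50_000):
            vals = rng.normal(0.0, 1.0, n)
            sems.append(nk.ObservableSeries("x", vals, block_size=25).sem)
        assert sems[0] > sems[1] > sems[2]
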