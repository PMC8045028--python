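import numpy as np
import pytest

import necklace as nk
from necklace.energy import SystemState


@pytest.fixture(scope="session")
def wt():
    """Histatin 5 wild type charged at pH 8.4 (integer scheme)."""
    return nk.hst5_wild_type()


@pytest.fixture(scope="session")
def ff():
    return nk.ForceField()


def random_state(seed: int, n_sites: int = 20, box: float = 60.0) -> SystemState:
    """Random overlap-free mixed system (charged beads, arginines, ions)
    with no bonds, for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    radii = rng.uniform(1.0, 2.5, n_sites)
    coords = []
    while len(coords) < n_sites:
        cand = rng.uniform(0, box, 3)
        ok = True
        for j, p in enumerate(coords):
            d = cand - p
            d -= box * np.round(d / box)
            if np.linalg.norm(d) < radii[len(coords)] + radii[j]:
                ok = False
                break
        if ok:
            coords.append(cand)
    charges = rng.integers(-5, 3, n_sites).astype(float)
    is_ion = rng.random(n_sites) < 0.3
    is_arg = ~is_ion & (rng.random(n_sites) < 0.3)
    eps = np.where(is_ion, 0.0, rng.uniform(0, 1e4, n_sites))
    chain_id = np.where(is_ion, -1, 0)
    return SystemState(
        coords=np.array(coords),
        radii=radii,
        charges=charges,
        epsilon=eps,
        is_arg=is_arg,
        is_polyvalent_ion=is_ion & (np.abs(charges) >= 2),
        chain_id=chain_id,
        species=np.array(["X"] * n_sites, dtype=object),
        bonds=np.empty((0, 2), int),
        box_length=box,
        periodic=True,
    )


def brute_force_energy(state: SystemState, ff: nk.ForceField) -> float:
    """Independent double-loop oracle built from the scalar pair functions."""
    n = state.n_sites
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = state.coords[j] - state.coords[i]
            if state.periodic:
                d = d - state.box_length * np.round(d / state.box_length)
            r = float(np.linalg.norm(d))
            total += nk.hard_sphere_pair(r, state.radii[i], state.radii[j])
            if not np.isfinite(total):
                return float("inf")
            total += nk.debye_huckel_pair(
                state.charges[i], state.charges[j], r, ff,
                Ri=state.radii[i], Rj=state.radii[j],
            )
            arg_ion = ff.arg_ion_attraction and (
                (state.is_arg[i] and state.is_polyvalent_ion[j])
                or (state.is_arg[j] and state.is_polyvalent_ion[i])
            )
            eps = ff.epsilon_arg_ion if arg_ion else 0.5 * (
                state.epsilon[i] + state.epsilon[j]
            )
            total += nk.short_range_pair(r, eps, ff)
    for a, b in state.bonds:
        d = state.coords[b] - state.coords[a]
        if state.periodic:
            d = d - state.box_length * np.round(d / state.box_length)
        total += nk.bond_pair(float(np.linalg.norm(d)), ff)
    return total
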