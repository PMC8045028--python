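"""Coarse-grained force field for charged bead-necklace chains with explicit ions.

The potential energy is a pairwise-additive sum of four terms:

* hard-sphere excluded volume  (∞ below contact, 0 at and beyond contact),
* an extended (finite-ion-size) Debye–Hückel screened Coulomb term,
* a short-ranged −ε/r⁶ attraction whose pair strength is the arithmetic
  mean of the two sites' ε — except arginine/polyvalent-anion pairs, which
  use a dedicated, much stronger ε mimicking the specific multimodal
  guanidinium–phosphate interaction,
* harmonic bonds between adjacent residue beads.

Explicit polyvalent anions are hard spheres of the same radius as the
amino-acid beads, carrying their full valence.  The screening constant κ
represents only the implicit background electrolyte (buffer and 1:1 salt);
explicit ions are excluded from it to avoid double counting.

Everything is evaluated in kT at the force field temperature.  Pair
distances use the minimum image convention in a periodic cubic box.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .sequence import ChainTopology

#: Default anion valences at pH 8.4 (fully deprotonated species).
DEFAULT_ION_CHARGES = {
    "citrate": -3.0,
    "PP": -4.0,
    "TPP": -5.0,
    "Na": 1.0,
    "Cl": -1.0,
}

#: Generic amino-acid dispersion strength, kJ Å⁶/mol — calibrated so that
#: the bead–bead contact attraction (r = 4 Å) is 0.6 kT at 298 K.
DEFAULT_EPSILON_GENERIC = 6.1e3

#: Arginine–polyvalent-anion dispersion strength, kJ Å⁶/mol (≈ 8 kT at contact).
DEFAULT_EPSILON_ARG_ION = 8.0e4


@dataclass(frozen=True)
class ForceField:
    """Force-field parameters.

    Units: lengths Å, k_bond N/m, ε in kJ Å⁶/mol, temperature K, κ in Å⁻¹.
    The default temperature, 293.15 K, is ambient room temperature.
    """

    bead_radius: float = 2.0
    r0: float = 4.1
    k_bond: float = 0.4
    epsilon_generic: float = DEFAULT_EPSILON_GENERIC
    epsilon_arg_ion: float = DEFAULT_EPSILON_ARG_ION
    temperature: float = 293.15
    dielectric: float = 78.4
    kappa: float = 0.0
    ion_charges: dict = field(default_factory=lambda: dict(DEFAULT_ION_CHARGES))
    #: when False the specific Arg–polyvalent-anion term is disabled and
    #: those pairs fall back to the arithmetic-mean dispersion rule
    #: (the "electrostatics-only" model of the with/without comparison)
    arg_ion_attraction: bool = True

    def __post_init__(self) -> None:
        for name in ("bead_radius", "r0", "k_bond", "epsilon_generic",
                     "epsilon_arg_ion", "temperature", "dielectric"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    @property
    def kt_kj_per_mol(self) -> float:
        return constants.thermal_energy_kj_per_mol(self.temperature)

    @property
    def bjerrum(self) -> float:
        """Bjerrum length in Å at the force-field temperature/dielectric."""
        return constants.bjerrum_length(self.temperature, self.dielectric)

    @property
    def k_bond_kt(self) -> float:
        """Bond force constant in kT/Å²."""
        return constants.spring_constant_to_kt_per_A2(self.k_bond, self.temperature)

    def with_ionic_strength(self, ionic_strength: float) -> "ForceField":
        """Copy of the force field with κ set from an implicit ionic strength (mol/L)."""
        kappa = constants.debye_kappa(ionic_strength, self.temperature, self.dielectric)
        return dataclasses.replace(self, kappa=kappa)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(**d)


def debye_kappa(ionic_strength: float, temperature: float, dielectric: float) -> float:
    """Inverse Debye length κ (Å⁻¹) for an ionic strength in mol/L."""
    return constants.debye_kappa(ionic_strength, temperature, dielectric)


# ---------------------------------------------------------------------------
# scalar pair potentials (reference implementations; the calculator below
# vectorizes the same expressions)
# ---------------------------------------------------------------------------

def hard_sphere_pair(r: float, Ri: float, Rj: float) -> float:
    """Hard-sphere pair energy in kT: ∞ for r < Ri+Rj, else 0 (contact allowed)."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    return np.inf if r < Ri + Rj else 0.0


def debye_huckel_pair(
    zi: float, zj: float, r: float, ff: ForceField,
    Ri: float | None = None, Rj: float | None = None,
) -> float:
    """Extended Debye–Hückel pair energy in kT.

    U = z_i z_j λ_B/r · e^{κ(R_i+R_j)} / ((1+κR_i)(1+κR_j)) · e^{−κr};
    the hard-core factors correct the screening cloud for the finite ion
    size, and the expression reduces to the bare Coulomb form at κ = 0.
    """
    if r <= 0:
        raise ValueError("distance must be strictly positive")
    Ri = ff.bead_radius if Ri is None else Ri
    Rj = ff.bead_radius if Rj is None else Rj
    k = ff.kappa
    core = np.exp(k * (Ri + Rj)) / ((1.0 + k * Ri) * (1.0 + k * Rj))
    return zi * zj * ff.bjerrum / r * core * np.exp(-k * r)


def short_range_pair(r: float, epsilon: float, ff: ForceField) -> float:
    """Attractive dispersion term −ε/r⁶, converted from kJ Å⁶/mol to kT."""
    if r <= 0:
        raise ValueError("distance must be strictly positive")
    return -(epsilon / r**6) / ff.kt_kj_per_mol


def bond_pair(r: float, ff: ForceField) -> float:
    """Harmonic bond energy (k/2)(r − r₀)² in kT."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * ff.k_bond_kt * (r - ff.r0) ** 2


# ---------------------------------------------------------------------------
# system state
# ---------------------------------------------------------------------------

@dataclass
class SystemState:
    """Coordinates and per-site attributes of chains plus explicit ions.

    Per-site arrays: `coords` (n, 3) Å, `radii`, `charges`, `epsilon`
    (site dispersion strength, kJ Å⁶/mol), `is_arg`, `is_polyvalent_ion`,
    `chain_id` (−1 for ions) and `species` (residue code or ion label).
    `bonds` holds global index pairs of harmonically bonded beads.
    Terminal charges are folded into the first/last bead of each chain:
    the terminal sites are point charges co-located with those beads, so
    merging is exact once the degenerate zero-distance self-pair is excluded.
    """

    coords: np.ndarray
    radii: np.ndarray
    charges: np.ndarray
    epsilon: np.ndarray
    is_arg: np.ndarray
    is_polyvalent_ion: np.ndarray
    chain_id: np.ndarray
    species: np.ndarray
    bonds: np.ndarray  # (n_bonds, 2) int
    box_length: float = 250.0
    periodic: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        n = len(self.coords)
        for name in ("radii", "charges", "epsilon", "is_arg",
                     "is_polyvalent_ion", "chain_id", "species"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        if self.periodic:
            self.coords = np.mod(self.coords, self.box_length)

    @property
    def n_sites(self) -> int:
        return len(self.coords)

    @property
    def chain_ids(self) -> list[int]:
        return sorted({int(c) for c in self.chain_id if c >= 0})

    def chain_indices(self, chain: int) -> np.ndarray:
        idx = np.flatnonzero(self.chain_id == chain)
        if idx.size == 0:
            raise KeyError(f"unknown chain id {chain}")
        return idx

    @property
    def ion_indices(self) -> np.ndarray:
        return np.flatnonzero(self.chain_id < 0)

    def copy(self) -> "SystemState":
        return SystemState(
            coords=self.coords.copy(),
            radii=self.radii,
            charges=self.charges,
            epsilon=self.epsilon,
            is_arg=self.is_arg,
            is_polyvalent_ion=self.is_polyvalent_ion,
            chain_id=self.chain_id,
            species=self.species,
            bonds=self.bonds,
            box_length=self.box_length,
            periodic=self.periodic,
        )

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vectors b − a."""
        d = b - a
        if self.periodic:
            d -= self.box_length * np.round(d / self.box_length)
        return d


def sites_from_topologies(
    topologies: list[ChainTopology],
    coords: np.ndarray,
    ff: ForceField,
    ion_species: list[str] = (),
    ion_coords: np.ndarray | None = None,
    box_length: float = 250.0,
    periodic: bool = True,
) -> SystemState:
    """Assemble a :class:`SystemState` from charged topologies plus ions.

    `coords` stacks the residue-bead coordinates of all chains in order;
    terminal charges are added onto the first/last bead of each chain.
    """
    radii, charges, eps, is_arg, chain_ids, species, bonds = [], [], [], [], [], [], []
    offset = 0
    for ci, topo in enumerate(topologies):
        for b in topo.beads:
            radii.append(b.radius)
            charges.append(b.charge)
            eps.append(ff.epsilon_generic)
            is_arg.append(b.is_arginine)
            chain_ids.append(ci)
            species.append(b.code)
        charges[offset] += topo.n_term.charge
        charges[offset + len(topo.beads) - 1] += topo.c_term.charge
        bonds.extend((offset + i, offset + j) for i, j in topo.bonds)
        offset += len(topo.beads)
    n_ions = len(ion_species)
    all_coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if all_coords.shape[0] != offset:
        raise ValueError("coordinate count does not match bead count")
    if n_ions:
        ion_coords = np.asarray(ion_coords, dtype=float).reshape(n_ions, 3)
        all_coords = np.vstack([all_coords, ion_coords])
    for sp in ion_species:
        z = ff.ion_charges.get(sp)
        if z is None:
            raise KeyError(f"ion species {sp!r} not in ForceField.ion_charges")
        radii.append(ff.bead_radius)
        charges.append(z)
        eps.append(0.0)
        is_arg.append(False)
        chain_ids.append(-1)
        species.append(sp)
    charges = np.array(charges, float)
    return SystemState(
        coords=all_coords,
        radii=np.array(radii, float),
        charges=charges,
        epsilon=np.array(eps, float),
        is_arg=np.array(is_arg, bool),
        is_polyvalent_ion=(np.array(chain_ids) < 0) & (np.abs(charges) >= 2.0),
        chain_id=np.array(chain_ids, int),
        species=np.array(species, dtype=object),
        bonds=np.array(bonds, int).reshape(-1, 2),
        box_length=box_length,
        periodic=periodic,
    )


# ---------------------------------------------------------------------------
# vectorized evaluation
# ---------------------------------------------------------------------------

class EnergyCalculator:
    """Vectorized energy evaluation bound to one (state layout, force field).

    Precomputes the pair ε matrix (with the Arg–polyvalent-ion override),
    charge products and contact distances; per-site attributes must not
    change between calls (coordinates may).
    """

    def __init__(self, state: SystemState, ff: ForceField):
        self.ff = ff
        n = state.n_sites
        self.n = n
        eps_pair = 0.5 * (state.epsilon[:, None] + state.epsilon[None, :])
        if ff.arg_ion_attraction:
            arg_ion = (
                state.is_arg[:, None] & state.is_polyvalent_ion[None, :]
            ) | (state.is_polyvalent_ion[:, None] & state.is_arg[None, :])
            eps_pair[arg_ion] = ff.epsilon_arg_ion
        self.eps_pair_kt = eps_pair / ff.kt_kj_per_mol
        self.zz = state.charges[:, None] * state.charges[None, :]
        self.contact = state.radii[:, None] + state.radii[None, :]
        k = ff.kappa
        self.dh_core = (
            ff.bjerrum
            * np.exp(k * self.contact)
            / ((1.0 + k * state.radii[:, None]) * (1.0 + k * state.radii[None, :]))
        )
        self.bond_k = ff.k_bond_kt
        self.r0 = ff.r0
        self.kappa = k
        # bonds touching each site, for incremental updates
        self.bonds = state.bonds
        self.bond_partners: list[np.ndarray] = [
            np.array(sorted(
                set(self.bonds[self.bonds[:, 0] == i, 1])
                | set(self.bonds[self.bonds[:, 1] == i, 0])
            ), dtype=int)
            for i in range(n)
        ]

    def _min_image(self, d: np.ndarray, state: SystemState) -> np.ndarray:
        if state.periodic:
            d = d - state.box_length * np.round(d / state.box_length)
        return d

    def _nonbonded(self, r: np.ndarray, i_idx, j_idx) -> np.ndarray:
        """Nonbonded pair energies for distances r between sites i_idx, j_idx."""
        zz = self.zz[i_idx, j_idx]
        contact = self.contact[i_idx, j_idx]
        eps = self.eps_pair_kt[i_idx, j_idx]
        core = self.dh_core[i_idx, j_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = zz * core / r * np.exp(-self.kappa * r) - eps / r**6
        u = np.where(r < contact, np.inf, u)
        return u

    def total(self, state: SystemState) -> float:
        """Total energy in kT; +∞ iff any hard-sphere overlap."""
        n = self.n
        if n <= 1:
            return self._bond_energy(state)
        iu, ju = np.triu_indices(n, k=1)
        d = self._min_image(state.coords[ju] - state.coords[iu], state)
        r = np.linalg.norm(d, axis=1)
        u = self._nonbonded(r, iu, ju)
        if np.isinf(u).any():
            return np.inf
        return float(u.sum()) + self._bond_energy(state)

    def _bond_energy(self, state: SystemState) -> float:
        if len(self.bonds) == 0:
            return 0.0
        d = self._min_image(
            state.coords[self.bonds[:, 1]] - state.coords[self.bonds[:, 0]], state
        )
        r = np.linalg.norm(d, axis=1)
        return float(np.sum(0.5 * self.bond_k * (r - self.r0) ** 2))

    def site_energy(self, state: SystemState, i: int, pos: np.ndarray | None = None) -> float:
        """Energy of site i with all other sites (nonbonded + its bonds), in kT.

        If `pos` is given it is used in place of the stored coordinate.
        """
        xi = state.coords[i] if pos is None else pos
        others = np.arange(self.n) != i
        j_idx = np.flatnonzero(others)
        d = self._min_image(state.coords[j_idx] - xi, state)
        r = np.linalg.norm(d, axis=1)
        u = self._nonbonded(r, np.full(j_idx.size, i), j_idx)
        if np.isinf(u).any():
            return np.inf
        total = float(u.sum())
        partners = self.bond_partners[i]
        if partners.size:
            db = self._min_image(state.coords[partners] - xi, state)
            rb = np.linalg.norm(db, axis=1)
            total += float(np.sum(0.5 * self.bond_k * (rb - self.r0) ** 2))
        return total

    def subset_energy(self, state: SystemState, idx: np.ndarray,
                      pos: np.ndarray | None = None) -> float:
        """Energy of the subset `idx`: internal pairs + interaction with the rest.

        `pos` optionally overrides the subset coordinates (same order as idx).
        """
        idx = np.asarray(idx, int)
        coords = state.coords.copy() if pos is not None else state.coords
        if pos is not None:
            coords = state.coords.copy()
            coords[idx] = pos
        mask = np.zeros(self.n, bool)
        mask[idx] = True
        rest = np.flatnonzero(~mask)
        total = 0.0
        # cross term
        if rest.size:
            d = coords[rest][None, :, :] - coords[idx][:, None, :]
            d = self._min_image(d, state)
            r = np.linalg.norm(d, axis=2)
            u = self._nonbonded(r, idx[:, None], rest[None, :])
            if np.isinf(u).any():
                return np.inf
            total += float(u.sum())
        # internal pairs
        if idx.size > 1:
            ii, jj = np.triu_indices(idx.size, k=1)
            d = self._min_image(coords[idx[jj]] - coords[idx[ii]], state)
            r = np.linalg.norm(d, axis=1)
            u = self._nonbonded(r, idx[ii], idx[jj])
            if np.isinf(u).any():
                return np.inf
            total += float(u.sum())
        # bonds with at least one end in the subset
        if len(self.bonds):
            touch = mask[self.bonds[:, 0]] | mask[self.bonds[:, 1]]
            b = self.bonds[touch]
            if len(b):
                d = self._min_image(coords[b[:, 1]] - coords[b[:, 0]], state)
                r = np.linalg.norm(d, axis=1)
                total += float(np.sum(0.5 * self.bond_k * (r - self.r0) ** 2))
        return total

    def has_overlap(self, state: SystemState) -> bool:
        iu, ju = np.triu_indices(self.n, k=1)
        d = self._min_image(state.coords[ju] - state.coords[iu], state)
        r = np.linalg.norm(d, axis=1)
        return bool(np.any(r < self.contact[iu, ju]))


def total_energy(state: SystemState, ff: ForceField) -> float:
    """Total potential energy of `state` in kT (convenience wrapper)."""
    return EnergyCalculator(state, ff).total(state)
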