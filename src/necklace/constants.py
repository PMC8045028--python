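"""Physical constants and unit conversions.

All energies inside the package are handled in units of kT at the force
field's temperature; lengths are in Ångström, concentrations in mol/L
unless a function says otherwise.  Every conversion from laboratory units
(kJ/mol, N/m, mol/L) lives here so there is exactly one place where CODATA
values enter.
"""

from __future__ import annotations

import math

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

GAS_CONSTANT = BOLTZMANN * AVOGADRO  # J/(mol K)

ANGSTROM = 1e-10  # m


def thermal_energy_kj_per_mol(temperature: float) -> float:
    """RT in kJ/mol at `temperature` (K)."""
    return GAS_CONSTANT * temperature / 1000.0


def kj_per_mol_to_kt(energy: float, temperature: float) -> float:
    """Convert an energy in kJ/mol to units of kT at `temperature` (K)."""
    return energy / thermal_energy_kj_per_mol(temperature)


def spring_constant_to_kt_per_A2(k_newton_per_m: float, temperature: float) -> float:
    """Convert a force constant in N/m to kT/Å²  (0.4 N/m ≈ 0.97 kT/Å² at 298 K)."""
    joule_per_A2 = k_newton_per_m * ANGSTROM**2  # J/Å²
    return joule_per_A2 / (BOLTZMANN * temperature)


def bjerrum_length(temperature: float, dielectric: float) -> float:
    """Bjerrum length λ_B = e²/(4π ε₀ ε_r k_B T), in Å.

    ≈ 7.1 Å for water (ε_r = 78.4) at 298 K.
    """
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * dielectric * BOLTZMANN * temperature
    )
    return lb_m / ANGSTROM


def debye_kappa(ionic_strength: float, temperature: float, dielectric: float) -> float:
    """Inverse Debye screening length κ in Å⁻¹.

    κ = sqrt(2 N_A e² I·10³ / (ε₀ ε_r k_B T)) with I in mol/L.
    κ(0) = 0; κ scales as √I (κ⁻¹ ≈ 9.6 Å at 0.1 M, 298 K, ε_r 78.4).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength == 0.0:
        return 0.0
    kappa_sq_m = (
        2.0
        * AVOGADRO
        * ELEMENTARY_CHARGE**2
        * ionic_strength
        * 1000.0
        / (VACUUM_PERMITTIVITY * dielectric * BOLTZMANN * temperature)
    )
    return math.sqrt(kappa_sq_m) * ANGSTROM
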