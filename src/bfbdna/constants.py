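"""Physical constants in the package unit system.

Internal units are kJ/mol (energy), nm (length), ps (time), K (temperature),
amu = g/mol (mass) and elementary charges.  With these choices velocities are
nm/ps and the Boltzmann constant is kB in kJ/mol/K; no unit conversion is
needed anywhere except at file I/O boundaries.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 8.31446261815324e-3

#: Coulomb prefactor e^2 N_A / (4 pi eps0), kJ mol^-1 nm e^-2
COULOMB = 138.935458

#: Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23

#: elementary charge, C
E_CHARGE = 1.602176634e-19

#: vacuum permittivity, F/m
EPSILON_0 = 8.8541878128e-12

#: Boltzmann constant, J/K
KB_SI = 1.380649e-23


def debye_length(ionic_strength_mM: float, temperature: float, dielectric: float) -> float:
    """Debye screening length in nm.

    lambda_D = sqrt(eps0 * kappa * kB * T / (2 * N_A * I * e^2)) with the ionic
    strength given in mM (= mol/m^3, so no molarity conversion is needed).
    """
    if ionic_strength_mM <= 0 or temperature <= 0 or dielectric <= 0:
        raise ValueError("ionic strength, temperature and dielectric must be positive")
    lam_m = math.sqrt(
        EPSILON_0 * dielectric * KB_SI * temperature
        / (2.0 * N_AVOGADRO * ionic_strength_mM * E_CHARGE**2)
    )
    return lam_m * 1e9
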