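"""Physical constants and unit conversions.

Everything inside the package is in Hartree atomic units (energy in
hartree, length in bohr, charge in e, mass in electron masses, hbar = 1).
Conversions live here and are applied only at I/O boundaries, so the
working equations never carry unit factors.
"""

from __future__ import annotations

# Boltzmann constant, hartree per kelvin (CODATA).
KB_HARTREE_PER_K = 3.166811563e-6

# One atomic unit of time in seconds (CODATA).
AU_TIME_S = 2.4188843265e-17

# One bohr in angstrom.
BOHR_ANGSTROM = 0.529177210903

# Wavenumber (cm^-1) to hartree: 1 / 219474.6313632 cm^-1 per hartree.
CM1_HARTREE = 1.0 / 219474.6313632

# Atomic mass unit (dalton) in electron masses.
AMU_ME = 1822.888486209

# Hartree in kJ/mol, for human-readable activation energies.
HARTREE_KJMOL = 2625.4996394799


def angstrom_to_bohr(x):
    return x / BOHR_ANGSTROM


def bohr_to_angstrom(x):
    return x * BOHR_ANGSTROM


def cm1_to_hartree(x):
    return x * CM1_HARTREE


def hartree_to_cm1(x):
    return x / CM1_HARTREE


def rate_au_to_per_s(k_au: float) -> float:
    """Convert a rate constant from (a.u. time)^-1 to s^-1."""
    return k_au / AU_TIME_S


def rate_per_s_to_au(k_si: float) -> float:
    """Convert a rate constant from s^-1 to (a.u. time)^-1."""
    return k_si * AU_TIME_S


def thermal_energy(temperature: float) -> float:
    """k_B T in hartree for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_HARTREE_PER_K * temperature
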