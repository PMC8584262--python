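"""Physical constants and unit conversions used throughout the package.

Conventions: coordinates in Å, time in ns, temperature in K, moduli in J,
surface pressures and compressibilities in mN/m, diffusion in µm²/s,
molar free energies in J/mol.  Every conversion factor lives here so that
unit handling is testable in one place.
"""

from scipy.constants import Avogadro, Boltzmann

#: Boltzmann constant, J/K.
KB_J_PER_K: float = Boltzmann

#: Avogadro constant, 1/mol.
N_AVOGADRO: float = Avogadro

#: 1 J/Å² expressed in mN/m (1 J/Å² = 1 J / 1e-20 m² = 1e20 N/m = 1e23 mN/m).
MNM_PER_J_PER_A2: float = 1e23

#: 1 µm²/s expressed in Å²/ns (1e8 Å² / 1e9 ns).
A2_PER_NS_PER_UM2_PER_S: float = 0.1

#: nm per Å.
NM_PER_A: float = 0.1

#: (Å² · mN/m) expressed in J: 1 Å² · 1 mN/m = 1e-20 m² · 1e-3 N/m = 1e-23 J.
J_PER_A2_MNM: float = 1e-23

#: (Å² · mN/m) per molecule expressed in J/mol.
J_PER_MOL_PER_A2_MNM: float = Avogadro * J_PER_A2_MNM


def thermal_energy(temperature_K: float) -> float:
    """Return k_B·T in J for a temperature in K."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return KB_J_PER_K * temperature_K
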