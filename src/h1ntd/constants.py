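"""Physical constants and unit conventions.

Internal units are kJ/mol for energies, nm for lengths and K for
temperatures.  The only Angstrom-denominated quantities in the package are
the clustering / DNA-contact cutoffs (2.5 / 3.2 A) and the radius-of-gyration
baselines, which follow the conventions of the structural literature; they
are converted explicitly at the call sites.
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.0083145

#: Coulomb constant e^2 / (4 pi eps0), kJ mol^-1 nm (vacuum).
COULOMB_K = 138.935

#: Relative dielectric permittivity of water used for screened electrostatics.
WATER_EPS_R = 80.0

#: Debye screening length at 0.15 M monovalent salt, nm.
DEBYE_LENGTH_150MM = 0.78

#: nm per Angstrom.
NM_PER_ANGSTROM = 0.1


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
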