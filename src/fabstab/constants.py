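"""Physical constants and package-wide defaults.

Internal units: length nm, energy kJ/mol, time ps, temperature K.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 8.314462618e-3

#: Default simulation temperature, K
T_DEFAULT = 310.0

#: Default umbrella spring constant, kJ mol^-1 nm^-2
SPRING_DEFAULT = 1000.0

#: Fraction of each umbrella window discarded as equilibration
# (mirrors dropping the first 5 ns of a 50 ns window)
EQUIL_FRACTION_DEFAULT = 0.10

#: Angstrom -> nm conversion applied at every PDB boundary
A_TO_NM = 0.1


def kt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kB*T in kJ/mol."""
    return KB * temperature
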