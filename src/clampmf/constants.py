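"""Physical constants and unit conventions.

Internal units are nm (length), ps (time), kcal/mol (energy), degrees
(angles).  PDB files carry Angstrom; conversion happens at the I/O boundary.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: kT at 300 K, kcal/mol (~0.596).
KT_300 = KB_KCAL * DEFAULT_TEMPERATURE

#: Angstrom per nm.
ANGSTROM_PER_NM = 10.0


def kt(temperature: float) -> float:
    """kT in kcal/mol at the given temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
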