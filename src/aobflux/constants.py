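"""Physical constants and unit conventions shared across the package.

Units are fixed package-wide: time in days, concentrations in mmol L^-1,
activities dimensionless (relative to 1 mol L^-1), energies in kJ mol^-1,
isotope compositions in permil versus VPDB.
"""

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314e-3

#: Reference temperature for all standard free energies, K.
T_STANDARD = 298.0

#: 13C/12C isotope ratio of the VPDB standard.
R_VPDB = 0.01123720

#: Free energy of translocating one proton across the membrane, kJ mol^-1.
PROTON_QUANTUM = -20.0

#: Carbons per butane molecule.
N_BUTANE = 4

#: Sulfate reduced per butane oxidized (26 e- / 8 e- per sulfate).
SULFATE_PER_BUTANE = 3.25


def rt(temperature: float = T_STANDARD) -> float:
    """Return R*T in kJ mol^-1."""
    return R_KJ * temperature
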