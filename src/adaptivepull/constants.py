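"""Physical constants and unit conventions.

The package works in a single consistent unit system throughout:
length in angstrom, energy in kcal/mol, time in ps, temperature in K.
The implied mass unit is kcal/mol * ps^2 / A^2; toy-model masses are
specified directly in that unit (mass = 1 gives a thermal oscillation
period of order a ps for stiffnesses of order 1 kcal/mol/A^2).

Pulling velocities are quoted in A/ns at configuration level and
converted to A/ps internally.
"""

#: Boltzmann constant [kcal/(mol K)]
KB: float = 0.0019872041

#: Conversion factor from A/ns (user-facing) to A/ps (internal)
A_PER_NS_TO_A_PER_PS: float = 1.0e-3


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature
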