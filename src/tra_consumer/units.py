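"""Internal unit conventions and conversion constants.

The package fixes one internal unit per quantity and converts only at I/O
boundaries: masses g (products) or mg (doses, airborne mass), areas cm2,
lengths cm, volumes m3 (air) or cm3 (ingested material), times h (scenario)
or s (diffusion), pressures Pa, molar masses g/mol, densities g/cm3,
body weight kg. Doses are mg/kg body weight/day; air concentrations mg/m3.
"""

#: Ideal-gas constant, J/(mol K).
R_GAS = 8.314

#: Default temperature for saturated-vapor-concentration estimates, K.
DEFAULT_TEMPERATURE_K = 298.15

MG_PER_G = 1_000.0
UG_PER_MG = 1_000.0
CM2_PER_M2 = 10_000.0
M2_PER_CM2 = 1.0 / CM2_PER_M2
S_PER_H = 3_600.0
MIN_PER_H = 60.0


def round_sig(x: float, digits: int = 3) -> float:
    """Round ``x`` to ``digits`` significant figures (reports only).

    Internal computation always keeps full precision.
    """
    if x == 0 or not (x == x):  # zero or NaN pass through
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (digits - 1))
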