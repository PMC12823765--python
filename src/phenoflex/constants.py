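"""Framework-wide physical constants.

The Kelvin offset is 273 (not 273.15) so that the fixed optimal chilling
temperature of 279 K corresponds to 6 °C, matching the convention of the
chill-modelling ecosystem this package interoperates with.
"""

#: Additive offset used for all °C → K conversions.
KELVIN_OFFSET: float = 273.0

#: Optimal constant temperature for chill accumulation (K); held fixed
#: throughout calibration.
THETA_STAR: float = 279.0

#: Critical temperature of the heat (GDH) submodel (°C); held fixed
#: throughout calibration.
TC_HEAT: float = 36.0


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + KELVIN_OFFSET


def kelvin_to_celsius(temp_k: float) -> float:
    return temp_k - KELVIN_OFFSET
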