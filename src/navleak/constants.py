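"""Physical constants and unit helpers.

Internal units throughout the package: time in ms, voltage in mV,
concentration in mM, temperature in degrees Celsius, current in µA.
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
CELSIUS_OFFSET = 273.15


def thermal_voltage_mV(temperature_C: float) -> float:
    """RT/F in mV at the given temperature (≈24.53 mV at 11.5 °C)."""
    return GAS_CONSTANT * (temperature_C + CELSIUS_OFFSET) / FARADAY * 1e3
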