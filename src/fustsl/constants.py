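"""Physical constants and common defaults (SI units throughout)."""

#: Boltzmann constant (J/K).
BOLTZMANN = 1.380649e-23

#: Dynamic viscosity of water at 310 K (Pa s). Configurable wherever it is used.
WATER_VISCOSITY_310K = 6.92e-4

#: Core body temperature (K); initial and far-field tissue temperature.
T_BODY = 310.15

#: Kelvin <-> Celsius offset.
CELSIUS_OFFSET = 273.15

SECONDS_PER_DAY = 86400.0
SECONDS_PER_HOUR = 3600.0
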