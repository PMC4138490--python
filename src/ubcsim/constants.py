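"""Physical constants and unit conventions.

The package uses NEURON-compatible units throughout:

* voltage        mV
* time           ms
* current        nA  (1 uS * 1 mV = 1 nA)
* conductance    uS  (densities in S/cm^2)
* permeability   cm/s
* capacitance    nF  (specific capacitance in uF/cm^2)
* length         um  (areas internally in cm^2)
* concentration  mM
* temperature    degrees Celsius
"""

FARADAY = 96485.3321  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
ZERO_CELSIUS = 273.15  # K
CA_VALENCE = 2

#: simulation temperature of the canonical model, degC
SIM_TEMPERATURE = 30.0


def rt_over_f(temperature_c: float) -> float:
    """RT/F in mV at the given temperature (degC)."""
    return 1000.0 * GAS_CONSTANT * (ZERO_CELSIUS + temperature_c) / FARADAY
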