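"""Passive properties from a voltage-clamp transient.

Applies the experimental transient protocol — a -10 mV, 250 ms step from
-70 mV through the 20 MOhm pipette — to the canonical UBC model, fits
the capacitive current with three exponentials, and derives the input
capacitance (displaced charge / step size), input resistance
(steady-state current) and series resistance (tau1 / C_in).

C_in should sit near the cell's summed compartmental capacitance
(16.7 pF) and R_in near 1 GOhm; tau1 ~ R_s * C_in ~ 0.3 ms reflects
somatic charging, the slower components the brush/shaft and axon.
"""

import numpy as np

import ubcsim

model = ubcsim.load_canonical()
print(f"summed compartmental capacitance: "
      f"{model.morphology.total_capacitance_pF():.2f} pF")

trace = ubcsim.passive_transient(model, delta_v=-10.0, holding=-70.0)
fit = ubcsim.fit_triexponential(
    trace, step_onset=50.0, step_duration=250.0, delta_v=-10.0,
    access_resistance=model.morphology.pipette.access_resistance,
)

print(f"tri-exponential fit: taus = {np.round(fit.taus, 3)} ms, "
      f"amplitudes = {np.round(fit.amplitudes * 1e3, 1)} pA")
print(f"C_in = {fit.c_in:.2f} pF   (charge integral / step)")
print(f"R_in = {fit.r_in:.3f} GOhm (steady-state current)")
print(f"R_s  = {fit.r_s:.1f} MOhm  (tau1 / C_in; pipette is 20 MOhm)")
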