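"""Intrinsic electroresponsiveness under current steps.

From a -80 mV holding potential (maintained by a computed bias current,
as in the experiments), a +16 pA / 800 ms step triggers a low-threshold
calcium spike crowned by a fast Na spike burst that relaxes into tonic
firing; a -20 pA step produces the H-current sag.

Printed metrics: first-spike delay (ms), overshoot of the first spike
(mV), instantaneous frequency (1000/first ISI), steady-state frequency
(1000/fourth ISI), their ratio ISI1/ISI4, and the sag amplitude
(minimum minus steady-state voltage, negative = sag below steady
state).
"""

import ubcsim

model = ubcsim.load_canonical()

step = ubcsim.step_response(model, 16.0, duration=800.0, holding=-80.0)
m = ubcsim.step_metrics(step)
print("+16 pA step from -80 mV:")
print(f"  holding bias current  {step.meta['holding_current_nA'] * 1e3:7.2f} pA")
print(f"  first-spike delay     {m.first_spike_delay:7.1f} ms")
print(f"  overshoot             {m.overshoots[0]:7.1f} mV")
print(f"  instantaneous freq    {m.instantaneous_frequency:7.1f} Hz")
print(f"  steady-state freq     {m.steady_state_frequency:7.1f} Hz")
print(f"  frequency ratio       {m.frequency_ratio:7.3f}")
print(f"  spikes in step        {m.spike_count:4d}")

sag_trace = ubcsim.step_response(model, -20.0, duration=800.0, holding=-80.0)
onset = sag_trace.meta["stim_onset"]
sag = ubcsim.sag_amplitude(sag_trace, (onset, onset + 800.0))
print(f"-20 pA step from -80 mV: sag amplitude {sag:.2f} mV")
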