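"""Conductance robustness of the canonical model.

Scales selected maximum conductances by +/-20% and re-runs the +16 pA
step protocol, checking that every spike metric stays inside the
experimental acceptance windows (delay 31.1-93.4 ms, overshoot
15.0-45.1 mV, instantaneous 95.9-202.7 Hz, steady-state 41.2-141.8 Hz,
ratio 0.61-1.3).  A well-balanced canonical model tolerates these
variations; the admissible envelope per mechanism summarizes the result.

The full ten-mechanism sweep is the same call with more mechanisms and
a denser scale grid (see ubcsim.robustness_sweep / `ubcsim sweep`).
"""

import ubcsim
from ubcsim.analysis import admissible_envelope

model = ubcsim.load_canonical()
ranges = {m: (0.8, 1.0, 1.2) for m in ("h", "calva", "kca")}
df = ubcsim.robustness_sweep(model, ranges, include_lor=False)

cols = ["mechanism", "scale", "step_delay", "step_overshoot", "step_inst",
        "step_ss", "step_ratio", "ok"]
print(df[cols].to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print()
print(admissible_envelope(df).to_string(index=False))
print("\n'ok' rows stay inside every experimental window at that scaling.")
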