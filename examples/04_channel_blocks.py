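"""In-silico pharmacology of the LOR.

Re-runs the canonical 10-pulse 100 Hz LOR protocol with individual
conductances switched off, mimicking TRP block (SKF96365), H block
(ZD7288/Cs+), and combined T+L-type calcium block
(mibefradil + nimodipine), and reports the relative effects:

* TRP block removes the main depolarizing drive: the post-train ramp
  slope collapses (reported as % reduction vs control).
* Combined Ca block leaves the LOR but strips most spikes from the
  burst (% reduction in spike count).
* H block slows the ramp, delaying the first spike (% increase in
  delay), and hyperpolarizes the resting potential by a few mV.
* H + TRP block together abolish the LOR entirely.
"""

import ubcsim
from ubcsim.analysis import lor_metrics, lor_response

model = ubcsim.load_canonical()


def run_lor(m, bias=None):
    tr = lor_response(m, bias_nA=bias)
    onset = tr.meta["stim_onset"]
    return tr, lor_metrics(tr, onset, tr.meta["pulse_times"][-1] + 10.0)


# blocked runs keep the intact model's holding current, as when a drug
# washes in without re-adjusting the amplifier
ctrl_trace, ctrl = run_lor(model)
bias = ctrl_trace.meta["holding_current_nA"]
print(f"control LOR: delay {ctrl.delay:.0f} ms, slope {ctrl.ramp_slope:.2f} mV/s, "
      f"{ctrl.spike_count} spikes")

_, trp = run_lor(model.with_block({"trp"}), bias)
print(f"TRP block:  ramp slope {trp.ramp_slope:.2f} mV/s "
      f"-> {100 * (1 - trp.ramp_slope / ctrl.ramp_slope):.0f}% reduction")

_, ca = run_lor(model.with_block({"cahva", "calva"}), bias)
print(f"Ca block:   {ca.spike_count} spikes "
      f"-> {100 * (1 - ca.spike_count / ctrl.spike_count):.0f}% fewer spikes")

_, h = run_lor(model.with_block({"h"}), bias)
print(f"H block:    delay {h.delay:.0f} ms "
      f"-> {100 * (h.delay / ctrl.delay - 1):.1f}% longer")

_, both = run_lor(model.with_block({"h", "trp"}), bias)
print(f"H+TRP block: {'no LOR (no spikes)' if both.no_lor else 'LOR persists!'}")
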