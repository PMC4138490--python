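# Methods

`ubcsim` is a deterministic, conductance-based compartmental model of the
cerebellar unipolar brush cell (UBC), built to reproduce three layers of
UBC physiology: passive properties (input capacitance and resistance
measured from voltage-clamp transients), intrinsic electroresponsiveness
(low-threshold-spike bursts, tonic discharge, sag and rebound), and the
late-onset response (LOR) — a slow depolarizing ramp and delayed spike
burst driven by a second-messenger cascade that couples synaptic train
stimulation to TRP- and H-channel modulation, independently of
ionotropic receptors.

## Model structure

**Morphology.** Thirteen compartments in an unbranched chain: dendritic
brush (cylinder, 25.25 x 10 um), dendritic shaft (50 x 2 um), spherical
soma (8 um), five axon-initial-segment compartments (0.5 um long,
diameters stepping 3.2 -> 0.8 um) and five axonal sections (80 x 0.5
um).  Passive parameters: Ra = 100 Ohm cm, Cm = 1 uF/cm^2, leak density
2.101e-5 S/cm^2 (1/47.6 kOhm cm^2) with E_leak = -70 mV.  Each
compartment carries an effective-area scale so that the capacitance
split is exactly 2 pF (soma), 12.7 pF (brush + shaft) and 2 pF (axon +
AIS), 16.7 pF in total: the brush membrane of a real UBC is folded into
dendrioles (effective area larger than the plain cylinder, scale
1.205), while the effective axonal area is smaller than its nominal
geometry (scale 0.311).  Area scales apply to capacitance and channel
totals only; axial resistances use the raw geometry (e.g. 407 MOhm per
axonal section, 15.9 MOhm for the shaft).  A recording pipette —
sealed end, no wall capacitance, 20 MOhm access resistance — is placed
at the soma and enters the circuit only in voltage clamp; current clamp
uses an ideal source.

**Ionic mechanisms.** Ten mechanisms with Hodgkin–Huxley or Markov
gating.  Kinetics are taken from the published cerebellar formulations
each mechanism derives from, with the UBC-specific parameters overlaid:

* `na` — 13-state Markov resurgent Na scheme (five closed, open,
  open-blocked, six inactivated states; transient, persistent and
  resurgent components), density 0.192 S/cm^2, E = +63 mV, in soma, AIS
  and axon.
* `kv` — Kv3-type delayed rectifier (m^3 h), 6.75e-4 S/cm^2, E_K =
  -84.69 mV, soma/AIS/axon.
* `ka` — A-type K (a^3 b), 0.007 S/cm^2, brush/shaft/soma; controls
  first-spike delay.
* `kslow` — M-type slow K (x), 8e-4 S/cm^2, soma; controls tonic
  discharge frequency.
* `kca` — BK-type Ca-dependent K (single gate with [Ca]-dependent
  rates), 0.0052 S/cm^2, brush/shaft/soma; shapes the fast AHP.
* `cahva` — L-type Ca (s^2 u), 2.15e-4 S/cm^2, uniform over
  brush/shaft/soma, ohmic law with the Ca reversal updated at run time
  from the shell (Nernst; 129.33 mV at rest, bath concentration
  back-solved to 2.0 mM).
* `calva` — T-type Ca (m^2 h, Cav3.1 kinetics), GHK permeation with
  permeability 6.3e-5 cm/s, denser in the brush than shaft and soma;
  generates the low-threshold spike (LTS).
* `h` — HCN (single gate), 5.72e-4 S/cm^2, E = -30 mV, half-activation
  -91.5 mV, slope 7.7 mV; produces the sag and rebound, and its
  midpoint is shifted by the cascade.
* `trp` — voltage-independent cationic leak, E = 0 mV, in the brush
  (the synaptic site); its maximum conductance is scaled by the
  cascade.
* `leak` — background leak in all 13 compartments.

Base maximum densities are stored verbatim in the packaged config; the
compartment-specific tuning lives in dimensionless per-compartment
multipliers (the experimental papers constrain H, T- and L-type
densities; the remaining densities are free parameters calibrated
against the printed response metrics, as in the source model).

**Temperature.** The model runs at 30 degC.  Rates are Q10-corrected
(Q10 = 5 for T-type activation, 3 elsewhere) from per-mechanism
reference temperatures recorded in the config.  Reference temperatures
are calibration parameters: the source models were fitted at different
(sometimes unstated) temperatures, so each mechanism's T_exp was chosen
once, during calibration against the UBC step-response metrics, and
frozen.

**Calcium shells.** Brush, shaft and soma each carry a 200 nm
sub-membrane shell obeying d[Ca]/dt = -I_Ca/(2 F A d) - beta_ca
([Ca] - [Ca]_rest), with [Ca]_rest = 100 nM.  Only the L-type current
feeds the shell; the T-type current is excluded by construction.  The
shell gates the BK current and sets the Ca reversal.  beta_ca's printed
value (1.5) carries no printed units; it is interpreted as 1/ms
(sub-millisecond clearance, shaping a fast AHP) and exposed in the
config.

**Second-messenger cascade.** A receptor pool X (total 4.5 mM) converts
to X* at rate alpha(t), the sum of omega-weighted boxcar windows (tau =
50 ms) opened by each synaptic pulse; X* decays back at beta.  X*
drives Y -> Y* (Y total 5 mM, the ATP scale) through a sigmoidal rate
delta(X*) with half-point X*_half = 2.7 mM and width K = 0.75 mM —
with x_total = 4.5 mM the half-point sits at 60% of the X* range, so
conversion effectively switches on when X* exceeds ~60% of its maximum.
Y* reverts at gamma.  Normalized Y* modulates the membrane globally:
TRP conductance is Gmax_TRP (0.16 + Y*norm), and the H activation
midpoint shifts right by up to 25 mV through a logistic in Y*norm
(midpoint 0.6, slope 0.1), spanning -91.5 to -66.5 mV.  The resting
state of the cascade is its fixed point: X* = 0 exactly, and a small
resting Y* set by the sigmoid floor delta(0); both modulation laws are
evaluated at that resting Y* when the cell is unstimulated, so rest is
a true steady state.  omega, beta, delta_max, gamma and the TRP density
are calibration parameters frozen so that a 10-pulse 100 Hz train
reproduces the reference LOR.

Synaptic pulses have no direct electrical effect (the LOR experiments
are performed under ionotropic-receptor block); they only drive the
cascade.

## Numerics

Fixed-step implicit integration, default dt = 0.025 ms.  The voltage
equation is advanced by backward Euler on the chain-ordered tridiagonal
(Hines) system via the Thomas algorithm; HH gates by exponential Euler
at the pre-step voltage; the Markov Na occupancies by implicit Euler
with a dense 13x13 Gaussian elimination (I - dt Q is strictly
diagonally dominant, so pivoting is unnecessary), renormalized to unit
sum each step with the worst deviation reported in the trace metadata;
calcium shells and cascade variables by exact exponential updates with
currents frozen over the step.  The GHK (T-type) current is nonlinear
in V and is treated explicitly; its removable singularity at V = 0 is
series-expanded.  All state is float64 and runs are bit-reproducible;
the identical kernel source executes under numba (preferred) or as
plain Python.

Holding potentials are realized as in the experiments: a constant bias
current, found by secant iteration on the settled somatic voltage
(tolerance 0.1 mV, 3 s relaxation per iterate), holds the soma at the
requested potential in current clamp.  Voltage clamp drives the soma
through the 20 MOhm pipette conductance.

## Measurement pipeline

Spikes are detected where the depolarization rate first reaches 5
mV/ms, with 0.5 mV/ms re-arm hysteresis and a 1.5 ms refractory group
so each spike yields one event; the overshoot is the voltage maximum
before the next event.  Step metrics: first-spike delay from step
onset; instantaneous frequency 1000/ISI1; steady-state frequency
1000/ISI4; frequency ratio ISI1/ISI4 (the printed 176 Hz / 126 Hz /
0.715 triple is consistent only with this reading — note the ratio
equals steady-state/instantaneous frequency).  Sag: minimum voltage
during a hyperpolarizing step minus the mean over the final 10% of the
step.  LOR metrics: delay from train onset to the first spike
threshold; ramp slope from a linear fit between train end and the first
spike threshold (trace end if no spike fires); duration first-to-last
spike; instantaneous frequency from the first ISI of the late burst.

Voltage-clamp transients are fitted with a three-exponential-plus-offset
model.  The fit window is restricted to 50 ms after the step so that
slow active conductances (H relaxes over hundreds of milliseconds) do
not contaminate the capacitive components; C_in comes from the
displaced-charge integral over the window (and, secondarily, from
sum(A_i tau_i)); R_in from the steady-state current minus the pipette
contribution; R_s = tau_1 / C_in.

## Calibration

Construction followed the reference order: morphology and passive
properties first, then the conductance complement against the +16 pA
step metrics (delay 30.3 ms, overshoot 36.7 mV, 176/126 Hz, ratio
0.715), a silent resting state near -67 mV, the input resistance, the
-20 pA sag (-17.3 mV), the LOR windows (delay 98–1000 ms, duration
100–2500 ms, burst frequency 92–209 Hz) and the three in-silico block
effects, using a randomized coordinate search over the per-compartment
density multipliers, reference temperatures and cascade rates; the
result is frozen in `config/canonical.yaml`.  The calibrated canonical
model fires a decelerating burst (inst. 154 Hz into tonic 121 Hz,
ratio 0.79) with a 34.9 ms delay and 39.6 mV overshoot, rests silently
at -65.8 mV, and produces a 10-pulse LOR at 190 ms delay that is
abolished by combined H+TRP block.

In-silico pharmacology keeps the intact model's holding current when a
conductance is switched off (the amplifier is not re-adjusted when a
blocker washes in), so the blocked cell settles away from -80 mV — as
in the experiments, where H-current block visibly hyperpolarizes the
baseline.  With a re-solved bias the H-block comparison inverts: a
constant bias replacement always outruns the H current, whose driving
force collapses during depolarization.

## Design decisions on ambiguous sources

* The printed delayed-rectifier time-constant expression restores a
  sign lost in transcription (exp(v/28.29), matching the source model's
  monotone deactivation), and the source's piecewise forms are used for
  the activation/inactivation time constants (expressed in seconds in
  the original).
* The L-type backward rates are taken from the source model (the
  printed table duplicates the forward rates for both columns, which
  would make the gate voltage-independent).
* Printed granule-cell rate prefactors are interpreted in 1/ms as in
  the source implementations; read as 1/s they would give A-type
  activation time constants of ~200 ms, two orders slower than any
  A-type current.
* The H time constant: the printed Boltzmann-derived expression peaks
  at ~230 ms near -88 mV, while the stated behavior is ~180 ms at -130
  mV rising to ~630 ms at -90 mV.  No single multiplicative scale fits
  both anchors, so the calibrated mode refits the two free shape
  parameters of the same expression family (delta = 0.075 /mV,
  amplitude 8.0594e-4 /ms, gamma = 0.65) to hit both anchors exactly;
  the raw printed expression remains selectable (`tau_mode: raw`).
* The stated "10% activation at -108 mV" is inconsistent with the
  printed H Boltzmann (which gives ~90% there); the printed formula is
  taken as canonical.
* delta(X*) as printed is a decaying exponential while the text calls
  it sigmoidal; a logistic with the printed half-point and slope (used
  multiplicatively) is adopted, and Y* in the modulation laws is the
  normalized fraction Y*/Y_total (the additive 0.16 baseline only makes
  sense against an order-one variable).
* The H shift coefficient defaults to 25 mV (the stated -91.5..-66.5 mV
  range); the printed 10 mV coefficient is available in the config.
* The H conductance is restricted to the soma: distributing the printed
  density over soma plus dendrites makes the H-block resting shift
  ~-13 mV, inconsistent with the reported ~-4 mV.
* The Markov Na rate constants are not printed; the canonical
  resurgent-scheme constants are used, with the open-block entry and
  exit rates treated as calibration parameters of the UBC burst
  (recorded in the config), consistent with the reported
  cell-type-dependence of the resurgent component.

## The synthetic fixture generator

`ubcsim.io.generate_fixtures` produces seeded, deterministic traces
with exact ground truth for the analysis pipeline: stereotyped spike
trains at known times with band-limited noise, tri-exponential
transients with known amplitudes/time constants, sag traces with known
minimum and steady state, and LOR-like ramp-plus-burst traces.  These
emulate waveform shapes, not biophysics: passing analysis tests on
fixtures shows the measurement code is correct, not that the simulator
is; the simulator is validated separately against the analytic RC
oracle, the Kirchhoff and conservation invariants, dt-refinement
convergence, and the calibrated response metrics.

## Problem sizes and runtimes

All protocols are desk-scale: 13 compartments, 1–3.7 s of simulated
time per run at dt = 0.025 ms (40,000–148,000 steps), a few seconds per
run on one CPU.  The robustness sweep and response-space maps run the
same protocols over parameter grids and scale linearly in grid size.

## Known limitations

* The brush is a single cylinder with an effective-area scale, not a
  reconstructed dendriolar tree; local synaptic computations within the
  brush are outside scope.
* One calcium shell per compartment, no buffering or inter-compartment
  diffusion; shell parameters are effective, not measured.
* The cascade is deliberately generic (the real pathway is unknown);
  its state variables are physiologically suggestive (ATP/cAMP scale)
  but not identified molecules.
* The Markov Na scheme is deterministic mean-field; single-channel
  stochasticity is not modeled.
* Fixed-step integration only; no adaptive error control (convergence
  is instead checked by dt halving).
* The calibrated compromise under-expresses three quantities relative
  to the reference values: the sag is ~-13.3 mV (vs -17.3; the slow H
  time constant near -100 mV cannot fully develop within the 800 ms
  step at the H density the silent-rest requirement allows), the
  TRP-block ramp-slope reduction is ~90% (vs 69%; the intact ramp must
  stay fast enough to outrun T-type inactivation, which makes the
  residual H-only ramp comparatively small), and combined Ca block
  abolishes the LOR spikes entirely (vs an 80% reduction; without the
  low-threshold spike the cascade drive saturates ~15 mV below sodium
  threshold, and raising the drive would destabilize the resting
  state).  These are properties of the reconstructed parameter regime,
  not numerical artifacts, and the corresponding tests report them
  honestly.
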