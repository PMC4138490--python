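# Canonical UBC model parameterization.
#
# `gmax` holds the mechanism's base maximum conductance density (S/cm^2;
# cm/s for the GHK-permeation CaLVA) as published; `density` maps
# compartments (or the groups all/ais/axon/dend) to dimensionless
# multipliers carrying the compartment-specific calibration.  `texp` is
# the reference temperature of each mechanism's kinetics; rates are
# Q10-corrected to the simulation temperature (30 C).  Cascade rates
# are in 1/s, amounts in mM.
name: canonical-ubc
temperature: 30.0
passive:
  axial_resistivity: 100.0
  specific_capacitance: 1.0
pipette:
  access_resistance: 20.0
mechanisms:
  leak:
    gmax: 2.269e-05
    reversal: -70.0
    q10: 3.0
    texp: 30.0
    density:
      all: 1.0
  trp:
    gmax: 5.813e-05
    reversal: 0.0
    q10: 3.0
    texp: 30.0
    density:
      brush: 1.0
  h:
    gmax: 0.000572
    reversal: -30.0
    q10: 3.0
    texp: 30.0
    tau_mode: calibrated
    density:
      soma: 0.5
  kv:
    gmax: 0.000675
    reversal: -84.69
    q10: 3.0
    texp: 30.0
    density:
      soma: 90.0
      ais: 90.0
      axon: 9.74
  ka:
    gmax: 0.007
    reversal: -84.69
    q10: 3.0
    texp: 30.0
    density:
      brush: 0.117
      shaft: 0.117
      soma: 0.117
  kslow:
    gmax: 0.0008
    reversal: -84.69
    q10: 3.0
    texp: 30.0
    density:
      soma: 6.986
  kca:
    gmax: 0.0052
    reversal: -84.69
    q10: 3.0
    texp: 30.0
    density:
      brush: 7.03
      shaft: 7.03
      soma: 7.03
  cahva:
    gmax: 0.000215
    q10: 3.0
    texp: 30.0
    density:
      brush: 0.707
      shaft: 0.707
      soma: 0.707
  calva:
    gmax: 6.3e-05
    q10: 5.0
    q10_inact: 3.0
    texp: 12.0
    density:
      brush: 1.62
      shaft: 0.81
      soma: 0.405
    texp_inact: 34.6
  na:
    gmax: 0.192
    reversal: 63.0
    q10: 3.0
    texp: 30.0
    density:
      soma: 0.762
      ais: 6.185
      axon: 0.31
    markov:
      Aalfa: 353.91
      Valfa: 13.99
      Abeta: 1.272
      Vbeta: 13.99
      Agamma: 150.0
      Adelta: 40.0
      Aepsilon: 1.096
      Ateta: 0.02335
      Vteta: 25.0
      Con: 0.005
      Coff: 0.5
      Oon: 0.75
      Ooff: 0.005
      n1: 5.422
      n2: 3.279
      n3: 1.83
      n4: 0.738
calcium:
  shell_depth_um: 0.2
  beta_ca: 1.399
  ca_rest: 0.0001
  reversal_init: 129.33
  compartments:
  - brush
  - shaft
  - soma
cascade:
  omega: 2.341
  window: 50.0
  beta: 0.843
  x_total: 4.5
  x_half: 2.7
  slope_k: 0.75
  slope_form: divisive
  delta_max: 12.196
  gamma: 2.583
  y_total: 5.0
  trp_baseline: 0.16
  h_shift_max: 25.0
  h_shift_mid: 0.6
  h_shift_slope: 0.1
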