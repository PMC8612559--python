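# Default membrane mechanism parameters.
#
# Calibrated (see docs/methods.md) so that the ball model (soma d = 46.6 um,
# g_pas = 1.28e-5 S/cm2, E_pas = -50.5 mV) reproduces the reported
# excitability of immature CA3 pyramidal neurons: rest ~-50.5 mV, long-step
# rheobase converging to 4.2497 pA, stationary AP threshold (maximal
# subthreshold voltage) ~-42.9 mV, and a GABA-clamp excitation threshold
# ~-42.7 mV.  The Na activation gain and midpoint were solved so that the
# steady-state somatic I-V curve has its fold (local outward maximum)
# exactly at 4.2497 pA and returns through zero ~0.27 mV above the fold;
# the strong cooperativity factor produces the abrupt regenerative onset
# and the steep K window below threshold sharpens the descent.
#
# Units: conductance densities S/cm2, voltages mV, time constants ms,
# cooperativity factor cf in mV per unit open fraction, gains dimensionless.
na:
  gna_max: 5.419898e-03
  e_na: 60.0
  g_co: 1.0
  g_oc: 1.0
  g_ic: 1.0
  g_ci: 1.0
  v_co: -28.65351
  v_ic: -35.0
  k_co: 1.7
  k_ic: 7.0
  tau_act: 0.5
  tau_ina: 4.0
  tau_rel: 20.0
  cf: 3000.0
  q10: 1.0
k:
  gk_max: 1.3e-3
  e_k: -90.0
  g_co: 1.0
  g_oc: 1.0
  v_co: -40.0
  v_ic: -40.0
  k_co: 0.7
  k_ic: 0.7
  tau_act: 10.0
  tau_ina: 1.5
  tau_rel: 20.0
  cf: 0.0
  q10: 1.0
leak:
  g_pas: 1.28e-5
  e_pas: -50.5
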