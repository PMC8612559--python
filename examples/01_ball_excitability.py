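"""Excitability of the single-compartment model: rheobase and the four
action-potential threshold estimators.

Builds the default ball model (46.6 um soma, calibrated channel set),
searches the minimal long-step current that fires it, and reads the AP
threshold four ways from a suprathreshold sweep.
"""
import gabathresh as gt
import gabathresh.thresholds as th
from gabathresh.synapses import CurrentStep

model = gt.CompartmentalModel(gt.build_ball())

rheo = th.rheobase_search(model, duration_ms=4000.0)
print(f"rheobase (4 s steps): {rheo.threshold:.4f} pA "
      f"({rheo.sweep_count} sweeps)")
print(f"stationary threshold E_Thr^ST: {rheo.st_peak_mv:.2f} mV")

cfg = gt.SolverConfig(t_stop=1200.0)
sweep = gt.integrate(model, [CurrentStep(("soma", 0.5),
                                         rheo.threshold * 1.5e-3,
                                         10.0, 1210.0)], cfg)
print(f"E_Thr^dVdt: {th.e_thr_dvdt(sweep).value:.2f} mV  "
      f"(first 10 V/s crossing)")
print(f"E_Thr^d3:   {th.e_thr_d3(sweep).value:.2f} mV  "
      f"(first third-derivative peak)")
print(f"E_Thr^IS:   {th.e_thr_is(sweep).value:.2f} mV  "
      f"(baseline/upstroke line intersection)")

# The stationary estimate is the most negative: it marks the maximal
# voltage that does not enter the regenerative cycle, while the dynamic
# estimators fire later on the upstroke.
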