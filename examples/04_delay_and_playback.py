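"""Timing dependence of the GABAergic effect, and current playback.

Delaying the AMPA input relative to the GABA input shifts E_GABA^Thr
from near the AP threshold toward the resting potential: late inputs see
only the lingering depolarisation, not the shunt.  Replaying the
recorded GABAergic *current* (no conductance at all) gives E_GABA^Thr
exactly at the passive reversal potential.
"""
import gabathresh as gt

model = gt.CompartmentalModel(gt.build_ball())
grid = gt.default_egaba_grid(-52.0, -42.0, 0.5)

print("conductance co-stimulation (g_GABA = 3.95 nS):")
for delay, est in gt.delay_scan(model, ("soma", 0.5), ("soma", 0.5),
                                3.95, grid, [-20.0, 0.0, 60.0, 300.0]):
    print(f"  AMPA delay {delay:+6.0f} ms -> E_GABA^Thr = "
          f"{est.value:.2f} mV")

pb_grid = gt.default_egaba_grid(-52.0, -48.0, 0.5)
curve = gt.scan_delta_g_ampa(model, ("soma", 0.5), ("soma", 0.5), 3.95,
                             pb_grid, playback=True)
est = gt.egaba_thr_intersection(curve)
print(f"\ncurrent playback (depolarisation without shunt): "
      f"E_GABA^Thr = {est.value:.2f} mV  (= E_pas)")
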