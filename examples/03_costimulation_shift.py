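"""GABAergic shift of the AMPA firing threshold (synchronous inputs).

Measures g_AMPA^Thr with and without a co-active somatic GABA synapse
over an E_GABA grid.  The sign change of the shift Delta g_AMPA^Thr is
the excitation threshold E_GABA^Thr, which lies clearly *below* the AP
threshold: the GABAergic depolarisation outlasts its conductance, so
GABA helps AMPA inputs before E_GABA reaches the spike threshold.
"""
import numpy as np

import gabathresh as gt

model = gt.CompartmentalModel(gt.build_ball())
grid = gt.default_egaba_grid(-47.0, -41.0, 0.5)

for g_gaba in (3.95, 0.789):
    curve = gt.scan_delta_g_ampa(model, ("soma", 0.5), ("soma", 0.5),
                                 g_gaba, grid)
    est = gt.egaba_thr_intersection(curve)
    print(f"g_GABA = {g_gaba} nS: baseline g_AMPA^Thr = "
          f"{curve.g_ampa_thr_without:.3f} nS, "
          f"E_GABA^Thr = {est.value:.2f} mV")
    for e, d in zip(curve.e_gaba, curve.delta):
        tag = "inhibitory" if d > 0 else "excitatory"
        print(f"    E_GABA {e:6.1f} mV: delta {d:+.4f} nS  ({tag})")
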