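"""GABA-only excitation threshold: g_GABA^Thr(E_GABA) and E_GABA^Thr.

For each GABA reversal potential on a grid, the minimal peak conductance
of a single somatic GABA synapse that fires the ball model is confined by
the staircase search; the reciprocal plot's abscissa intercept locates
the reversal potential below which no conductance can excite the cell.
"""
import numpy as np

import gabathresh as gt

model = gt.CompartmentalModel(gt.build_ball())
grid = gt.default_egaba_grid(-44.0, -38.0, 0.5)

curve = gt.scan_g_gaba_thr(model, ("soma", 0.5), grid)
for e, g in zip(curve.e_gaba, curve.g_thr):
    label = f"{g:8.3f} nS" if np.isfinite(g) else "no threshold"
    print(f"  E_GABA = {e:6.1f} mV -> g_GABA^Thr = {label}")

est = gt.egaba_thr_reciprocal(curve)
print(f"\nE_GABA^Thr (reciprocal intercept): {est.value:.2f} mV")
print("Below this reversal potential the GABAergic input is inhibitory "
      "regardless of its conductance; above it, a large enough synapse "
      "fires the cell directly.")
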