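# Methods

## Scientific problem

GABA_A receptors pass mainly Cl⁻ (plus some HCO₃⁻), so the effect of a
GABAergic input depends on where the reversal potential E_GABA sits
relative to the resting potential and the action-potential threshold.
In immature or injured neurons E_GABA is depolarized, yet a depolarizing
GABA response is not automatically excitatory: the conductance it opens
also shunts concurrent excitation.  The package quantifies the switch
point — the **threshold reversal potential E_GABA^Thr** at which the net
effect of a GABAergic input on spiking turns from inhibitory to
excitatory — in compartmental model neurons, under phasic GABA-only
input, GABA×AMPA co-stimulation with controlled timing and dendritic
placement, tonic (extrasynaptic) GABA conductance, and random synaptic
bombardment of branched morphologies.

## Membrane model

Every model carries a passive leak (`g_pas = 1.28e-5 S/cm²`,
`E_pas = −50.5 mV` — the measured resting potential of immature CA3
pyramidal neurons), a 3-state Na⁺ channel and a 2-state delayed-rectifier
K⁺ channel on the excitable compartments (the soma, except in the axon
variant).  The Na⁺ channel has closed/open/inactivated fractions
(`1−O−H`, `O`, `H`); transition rates are Boltzmann sigmoids and the
open-fraction rates are evaluated at the *effective* voltage
`v + cf·O_Na`.  This cooperative shift — the more channels open, the
further the activation curve moves leftward — produces the abrupt,
regenerative spike onset that independent-gate Hodgkin–Huxley kinetics
cannot reproduce.  Both Na⁺ states and the K⁺ open fraction additionally
relax with a voltage-independent rate `1/tau_rel`.  Currents are Ohmic:
`I = g_max·O·(V−E)`.

### Parameter calibration

The numerical channel constants for this cell type are not publicly
tabulated, so the packaged defaults (`data/channels_default.yaml`) were
re-derived by calibrating the single-compartment ("ball", d = 46.6 µm)
model against the reported excitability of immature CA3 pyramidal
neurons:

* resting potential −50.5 mV (net channel current ≈ 0 at rest),
* long-step rheobase converging to 4.2497 pA,
* stationary spike threshold (maximal subthreshold voltage) ≈ −42.8 mV,
* GABA-clamp excitation threshold ≈ −42.7 mV.

These observables pin the *steady-state somatic I–V curve*: its outward
hump must peak at exactly 4.2497 pA near −42.8 mV (rheobase = hump
height, stationary threshold = hump position) and must return through
zero only ~0.2 mV higher (a strong GABA input clamps the soma near
E_GABA, so firing from a decaying GABA conductance requires net inward
steady-state current at that voltage).  A single-Boltzmann activation
cannot produce such an asymmetric hump — with the fold slope fixed at
the leak conductance, the descent to zero is forced to span
`~hump/(2·g_leak) ≈ 2 mV`.  The defaults therefore combine

1. a gentle Na⁺ activation toe (`k_co = 1.7 mV`) that carries the
   subthreshold persistent current setting the hump height,
2. a steep K⁺ window (`k = 0.7 mV`, midpoint −40 mV, slow kinetics
   `tau_act = 10 ms`) that sharpens the descent and provides subthreshold
   accommodation and spike repolarisation, and
3. a strong cooperativity factor (`cf = 3000 mV` per unit open fraction)
   placing a near-vertical activation runaway ~0.27 mV above the fold.

`gna_max` and the activation midpoint were solved (fixed-point iteration
on the self-consistent steady state, then Gauss–Seidel on the two
targets) so the fold sits at (−42.888 mV, 4.2497 pA) with the zero
crossing at −42.62 mV.  Axial resistivity is not reported for this
preparation; the default `Ra = 208 Ω·cm` was chosen once so that the
ball-and-stick rheobase reproduces the reported 6.55 pA.  Specific
capacitance is the standard 1 µF/cm².  All of these are config-exposed.

Everything downstream — the co-stimulation thresholds near −44.4 mV,
the small-conductance limit −44.6 mV, the delay dependence, the playback
threshold at exactly −50.5 mV, and the tonic plateau near −48.4 mV — is
*emergent*: none of those protocols entered the calibration.

## Numerics

Space: spherical soma as one isopotential compartment (area πd²);
cylinders split into `nseg` equal compartments; axial coupling from the
half-segment resistances; branched trees solved directly (root-first
ordering, leaf-to-root elimination) at tridiagonal cost.  Time: gates are
advanced by an exponential integrator with rates frozen at the current
voltage (the gate ODEs are linear given V), then the voltage system is
advanced θ-implicitly (θ = 0.5, Crank–Nicolson) with conductances frozen
over the step.  Default `dt = 0.025 ms`; halving dt changes all
AP-threshold estimates by < 0.1 mV and the rheobase by < 1e-5 pA.
Exp2 synapse states decay analytically per step; events add the
peak-normalising factor so `g_max` is the true peak conductance.  Gating
states are clipped to the unit simplex after each step; clips beyond
1e-9 are counted and reported in the sweep metadata.  Sweeps abort with
a diagnostic if |V| exceeds 500 mV.  Each sweep starts from a cached
resting state obtained by 500 ms of stimulus-free settling.

## Threshold definitions and searches

Four AP-threshold estimators: the voltage at the first 10 V/s crossing
of dV/dt; the voltage at the first positive peak of d³V/dt³
(Savitzky–Golay differentiator, window 5, order 4); the intersection of
straight-line fits to the pre-spike baseline (20 ms before the 10 V/s
crossing) and the upstroke (samples with dV/dt in 50–200 V/s, falling
back to the first supra-band samples for very sharp onsets); and the
stationary threshold from the strongest subthreshold sweep of a search.

For the stationary threshold the package reads the voltage at the
*slowest point* (minimum positive dV/dt) of the depolarising trajectory
rather than the raw maximum.  For a genuinely saturating sweep the two
are identical (the plateau).  But a deterministic search that brackets
the threshold to 1e-6 units always leaves a "subthreshold" sweep that
lingers at the unstable threshold voltage and escapes just after the
analysis window closes; its raw maximum reflects the truncated spike
upstroke, not the threshold, while its slowest point is exactly the
quasi-stationary threshold voltage.  This is the package's operational
reading of "the maximal potential that does not lead into the
regenerative cycle".

Conductance/current thresholds use an alternating staircase: raise the
stimulus in coarse steps (1 nS for GABA, 0.01 nS for AMPA, 1 pA for
current) until a spike occurs in the analysis window, lower it in ~3×
finer steps until the spike vanishes, raise in 10× finer steps until it
reappears, and repeat for 6 rounds with all steps shrunk 10-fold per
round (final bracket 1e-6 of the initial step).  The spike criterion is
a somatic crossing of 0 mV (config-exposed).  Windows: 800 ms after a
GABA-only input; from AMPA onset until the passive AMPA depolarisation
has decayed to 63 % of its peak (measured once per site with the spike
mechanism off).  GABA-only searches are capped at 200 nS by default and
report "no threshold" at the cap — the encoding of stable inhibition.
The cap is deliberately moderate: a much larger clamp conductance shunts
the spike below the detection level, breaking the monotonicity the
staircase assumes.  Scans warm-start each grid point from its
neighbour's threshold, which keeps sweep counts near the single-search
cost.

## E_GABA^Thr estimators

* **Reciprocal intercept** (GABA-only): `1/g_GABA^Thr` is fitted with a
  straight line through the two finite points closest to the
  no-threshold region; the abscissa intercept is E_GABA^Thr
  (extrapolation limited to 2 mV past the grid).
* **Baseline intersection** (co-stimulation and tonic): the zero
  crossing of `Δg_AMPA^Thr = g_AMPA^Thr(with GABA) − g_AMPA^Thr(without)`
  over the E_GABA grid, linearly interpolated.
* **p_AP crossing** (random bombardment): the E_GABA at which the
  spike-probability curve crosses the GABA-free baseline obtained with
  the same random-number sequence.

The default E_GABA grid is −56…−36 mV in 0.5 mV steps; analyses shipped
here use focused sub-grids around the crossing for speed (results are
grid-insensitive because the estimators interpolate).

Spatial scans shift onsets so the somatic peak depolarisations of the
GABA and AMPA inputs coincide, with peak times taken from spike-free
control sweeps per site.  Current playback records the synaptic current
of a spike-free conductance sweep and re-injects its negative as a
current-clamp stimulus, isolating the GABAergic depolarisation from the
conductance shunt; in the passive case the replayed voltage reproduces
the source sweep exactly.

## GHK chloride conversion

`[Cl⁻]ᵢ = 10^(E/60 mV)·(Cl_e + P_HCO3·HCO3_e) − P_HCO3·HCO3_i` with
Cl_e = 133.5 mM, HCO3_e = 24 mM, HCO3_i = 14.1 mM, P_HCO3 = 0.44
(relative to Cl⁻).  The inverse expression is exact, and the round trip
is tested to 1e-9.

## Synthetic morphologies and what they do not show

The spike-probability experiments require a reconstructed pyramidal-cell
morphology that is not publicly available, so the generator produces
*synthetic* branched neurons: a 15 µm soma with (by default) 56 passive
dendrites of 2–193 segments (~5 µm each, lognormal segment counts),
attached to the soma or, with probability 0.35, to the tip of an earlier
dendrite.  Synapse sites are drawn uniformly per unit dendritic length
(a documented choice; per-area or per-segment sampling would weight long
thin branches differently), onsets uniformly over a 2 s window, with
2/10/20/40 events per receptor class for 1/5/10/20 Hz.  Spike
probability uses common random numbers across grid points: per-sweep
seeds derive from (seed, sweep index) only.

Because the synthetic tree is not the reconstructed cell, millivolt
values of E_GABA^Thr from these protocols are morphology-specific;
the package (and its tests) therefore assert *directions and orderings*
— p_AP monotone in g_AMPA and E_GABA, thresholds less negative at higher
input frequency, proximal GABA placements at least as depolarized as
distal ones, tonic thresholds increasing with density — which are the
morphology-robust content of those experiments.  Passing these says
nothing about the exact values a particular reconstruction would give.

## Problem sizes used by the shipped tests

Deterministic protocols run at full fidelity (ball and 301-segment
ball-and-stick, dt = 0.025 ms, 3–4 s rheobase steps).  The stochastic
assertions run scaled down as the package's chosen test design: a
6-dendrite synthetic neuron (~80 compartments), 99 sweeps per
probability estimate, 4-point conductance and reversal grids; the
dendritic-position scan uses a 51-segment dendrite (somatic responses to
dendritic synapses change by < 1 % between 301 and 903 segments, and the
asserted properties are directions, not values).  Paper-scale settings
(999 sweeps, 56 dendrites, 20-position scans) remain the library
defaults.

## Known limitations

* E_GABA is an imposed parameter: no Cl⁻ accumulation, HCO₃⁻ dynamics or
  somato-dendritic Cl⁻ gradients.
* Dendrites are passive (no dendritic spike initiation); active membrane
  is somatic, or axonal in the axon variant.
* The calibrated channel set reproduces threshold-level behaviour;
  spike shape (width, repolarisation speed) was constrained only loosely
  and the AP waveform is broader than typical recordings.
* The ball-and-stick GABA-only threshold comes out ~0.5 mV more negative
  than the soma-only value; reproducing a larger separation while keeping
  the single-compartment thresholds would require a shallower post-fold
  I–V descent, which conflicts with the calibrated knee sharpness (see
  the fold analysis above).
* The AMPA reversal potential of −12 mV is adopted as reported for this
  preparation (junction-potential-corrected); it is unusual relative to
  the conventional 0 mV.
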