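"""Randomised experiments on synthetic branched morphologies.

The reconstructed pyramidal-neuron morphology used for the spike-probability
experiments is not publicly printed, so this module generates *synthetic*
branched morphologies that emulate its gross statistics (a small soma with
tens of dendrites whose segment counts span a wide range) and runs the same
protocols on them: random synapse placement and timing, spike probability
(p_AP) over many sweeps with common random numbers, the AMPA conductance at
half-maximal spike probability (g_AMPA^50), and the E_GABA^Thr read from
the crossing of the p_AP(E_GABA) curve with the GABA-free baseline.

Quantities here are morphology-specific; analyses assert directions and
orderings rather than the millivolt values of any particular reconstruction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cable import (CompartmentalModel, Morphology, Section, SolverConfig,
                    integrate, DEFAULT_RA, DEFAULT_CM)
from .synapses import (ampa_synapse, gaba_synapse, Exp2SynapseSpec,
                       TonicConductanceSpec, apply_tonic)
from .egaba import EGabaThrEstimate

__all__ = [
    "SyntheticMorphologySpec", "StimulationPattern", "PAPCurve",
    "generate_synthetic_morphology", "draw_pattern", "estimate_p_ap",
    "p_ap_curve", "g_ampa_50", "egaba_thr_from_pap",
    "counts_for_frequency",
]

#: Synapse counts per 2 s window for the canonical stimulation frequencies.
FREQ_COUNTS = {1.0: 2, 5.0: 10, 10.0: 20, 20.0: 40}


def counts_for_frequency(freq_hz: float, window_ms: float = 2000.0) -> int:
    """Number of stimuli of one receptor class in the window (freq * window)."""
    if freq_hz in FREQ_COUNTS and window_ms == 2000.0:
        return FREQ_COUNTS[freq_hz]
    return max(1, int(round(freq_hz * window_ms / 1000.0)))


@dataclass
class SyntheticMorphologySpec:
    """Generator settings for a synthetic branched neuron.

    Defaults emulate the reference reconstruction's gross statistics:
    soma diameter 15 um and 56 dendritic sections with segment counts
    between 2 and 193 (segments of ~5 um).  ``branch_prob`` is the chance
    that a dendrite attaches to the tip of an earlier dendrite instead of
    the soma, up to ``max_depth`` levels.
    """
    n_dendrites: int = 56
    soma_diam: float = 15.0
    dend_diam: float = 1.0
    seg_length: float = 5.0                 # um
    nseg_range: tuple = (2, 193)
    nseg_log_mean: float = 3.0              # lognormal parameters of nseg
    nseg_log_sigma: float = 1.0
    branch_prob: float = 0.35
    max_depth: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_dendrites < 0:
            raise ValueError("n_dendrites must be >= 0")
        lo, hi = self.nseg_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid nseg_range")


def generate_synthetic_morphology(spec: SyntheticMorphologySpec,
                                  na=None, k=None, leak=None,
                                  ra: float = DEFAULT_RA,
                                  cm: float = DEFAULT_CM) -> Morphology:
    """Seeded synthetic branched morphology (soma active, dendrites passive).

    With ``n_dendrites = 0`` this reduces to a ball model with the given
    soma diameter.  The same spec (same seed) always yields an identical
    morphology.
    """
    rng = np.random.default_rng(spec.seed)
    soma = Section("soma", "soma", diam=spec.soma_diam,
                   mechanisms={"leak": 1.0, "na": 1.0, "k": 1.0})
    sections = [soma]
    depth = {"soma": 0}
    lo, hi = spec.nseg_range
    for i in range(spec.n_dendrites):
        nseg = int(np.clip(round(rng.lognormal(spec.nseg_log_mean,
                                               spec.nseg_log_sigma)),
                           lo, hi))
        parent, parent_pos = "soma", 0.5
        if sections[1:] and rng.random() < spec.branch_prob:
            cand = rng.integers(1, len(sections))
            if depth[sections[cand].id] < spec.max_depth:
                parent, parent_pos = sections[cand].id, 1.0
        sec = Section(f"dend{i:03d}", "cylinder", diam=spec.dend_diam,
                      length=nseg * spec.seg_length, nseg=nseg,
                      parent=parent, parent_pos=parent_pos,
                      mechanisms={"leak": 1.0})
        depth[sec.id] = depth[parent] + 1
        sections.append(sec)
    return Morphology(sections, ra=ra, cm=cm, na=na, k=k, leak=leak)


@dataclass
class StimulationPattern:
    """Seeded random synapse sites and event times for one sweep."""
    ampa: list                      # [(site, onset_ms)]
    gaba: list
    window_ms: float
    seed: tuple

    def __post_init__(self):
        for site, onset in list(self.ampa) + list(self.gaba):
            if not 0 <= onset <= self.window_ms:
                raise ValueError("onset outside the stimulation window")


def _dendrite_table(model: CompartmentalModel):
    """(sites, lengths, path_distances) for every dendritic compartment."""
    sites, lengths, dists = [], [], []
    for i in range(model.n):
        sec = model.morph.section(model.owner[i])
        if sec.kind != "cylinder":
            continue
        first, nseg = model._offset[sec.id]
        j = i - first
        x = (j + 0.5) / nseg
        sites.append((sec.id, x))
        lengths.append(sec.length / sec.nseg)
        dists.append(model.path_distance(i))
    return sites, np.array(lengths), np.array(dists)


def _region_mask(lengths, dists, placement):
    if placement == "global":
        return np.ones(len(lengths), dtype=bool)
    # proximal/distal split at the length-weighted median path distance
    order = np.argsort(dists)
    cum = np.cumsum(lengths[order])
    median = dists[order][np.searchsorted(cum, 0.5 * cum[-1])]
    if placement == "proximal":
        return dists <= median
    if placement == "distal":
        return dists > median
    raise ValueError(f"unknown placement {placement!r}")


def draw_pattern(model: CompartmentalModel, n_ampa: int, n_gaba: int,
                 window_ms: float, seed,
                 ampa_placement: str = "global",
                 gaba_placement: str = "global") -> StimulationPattern:
    """Random synapse sites (uniform per unit dendritic length within the
    allowed region) and onsets (uniform over the window)."""
    rng = np.random.default_rng(seed)
    sites, lengths, dists = _dendrite_table(model)
    if len(sites) == 0:
        raise ValueError("morphology has no dendritic compartments")

    def draw(n, placement):
        mask = _region_mask(lengths, dists, placement)
        if not mask.any():
            raise ValueError(f"empty region {placement!r}")
        w = lengths * mask
        p = w / w.sum()
        idx = rng.choice(len(sites), size=n, p=p)
        onsets = rng.uniform(0.0, window_ms, size=n)
        return [(sites[i], float(t)) for i, t in zip(idx, onsets)]

    ampa = draw(n_ampa, ampa_placement)
    gaba = draw(n_gaba, gaba_placement)
    return StimulationPattern(ampa=ampa, gaba=gaba, window_ms=window_ms,
                              seed=tuple(np.atleast_1d(seed).tolist()))


@dataclass
class PAPCurve:
    grid: np.ndarray              # g_AMPA (nS) or E_GABA (mV)
    p_ap: np.ndarray
    n_sweeps: int
    variable: str                 # "g_ampa" | "e_gaba"
    meta: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        """Binomial standard error of each p_AP estimate."""
        p = self.p_ap
        return np.sqrt(p * (1 - p) / self.n_sweeps)


def _run_sweeps(model, n_sweeps, seed, n_ampa, n_gaba, g_ampa, g_gaba,
                e_gaba, window_ms, dt, ampa_placement, gaba_placement,
                detect_level=0.0):
    """Fraction of sweeps with >= 1 AP; per-sweep seeds derived from
    (seed, sweep index) so conditions share random number sequences."""
    hits = 0
    raster = []
    cfg = SolverConfig(dt=dt, t_stop=window_ms + 100.0,
                       record=(("soma", 0.5),), settle_ms=500.0)
    for s in range(n_sweeps):
        pat = draw_pattern(model, n_ampa, n_gaba, window_ms, (seed, s),
                           ampa_placement=ampa_placement,
                           gaba_placement=gaba_placement)
        stimuli = [ampa_synapse(site, g_ampa, onset=t)
                   for site, t in pat.ampa]
        if g_gaba > 0 and n_gaba > 0:
            stimuli += [gaba_synapse(site, g_gaba, e_gaba, onset=t)
                        for site, t in pat.gaba]
        sw = integrate(model, stimuli, cfg,
                       detect=(("soma", 0.5), detect_level, 0.0,
                               window_ms + 100.0),
                       stop_at_spike=True)
        if sw.meta["ap"]:
            hits += 1
            raster.append(sw.meta["ap_time"])
        else:
            raster.append(None)
    return hits / n_sweeps, raster


def estimate_p_ap(model: CompartmentalModel, g_ampa: float,
                  freq_hz: float = 10.0, n_sweeps: int = 999,
                  seed: int = 0, g_gaba: float = 0.0,
                  e_gaba: float = -50.5, window_ms: float = 2000.0,
                  dt: float = 0.025, ampa_placement: str = "global",
                  gaba_placement: str = "global"):
    """Spike probability under random bombardment.

    Each sweep draws a fresh synapse distribution and stimulus times (one
    AMPA and optionally one GABA roster of ``freq * window`` events).
    Returns ``(p_ap, standard_error, raster)``.
    """
    n = counts_for_frequency(freq_hz, window_ms)
    p, raster = _run_sweeps(model, n_sweeps, seed, n, n, g_ampa, g_gaba,
                            e_gaba, window_ms, dt, ampa_placement,
                            gaba_placement)
    return p, math.sqrt(p * (1 - p) / n_sweeps), raster


def p_ap_curve(model, grid, variable: str, *, freq_hz=10.0, n_sweeps=99,
               seed=0, g_ampa=None, g_gaba=0.789, window_ms=2000.0,
               dt=0.025, ampa_placement="global", gaba_placement="global",
               tonic_morph=None) -> PAPCurve:
    """p_AP over a grid of g_AMPA (GABA-free) or E_GABA (fixed g values).

    The same per-sweep seed sequence is reused at every grid point
    (common random numbers), so curves are smooth in the grid variable.
    With ``variable="e_gaba"`` and ``tonic_morph`` set, the GABA conductance
    is tonic (uniform density ``g_gaba`` in S/cm2 on that morphology)
    instead of synaptic.
    """
    n = counts_for_frequency(freq_hz, window_ms)
    ps = []
    for val in grid:
        if variable == "g_ampa":
            p, _ = _run_sweeps(model, n_sweeps, seed, n, 0, float(val), 0.0,
                               -50.5, window_ms, dt, ampa_placement,
                               gaba_placement)
        elif variable == "e_gaba":
            if tonic_morph is not None:
                morph_t = apply_tonic(tonic_morph,
                                      TonicConductanceSpec(g_gaba, float(val)))
                m_t = CompartmentalModel(morph_t)
                p, _ = _run_sweeps(m_t, n_sweeps, seed, n, 0, g_ampa, 0.0,
                                   float(val), window_ms, dt, ampa_placement,
                                   gaba_placement)
            else:
                p, _ = _run_sweeps(model, n_sweeps, seed, n, n, g_ampa,
                                   g_gaba, float(val), window_ms, dt,
                                   ampa_placement, gaba_placement)
        else:
            raise ValueError(variable)
        ps.append(p)
    return PAPCurve(np.asarray(grid, dtype=float), np.asarray(ps),
                    n_sweeps, variable,
                    meta={"seed": seed, "freq_hz": freq_hz})


def g_ampa_50(curve: PAPCurve, target: float = 0.5) -> float:
    """Grid value at p_AP = ``target`` by linear interpolation between the
    two points closest to the target (the curve must bracket it)."""
    p = curve.p_ap
    x = curve.grid
    above = p >= target
    if above.all() or (~above).all():
        raise ValueError("p_AP curve does not bracket the target")
    # first bracketing pair along the grid
    for i in range(len(p) - 1):
        if (p[i] - target) * (p[i + 1] - target) <= 0 and p[i] != p[i + 1]:
            w = (target - p[i]) / (p[i + 1] - p[i])
            return float(x[i] + w * (x[i + 1] - x[i]))
    raise ValueError("no bracketing pair found")


def egaba_thr_from_pap(model, e_gaba_grid, *, g_ampa, freq_hz=10.0,
                       n_sweeps=99, seed=0, g_gaba=0.789,
                       window_ms=2000.0, dt=0.025,
                       ampa_placement="global", gaba_placement="global",
                       tonic_morph=None, baseline_p=None):
    """E_GABA^Thr from the p_AP(E_GABA) curve.

    The baseline is the spike probability of the same AMPA pattern without
    GABA (shared seeds); the threshold is the E_GABA at which the GABA
    curve crosses that baseline (inhibitory below, excitatory above).
    Returns ``(EGabaThrEstimate, curve, baseline_p)``.
    """
    n = counts_for_frequency(freq_hz, window_ms)
    if baseline_p is None:
        baseline_p, _ = _run_sweeps(model, n_sweeps, seed, n, 0, g_ampa,
                                    0.0, -50.5, window_ms, dt,
                                    ampa_placement, gaba_placement)
    curve = p_ap_curve(model, e_gaba_grid, "e_gaba", freq_hz=freq_hz,
                       n_sweeps=n_sweeps, seed=seed, g_ampa=g_ampa,
                       g_gaba=g_gaba, window_ms=window_ms, dt=dt,
                       ampa_placement=ampa_placement,
                       gaba_placement=gaba_placement,
                       tonic_morph=tonic_morph)
    d = curve.p_ap - baseline_p
    cross = None
    for i in range(len(d) - 1):
        if d[i] <= 0 <= d[i + 1] and d[i] != d[i + 1]:
            w = -d[i] / (d[i + 1] - d[i])
            cross = float(curve.grid[i] + w * (curve.grid[i + 1]
                                               - curve.grid[i]))
            break
    est = EGabaThrEstimate(cross, "pap-crossing",
                           {"baseline_p": baseline_p,
                            "n_sweeps": n_sweeps})
    return est, curve, baseline_p
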