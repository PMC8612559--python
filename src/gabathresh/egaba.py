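"""E_GABA^Thr analyses: the reversal potential at which a GABAergic input's
net effect on spiking switches from inhibitory to excitatory.

Two estimators are used, matching the two stimulation paradigms:

* **Reciprocal intercept** (GABA-only inputs): the threshold conductance
  g_GABA^Thr grows hyperbolically as E_GABA falls toward E_GABA^Thr, so the
  abscissa intercept of a straight-line fit to 1/g_GABA^Thr locates the
  threshold reversal potential.

* **Baseline intersection** (GABA x AMPA co-stimulation): the E_GABA at
  which g_AMPA^Thr with GABA crosses the GABA-free baseline, i.e. where the
  excitability shift Delta g_AMPA^Thr changes sign.

Scans over synaptic delay, dendritic position and tonic conductance density
reuse these estimators.  The GHK helper converts E_GABA to intracellular
chloride given a fixed HCO3- gradient.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cable import CompartmentalModel, Morphology, SolverConfig, integrate
from .synapses import (Exp2SynapseSpec, TonicConductanceSpec, apply_tonic,
                       ampa_synapse, gaba_synapse, record_and_playback,
                       GABA_G_PHYS)
from .thresholds import (ThresholdSearchResult, gaba_threshold_search,
                         ampa_threshold_search, ampa_analysis_window)

__all__ = [
    "GThrCurve", "EGabaThrEstimate", "DeltaGAmpaCurve", "GhkParams",
    "default_egaba_grid", "scan_g_gaba_thr", "egaba_thr_reciprocal",
    "egaba_thr_intersection", "scan_delta_g_ampa", "delay_scan",
    "spatial_scan", "dendritic_gaba_scan", "tonic_scan",
    "ghk_cl_from_egaba", "egaba_from_ghk_cl",
]


def default_egaba_grid(lo: float = -56.0, hi: float = -36.0,
                       step: float = 0.5) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2, step), 6)


@dataclass
class GThrCurve:
    e_gaba: np.ndarray                # mV, strictly increasing
    g_thr: np.ndarray                 # nS; NaN where no threshold exists
    site: tuple = ("soma", 0.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.e_gaba = np.asarray(self.e_gaba, dtype=float)
        self.g_thr = np.asarray(self.g_thr, dtype=float)
        if np.any(np.diff(self.e_gaba) <= 0):
            raise ValueError("E_GABA grid must be strictly increasing")
        if np.any(self.g_thr[np.isfinite(self.g_thr)] <= 0):
            raise ValueError("finite g_thr values must be positive")


@dataclass
class EGabaThrEstimate:
    value: Optional[float]            # mV; None = outside the scanned range
    method: str                       # reciprocal-intercept | intersection | pap-crossing
    diagnostics: dict = field(default_factory=dict)


@dataclass
class DeltaGAmpaCurve:
    e_gaba: np.ndarray
    g_ampa_thr_with: np.ndarray       # nS, with GABA co-stimulation
    g_ampa_thr_without: float         # nS, baseline

    @property
    def delta(self) -> np.ndarray:
        return self.g_ampa_thr_with - self.g_ampa_thr_without


# ---------------------------------------------------------------------------
# GABA-only threshold curves

def scan_g_gaba_thr(model: CompartmentalModel, site, e_gaba_grid,
                    tonic: Optional[TonicConductanceSpec] = None,
                    **search_kw) -> GThrCurve:
    """One conductance-threshold search per E_GABA grid point; NaN marks
    grid points where even the conductance cap cannot evoke a spike (the
    stable-inhibition region below E_GABA^Thr).
    """
    grid = np.asarray(e_gaba_grid, dtype=float)
    out = np.full(grid.shape, np.nan)
    sweeps = np.zeros(grid.shape, dtype=int)
    up0 = search_kw.get("up0", 1.0)
    start = search_kw.pop("start", 0.0)
    warm = search_kw.pop("warm_start", True)
    # descend the grid: thresholds grow monotonically toward the sentinel
    # region, so each search can warm start just below its predecessor
    for idx in range(len(grid) - 1, -1, -1):
        res = gaba_threshold_search(model, site, grid[idx], start=start,
                                    **search_kw)
        if res.threshold is not None:
            out[idx] = res.threshold
            if warm:
                start = max(0.0, res.threshold - 2.0 * up0)
        sweeps[idx] = res.sweep_count
    return GThrCurve(grid, out, site=site,
                     meta={"sweep_counts": sweeps})


def egaba_thr_reciprocal(curve: GThrCurve, n_fit: int = 2,
                         max_extrapolation_mv: float = 2.0) -> EGabaThrEstimate:
    """E_GABA^Thr as the abscissa intercept of the reciprocal plot.

    Straight line through the ``n_fit`` finite points of 1/g_thr closest to
    the no-threshold region (default 2); the intercept must have positive
    fitted slope (1/g falling to zero as E_GABA decreases) and lie within
    ``max_extrapolation_mv`` of the last finite grid point.
    """
    finite = np.isfinite(curve.g_thr)
    if finite.sum() < n_fit or n_fit < 2:
        raise ValueError("need at least two finite threshold points")
    idx = np.flatnonzero(finite)[:n_fit]     # lowest-E_GABA finite points
    x = curve.e_gaba[idx]
    y = 1.0 / curve.g_thr[idx]
    slope, inter = np.polyfit(x, y, 1)
    if slope < 1e-9:
        raise ValueError("reciprocal curve does not approach the axis")
    x0 = -inter / slope
    lo = curve.e_gaba[idx[0]] - max_extrapolation_mv
    value = float(x0) if x0 >= lo else None
    return EGabaThrEstimate(value, "reciprocal-intercept",
                            {"slope": float(slope), "points": idx.tolist()})


# ---------------------------------------------------------------------------
# GABA x AMPA interaction

def egaba_thr_intersection(curve: DeltaGAmpaCurve) -> EGabaThrEstimate:
    """E_GABA at the sign change of Delta g_AMPA^Thr (linear interpolation).

    Delta > 0 (GABA raises the AMPA threshold) marks inhibition, Delta < 0
    excitation; the zero crossing is E_GABA^Thr.  Returns ``value=None``
    when the scanned range contains no sign change.
    """
    d = curve.delta
    e = curve.e_gaba
    ok = np.isfinite(d)
    d, e = d[ok], e[ok]
    if len(d) == 0:
        return EGabaThrEstimate(None, "intersection", {"reason": "empty"})
    sign = np.sign(d)
    hits = np.flatnonzero(sign == 0)
    if hits.size:
        return EGabaThrEstimate(float(e[hits[0]]), "intersection", {})
    cross = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if cross.size == 0:
        return EGabaThrEstimate(None, "intersection",
                                {"reason": "no sign change"})
    i = cross[0]
    w = d[i] / (d[i] - d[i + 1])
    return EGabaThrEstimate(float(e[i] + w * (e[i + 1] - e[i])),
                            "intersection", {"bracket": (float(e[i]),
                                                         float(e[i + 1]))})


def scan_delta_g_ampa(model: CompartmentalModel, ampa_site, gaba_site,
                      g_gaba: float, e_gaba_grid, gaba_onset: float = 10.0,
                      ampa_onset: float = 10.0, window=None,
                      playback: bool = False,
                      baseline: Optional[float] = None,
                      **search_kw) -> DeltaGAmpaCurve:
    """g_AMPA^Thr with and without a GABA co-stimulus over an E_GABA grid.

    With ``playback=True`` the GABAergic conductance sweep is replaced by
    current injection of the recorded GABAergic current (isolating the
    depolarisation from the shunt).  The analysis window is the
    onset-to-63%-decay interval of the passive AMPA response throughout.
    """
    if window is None:
        window = ampa_analysis_window(model, ampa_site, onset=ampa_onset)
    if baseline is None:
        base = ampa_threshold_search(model, ampa_site, onset=ampa_onset,
                                     window=window, **search_kw)
        if base.threshold is None:
            raise RuntimeError("no baseline AMPA threshold below the cap")
        baseline = base.threshold
    grid = np.asarray(e_gaba_grid, dtype=float)
    g_with = np.full(grid.shape, np.nan)
    t_stop_needed = max(window[1], gaba_onset + 5.0)
    up0 = search_kw.get("up0", 0.01)
    start = search_kw.pop("start", 0.0)
    warm = search_kw.pop("warm_start", True)
    for i in range(len(grid) - 1, -1, -1):
        eg = grid[i]
        gaba = gaba_synapse(gaba_site, g_gaba, eg, onset=gaba_onset)
        if playback:
            cfg = SolverConfig(t_stop=t_stop_needed + 200.0,
                               record=(("soma", 0.5),))
            pb, _src = record_and_playback(model, gaba, cfg)
            co = [pb]
        else:
            co = [gaba]
        res = ampa_threshold_search(model, ampa_site, co_stimuli=co,
                                    onset=ampa_onset, window=window,
                                    start=start, **search_kw)
        if res.threshold is not None:
            g_with[i] = res.threshold
            if warm:
                start = max(0.0, res.threshold - 5.0 * up0)
    return DeltaGAmpaCurve(grid, g_with, baseline)


def delay_scan(model: CompartmentalModel, ampa_site, gaba_site,
               g_gaba: float, e_gaba_grid, delays_ms,
               gaba_onset: float = 200.0, playback: bool = False,
               **search_kw):
    """E_GABA^Thr as a function of the AMPA-vs-GABA delay.

    ``delay > 0`` means the AMPA input follows the GABA input.  Returns a
    list of ``(delay, EGabaThrEstimate)``; each estimate comes from the
    intersection of the per-delay Delta g_AMPA^Thr curve with the shared
    GABA-free baseline.
    """
    window0 = ampa_analysis_window(model, ampa_site, onset=gaba_onset)
    rel = window0[1] - window0[0]
    base = ampa_threshold_search(model, ampa_site, onset=gaba_onset,
                                 window=window0, **search_kw)
    out = []
    for d in delays_ms:
        onset = gaba_onset + d
        window = (onset, onset + rel)
        curve = scan_delta_g_ampa(model, ampa_site, gaba_site, g_gaba,
                                  e_gaba_grid, gaba_onset=gaba_onset,
                                  ampa_onset=onset, window=window,
                                  playback=playback,
                                  baseline=base.threshold, **search_kw)
        out.append((float(d), egaba_thr_intersection(curve)))
    return out


def peak_time(model: CompartmentalModel, spec: Exp2SynapseSpec,
              t_stop: float = 600.0) -> float:
    """Time (ms after onset) of the somatic depolarisation peak of a single
    synaptic input, measured with the spike mechanism disabled."""
    cfg = SolverConfig(t_stop=float(np.max(spec.onsets)) + t_stop,
                       record=(("soma", 0.5),), enable_ap_mechanism=False)
    sw = integrate(model, [spec], cfg)
    return float(sw.t[int(np.argmax(sw.soma_v))] - np.min(spec.onsets))


def spatial_scan(model: CompartmentalModel, gaba_positions, ampa_positions,
                 e_gaba_grid, g_gaba: float = 7.89,
                 base_onset: float = 50.0, **search_kw):
    """E_GABA^Thr for every (GABA position, AMPA position) pair on the
    dendrite, with onsets shifted so that the somatic peak depolarisations
    of the two inputs coincide (peaks taken from spike-free control sweeps).

    Returns ``(matrix, gaba_positions, ampa_positions)`` where
    ``matrix[i, j]`` is the estimate for GABA at ``gaba_positions[i]`` and
    AMPA at ``ampa_positions[j]``.
    """
    gaba_positions = list(gaba_positions)
    ampa_positions = list(ampa_positions)
    # control peak times per site (cached per kinetics by construction)
    tp_gaba = {x: peak_time(model, gaba_synapse(("dend", x), 1.0, -40.0,
                                                onset=0.0))
               for x in gaba_positions}
    tp_ampa = {x: peak_time(model, ampa_synapse(("dend", x), 1.0, onset=0.0))
               for x in ampa_positions}
    mat = np.empty((len(gaba_positions), len(ampa_positions)), dtype=object)
    for i, xg in enumerate(gaba_positions):
        for j, xa in enumerate(ampa_positions):
            shift = tp_gaba[xg] - tp_ampa[xa]
            gaba_on = base_onset
            ampa_on = base_onset + shift
            window = ampa_analysis_window(model, ("dend", xa),
                                          onset=ampa_on)
            curve = scan_delta_g_ampa(
                model, ("dend", xa), ("dend", xg), g_gaba, e_gaba_grid,
                gaba_onset=gaba_on, ampa_onset=ampa_on, window=window,
                **search_kw)
            mat[i, j] = egaba_thr_intersection(curve)
    return mat, gaba_positions, ampa_positions


def dendritic_gaba_scan(model: CompartmentalModel, positions, e_gaba_grid,
                        **search_kw):
    """GABA-only E_GABA^Thr, E_GABA^Peak and stationary threshold per
    dendritic position.

    For each position the g_GABA^Thr(E_GABA) curve is scanned, E_GABA^Thr
    estimated from the reciprocal plot, and E_GABA^Peak measured as the
    somatic peak of the threshold-conductance response with the spike
    mechanism disabled (at the most negative E_GABA with a finite
    threshold).
    """
    results = []
    for x in positions:
        site = ("dend", x) if x > 0 else ("soma", 0.5)
        curve = scan_g_gaba_thr(model, site, e_gaba_grid, **search_kw)
        est = egaba_thr_reciprocal(curve)
        finite = np.flatnonzero(np.isfinite(curve.g_thr))
        peaks = []
        for idx in finite[:2]:
            g = curve.g_thr[idx]
            cfg = SolverConfig(t_stop=900.0, record=(("soma", 0.5),),
                               enable_ap_mechanism=False)
            sw = integrate(model,
                           [gaba_synapse(site, g, curve.e_gaba[idx],
                                         onset=10.0)], cfg)
            peaks.append(float(sw.soma_v.max()))
        results.append({"x": x, "curve": curve, "egaba_thr": est,
                        "egaba_peak": peaks[0] if peaks else math.nan,
                        "egaba_peaks": peaks})
    return results


def tonic_scan(model_morph: Morphology, densities, e_gaba_grid,
               ampa_site=("soma", 0.5), **search_kw):
    """E_GABA^Thr versus tonic GABA conductance density.

    For each density the AMPA threshold is searched over the E_GABA grid on
    a model carrying a uniform tonic conductance, and E_GABA^Thr is the
    intersection with the tonic-free baseline g_AMPA^Thr.  ``densities`` in
    S/cm2.  Returns a list of ``(density, EGabaThrEstimate)``.
    """
    base_model = CompartmentalModel(model_morph)
    window = ampa_analysis_window(base_model, ampa_site)
    base = ampa_threshold_search(base_model, ampa_site, window=window,
                                 **search_kw)
    out = []
    for dens in densities:
        grid = np.asarray(e_gaba_grid, dtype=float)
        g_with = np.full(grid.shape, np.nan)
        for i, eg in enumerate(grid):
            morph_t = apply_tonic(model_morph,
                                  TonicConductanceSpec(dens, eg))
            model_t = CompartmentalModel(morph_t)
            res = ampa_threshold_search(model_t, ampa_site, window=window,
                                        **search_kw)
            if res.threshold is not None:
                g_with[i] = res.threshold
        curve = DeltaGAmpaCurve(grid, g_with, base.threshold)
        out.append((float(dens), egaba_thr_intersection(curve)))
    return out


# ---------------------------------------------------------------------------
# GHK chloride conversion

@dataclass(frozen=True)
class GhkParams:
    """Constants of the chloride/bicarbonate GHK relation.

    ``p_hco3`` is the HCO3- permeability relative to Cl- (P_Cl = 1);
    ``slope`` the Nernst slope in mV per decade.
    """
    cl_e: float = 133.5       # mM
    hco3_e: float = 24.0      # mM
    hco3_i: float = 14.1      # mM
    p_hco3: float = 0.44
    slope: float = 60.0       # mV per decade

    def __post_init__(self):
        if min(self.cl_e, self.hco3_e, self.hco3_i) <= 0:
            raise ValueError("concentrations must be positive")
        if not 0 <= self.p_hco3 <= 1:
            raise ValueError("relative permeability must be in [0, 1]")


def ghk_cl_from_egaba(e_gaba, p: GhkParams = GhkParams()):
    """Intracellular chloride (mM) for a given GABA_A reversal potential.

    [Cl-]_i = 10^(E/slope) * (Cl_e + P_HCO3*HCO3_e) - P_HCO3*HCO3_i.
    Strictly increasing in E_GABA; results <= 0 are outside the
    physiological range of the relation (returned as-is for the caller to
    flag).
    """
    e = np.asarray(e_gaba, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("E_GABA must be finite")
    out = (10.0 ** (e / p.slope) * (p.cl_e + p.p_hco3 * p.hco3_e)
           - p.p_hco3 * p.hco3_i)
    return float(out) if np.isscalar(e_gaba) else out


def egaba_from_ghk_cl(cl_i, p: GhkParams = GhkParams()):
    """Inverse of :func:`ghk_cl_from_egaba` (exact round trip)."""
    cl = np.asarray(cl_i, dtype=float)
    num = cl + p.p_hco3 * p.hco3_i
    den = p.cl_e + p.p_hco3 * p.hco3_e
    if np.any(num <= 0):
        raise ValueError("chloride out of the invertible range")
    out = p.slope * np.log10(num / den)
    return float(out) if np.isscalar(cl_i) else out
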