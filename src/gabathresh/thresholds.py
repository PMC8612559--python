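"""Action-potential detection, the four AP-threshold estimators, the
iterative conductance/current threshold searches, and the AP feature error.

Threshold estimators
--------------------
``e_thr_dvdt``  voltage at the first upward crossing of dV/dt = 10 V/s
``e_thr_d3``    voltage at the first positive peak of d3V/dt3
``e_thr_is``    intersection of straight-line fits to the pre-spike baseline
                and the spike upstroke
``e_thr_st``    peak voltage of the strongest subthreshold sweep of a
                threshold search (a quasi-stationary definition)

Search procedure
----------------
Thresholds in stimulus strength are confined by an alternating staircase:
increase by a coarse step until a spike appears, decrease by a ~3x finer
step until it vanishes, increase by a 10x finer step until it reappears,
and repeat with all steps shrunk 10-fold per round (6 rounds by default).
The strongest subthreshold sweep of the final round defines ``e_thr_st``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.signal import savgol_filter

from .cable import CompartmentalModel, SolverConfig, Sweep, integrate
from .synapses import (Exp2SynapseSpec, CurrentStep, ampa_synapse,
                       gaba_synapse)

__all__ = [
    "APThresholdEstimate", "ThresholdSearchResult", "NoAPError",
    "detect_ap", "e_thr_dvdt", "e_thr_d3", "e_thr_is",
    "e_thr_st_value",
    "staircase_search", "gaba_threshold_search", "ampa_threshold_search",
    "rheobase_search", "ampa_analysis_window",
    "extract_ap_features", "ap_feature_error",
]

#: Default AP detection level (mV): the somatic voltage must cross this.
AP_DETECT_LEVEL = 0.0
#: Analysis window after a GABA-only input (ms).
GABA_WINDOW_MS = 800.0


class NoAPError(ValueError):
    """The sweep contains no action potential."""


@dataclass
class APThresholdEstimate:
    method: str          # dVdt | d3 | IS | ST
    value: float         # mV
    time: float          # ms (detection time; nan for ST)


@dataclass
class ThresholdSearchResult:
    threshold: Optional[float]     # nS (or pA for rheobase); None = capped
    sweep_count: int
    history: list                  # [(value, spiked)]
    final_step: float
    window: tuple                  # (t0, t1) ms
    last_subthreshold: Optional[float] = None   # stimulus value
    st_peak_mv: Optional[float] = None          # e_thr_st of this search
    meta: dict = field(default_factory=dict)

    @property
    def no_threshold(self) -> bool:
        return self.threshold is None


def detect_ap(sweep: Sweep, window=None, level: float = AP_DETECT_LEVEL,
              trace: int = 0):
    """Return ``(spiked, ap_time)``: first upward crossing of ``level`` by the
    recorded voltage inside ``window = (t0, t1)`` ms (whole sweep if None)."""
    v = sweep.v[trace]
    t = sweep.t
    if window is None:
        i0, i1 = 0, len(t) - 1
    else:
        t0, t1 = window
        i0 = int(np.searchsorted(t, t0, side="left"))
        i1 = int(np.searchsorted(t, t1, side="right")) - 1
    seg = v[i0:i1 + 1]
    above = seg >= level
    if not above.any():
        return False, None
    j = int(np.argmax(above))
    return True, float(t[i0 + j])


def _ap_peak_index(v, level=AP_DETECT_LEVEL):
    above = np.flatnonzero(v >= level)
    if above.size == 0:
        raise NoAPError("no action potential in sweep")
    j0 = j1 = above[0]
    while j1 < len(v) - 1 and v[j1 + 1] >= level:
        j1 += 1
    return j0 + int(np.argmax(v[j0:j1 + 1]))


def e_thr_dvdt(sweep: Sweep, crossing_v_per_s: float = 10.0,
               trace: int = 0) -> APThresholdEstimate:
    """Voltage at which dV/dt first crosses ``crossing_v_per_s`` (default
    10 V/s) on the way into the first AP.  Linear interpolation between
    samples keeps the estimate stable under dt refinement."""
    v = sweep.v[trace]
    t = sweep.t
    peak = _ap_peak_index(v)
    dvdt = np.gradient(v, sweep.dt)           # mV/ms == V/s
    thr = crossing_v_per_s
    for i in range(peak, 0, -1):
        if dvdt[i - 1] < thr <= dvdt[i]:
            w = (thr - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
            return APThresholdEstimate(
                "dVdt", float(v[i - 1] + w * (v[i] - v[i - 1])),
                float(t[i - 1] + w * sweep.dt))
    raise NoAPError("dV/dt never crosses the detection velocity")


def e_thr_d3(sweep: Sweep, smooth_window: int = 5,
             trace: int = 0) -> APThresholdEstimate:
    """Voltage at the first positive local maximum of d3V/dt3 before the AP
    peak.  The third derivative is taken with a short Savitzky-Golay
    polynomial differentiator (window 5, order 4) at the solver dt."""
    v = sweep.v[trace]
    t = sweep.t
    peak = _ap_peak_index(v)
    d3 = savgol_filter(v, smooth_window, polyorder=4, deriv=3,
                       delta=sweep.dt)
    # restrict to the rise into the first AP: start where dV/dt leaves rest
    dvdt = np.gradient(v, sweep.dt)
    for i in range(2, peak - 1):
        if d3[i] > 0 and d3[i] >= d3[i - 1] and d3[i] > d3[i + 1] \
                and dvdt[i] > 1.0:
            return APThresholdEstimate("d3", float(v[i]), float(t[i]))
    raise NoAPError("no positive third-derivative peak before the AP")


def e_thr_is(sweep: Sweep, baseline_ms: float = 20.0,
             rise_band_v_per_s=(50.0, 200.0),
             trace: int = 0) -> APThresholdEstimate:
    """Intersection of linear fits to the pre-spike baseline and the AP
    upstroke.

    Baseline: from ``baseline_ms`` before the 10 V/s crossing up to that
    crossing.  Upstroke: samples whose dV/dt lies in ``rise_band_v_per_s``
    on the rising flank before the peak.
    """
    v = sweep.v[trace]
    t = sweep.t
    peak = _ap_peak_index(v)
    anchor = e_thr_dvdt(sweep, trace=trace)
    i_anchor = int(np.searchsorted(t, anchor.time))
    i0 = max(0, i_anchor - int(round(baseline_ms / sweep.dt)))
    if i_anchor - i0 < 3:
        raise NoAPError("baseline window too short")
    p_base = np.polyfit(t[i0:i_anchor], v[i0:i_anchor], 1)

    dvdt = np.gradient(v, sweep.dt)
    lo, hi = rise_band_v_per_s
    idx = [i for i in range(i_anchor, peak + 1) if lo <= dvdt[i] <= hi]
    if len(idx) < 2:
        # very sharp upstroke: take the two samples bracketing the band
        idx = [i for i in range(i_anchor, peak + 1) if dvdt[i] >= lo][:3]
    if len(idx) < 2:
        raise NoAPError("no samples on the rising phase")
    p_rise = np.polyfit(t[idx], v[idx], 1)
    if abs(p_rise[0] - p_base[0]) < 1e-12:
        raise NoAPError("baseline and upstroke fits are parallel")
    t_x = (p_base[1] - p_rise[1]) / (p_rise[0] - p_base[0])
    v_x = np.polyval(p_base, t_x)
    return APThresholdEstimate("IS", float(v_x), float(t_x))


def e_thr_st_value(sweep: Sweep, t_from: float = 0.0,
                   trace: int = 0) -> float:
    """Stationary-threshold reading of a (sub)threshold sweep (mV).

    The stationary AP threshold is the maximal potential that does not lead
    into the regenerative cycle.  On a saturating subthreshold sweep this is
    simply the plateau maximum.  A marginal sweep, however, can linger at the
    unstable threshold voltage and then escape late in the window; its raw
    maximum then reflects the spike upstroke, not the threshold.  Both cases
    are covered by reading the voltage at the *slowest* point of the
    depolarising trajectory (minimum positive dV/dt between stimulus onset
    and the voltage maximum): for a saturating sweep that is the plateau,
    for a lingering sweep the quasi-stationary threshold itself.
    """
    v = sweep.v[trace]
    t = sweep.t
    i0 = int(np.searchsorted(t, t_from)) + 1
    ipk = i0 + int(np.argmax(v[i0:]))
    if ipk - i0 < 3:
        return float(v[ipk])
    dvdt = np.gradient(v, sweep.dt)
    seg = dvdt[i0:ipk]
    rising = seg >= 0
    if not rising.any():
        return float(v[ipk])
    idx = np.flatnonzero(rising)
    j = idx[int(np.argmin(seg[idx]))]
    return float(v[i0 + j])


# ---------------------------------------------------------------------------
# staircase search

def staircase_search(test: Callable[[float], tuple], up0: float,
                     rounds: int = 6, start: float = 0.0,
                     cap: float = math.inf, down_ratio: float = 0.33,
                     up_ratio: float = 0.1,
                     pretest_cap: bool = True) -> ThresholdSearchResult:
    """Alternating staircase confinement of a monotone yes/no threshold.

    ``test(x)`` returns ``(spiked, peak_mv)`` where ``peak_mv`` is the
    maximal (somatic) voltage of the sweep -- used to report the strongest
    subthreshold depolarisation.  The stimulus rises from ``start`` in
    ``up0`` steps until a spike occurs, then alternates finer down/up steps
    (``down_ratio * up0 * 10^-r`` and ``up_ratio * up0 * 10^-r`` in round
    r), shrinking 10-fold per round.

    If no spike occurs at ``cap`` the search reports ``threshold = None``
    (encoding that the input cannot excite the cell, however strong).
    A non-monotone bracket raises ``RuntimeError`` with the history.

    ``start`` may warm start the search (e.g. from a neighbouring grid
    point's threshold); a suprathreshold start is handled by the first
    down-phase.
    """
    history = []
    st_value, st_peak = None, None

    def run(x):
        nonlocal st_value, st_peak
        spiked, peak = test(x)
        history.append((x, bool(spiked)))
        if not spiked and (st_value is None or x > st_value):
            st_value, st_peak = x, peak
        return spiked

    if math.isfinite(cap) and pretest_cap:
        if not run(cap):
            return ThresholdSearchResult(
                threshold=None, sweep_count=len(history), history=history,
                final_step=up0 * up_ratio * 10.0 ** -(rounds - 1),
                window=(math.nan, math.nan),
                last_subthreshold=cap, st_peak_mv=st_peak)

    x = start
    spiked = run(x)
    step = up0
    while not spiked:
        x += step
        if x > cap + 1e-12:
            return ThresholdSearchResult(
                threshold=None, sweep_count=len(history), history=history,
                final_step=step, window=(math.nan, math.nan),
                last_subthreshold=st_value, st_peak_mv=st_peak)
        spiked = run(x)

    for r in range(rounds):
        down = up0 * down_ratio * 10.0 ** -r
        guard = 0
        while spiked:
            x -= down
            if x < -1e-12:
                raise RuntimeError(
                    f"search walked below zero; history={history}")
            spiked = run(x)
            guard += 1
            if guard > 1000:
                raise RuntimeError(f"non-monotone bracket; history={history}")
        up = up0 * up_ratio * 10.0 ** -r
        guard = 0
        while not spiked:
            x += up
            spiked = run(x)
            guard += 1
            if guard > 1000:
                raise RuntimeError(f"non-monotone bracket; history={history}")
        final_up = up

    return ThresholdSearchResult(
        threshold=x, sweep_count=len(history), history=history,
        final_step=final_up, window=(math.nan, math.nan),
        last_subthreshold=x - final_up, st_peak_mv=st_peak)


# ---------------------------------------------------------------------------
# concrete searches

def _sweep_test(model, stimuli_for, window, dt, level, extra_record=None,
                settle_ms=500.0):
    """Build a test(x) closure running one detection sweep per stimulus value."""
    t0, t1 = window

    def test(x):
        cfg = SolverConfig(dt=dt, t_stop=t1, record=(("soma", 0.5),),
                           settle_ms=settle_ms)
        sw = integrate(model, stimuli_for(x), cfg,
                       detect=(("soma", 0.5), level, t0, t1),
                       stop_at_spike=True)
        if sw.meta["ap"]:
            return True, None
        return False, e_thr_st_value(sw, t_from=t0)

    return test


def gaba_threshold_search(model: CompartmentalModel, site, e_gaba: float,
                          g_phys_extra=(), onset: float = 10.0,
                          window_ms: float = GABA_WINDOW_MS,
                          dt: float = 0.025, up0: float = 1.0,
                          cap: float = 200.0, rounds: int = 6,
                          level: float = AP_DETECT_LEVEL, start: float = 0.0,
                          pretest_cap: bool = False) -> ThresholdSearchResult:
    """Minimal peak GABA conductance (nS) at ``site`` that fires the cell
    within ``window_ms`` after the input, at reversal potential ``e_gaba``."""
    t1 = onset + window_ms

    def stimuli_for(g):
        return [gaba_synapse(site, g, e_gaba, onset=onset),
                *g_phys_extra]

    test = _sweep_test(model, stimuli_for, (onset, t1), dt, level)
    res = staircase_search(test, up0=up0, cap=cap, rounds=rounds,
                           start=start, pretest_cap=pretest_cap)
    return replace(res, window=(onset, t1))


def ampa_analysis_window(model: CompartmentalModel, site,
                         onset: float = 10.0, dt: float = 0.025,
                         g_ref: float = 1.0, decay_frac: float = 0.63):
    """Analysis window for AMPA threshold searches.

    The window runs from stimulus onset to the time at which the AMPA
    depolarisation -- measured at the soma with the spike mechanism
    disabled -- has decayed back to ``decay_frac`` of its peak amplitude.
    It is measured once at a reference conductance ``g_ref`` (the shunt of
    the synapse itself makes the window only weakly conductance
    dependent).
    """
    t_stop = onset + 400.0
    cfg = SolverConfig(dt=dt, t_stop=t_stop, record=(("soma", 0.5),),
                       enable_ap_mechanism=False)
    sw = integrate(model, [ampa_synapse(site, g_ref, onset=onset)], cfg)
    v = sw.soma_v
    rest = v[int(np.searchsorted(sw.t, onset)) - 1]
    dep = v - rest
    ipk = int(np.argmax(dep))
    target = decay_frac * dep[ipk]
    after = dep[ipk:]
    below = np.flatnonzero(after <= target)
    if below.size == 0:
        return (onset, t_stop)
    return (onset, float(sw.t[ipk + below[0]]))


def ampa_threshold_search(model: CompartmentalModel, site,
                          co_stimuli=(), onset: float = 10.0,
                          window=None, dt: float = 0.025,
                          up0: float = 0.01, cap: float = 100.0,
                          rounds: int = 6, level: float = AP_DETECT_LEVEL,
                          start: float = 0.0,
                          pretest_cap: bool = False) -> ThresholdSearchResult:
    """Minimal peak AMPA conductance (nS) at ``site`` that fires the cell.

    ``co_stimuli`` can hold GABA synapse specs (or playback currents) that
    are co-applied in every sweep.  The analysis window defaults to the
    onset-to-63%-decay interval of the passive AMPA response (see
    :func:`ampa_analysis_window`).
    """
    if window is None:
        window = ampa_analysis_window(model, site, onset=onset, dt=dt)
    t0, t63 = window

    def stimuli_for(g):
        return [ampa_synapse(site, g, onset=onset), *co_stimuli]

    test = _sweep_test(model, stimuli_for, (t0, t63), dt, level)
    res = staircase_search(test, up0=up0, cap=cap, rounds=rounds,
                           down_ratio=0.33, up_ratio=0.1, start=start,
                           pretest_cap=pretest_cap)
    return replace(res, window=(t0, t63))


def rheobase_search(model: CompartmentalModel, duration_ms: float = 2000.0,
                    onset: float = 10.0, dt: float = 0.025,
                    up0_pA: float = 1.0, cap_pA: float = 1000.0,
                    rounds: int = 6,
                    level: float = AP_DETECT_LEVEL) -> ThresholdSearchResult:
    """Minimal amplitude (pA) of a somatic current step of ``duration_ms``
    that fires the cell; the same staircase scheme scaled to pA."""
    t1 = onset + duration_ms

    def stimuli_for(i_pA):
        return [CurrentStep(("soma", 0.5), amp_nA=i_pA * 1e-3,
                            t_on=onset, t_off=t1)]

    test = _sweep_test(model, stimuli_for, (onset, t1), dt, level)
    res = staircase_search(test, up0=up0_pA, cap=cap_pA, rounds=rounds,
                           pretest_cap=False)
    return replace(res, window=(onset, t1))


# ---------------------------------------------------------------------------
# AP features / fitting error

AP_FEATURES = ("e_thr_d3", "v_rise_max", "v_decay_max", "half_width",
               "e_peak")
_FEATURE_WEIGHTS = {"e_thr_d3": 10.0, "v_rise_max": 3.0, "v_decay_max": 1.0,
                    "half_width": 1.0, "e_peak": 1.0}


def extract_ap_features(sweep: Sweep, trace: int = 0) -> dict:
    """AP waveform features of the first AP in a sweep.

    Returns threshold voltage (d3 method, mV), maximal rise and decay slopes
    (V/s), half-width (ms, at half amplitude between threshold and peak) and
    peak voltage (mV).
    """
    v = sweep.v[trace]
    t = sweep.t
    peak = _ap_peak_index(v)
    thr = e_thr_d3(sweep, trace=trace)
    dvdt = np.gradient(v, sweep.dt)
    i_thr = int(np.searchsorted(t, thr.time))
    # decay: follow until V returns below threshold (or trace end)
    i_end = peak
    while i_end < len(v) - 1 and v[i_end] > thr.value:
        i_end += 1
    half = 0.5 * (v[peak] + thr.value)
    above = np.flatnonzero(v[i_thr:i_end + 1] >= half)
    width = (above[-1] - above[0]) * sweep.dt if above.size else math.nan
    return {
        "e_thr_d3": thr.value,
        "v_rise_max": float(dvdt[i_thr:peak + 1].max()),
        "v_decay_max": float(dvdt[peak:i_end + 1].min()),
        "half_width": float(width),
        "e_peak": float(v[peak]),
    }


def ap_feature_error(sim_features: dict, ref_features: dict) -> float:
    """Weighted sum of squared feature differences (sim - ref).

    Weights: threshold 10, max rise slope 3, max decay slope / half-width /
    peak voltage 1.  Zero iff all five features agree.
    """
    err = 0.0
    for name in AP_FEATURES:
        if name not in sim_features or name not in ref_features:
            raise KeyError(f"missing AP feature {name!r}")
        d = sim_features[name] - ref_features[name]
        err += _FEATURE_WEIGHTS[name] * d * d
    return err
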