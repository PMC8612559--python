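"""Morphologies, spatial discretisation and time integration.

A :class:`Morphology` is a tree of :class:`Section` objects (a spherical soma
plus cylinders).  :func:`compile_model` turns it into flat per-compartment
arrays (a :class:`CompartmentalModel`) that the numba kernel integrates with
a theta-implicit (Crank-Nicolson by default) scheme; the axial system is
solved directly on the tree, so arbitrary branching is supported at
tridiagonal cost.

Builders for the canonical geometries used throughout the package:

``build_ball``             single isopotential soma, d = 46.6 um
``build_ball_and_stick``   soma + 1 mm passive dendrite, 301 segments
``build_ball_stick_axon``  as above plus an axon whose initial segment is
                           the only excitable compartment
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._kernels import simulate_kernel
from .biophysics import (
    LeakParams, NaChannelParams, KChannelParams,
    default_channel_params, na_steady_state, k_steady_state,
)

__all__ = [
    "Section", "Morphology", "CompartmentalModel", "SolverConfig", "Sweep",
    "build_ball", "build_ball_and_stick", "build_ball_stick_axon",
    "compile_model", "integrate", "input_resistance",
    "DEFAULT_RA", "DEFAULT_CM", "DENDRITE_POSITIONS",
]

#: Axial resistivity (ohm*cm).  Calibrated together with the channel set so
#: that the ball-and-stick model reproduces the reported rheobase (see
#: docs/methods.md); config-exposed on every builder.
DEFAULT_RA = 208.0
#: Specific membrane capacitance (uF/cm2), the standard value.
DEFAULT_CM = 1.0

#: The 20 equidistant candidate synapse positions along the dendrite
#: (fraction of dendritic length, 0.05 ... 1.0).
DENDRITE_POSITIONS = tuple((i + 1) / 20 for i in range(20))


@dataclass
class Section:
    """One unbranched piece of membrane.

    ``kind`` is ``"soma"`` (isopotential sphere, area pi*d^2) or
    ``"cylinder"`` (length ``length`` um, ``nseg`` compartments).
    ``mechanisms`` maps mechanism name ("leak", "na", "k") to a density
    scale factor relative to the channel parameter set.
    """
    id: str
    kind: str
    diam: float                       # um
    length: float = 0.0               # um, cylinders only
    nseg: int = 1
    parent: Optional[str] = None
    parent_pos: float = 1.0
    mechanisms: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.diam <= 0:
            raise ValueError("diameter must be positive")
        if self.nseg < 1:
            raise ValueError("nseg must be >= 1")
        if self.kind not in ("soma", "cylinder"):
            raise ValueError(f"unknown section kind {self.kind!r}")
        if self.kind == "cylinder" and self.length <= 0:
            raise ValueError("cylinder needs a positive length")


@dataclass
class Morphology:
    sections: list
    ra: float = DEFAULT_RA            # ohm*cm
    cm: float = DEFAULT_CM            # uF/cm2
    na: NaChannelParams = None
    k: KChannelParams = None
    leak: LeakParams = None
    tonic_density: float = 0.0        # S/cm2, uniform over all membrane
    tonic_e: float = -50.5

    def __post_init__(self):
        if self.na is None or self.k is None or self.leak is None:
            na, k, leak = default_channel_params()
            if self.na is None:
                self.na = na
            if self.k is None:
                self.k = k
            if self.leak is None:
                self.leak = leak
        self._validate_tree()

    def _validate_tree(self):
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate section ids")
        roots = [s for s in self.sections if s.parent is None]
        if len(roots) != 1:
            raise ValueError("morphology must have exactly one root")
        known = set()
        for s in self.sections:
            if s.parent is not None and s.parent not in known:
                raise ValueError(
                    f"section {s.id!r} appears before its parent {s.parent!r} "
                    "or the tree has a cycle")
            known.add(s.id)

    def section(self, sec_id: str) -> Section:
        for s in self.sections:
            if s.id == sec_id:
                return s
        raise KeyError(sec_id)


class CompartmentalModel:
    """Flat compartment arrays compiled from a :class:`Morphology`."""

    def __init__(self, morph: Morphology):
        self.morph = morph
        na, k, leak = morph.na, morph.k, morph.leak
        parent, area, g_ax, owner = [], [], [], []
        offset = {}          # section id -> (first compartment, nseg)
        half_r = {}          # section id -> axial half-resistance per segment (ohm)
        for s in morph.sections:
            first = len(parent)
            offset[s.id] = (first, s.nseg)
            if s.kind == "soma":
                d_cm = s.diam * 1e-4
                parent.append(-1 if s.parent is None else
                              self._attach_index(offset, s))
                area.append(math.pi * d_cm * d_cm)
                g_ax.append(0.0)
                half_r[s.id] = 0.0
                owner.append(s.id)
            else:
                d_cm = s.diam * 1e-4
                dx_cm = s.length / s.nseg * 1e-4
                seg_area = math.pi * d_cm * dx_cm
                hr = 0.5 * dx_cm * morph.ra / (math.pi * d_cm * d_cm / 4.0)
                half_r[s.id] = hr
                for i in range(s.nseg):
                    if i == 0:
                        if s.parent is None:
                            parent.append(-1)
                            g_ax.append(0.0)
                        else:
                            p_idx = self._attach_index(offset, s)
                            parent.append(p_idx)
                            r = hr + half_r[s.parent]
                            g_ax.append(1e6 / r)
                    else:
                        parent.append(first + i - 1)
                        g_ax.append(1e6 / (2 * hr))
                    area.append(seg_area)
                    owner.append(s.id)

        n = len(parent)
        self.n = n
        self.parent = np.array(parent, dtype=np.int64)
        self.area = np.array(area)                     # cm2
        self.g_ax = np.array(g_ax)                     # uS
        self.cm_nf = morph.cm * self.area * 1e3        # uF/cm2*cm2 -> nF
        self._offset = offset
        self.owner = owner

        self.gpas_us = np.zeros(n)
        self.gna_us = np.zeros(n)
        self.gk_us = np.zeros(n)
        for i in range(n):
            sec = morph.section(owner[i])
            mech = sec.mechanisms
            a_us = self.area[i] * 1e6                  # S/cm2*cm2 -> uS factor
            if "leak" in mech:
                self.gpas_us[i] = leak.g_pas * mech["leak"] * a_us
            if "na" in mech:
                self.gna_us[i] = na.gna_max * mech["na"] * a_us
            if "k" in mech:
                self.gk_us[i] = k.gk_max * mech["k"] * a_us
        self.gton_us = morph.tonic_density * self.area * 1e6
        self.e_tonic = morph.tonic_e
        self.napar = na.as_array()
        self.kpar = k.as_array()
        self.e_pas = leak.e_pas
        self._rest_cache = {}

    @staticmethod
    def _attach_index(offset, s: Section):
        p_first, p_nseg = offset[s.parent]
        j = min(p_nseg - 1, int(s.parent_pos * p_nseg))
        return p_first + j

    def locate(self, site) -> int:
        """Compartment index for ``(section_id, x)`` with x in [0, 1]."""
        sec_id, x = site
        first, nseg = self._offset[sec_id]
        if not 0 <= x <= 1:
            raise ValueError("position must lie in [0, 1]")
        return first + min(nseg - 1, int(x * nseg))

    def path_distance(self, comp: int) -> float:
        """Path distance (um) from the root to a compartment centre."""
        dist = 0.0
        i = comp
        while self.parent[i] >= 0:
            sec = self.morph.section(self.owner[i])
            if sec.kind == "cylinder":
                dist += sec.length / sec.nseg
            i = self.parent[i]
        return dist

    def with_ap_mechanism(self, enabled: bool):
        """This model, or a cached passive view with Na/K conductances zeroed."""
        if enabled:
            return self
        view = getattr(self, "_passive_view", None)
        if view is None:
            import copy
            view = copy.copy(self)
            view.gna_us = np.zeros(self.n)
            view.gk_us = np.zeros(self.n)
            view._rest_cache = {}
            self._passive_view = view
        return view

    def initial_state(self, settle_ms: float = 500.0, dt: float = 0.025):
        """Resting state after ``settle_ms`` of stimulus-free integration.

        Started from E_pas with gates at their clamped-voltage fixed point;
        cached, so repeated sweeps reuse it.
        """
        key = (round(settle_ms, 6), round(dt, 9))
        if key in self._rest_cache:
            return self._rest_cache[key]
        na, k, leak = self.morph.na, self.morph.k, self.morph.leak
        v0 = np.full(self.n, self.e_pas)
        o, h = na_steady_state(self.e_pas, na)
        okk = k_steady_state(self.e_pas, k)
        ona = np.where(self.gna_us > 0, o, 0.0)
        hna = np.where(self.gna_us > 0, h, 0.0)
        ok = np.where(self.gk_us > 0, okk, 0.0)
        if settle_ms > 0:
            res = _run_kernel(self, dt, int(round(settle_ms / dt)), 0.5,
                              [], [], (-1, np.zeros(1)),
                              v0, ona, hna, ok,
                              rec_idx=np.array([0], dtype=np.int64),
                              rec_syn=-1, detect=None)
            state = (res[5], res[6], res[7], res[8])
        else:
            state = (v0, ona, hna, ok)
        self._rest_cache[key] = state
        return state


@dataclass
class SolverConfig:
    dt: float = 0.025                 # ms
    t_stop: float = 100.0             # ms
    record: Sequence = (("soma", 0.5),)
    enable_ap_mechanism: bool = True
    theta: float = 0.5                # 0.5 = Crank-Nicolson, 1.0 = implicit Euler
    settle_ms: float = 500.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class Sweep:
    t: np.ndarray                     # ms
    v: np.ndarray                     # mV, shape (n_sites, n_samples)
    sites: list
    dt: float
    isyn: Optional[np.ndarray] = None  # nA, recorded synaptic current
    meta: dict = field(default_factory=dict)

    @property
    def soma_v(self) -> np.ndarray:
        return self.v[0]


def _run_kernel(model, dt, nsteps, theta, syn_specs, current_specs, playback,
                v0, ona, hna, ok, rec_idx, rec_syn, detect,
                stop_at_spike=False):
    ns = len(syn_specs)
    syn_comp = np.empty(ns, dtype=np.int64)
    syn_tau1 = np.empty(ns)
    syn_tau2 = np.empty(ns)
    syn_e = np.empty(ns)
    events = []
    for j, spec in enumerate(syn_specs):
        syn_comp[j] = model.locate(spec.site)
        syn_tau1[j] = spec.tau1
        syn_tau2[j] = spec.tau2
        syn_e[j] = spec.e_rev
        for onset in np.atleast_1d(spec.onsets):
            # events land on the first integration step at or after onset
            step = max(1, int(math.ceil(onset / dt)))
            events.append((step, j, spec.g_max * 1e-3))   # nS -> uS
    events.sort()
    ne = len(events)
    ev_step = np.array([e[0] for e in events], dtype=np.int64)
    ev_syn = np.array([e[1] for e in events], dtype=np.int64)
    ev_w = np.array([e[2] for e in events])

    nc = len(current_specs)
    ic_comp = np.empty(nc, dtype=np.int64)
    ic_amp = np.empty(nc)
    ic_t0 = np.empty(nc, dtype=np.int64)
    ic_t1 = np.empty(nc, dtype=np.int64)
    for c, spec in enumerate(current_specs):
        ic_comp[c] = model.locate(spec.site)
        ic_amp[c] = spec.amp_nA
        ic_t0[c] = int(math.ceil(spec.t_on / dt))
        ic_t1[c] = int(math.floor(spec.t_off / dt))

    pb_comp, pb_curr = playback
    if pb_curr.shape[0] < nsteps + 1:
        pb_curr = np.concatenate([pb_curr,
                                  np.zeros(nsteps + 1 - pb_curr.shape[0])])

    if detect is None:
        d_comp, d_level, d_s0, d_s1 = -1, 0.0, 0, nsteps
    else:
        d_comp, d_level, d_s0, d_s1 = detect

    return simulate_kernel(
        dt, nsteps, theta,
        model.parent, model.cm_nf, model.gpas_us, model.e_pas, model.g_ax,
        model.gna_us, model.gk_us, model.napar, model.kpar,
        model.gton_us, model.e_tonic,
        syn_comp, syn_tau1, syn_tau2, syn_e,
        ev_syn, ev_step, ev_w,
        ic_comp, ic_amp, ic_t0, ic_t1,
        np.int64(pb_comp), pb_curr,
        v0, ona, hna, ok,
        rec_idx, np.int64(rec_syn),
        np.int64(d_comp), d_level, np.int64(d_s0), np.int64(d_s1),
        stop_at_spike,
    )


class DivergenceError(RuntimeError):
    """Raised when the membrane potential leaves the physical range."""


def integrate(model: CompartmentalModel, stimuli, cfg: SolverConfig,
              record_current_of: Optional[int] = None,
              detect=None, stop_at_spike=False) -> Sweep:
    """Integrate ``model`` under a list of stimuli.

    ``stimuli`` may mix Exp2 synapse specs, current steps and playback
    currents (see :mod:`gabathresh.synapses`).  ``detect`` is an optional
    ``(site, level_mV, t0_ms, t1_ms)`` spike monitor; when given, the sweep's
    ``meta`` carries ``ap`` / ``ap_time``; ``stop_at_spike`` additionally
    aborts the sweep at the first crossing (threshold searches only need the
    verdict).

    Raises :class:`DivergenceError` if |V| exceeds 500 mV anywhere.
    """
    from . import synapses as _syn

    m = model.with_ap_mechanism(cfg.enable_ap_mechanism)
    syn_specs, current_specs = [], []
    pb = (-1, np.zeros(1))
    for s in stimuli:
        if isinstance(s, _syn.Exp2SynapseSpec):
            syn_specs.append(s)
        elif isinstance(s, _syn.CurrentStep):
            current_specs.append(s)
        elif isinstance(s, _syn.PlaybackCurrent):
            if abs(s.dt - cfg.dt) > 1e-12:
                raise ValueError("playback sampling does not match solver dt")
            pb = (m.locate(s.site), np.asarray(s.current, dtype=float))
        else:
            raise TypeError(f"unknown stimulus {type(s).__name__}")

    nsteps = int(round(cfg.t_stop / cfg.dt))
    v0, ona, hna, ok = m.initial_state(cfg.settle_ms, cfg.dt)
    rec_idx = np.array([m.locate(site) for site in cfg.record],
                       dtype=np.int64)
    rec_syn = -1
    if record_current_of is not None:
        rec_syn = syn_specs.index(stimuli[record_current_of])

    if detect is not None:
        site, level, t0, t1 = detect
        detect_tuple = (m.locate(site), level,
                        int(math.ceil(t0 / cfg.dt)),
                        int(math.floor(t1 / cfg.dt)))
    else:
        detect_tuple = None

    (status, spike_step, last_step, out_v, out_isyn,
     *_rest, clip_count) = _run_kernel(
        m, cfg.dt, nsteps, cfg.theta, syn_specs, current_specs, pb,
        v0, ona, hna, ok, rec_idx, rec_syn, detect_tuple, stop_at_spike)

    if status != 0:
        raise DivergenceError(
            f"voltage diverged at t = {last_step * cfg.dt:.3f} ms")

    t = np.arange(nsteps + 1) * cfg.dt
    meta = {"clip_count": int(clip_count), "last_step": int(last_step)}
    if detect is not None:
        meta["ap"] = spike_step >= 0
        meta["ap_time"] = spike_step * cfg.dt if spike_step >= 0 else None
    if stop_at_spike and spike_step >= 0:
        out_v[:, last_step + 1:] = out_v[:, last_step:last_step + 1]
    return Sweep(t=t, v=out_v, sites=list(cfg.record), dt=cfg.dt,
                 isyn=out_isyn if rec_syn >= 0 else None, meta=meta)


# ---------------------------------------------------------------------------
# builders

def build_ball(soma_diam: float = 46.6, ra: float = DEFAULT_RA,
               cm: float = DEFAULT_CM, na=None, k=None, leak=None,
               mech_scale: float = 1.0) -> Morphology:
    """Single isopotential soma carrying leak + Na + K ("ball" model)."""
    soma = Section("soma", "soma", diam=soma_diam,
                   mechanisms={"leak": 1.0, "na": mech_scale, "k": mech_scale})
    return Morphology([soma], ra=ra, cm=cm, na=na, k=k, leak=leak)


def build_ball_and_stick(soma_diam: float = 46.6, dend_length: float = 1000.0,
                         dend_diam: float = 1.0, nseg: int = 301,
                         ra: float = DEFAULT_RA, cm: float = DEFAULT_CM,
                         na=None, k=None, leak=None) -> Morphology:
    """Active soma plus a passive linear dendrite (default 1 mm, 301 seg).

    Candidate synapse positions along the dendrite are exposed as
    :data:`DENDRITE_POSITIONS` (20 equidistant fractions of the length).
    """
    soma = Section("soma", "soma", diam=soma_diam,
                   mechanisms={"leak": 1.0, "na": 1.0, "k": 1.0})
    dend = Section("dend", "cylinder", diam=dend_diam, length=dend_length,
                   nseg=nseg, parent="soma", parent_pos=0.5,
                   mechanisms={"leak": 1.0})
    return Morphology([soma, dend], ra=ra, cm=cm, na=na, k=k, leak=leak)


def build_ball_stick_axon(soma_diam: float = 46.6, dend_length: float = 1000.0,
                          dend_diam: float = 1.0, nseg: int = 301,
                          ais_length: float = 10.0, axon_diam: float = 0.2,
                          n_axon_seg: int = 10, axon_seg_length: float = 10.0,
                          distal_scale: float = 0.9,
                          ra: float = DEFAULT_RA, cm: float = DEFAULT_CM,
                          na=None, k=None, leak=None) -> Morphology:
    """Ball-and-stick plus an axon; spike mechanism on the axon only.

    The initial segment ("ais") carries the full Na/K density; the remaining
    ``n_axon_seg`` segments carry ``distal_scale`` (default 0.9, i.e. peak
    conductances reduced by 10%).  Soma and dendrite are passive.
    """
    soma = Section("soma", "soma", diam=soma_diam,
                   mechanisms={"leak": 1.0})
    dend = Section("dend", "cylinder", diam=dend_diam, length=dend_length,
                   nseg=nseg, parent="soma", parent_pos=0.5,
                   mechanisms={"leak": 1.0})
    ais = Section("ais", "cylinder", diam=axon_diam, length=ais_length,
                  nseg=1, parent="soma", parent_pos=0.5,
                  mechanisms={"leak": 1.0, "na": 1.0, "k": 1.0})
    axon = Section("axon", "cylinder", diam=axon_diam,
                   length=n_axon_seg * axon_seg_length, nseg=n_axon_seg,
                   parent="ais", parent_pos=1.0,
                   mechanisms={"leak": 1.0, "na": distal_scale,
                               "k": distal_scale})
    return Morphology([soma, dend, ais, axon], ra=ra, cm=cm,
                      na=na, k=k, leak=leak)


#: Compile a morphology into flat per-compartment arrays.
compile_model = CompartmentalModel


def input_resistance(morph: Morphology, amp_pA: float = -1.0,
                     t_step: float = 3000.0, dt: float = 0.1) -> float:
    """Steady-state somatic input resistance (GOhm) from a small current step,
    measured with the spike mechanism disabled."""
    from .synapses import CurrentStep
    model = CompartmentalModel(morph)
    cfg = SolverConfig(dt=dt, t_stop=t_step, record=(("soma", 0.5),),
                       enable_ap_mechanism=False, settle_ms=200.0)
    step = CurrentStep(site=("soma", 0.5), amp_nA=amp_pA * 1e-3,
                       t_on=0.0, t_off=t_step)
    sw = integrate(model, [step], cfg)
    dv = sw.soma_v[-1] - morph.leak.e_pas
    return (dv * 1e-3) / (amp_pA * 1e-12) / 1e9
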