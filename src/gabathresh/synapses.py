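"""Synaptic and other stimuli: double-exponential conductance synapses,
tonic GABA conductance, current steps and current playback.

Phasic synapses use the peak-normalised double-exponential convention: the
conductance transient ``g(t) = g_max * N * (exp(-t/tau2) - exp(-t/tau1))``
is scaled so that its maximum equals ``g_max`` (reached at
``t_p = tau1*tau2/(tau2-tau1) * ln(tau2/tau1)`` after onset).  Default
kinetics: AMPA tau1 = 0.1 ms, tau2 = 11 ms, e_rev = -12 mV; GABA_A
tau1 = 0.1 ms, tau2 = 37 ms, e_rev = E_GABA (the free parameter of the
whole study).
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cable import (CompartmentalModel, Morphology, SolverConfig, Sweep,
                    integrate)

__all__ = [
    "Exp2SynapseSpec", "TonicConductanceSpec", "CurrentStep",
    "PlaybackCurrent", "ampa_synapse", "gaba_synapse",
    "exp2_conductance", "exp2_peak_time", "apply_tonic",
    "record_and_playback",
]

AMPA_TAU1, AMPA_TAU2, AMPA_EREV = 0.1, 11.0, -12.0
GABA_TAU1, GABA_TAU2 = 0.1, 37.0
#: Peak conductance (nS) of a physiological unitary GABAergic input.
GABA_G_PHYS = 0.789
#: Experimentally determined tonic GABA conductance density (S/cm2);
#: printed as 8.75 nS/cm2.
TONIC_G_PHYS = 8.75e-9


@dataclass
class Exp2SynapseSpec:
    """A conductance synapse at ``site = (section_id, x)``.

    ``g_max`` is the *peak* conductance in nS; ``onsets`` lists event times
    in ms (multiple events sum linearly).
    """
    site: tuple
    tau1: float
    tau2: float
    e_rev: float
    g_max: float
    onsets: Sequence[float] = (0.0,)

    def __post_init__(self):
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("require 0 < tau1 < tau2")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")


def ampa_synapse(site, g_max, onset=0.0, tau1=AMPA_TAU1, tau2=AMPA_TAU2,
                 e_rev=AMPA_EREV) -> Exp2SynapseSpec:
    return Exp2SynapseSpec(site, tau1, tau2, e_rev, g_max, (onset,))


def gaba_synapse(site, g_max, e_gaba, onset=0.0, tau1=GABA_TAU1,
                 tau2=GABA_TAU2) -> Exp2SynapseSpec:
    return Exp2SynapseSpec(site, tau1, tau2, e_gaba, g_max, (onset,))


@dataclass
class TonicConductanceSpec:
    """Uniform, persistently open GABA_A conductance over all membrane.

    ``density`` in S/cm2 (the physiological reference value is
    :data:`TONIC_G_PHYS` = 8.75e-9 S/cm2 = 8.75 nS/cm2).
    """
    density: float
    e_gaba: float

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be non-negative")


@dataclass
class CurrentStep:
    site: tuple
    amp_nA: float
    t_on: float
    t_off: float


@dataclass
class PlaybackCurrent:
    """A sampled current waveform (nA, one sample per solver step) injected
    at ``site`` in current-clamp fashion."""
    site: tuple
    current: np.ndarray
    dt: float


def exp2_peak_time(tau1: float, tau2: float) -> float:
    """Time of the conductance peak after onset (ms)."""
    return tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)


def exp2_conductance(t, spec: Exp2SynapseSpec) -> np.ndarray:
    """Closed-form conductance (nS) of an Exp2 synapse at times ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    tp = exp2_peak_time(spec.tau1, spec.tau2)
    factor = 1.0 / (math.exp(-tp / spec.tau2) - math.exp(-tp / spec.tau1))
    g = np.zeros_like(t)
    for onset in np.atleast_1d(spec.onsets):
        dt = t - onset
        mask = dt >= 0
        g[mask] += spec.g_max * factor * (
            np.exp(-dt[mask] / spec.tau2) - np.exp(-dt[mask] / spec.tau1))
    return g


def apply_tonic(morph: Morphology, spec: TonicConductanceSpec) -> Morphology:
    """Return a copy of ``morph`` with the tonic conductance installed.

    Every compartment gains an Ohmic conductance density toward
    ``spec.e_gaba``; ``density = 0`` returns an equivalent morphology."""
    m = copy.copy(morph)
    m.sections = morph.sections
    m.tonic_density = spec.density
    m.tonic_e = spec.e_gaba
    return m


def record_and_playback(model: CompartmentalModel, gaba_spec: Exp2SynapseSpec,
                        cfg: SolverConfig,
                        inject_site: Optional[tuple] = None):
    """Capture the synaptic current of a GABA conductance sweep and re-inject
    it as current.

    The source sweep is run with the spike mechanism disabled (the voltage
    trajectory then reflects the pure postsynaptic response); the recorded
    current ``i(t) = g(t) * (V - E_GABA)`` is negated and returned as a
    :class:`PlaybackCurrent` suitable for a sweep with the spike mechanism
    enabled, isolating the GABAergic depolarisation from the conductance
    shunt.

    Returns ``(playback, source_sweep)``.
    """
    src_cfg = replace(cfg, enable_ap_mechanism=False)
    sweep = integrate(model, [gaba_spec], src_cfg, record_current_of=0)
    inject = inject_site if inject_site is not None else gaba_spec.site
    playback = PlaybackCurrent(site=inject, current=-sweep.isyn, dt=cfg.dt)
    return playback, sweep
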