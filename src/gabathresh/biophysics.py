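"""Membrane mechanisms: passive leak, a cooperative 3-state Na+ channel and a
2-state delayed-rectifier K+ channel.

The Na+ channel follows the cooperative-gating scheme in which the rate
functions for opening are evaluated at an *effective* voltage
``v + cf * O_Na``: the more channels are open, the further the activation
curve is shifted leftward, producing the abrupt spike onset seen in
recordings that independent-gate Hodgkin-Huxley kinetics cannot reproduce.
States are fractions of channels: ``O`` open, ``H`` inactivated, closed
fraction implicit as ``1 - O - H``.  Both states additionally relax with a
voltage-independent rate ``1/tau_rel``.

All rates are in 1/ms, voltages in mV, conductance densities in S/cm2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from ._kernels import na_rates_kernel, k_rates_kernel, NA_LEN, K_LEN

__all__ = [
    "LeakParams",
    "NaChannelParams",
    "NaChannelState",
    "KChannelParams",
    "KChannelState",
    "na_rates",
    "na_derivatives",
    "k_derivative",
    "membrane_currents",
    "load_channel_params",
    "default_channel_params",
]


@dataclass(frozen=True)
class LeakParams:
    """Passive leak: conductance density g_pas (S/cm2) and reversal e_pas (mV)."""
    g_pas: float = 1.28e-5
    e_pas: float = -50.5

    def __post_init__(self):
        if not self.g_pas > 0:
            raise ValueError("g_pas must be positive")


@dataclass(frozen=True)
class NaChannelParams:
    gna_max: float          # peak conductance density, S/cm2
    e_na: float             # reversal potential, mV
    g_co: float             # closed->open rate gain
    g_oc: float             # open->closed rate gain
    g_ic: float             # gain of the inactivation-side alpha rate
    g_ci: float             # gain of the inactivation-side beta rate
    v_co: float             # activation midpoint, mV
    v_ic: float             # inactivation midpoint, mV
    k_co: float             # activation slope, mV
    k_ic: float             # inactivation slope, mV
    tau_act: float          # activation rate time constant, ms
    tau_ina: float          # inactivation rate time constant, ms
    tau_rel: float          # voltage-independent relaxation, ms
    cf: float               # cooperativity factor, mV per unit open fraction
    q10: float = 1.0

    def __post_init__(self):
        for name in ("tau_act", "tau_ina", "tau_rel"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.k_co == 0 or self.k_ic == 0:
            raise ValueError("slope factors must be nonzero")

    def as_array(self) -> np.ndarray:
        a = np.array(
            [self.g_co, self.g_oc, self.g_ic, self.g_ci,
             self.v_co, self.v_ic, self.k_co, self.k_ic,
             self.tau_act, self.tau_ina, self.tau_rel,
             self.cf, self.q10, self.e_na],
            dtype=np.float64,
        )
        assert a.shape[0] == NA_LEN
        return a


@dataclass
class NaChannelState:
    o: float = 0.0
    h: float = 0.0

    def validate(self):
        if self.o < 0 or self.h < 0 or self.o + self.h > 1 + 1e-12:
            raise ValueError("Na state outside the unit simplex")


@dataclass(frozen=True)
class KChannelParams:
    gk_max: float
    e_k: float
    g_co: float
    g_oc: float
    v_co: float
    v_ic: float
    k_co: float
    k_ic: float
    tau_act: float
    tau_ina: float
    tau_rel: float
    cf: float
    q10: float = 1.0

    def __post_init__(self):
        for name in ("tau_act", "tau_ina", "tau_rel"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.k_co == 0 or self.k_ic == 0:
            raise ValueError("slope factors must be nonzero")

    def as_array(self) -> np.ndarray:
        a = np.array(
            [self.g_co, self.g_oc, self.v_co, self.v_ic,
             self.k_co, self.k_ic, self.tau_act, self.tau_ina,
             self.tau_rel, self.cf, self.q10, self.e_k],
            dtype=np.float64,
        )
        assert a.shape[0] == K_LEN
        return a


@dataclass
class KChannelState:
    o: float = 0.0

    def validate(self):
        if not 0 <= self.o <= 1 + 1e-12:
            raise ValueError("O_K outside [0, 1]")


def _check_finite(v):
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")


def na_rates(v: float, p: NaChannelParams):
    """Return (alpha_A, beta_A, alpha_IC, beta_IC) in 1/ms at voltage ``v``.

    alpha_A rises and beta_A falls sigmoidally with voltage (midpoint
    ``v_co``, slope ``k_co``); the inactivation pair behaves analogously
    around ``v_ic``.
    """
    _check_finite(v)
    return na_rates_kernel(float(v), p.as_array())


def na_derivatives(v: float, s: NaChannelState, p: NaChannelParams):
    """Time derivatives (dO/dt, dH/dt) of the Na channel state.

    The open-fraction rates are evaluated at the effective voltage
    ``v + cf*O`` (cooperative shift); the inactivation rates at ``v``.
    """
    _check_finite(v)
    s.validate()
    arr = p.as_array()
    a_a, b_a, _, _ = na_rates_kernel(float(v) + p.cf * s.o, arr)
    _, _, a_ic, b_ic = na_rates_kernel(float(v), arr)
    do = a_a * (1.0 - s.o - s.h) - b_a * s.o - s.o / p.tau_rel
    dh = a_ic * (1.0 - s.h) - b_ic * s.h - s.h / p.tau_rel
    return do, dh


def k_derivative(v: float, s: KChannelState, p: KChannelParams):
    """dO_K/dt; both rates are evaluated at the effective voltage v + cf*O_K."""
    _check_finite(v)
    s.validate()
    a_k, b_k = k_rates_kernel(float(v) + p.cf * s.o, p.as_array())
    return a_k * (1.0 - s.o) - b_k * s.o - s.o / p.tau_rel


def membrane_currents(v, s_na: NaChannelState, s_k: KChannelState,
                      na: NaChannelParams, k: KChannelParams,
                      leak: LeakParams):
    """Ohmic current densities (I_Na, I_K, I_leak) in mA/cm2.

    Each current is ``g * (v - e)`` with g = gmax * open fraction, hence
    exactly zero at its reversal potential.
    """
    _check_finite(v)
    s_na.validate()
    s_k.validate()
    i_na = na.gna_max * s_na.o * (v - na.e_na)
    i_k = k.gk_max * s_k.o * (v - k.e_k)
    i_leak = leak.g_pas * (v - leak.e_pas)
    return i_na, i_k, i_leak


def na_steady_state(v: float, p: NaChannelParams, n_iter: int = 60):
    """Fixed point (O, H) of the Na state at clamped voltage ``v``.

    Because the open-fraction rates depend on O through the cooperative
    shift, the fixed point is found by damped iteration.
    """
    arr = p.as_array()
    _, _, a_ic, b_ic = na_rates_kernel(float(v), arr)
    h = a_ic / (a_ic + b_ic + 1.0 / p.tau_rel)
    o = 0.0
    for _ in range(n_iter):
        a_a, b_a, _, _ = na_rates_kernel(float(v) + p.cf * o, arr)
        o_new = a_a * (1.0 - h) / (a_a + b_a + 1.0 / p.tau_rel)
        o = 0.5 * o + 0.5 * min(o_new, 1.0 - h)
    return o, h


def k_steady_state(v: float, p: KChannelParams, n_iter: int = 60):
    """Fixed-point open fraction of the K channel at clamped voltage ``v``."""
    arr = p.as_array()
    o = 0.0
    for _ in range(n_iter):
        a_k, b_k = k_rates_kernel(float(v) + p.cf * o, arr)
        o = 0.5 * o + 0.5 * (a_k / (a_k + b_k + 1.0 / p.tau_rel))
    return o


_KEYMAP_NA = {f.strip(): f.strip() for f in (
    "gna_max e_na g_co g_oc g_ic g_ci v_co v_ic k_co k_ic "
    "tau_act tau_ina tau_rel cf q10".split())}


def load_channel_params(path_or_dict):
    """Load (NaChannelParams, KChannelParams, LeakParams) from a YAML file or
    an already-parsed mapping with top-level keys ``na``, ``k``, ``leak``."""
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    na = NaChannelParams(**doc["na"])
    k = KChannelParams(**doc["k"])
    leak = LeakParams(**doc.get("leak", {}))
    return na, k, leak


def default_channel_params():
    """The packaged default channel parameter set.

    The defaults were calibrated so that the single-compartment ("ball")
    model reproduces the reported excitability of immature CA3 pyramidal
    neurons: resting potential -50.5 mV, long-step rheobase about 4.25 pA,
    stationary spike threshold about -42.8 mV and a sharp spike onset.
    """
    ref = resources.files("gabathresh").joinpath("data/channels_default.yaml")
    with ref.open() as fh:
        return load_channel_params(yaml.safe_load(fh))


def save_channel_params(path, na: NaChannelParams, k: KChannelParams,
                        leak: LeakParams):
    doc = {"na": asdict(na), "k": asdict(k), "leak": asdict(leak)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
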