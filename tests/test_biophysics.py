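"""Channel kinetics: rate functions, state derivatives, currents."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabathresh.biophysics import (
    LeakParams, NaChannelParams, NaChannelState, KChannelParams,
    KChannelState, na_rates, na_derivatives, k_derivative,
    membrane_currents, default_channel_params, na_steady_state,
    k_steady_state, load_channel_params, save_channel_params,
)


@pytest.fixture(scope="module")
def params():
    na, k, leak = default_channel_params()
    return na, k, leak


@pytest.fixture(scope="module")
def na_nocf(params):
    """Na parameters with the cooperative shift switched off."""
    na, _, _ = params
    import dataclasses
    return dataclasses.replace(na, cf=0.0)


def test_na_rate_half_point_and_limits(params):
    na, _, _ = params
    a, b, *_ = na_rates(na.v_co, na)
    assert a == pytest.approx(na.q10 / na.tau_act * na.g_co / 2, rel=1e-12)
    assert b == pytest.approx(na.q10 / na.tau_act * na.g_oc / 2, rel=1e-12)
    a_lo, *_ = na_rates(na.v_co - 500.0, na)
    a_hi, *_ = na_rates(na.v_co + 500.0, na)
    assert a_lo == pytest.approx(0.0, abs=1e-15)
    assert a_hi == pytest.approx(na.q10 / na.tau_act * na.g_co, rel=1e-12)


def test_na_rates_monotone_and_bounded(params):
    na, _, _ = params
    vs = np.linspace(-120, 80, 400)
    rates = np.array([na_rates(v, na) for v in vs])
    a_a, b_a = rates[:, 0], rates[:, 1]
    assert np.all(np.diff(a_a) >= -1e-15)       # alpha_A non-decreasing
    assert np.all(np.diff(b_a) <= 1e-15)        # beta_A non-increasing
    bound = na.q10 * max(na.g_co, na.g_oc, na.g_ic, na.g_ci) \
        / min(na.tau_act, na.tau_ina)
    assert np.all(rates >= 0) and np.all(rates <= bound + 1e-12)


def test_alpha_beta_mirror_symmetry(params):
    """With equal gains, the beta form at V_co - x equals the alpha form at
    V_co + x (sigmoid mirror identity), checked on a voltage grid."""
    na, _, _ = params
    import dataclasses
    sym = dataclasses.replace(na, g_oc=na.g_co)
    for x in np.linspace(-30, 30, 13):
        a, _, _, _ = na_rates(sym.v_co + x, sym)
        _, b, _, _ = na_rates(sym.v_co - x, sym)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-15)


def test_na_rejects_nonfinite(params):
    na, _, _ = params
    with pytest.raises(ValueError):
        na_rates(float("nan"), na)
    with pytest.raises(ValueError):
        na_derivatives(float("inf"), NaChannelState(0.1, 0.1), na)


def test_no_closed_channels_no_opening(params):
    na, _, _ = params
    do, dh = na_derivatives(-40.0, NaChannelState(o=0.0, h=1.0), na)
    assert do == pytest.approx(0.0, abs=1e-15)


def test_fully_rested_state_opens(params):
    na, _, _ = params
    do, _ = na_derivatives(-30.0, NaChannelState(0.0, 0.0), na)
    a, *_ = na_rates(-30.0, na)
    assert do == pytest.approx(a, rel=1e-12)


def test_na_fixed_point_matches_rate_formula(na_nocf):
    """With cf = 0 the steady state is the closed-form alpha/beta balance."""
    na = na_nocf
    for v in (-50.0, -42.0, -30.0):
        o, h = na_steady_state(v, na)
        a_a, b_a, a_ic, b_ic = na_rates(v, na)
        h_exp = a_ic / (a_ic + b_ic + 1.0 / na.tau_rel)
        o_exp = a_a * (1 - h_exp) / (a_a + b_a + 1.0 / na.tau_rel)
        assert h == pytest.approx(h_exp, rel=1e-9)
        assert o == pytest.approx(o_exp, rel=1e-6, abs=1e-12)
        do, dh = na_derivatives(v, NaChannelState(o, h), na)
        assert do == pytest.approx(0.0, abs=1e-8)
        assert dh == pytest.approx(0.0, abs=1e-10)


def test_k_fixed_point_and_deactivation(params):
    _, k, _ = params
    import dataclasses
    k0 = dataclasses.replace(k, cf=0.0)
    o = k_steady_state(-35.0, k0)
    from gabathresh._kernels import k_rates_kernel
    a, b = k_rates_kernel(-35.0, k0.as_array())
    assert o == pytest.approx(a / (a + b + 1.0 / k0.tau_rel), rel=1e-9)
    # closed channel opens, fully open channel at hyperpolarisation closes
    assert k_derivative(-30.0, KChannelState(0.0), k) > 0
    assert k_derivative(-120.0, KChannelState(1.0), k) < 0


def test_derivatives_match_fine_euler(params):
    """A fine forward-Euler micro-integration of the published derivative
    forms agrees with the state the production integrator reaches."""
    na, k, leak = params
    import gabathresh as gt
    from gabathresh.synapses import CurrentStep
    model = gt.CompartmentalModel(gt.build_ball())
    v0, o0, h0, ok0 = model.initial_state(settle_ms=200.0)
    # clamp-style check: integrate the gate ODEs at fixed V with dt=1e-4
    v = -40.0
    o, h = float(o0[0]), float(h0[0])
    dt = 1e-4
    for _ in range(20000):   # 2 ms
        do, dh = na_derivatives(v, NaChannelState(o, h), na)
        o, h = o + dt * do, h + dt * dh
    # production update: exponential integrator steps of 0.025 ms
    from gabathresh._kernels import na_rates_kernel
    arr = na.as_array()
    o2, h2 = float(o0[0]), float(h0[0])
    for _ in range(80):
        a_a, b_a, _, _ = na_rates_kernel(v + na.cf * o2, arr)
        _, _, a_ic, b_ic = na_rates_kernel(v, arr)
        d_o = a_a + b_a + 1 / na.tau_rel
        oinf = a_a * (1 - h2) / d_o
        o2 = oinf + (o2 - oinf) * np.exp(-0.025 * d_o)
        d_h = a_ic + b_ic + 1 / na.tau_rel
        hinf = a_ic / d_h
        h2 = hinf + (h2 - hinf) * np.exp(-0.025 * d_h)
    assert o2 == pytest.approx(o, rel=5e-2, abs=1e-6)
    assert h2 == pytest.approx(h, rel=1e-3, abs=1e-8)


def test_membrane_currents_ohmic(params):
    na, k, leak = params
    s_na, s_k = NaChannelState(0.5, 0.1), KChannelState(0.3)
    i_na, i_k, i_leak = membrane_currents(na.e_na, s_na, s_k, na, k, leak)
    assert i_na == 0.0
    i_na, i_k, i_leak = membrane_currents(
        leak.e_pas, NaChannelState(0, 0), KChannelState(0), na, k, leak)
    assert i_na == i_leak == 0.0
    i_na, _, _ = membrane_currents(na.e_na + 10.0,
                                   NaChannelState(0.5, 0.0),
                                   KChannelState(0), na, k, leak)
    assert i_na == pytest.approx(na.gna_max * 0.5 * 10.0, rel=1e-12)


def test_state_validation(params):
    na, _, _ = params
    with pytest.raises(ValueError):
        na_derivatives(-50.0, NaChannelState(0.8, 0.5), na)
    with pytest.raises(ValueError):
        KChannelState(1.5).validate()


@settings(max_examples=25, deadline=None)
@given(v=st.floats(-90, 20), o=st.floats(0, 1), h=st.floats(0, 1))
def test_simplex_is_invariant_under_flow(v, o, h):
    """The vector field never points out of the unit simplex from its
    boundary faces (so trajectories started inside remain inside)."""
    na, _, _ = default_channel_params()
    if o + h > 1:
        s = o + h
        o, h = o / s, h / s
    do, dh = na_derivatives(v, NaChannelState(o, h), na)
    if o == 0:
        assert do >= 0
    if h == 0:
        assert dh >= 0


def test_params_yaml_round_trip(tmp_path, params):
    na, k, leak = params
    path = tmp_path / "chan.yaml"
    save_channel_params(path, na, k, leak)
    na2, k2, leak2 = load_channel_params(path)
    assert na2 == na and k2 == k and leak2 == leak


def test_param_invariants():
    with pytest.raises(ValueError):
        LeakParams(g_pas=0.0)
    with pytest.raises(ValueError):
        NaChannelParams(gna_max=1e-3, e_na=60, g_co=1, g_oc=1, g_ic=1,
                        g_ci=1, v_co=-20, v_ic=-35, k_co=0.0, k_ic=7,
                        tau_act=1, tau_ina=1, tau_rel=1, cf=0)
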