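"""Morphology building, discretisation and integrator accuracy."""
import math

import numpy as np
import pytest

import gabathresh as gt
from gabathresh.biophysics import LeakParams
from gabathresh.cable import DivergenceError, Section, Morphology
from gabathresh.synapses import CurrentStep


def passive_ball(d=46.6):
    m = gt.build_ball(soma_diam=d)
    m.sections[0].mechanisms = {"leak": 1.0}
    return m


def test_ball_geometry_and_rest():
    morph = gt.build_ball()
    model = gt.CompartmentalModel(morph)
    d_cm = 46.6e-4
    assert model.area[0] == pytest.approx(math.pi * d_cm ** 2, rel=1e-12)
    # passive configuration rests exactly at E_pas
    pm = gt.CompartmentalModel(passive_ball())
    sw = gt.integrate(pm, [], gt.SolverConfig(t_stop=200.0, settle_ms=0.0))
    assert np.allclose(sw.soma_v, -50.5, atol=1e-9)
    # with channels, rest stays within a fraction of a millivolt
    sw2 = gt.integrate(model, [], gt.SolverConfig(t_stop=200.0))
    assert abs(sw2.soma_v[-1] + 50.5) < 0.3


def test_passive_rc_charging_matches_closed_form():
    model = gt.CompartmentalModel(passive_ball())
    amp = 0.005
    cfg = gt.SolverConfig(t_stop=500.0, settle_ms=0.0)
    sw = gt.integrate(model, [CurrentStep(("soma", 0.5), amp, 0.0, 500.0)],
                      cfg)
    gl = 1.28e-5 * math.pi * (46.6e-4) ** 2 * 1e6      # uS
    c = math.pi * (46.6e-4) ** 2 * 1e3                 # nF
    tau = c / gl
    v_inf = -50.5 + amp / gl
    ana = v_inf + (-50.5 - v_inf) * np.exp(-sw.t / tau)
    assert np.abs(sw.soma_v - ana).max() < 1e-6 * abs(v_inf + 50.5)


def test_two_compartment_matches_matrix_exponential():
    """Passive two-compartment relaxation against expm of the exact system."""
    from scipy.linalg import expm
    soma = Section("soma", "soma", diam=20.0, mechanisms={"leak": 1.0})
    dend = Section("dend", "cylinder", diam=2.0, length=100.0, nseg=1,
                   parent="soma", mechanisms={"leak": 1.0})
    morph = Morphology([soma, dend], ra=150.0)
    model = gt.CompartmentalModel(morph)
    # initial condition: settle, then a brief current pulse on the dendrite
    cfg = gt.SolverConfig(dt=0.0025, t_stop=40.0, settle_ms=0.0,
                          record=(("soma", 0.5), ("dend", 0.5)))
    pulse = CurrentStep(("dend", 0.5), 0.05, 0.0, 10.0)
    sw = gt.integrate(model, [pulse], cfg)
    v0 = sw.v[:, int(10.0 / cfg.dt)]
    # free relaxation from v0 via the matrix exponential
    g_ax = model.g_ax[1]
    A = np.array([[-(model.gpas_us[0] + g_ax), g_ax],
                  [g_ax, -(model.gpas_us[1] + g_ax)]])
    A = A / model.cm_nf[:, None]
    b = model.gpas_us * (-50.5) / model.cm_nf
    ts = np.arange(0.0, 25.0, 2.5)
    v_eq = np.linalg.solve(A, -b)
    for t in ts:
        exact = v_eq + expm(A * t) @ (v0 - v_eq)
        got = sw.v[:, int((10.0 + t) / cfg.dt)]
        assert np.allclose(got, exact, atol=2e-4)


def test_steady_state_attenuation_matches_cable_theory():
    """Somatic current step: dendritic steady-state profile follows the
    sealed-end closed form cosh((L-x)/lambda)/cosh(L/lambda)."""
    morph = gt.build_ball_and_stick()
    for s in morph.sections:
        s.mechanisms = {"leak": 1.0}
    model = gt.CompartmentalModel(morph)
    sites = [("dend", x) for x in (0.1, 0.3, 0.5, 0.7, 0.9)]
    cfg = gt.SolverConfig(t_stop=3000.0, dt=0.1, settle_ms=0.0,
                          record=[("soma", 0.5)] + sites)
    sw = gt.integrate(model, [CurrentStep(("soma", 0.5), -0.002, 0.0,
                                          3000.0)], cfg)
    v_end = sw.v[:, -1] + 50.5
    r_m = 1.0 / 1.28e-5                                  # ohm*cm2
    lam = math.sqrt(r_m * 1e-4 / (4.0 * morph.ra))       # cm
    L = 0.1                                              # cm
    for i, (_, x) in enumerate(sites):
        # profile relative to the dendrite's proximal end
        expected = (math.cosh((L - x * L) / lam) / math.cosh(L / lam))
        seg_x = (int(x * 301) + 0.5) / 301
        expected = (math.cosh((L - seg_x * L) / lam) / math.cosh(L / lam))
        got = v_end[1 + i] / v_end[0]
        assert got == pytest.approx(expected, rel=2e-3)


def test_ball_and_stick_input_resistance():
    rin = gt.input_resistance(gt.build_ball_and_stick())
    assert 0.6 < rin < 1.3          # GOhm range of the recorded neurons


def test_axon_variant_geometry():
    morph = gt.build_ball_stick_axon()
    ais = morph.section("ais")
    axon = morph.section("axon")
    assert ais.length == 10.0 and ais.diam == 0.2
    assert axon.length == 100.0 and axon.nseg == 10
    assert axon.mechanisms["na"] == pytest.approx(0.9)
    assert "na" not in morph.section("soma").mechanisms
    model = gt.CompartmentalModel(morph)
    sw = gt.integrate(model, [], gt.SolverConfig(t_stop=100.0))
    assert abs(sw.soma_v[-1] + 50.5) < 0.3


def test_nseg_refinement_insensitivity():
    """Tripling the dendritic segment count changes the somatic response to
    a dendritic synapse by well under 1%."""
    from gabathresh.synapses import gaba_synapse
    responses = []
    for nseg in (301, 903):
        morph = gt.build_ball_and_stick(nseg=nseg)
        model = gt.CompartmentalModel(morph)
        cfg = gt.SolverConfig(t_stop=200.0, enable_ap_mechanism=False)
        sw = gt.integrate(model, [gaba_synapse(("dend", 0.5), 5.0, -40.0,
                                               onset=10.0)], cfg)
        responses.append(sw.soma_v - sw.soma_v[0])
    a, b = responses
    assert np.abs(a - b).max() / np.abs(b).max() < 0.01


def test_divergence_raises():
    model = gt.CompartmentalModel(gt.build_ball())
    huge = CurrentStep(("soma", 0.5), 500.0, 0.0, 100.0)
    with pytest.raises(DivergenceError):
        gt.integrate(model, [huge], gt.SolverConfig(t_stop=100.0))


def test_sweep_determinism(ball_model):
    cfg = gt.SolverConfig(t_stop=300.0)
    step = CurrentStep(("soma", 0.5), 0.006, 10.0, 310.0)
    sw1 = gt.integrate(ball_model, [step], cfg)
    sw2 = gt.integrate(ball_model, [step], cfg)
    assert np.array_equal(sw1.v, sw2.v)


def test_tree_validation():
    with pytest.raises(ValueError):
        Morphology([Section("a", "soma", diam=10.0),
                    Section("b", "soma", diam=10.0)])
    with pytest.raises(ValueError):
        Morphology([Section("a", "soma", diam=10.0),
                    Section("b", "cylinder", diam=1.0, length=10.0,
                            parent="missing")])
    with pytest.raises(ValueError):
        Section("bad", "cylinder", diam=1.0, length=0.0)
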