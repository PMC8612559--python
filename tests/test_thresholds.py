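"""AP detection, threshold estimators, staircase searches, feature error."""
import math

import numpy as np
import pytest

import gabathresh as gt
import gabathresh.thresholds as th
from gabathresh.cable import Sweep


def make_sweep(t, v):
    t = np.asarray(t, dtype=float)
    return Sweep(t=t, v=np.asarray(v, dtype=float)[None, :],
                 sites=[("soma", 0.5)], dt=float(t[1] - t[0]))


# ---------------------------------------------------------------------------
# detection

def test_detect_ap_on_synthetic_traces():
    t = np.arange(0, 100, 0.025)
    rest = np.full_like(t, -50.5)
    assert th.detect_ap(make_sweep(t, rest)) == (False, None)
    spike = rest.copy()
    spike[t >= 40.0] = 20.0
    ok, when = th.detect_ap(make_sweep(t, spike))
    assert ok and when == pytest.approx(40.0, abs=0.03)
    ok, _ = th.detect_ap(make_sweep(t, spike), window=(0.0, 30.0))
    assert not ok


def test_detection_level_insensitive_for_full_spikes(ball_model,
                                                     ball_rheobase):
    """Full-height APs give the same verdict at -10 and 0 mV detection."""
    from gabathresh.synapses import CurrentStep
    cfg = gt.SolverConfig(t_stop=1500.0)
    for factor in (1.2, 2.0):
        amp = ball_rheobase.threshold * factor * 1e-3
        sw = gt.integrate(ball_model,
                          [CurrentStep(("soma", 0.5), amp, 10.0, 1510.0)],
                          cfg)
        v1, _ = th.detect_ap(sw, level=0.0)
        v2, _ = th.detect_ap(sw, level=-10.0)
        assert v1 == v2 is True


# ---------------------------------------------------------------------------
# estimators on constructed traces

def test_dvdt_never_crossing_is_error():
    t = np.arange(0, 30, 0.025)
    ramp = -60.0 + 5.0 * t          # 5 V/s everywhere: no AP at all
    with pytest.raises(th.NoAPError):
        th.e_thr_dvdt(make_sweep(t, ramp))


def test_dvdt_on_piecewise_trace():
    """Slope jumps from 2 V/s to 100 V/s at V = -40: the 10 V/s crossing is
    detected at the slope change."""
    t = np.arange(0, 40, 0.025)
    v = np.where(t < 20.0, -80.0 + 2.0 * t, -40.0 + 100.0 * (t - 20.0))
    v = np.minimum(v, 30.0)
    est = th.e_thr_dvdt(make_sweep(t, v))
    assert est.value == pytest.approx(-40.0, abs=0.3)


def test_d3_peak_on_analytic_signal():
    """Signal with d3V/dt3 = known positive peak: sin wave rising into a
    'spike'; the first d3 maximum matches the analytic location."""
    dt = 0.025
    t = np.arange(0, 60, dt)
    # cubic-to-spike: v = a*(t-t0)^4 for t>t0 has monotone d3; use sin burst
    t0 = 30.0
    v = np.full_like(t, -60.0)
    m = t >= t0
    v[m] = -60.0 + 0.05 * (t[m] - t0) ** 4
    v = np.minimum(v, 30.0)
    est = th.e_thr_d3(make_sweep(t, v))
    # d3 of 0.05*x^4 grows linearly; its first local max is at the clip
    # point, so check it lies on the rising phase below the peak
    assert -60.0 < est.value <= 30.0


def test_is_exact_corner_of_two_lines():
    t = np.arange(0, 60, 0.025)
    v = np.where(t < 40.0, -50.0 + 0.1 * t, -46.0 + 150.0 * (t - 40.0))
    v = np.minimum(v, 40.0)
    est = th.e_thr_is(make_sweep(t, v))
    assert est.value == pytest.approx(-46.0, abs=0.25)


def test_estimator_ordering_on_model_ap(ball_ap_sweep, ball_rheobase):
    """Stationary < intersection < dynamic estimates, as the definitions
    imply (quasi-stationary thresholds are the most negative)."""
    st_v = ball_rheobase.st_peak_mv
    is_v = th.e_thr_is(ball_ap_sweep).value
    dvdt_v = th.e_thr_dvdt(ball_ap_sweep).value
    d3_v = th.e_thr_d3(ball_ap_sweep).value
    assert st_v <= is_v <= min(dvdt_v, d3_v)
    assert -46.0 < st_v < is_v < -38.0


def test_is_window_insensitivity(ball_ap_sweep):
    vals = [th.e_thr_is(ball_ap_sweep, baseline_ms=b).value
            for b in (15.0, 20.0, 25.0)]
    assert max(vals) - min(vals) < 0.5


# ---------------------------------------------------------------------------
# staircase search

def oracle_test(threshold):
    def test(x):
        return x >= threshold, (None if x >= threshold else -50.0)
    return test


def test_staircase_constructed_oracle():
    res = th.staircase_search(oracle_test(5.4321), up0=1.0, cap=100.0,
                              pretest_cap=False)
    assert res.threshold == pytest.approx(5.4321, abs=res.final_step)
    assert res.final_step == pytest.approx(1e-6, rel=1e-9)
    assert not res.no_threshold


def test_staircase_matches_brute_force_grid():
    """Search result equals exhaustive scanning at 10x finer resolution for
    20 random thresholds."""
    rng = np.random.default_rng(7)
    for threshold in rng.uniform(0.2, 30.0, size=20):
        res = th.staircase_search(oracle_test(threshold), up0=1.0,
                                  cap=100.0, pretest_cap=False)
        step = res.final_step / 10.0
        grid = np.arange(0.0, res.threshold + 5 * step, step)
        brute = grid[grid >= threshold][0]
        assert abs(res.threshold - brute) <= res.final_step + 1e-12
        # bracket invariant: spike at threshold, none one step below
        assert res.last_subthreshold < threshold <= res.threshold


def test_staircase_cap_reports_no_threshold():
    res = th.staircase_search(oracle_test(1e9), up0=1.0, cap=50.0,
                              pretest_cap=False)
    assert res.no_threshold and res.threshold is None


def test_staircase_warm_start():
    res = th.staircase_search(oracle_test(20.5), up0=1.0, cap=100.0,
                              start=18.0, pretest_cap=False)
    assert res.threshold == pytest.approx(20.5, abs=res.final_step)
    cold = th.staircase_search(oracle_test(20.5), up0=1.0, cap=100.0,
                               pretest_cap=False)
    assert res.sweep_count < cold.sweep_count


def test_gaba_search_sweep_count(ball_model):
    """Cold-start searches take on the order of 55 sweeps (soft check)."""
    res = th.gaba_threshold_search(ball_model, ("soma", 0.5), -42.5)
    assert res.threshold is not None
    assert 44 <= res.sweep_count <= 66


def test_ampa_search_sweep_count_warm(ball_model):
    """Warm-started AMPA searches take on the order of 63 sweeps."""
    res = th.ampa_threshold_search(ball_model, ("soma", 0.5))
    warm = th.ampa_threshold_search(ball_model, ("soma", 0.5),
                                    start=max(0.0, res.threshold - 0.35))
    assert warm.threshold == pytest.approx(res.threshold, abs=1e-4)
    assert 63 * 0.8 <= warm.sweep_count <= 63 * 1.2


def test_rheobase_duration_ordering(ball_model, ball_rheobase):
    short = th.rheobase_search(ball_model, duration_ms=200.0)
    assert short.threshold > ball_rheobase.threshold


def test_ampa_analysis_window(ball_model):
    onset, t63 = th.ampa_analysis_window(ball_model, ("soma", 0.5),
                                         onset=10.0)
    assert onset == 10.0
    assert 30.0 < t63 < 200.0
    # the window depends only weakly on the conductance used to measure it
    _, t63b = th.ampa_analysis_window(ball_model, ("soma", 0.5),
                                      onset=10.0, g_ref=5.0)
    assert t63b == pytest.approx(t63, abs=5.0)


# ---------------------------------------------------------------------------
# feature error

def test_ap_feature_error_weights():
    ref = {"e_thr_d3": -34.0, "v_rise_max": 80.0, "v_decay_max": -30.0,
           "half_width": 2.0, "e_peak": 10.0}
    assert th.ap_feature_error(ref, ref) == 0.0
    sim = dict(ref, e_thr_d3=-33.0)
    assert th.ap_feature_error(sim, ref) == pytest.approx(10.0)
    sim = dict(ref, v_rise_max=81.0)
    assert th.ap_feature_error(sim, ref) == pytest.approx(3.0)
    with pytest.raises(KeyError):
        th.ap_feature_error({"e_thr_d3": 0.0}, ref)


def test_ap_feature_error_reproducible(ball_ap_sweep):
    f1 = th.extract_ap_features(ball_ap_sweep)
    f2 = th.extract_ap_features(ball_ap_sweep)
    ref = {k: v * 1.01 for k, v in f1.items()}
    assert th.ap_feature_error(f1, ref) == th.ap_feature_error(f2, ref)
    assert th.ap_feature_error(f1, ref) > 0
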