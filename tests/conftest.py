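"""Shared fixtures.

Expensive simulation products (threshold searches, scans, spike-probability
curves) are computed once per session and reused by unit, property and
acceptance tests alike; problem sizes are scaled down where the assertions
concern directions and orderings rather than calibrated values.
"""
import numpy as np
import pytest

import gabathresh as gt
import gabathresh.thresholds as th
from gabathresh.synapses import CurrentStep


@pytest.fixture(scope="session")
def ball_model():
    return gt.CompartmentalModel(gt.build_ball())


@pytest.fixture(scope="session")
def bs_model():
    return gt.CompartmentalModel(gt.build_ball_and_stick())


@pytest.fixture(scope="session")
def ball_rheobase(ball_model):
    """Long-step rheobase of the ball model (4 s steps)."""
    return th.rheobase_search(ball_model, duration_ms=4000.0)


@pytest.fixture(scope="session")
def ball_ap_sweep(ball_model, ball_rheobase):
    cfg = gt.SolverConfig(t_stop=1200.0)
    step = CurrentStep(("soma", 0.5), ball_rheobase.threshold * 1.5e-3,
                       10.0, 1210.0)
    return gt.integrate(ball_model, [step], cfg)


@pytest.fixture(scope="session")
def ball_gaba_curve(ball_model):
    grid = gt.default_egaba_grid(-44.0, -36.0, 0.5)
    return gt.scan_g_gaba_thr(ball_model, ("soma", 0.5), grid)


@pytest.fixture(scope="session")
def costim_curves(ball_model):
    """Delta g_AMPA^Thr curves at strong and physiological g_GABA."""
    grid = gt.default_egaba_grid(-47.0, -41.0, 0.5)
    strong = gt.scan_delta_g_ampa(ball_model, ("soma", 0.5), ("soma", 0.5),
                                  3.95, grid)
    phys = gt.scan_delta_g_ampa(ball_model, ("soma", 0.5), ("soma", 0.5),
                                0.789, grid)
    return {"strong": strong, "phys": phys}


@pytest.fixture(scope="session")
def bs_rheobase(bs_model):
    return th.rheobase_search(bs_model, duration_ms=3000.0)


@pytest.fixture(scope="session")
def bs_gaba_curve(bs_model):
    grid = gt.default_egaba_grid(-42.5, -41.0, 0.5)
    return gt.scan_g_gaba_thr(bs_model, ("soma", 0.5), grid)


# ---------------------------------------------------------------------------
# stochastic fixtures (scaled-down synthetic morphology)

N_SWEEPS = 99
N_SWEEPS_PLACEMENT = 300
G_GRIDS = {1.0: (0.4, 0.6, 0.8, 1.0), 20.0: (0.05, 0.1, 0.15, 0.2)}
E_GRID = (-54.0, -48.0, -45.0, -43.5, -42.0)
E_GRID_PLACEMENT = (-45.0, -42.0)
E_GRID_TONIC = (-51.0, -46.5, -42.0)
TONIC_DENSITIES = (8.75e-7, 8.75e-6)
STOCH_SEED = 11


@pytest.fixture(scope="session")
def stoch_settings():
    return {"n_sweeps": N_SWEEPS, "g_grids": G_GRIDS, "e_grid": E_GRID,
            "seed": STOCH_SEED}


@pytest.fixture(scope="session")
def synth_model():
    spec = gt.SyntheticMorphologySpec(n_dendrites=6, nseg_log_mean=2.5,
                                      nseg_log_sigma=0.8, seed=1)
    morph = gt.generate_synthetic_morphology(spec)
    return gt.CompartmentalModel(morph), morph


@pytest.fixture(scope="session")
def pap_g_curves(synth_model):
    """p_AP(g_AMPA) at 1 Hz and 20 Hz, common random numbers."""
    model, _ = synth_model
    return {f: gt.p_ap_curve(model, G_GRIDS[f], "g_ampa", freq_hz=f,
                             n_sweeps=N_SWEEPS, seed=STOCH_SEED)
            for f in (1.0, 20.0)}


@pytest.fixture(scope="session")
def pap_egaba(synth_model, pap_g_curves):
    """E_GABA^Thr from p_AP crossings at both frequencies."""
    model, _ = synth_model
    out = {}
    for f in (1.0, 20.0):
        g50 = gt.g_ampa_50(pap_g_curves[f])
        est, curve, base = gt.egaba_thr_from_pap(
            model, E_GRID, g_ampa=g50, freq_hz=f, n_sweeps=N_SWEEPS,
            seed=STOCH_SEED, g_gaba=0.789)
        out[f] = {"g50": g50, "est": est, "curve": curve, "baseline": base}
    return out


@pytest.fixture(scope="session")
def pap_placement(synth_model, pap_egaba):
    """20 Hz E_GABA^Thr with GABA restricted proximally vs distally.

    The placement contrast is subtle, so this fixture runs 300 sweeps per
    point on a 2-point bracketing grid (common random numbers throughout).
    """
    model, _ = synth_model
    g50 = pap_egaba[20.0]["g50"]
    out = {"n_sweeps": N_SWEEPS_PLACEMENT}
    base = None
    for placement in ("proximal", "distal"):
        est, curve, base = gt.egaba_thr_from_pap(
            model, E_GRID_PLACEMENT, g_ampa=g50, freq_hz=20.0,
            n_sweeps=N_SWEEPS_PLACEMENT, seed=STOCH_SEED, g_gaba=0.789,
            gaba_placement=placement, baseline_p=base)
        out[placement] = {"est": est, "curve": curve}
    return out


@pytest.fixture(scope="session")
def pap_tonic(synth_model, pap_egaba):
    """20 Hz E_GABA^Thr under tonic GABA at two conductance densities."""
    model, morph = synth_model
    g50 = pap_egaba[20.0]["g50"]
    base = pap_egaba[20.0]["baseline"]
    out = {"densities": TONIC_DENSITIES}
    for dens in TONIC_DENSITIES:
        est, curve, _ = gt.egaba_thr_from_pap(
            model, E_GRID_TONIC, g_ampa=g50, freq_hz=20.0,
            n_sweeps=N_SWEEPS, seed=STOCH_SEED, g_gaba=dens,
            tonic_morph=morph, baseline_p=base)
        out[dens] = {"est": est, "curve": curve}
    return out
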