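"""Synthetic morphologies, random stimulation patterns and spike
probability under common random numbers."""
import numpy as np
import pytest
from scipy.stats import chisquare

import gabathresh as gt
from gabathresh.stochastic import (_dendrite_table, _region_mask,
                                   counts_for_frequency)


def test_morphology_determinism_and_bounds():
    spec = gt.SyntheticMorphologySpec(seed=123)
    m1 = gt.generate_synthetic_morphology(spec)
    m2 = gt.generate_synthetic_morphology(spec)
    sig = lambda m: [(s.id, s.kind, s.nseg, s.length, s.parent)
                     for s in m.sections]
    assert sig(m1) == sig(m2)
    assert len(m1.sections) - 1 == 56
    lo, hi = spec.nseg_range
    assert all(lo <= s.nseg <= hi for s in m1.sections[1:])
    assert m1.sections[0].diam == 15.0


def test_zero_dendrites_reduces_to_ball():
    spec = gt.SyntheticMorphologySpec(n_dendrites=0, seed=0)
    m = gt.generate_synthetic_morphology(spec)
    assert len(m.sections) == 1 and m.sections[0].kind == "soma"


def test_swc_bytes_deterministic(tmp_path):
    from gabathresh.io import write_swc
    spec = gt.SyntheticMorphologySpec(n_dendrites=10, seed=9)
    p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
    write_swc(gt.generate_synthetic_morphology(spec), p1)
    write_swc(gt.generate_synthetic_morphology(spec), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_pattern_determinism_and_window(synth_model):
    model, _ = synth_model
    p1 = gt.draw_pattern(model, 20, 10, 2000.0, seed=(5, 0))
    p2 = gt.draw_pattern(model, 20, 10, 2000.0, seed=(5, 0))
    assert p1.ampa == p2.ampa and p1.gaba == p2.gaba
    assert all(0 <= t <= 2000.0 for _, t in p1.ampa + p1.gaba)
    assert len(p1.ampa) == 20 and len(p1.gaba) == 10


def test_frequency_count_mapping():
    assert [counts_for_frequency(f) for f in (1.0, 5.0, 10.0, 20.0)] \
        == [2, 10, 20, 40]


def test_placement_partition(synth_model):
    model, _ = synth_model
    sites, lengths, dists = _dendrite_table(model)
    prox = _region_mask(lengths, dists, "proximal")
    dist = _region_mask(lengths, dists, "distal")
    assert not np.any(prox & dist)
    assert np.all(prox | dist)
    assert prox.any() and dist.any()


def test_uniform_per_length_placement(synth_model):
    """Empirical site density is uniform per unit dendritic length
    (chi-square over compartments at n = 1e5)."""
    model, _ = synth_model
    sites, lengths, _ = _dendrite_table(model)
    n = 100_000
    pat = gt.draw_pattern(model, n, 0, 2000.0, seed=2)
    idx = {s: i for i, s in enumerate(sites)}
    counts = np.zeros(len(sites))
    for site, _ in pat.ampa:
        counts[idx[site]] += 1
    expected = n * lengths / lengths.sum()
    stat, p = chisquare(counts, expected)
    assert p > 0.01


def test_p_ap_zero_without_input(synth_model):
    model, _ = synth_model
    p, se, raster = gt.estimate_p_ap(model, g_ampa=0.0, freq_hz=10.0,
                                     n_sweeps=10, seed=1)
    assert p == 0.0 and all(r is None for r in raster)


def test_p_ap_monotone_in_g_ampa(pap_g_curves):
    """With common random numbers p_AP rises with g_AMPA (within 2 SE)."""
    for f, curve in pap_g_curves.items():
        p = curve.p_ap
        se = curve.se
        for i in range(len(p) - 1):
            assert p[i + 1] >= p[i] - 2 * (se[i] + se[i + 1])
        assert p[-1] > p[0]


def test_g_ampa_50_brackets_and_interpolates(pap_g_curves):
    for f, curve in pap_g_curves.items():
        g50 = gt.g_ampa_50(curve)
        assert curve.grid[0] <= g50 <= curve.grid[-1]
    # exact grid hit returns the grid value
    from gabathresh.stochastic import PAPCurve
    c = PAPCurve(np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.5, 0.9]),
                 99, "g_ampa")
    assert gt.g_ampa_50(c) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        gt.g_ampa_50(PAPCurve(np.array([0.1, 0.2]), np.array([0.6, 0.9]),
                              99, "g_ampa"))


def test_lower_frequency_needs_larger_g50(pap_g_curves):
    g50_1 = gt.g_ampa_50(pap_g_curves[1.0])
    g50_20 = gt.g_ampa_50(pap_g_curves[20.0])
    assert g50_1 > g50_20


def test_g50_reproducible_with_common_seeds(synth_model, pap_g_curves,
                                            stoch_settings):
    model, _ = synth_model
    again = gt.p_ap_curve(model, stoch_settings["g_grids"][20.0], "g_ampa",
                          freq_hz=20.0,
                          n_sweeps=stoch_settings["n_sweeps"],
                          seed=stoch_settings["seed"])
    assert np.array_equal(again.p_ap, pap_g_curves[20.0].p_ap)
    assert gt.g_ampa_50(again) == gt.g_ampa_50(pap_g_curves[20.0])


def test_p_ap_monotone_in_e_gaba(pap_egaba):
    """Depolarizing the GABA reversal raises spike probability."""
    for f, d in pap_egaba.items():
        p = d["curve"].p_ap
        se = d["curve"].se
        for i in range(len(p) - 1):
            assert p[i + 1] >= p[i] - 2 * (se[i] + se[i + 1])


def test_gaba_inhibits_below_and_excites_above(pap_egaba):
    for f, d in pap_egaba.items():
        base = d["baseline"]
        curve = d["curve"]
        # strongly hyperpolarized reversal: at most baseline (within noise)
        assert curve.p_ap[0] <= base + 2 * curve.se[0]
        assert curve.p_ap[-1] > base          # depolarized: excitation
        assert curve.p_ap[-1] > curve.p_ap[0]


def test_egaba_thr_frequency_ordering(pap_egaba):
    """Higher input frequency pushes the excitation threshold closer to
    the AP threshold (less negative)."""
    e1 = pap_egaba[1.0]["est"].value
    e20 = pap_egaba[20.0]["est"].value
    assert e1 is not None and e20 is not None
    assert e20 > e1


def test_proximal_vs_distal_gaba(pap_placement):
    """Proximal GABA maintains inhibition up to a less negative E_GABA
    than distal GABA (common random numbers, 300 sweeps)."""
    ep = pap_placement["proximal"]["est"].value
    ed = pap_placement["distal"]["est"].value
    assert ep is not None and ed is not None
    assert ep >= ed


def test_tonic_threshold_increases_with_density(pap_tonic):
    lo_d, hi_d = pap_tonic["densities"]
    low = pap_tonic[lo_d]["est"].value
    high = pap_tonic[hi_d]["est"].value
    assert low is not None and high is not None
    assert high >= low
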