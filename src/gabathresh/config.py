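"""Run configuration, presets and the pipeline driver.

A :class:`RunConfig` fully determines a run (model geometry, channel
parameter file, scan definition, solver settings, seed); its SHA1 hash is
recorded in every output so tables can be traced back to the exact
configuration.  Presets bundle the canonical protocols:

``ball-excitability``   rheobase + the four AP-threshold estimators
``gaba-thr``            g_GABA^Thr(E_GABA) curve + reciprocal E_GABA^Thr
``ampa-shift``          Delta g_AMPA^Thr(E_GABA) + intersection E_GABA^Thr
``delay-scan``          E_GABA^Thr versus AMPA-vs-GABA delay
``tonic-scan``          E_GABA^Thr versus tonic conductance density
``random-network``      p_AP experiments on a synthetic morphology
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cable, egaba, stochastic, thresholds
from .biophysics import load_channel_params
from .cable import (CompartmentalModel, SolverConfig, build_ball,
                    build_ball_and_stick, build_ball_stick_axon)
from .io import write_summary, write_table

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "PRESETS"]

_BUILDERS = {
    "ball": build_ball,
    "ball_and_stick": build_ball_and_stick,
    "ball_stick_axon": build_ball_stick_axon,
}


@dataclass
class RunConfig:
    model: str = "ball"                      # builder name or "synthetic"
    geometry: dict = field(default_factory=dict)
    channels: Optional[str] = None           # YAML path; None = packaged set
    scan: str = "gaba-thr"
    scan_params: dict = field(default_factory=dict)
    dt: float = 0.025
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self):
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        doc = self.to_dict()
        doc.pop("out_dir", None)      # output location is not part of the run
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def build_morphology(self):
        kw = dict(self.geometry)
        if self.channels:
            na, k, leak = load_channel_params(self.channels)
            kw.update(na=na, k=k, leak=leak)
        if self.model == "synthetic":
            spec = stochastic.SyntheticMorphologySpec(
                seed=self.seed, **{k_: v for k_, v in kw.items()
                                   if k_ in stochastic.SyntheticMorphologySpec().__dict__})
            return stochastic.generate_synthetic_morphology(spec)
        if self.model not in _BUILDERS:
            raise ValueError(f"unknown model {self.model!r}")
        return _BUILDERS[self.model](**kw)


@dataclass
class ResultBundle:
    tables: dict                     # name -> DataFrame
    summary: dict
    config: RunConfig

    def write(self, out_dir):
        os.makedirs(out_dir, exist_ok=True)
        meta = {"config_hash": self.config.hash, "seed": self.config.seed}
        for name, df in self.tables.items():
            write_table(df, os.path.join(out_dir, f"{name}.csv"), meta=meta)
        summary = dict(self.summary)
        summary["config"] = self.config.to_dict()
        summary["config_hash"] = self.config.hash
        write_summary(summary, os.path.join(out_dir, "summary.json"))
        return out_dir


def _scan_gaba_thr(model, cfg):
    p = dict(site=("soma", 0.5), grid=None)
    p.update(cfg.scan_params)
    grid = (np.asarray(p["grid"], dtype=float) if p["grid"] is not None
            else egaba.default_egaba_grid(-44.0, -36.0, 0.5))
    site = tuple(p["site"])
    kw = {k: v for k, v in p.items() if k not in ("site", "grid")}
    curve = egaba.scan_g_gaba_thr(model, site, grid, **kw)
    try:
        est = egaba.egaba_thr_reciprocal(curve)
        value = est.value
    except ValueError:
        value = None
    df = pd.DataFrame({"e_gaba_mv": curve.e_gaba, "g_thr_ns": curve.g_thr,
                       "sweeps": curve.meta["sweep_counts"]})
    return {"g_gaba_thr": df}, {"egaba_thr_mv": value,
                                "method": "reciprocal-intercept"}


def _scan_ampa_shift(model, cfg):
    p = dict(ampa_site=("soma", 0.5), gaba_site=("soma", 0.5),
             g_gaba=3.95, grid=None, playback=False)
    p.update(cfg.scan_params)
    grid = (np.asarray(p["grid"], dtype=float) if p["grid"] is not None
            else egaba.default_egaba_grid(-47.0, -41.0, 0.5))
    curve = egaba.scan_delta_g_ampa(model, tuple(p["ampa_site"]),
                                    tuple(p["gaba_site"]), p["g_gaba"],
                                    grid, playback=p["playback"])
    est = egaba.egaba_thr_intersection(curve)
    df = pd.DataFrame({"e_gaba_mv": curve.e_gaba,
                       "g_ampa_thr_with_ns": curve.g_ampa_thr_with,
                       "g_ampa_thr_without_ns": curve.g_ampa_thr_without,
                       "delta_ns": curve.delta})
    return {"delta_g_ampa": df}, {"egaba_thr_mv": est.value,
                                  "method": "intersection",
                                  "g_gaba_ns": p["g_gaba"]}


def _scan_delay(model, cfg):
    p = dict(ampa_site=("soma", 0.5), gaba_site=("soma", 0.5), g_gaba=3.95,
             grid=None, delays=None)
    p.update(cfg.scan_params)
    grid = (np.asarray(p["grid"], dtype=float) if p["grid"] is not None
            else egaba.default_egaba_grid(-52.0, -42.0, 0.5))
    delays = (p["delays"] if p["delays"] is not None
              else list(np.arange(-150.0, 151.0, 10.0)))
    out = egaba.delay_scan(model, tuple(p["ampa_site"]),
                           tuple(p["gaba_site"]), p["g_gaba"], grid, delays)
    df = pd.DataFrame({"delay_ms": [d for d, _ in out],
                       "egaba_thr_mv": [e.value for _, e in out]})
    return {"delay_scan": df}, {"egaba_thr_by_delay":
                                {str(d): e.value for d, e in out}}


def _scan_tonic(model_morph, cfg):
    p = dict(densities=None, grid=None, ampa_site=("soma", 0.5))
    p.update(cfg.scan_params)
    densities = (p["densities"] if p["densities"] is not None
                 else [8.75e-9 * f for f in (0.01, 0.1, 1.0, 10.0, 100.0)])
    grid = (np.asarray(p["grid"], dtype=float) if p["grid"] is not None
            else egaba.default_egaba_grid(-50.0, -42.0, 0.5))
    out = egaba.tonic_scan(model_morph, densities, grid,
                           ampa_site=tuple(p["ampa_site"]))
    df = pd.DataFrame({"density_s_per_cm2": [d for d, _ in out],
                       "egaba_thr_mv": [e.value for _, e in out]})
    return {"tonic_scan": df}, {"egaba_thr_by_density":
                                {f"{d:.3e}": e.value for d, e in out}}


def _scan_excitability(model, cfg):
    p = dict(duration_ms=2000.0)
    p.update(cfg.scan_params)
    res = thresholds.rheobase_search(model, duration_ms=p["duration_ms"])
    from .synapses import CurrentStep
    sweep_cfg = SolverConfig(dt=cfg.dt, t_stop=1500.0)
    sw = cable.integrate(model, [CurrentStep(("soma", 0.5),
                                             res.threshold * 1.5e-3,
                                             10.0, 1510.0)], sweep_cfg)
    summary = {"rheobase_pa": res.threshold,
               "e_thr_st_mv": res.st_peak_mv,
               "sweeps": res.sweep_count}
    for fn, name in ((thresholds.e_thr_dvdt, "e_thr_dvdt_mv"),
                     (thresholds.e_thr_d3, "e_thr_d3_mv"),
                     (thresholds.e_thr_is, "e_thr_is_mv")):
        try:
            summary[name] = fn(sw).value
        except thresholds.NoAPError:
            summary[name] = None
    df = pd.DataFrame({"g_pa": [g for g, _ in res.history],
                       "spiked": [s for _, s in res.history]})
    return {"rheobase_history": df}, summary


def _scan_random(model, cfg):
    p = dict(freq_hz=10.0, n_sweeps=99, g_ampa_grid=None, e_gaba_grid=None,
             g_gaba=0.789)
    p.update(cfg.scan_params)
    g_grid = (p["g_ampa_grid"] if p["g_ampa_grid"] is not None
              else list(np.round(np.linspace(0.1, 1.5, 8), 4)))
    curve = stochastic.p_ap_curve(model, g_grid, "g_ampa",
                                  freq_hz=p["freq_hz"],
                                  n_sweeps=p["n_sweeps"], seed=cfg.seed)
    summary = {"freq_hz": p["freq_hz"], "n_sweeps": p["n_sweeps"]}
    try:
        g50 = stochastic.g_ampa_50(curve)
        summary["g_ampa_50_ns"] = g50
    except ValueError:
        g50 = None
        summary["g_ampa_50_ns"] = None
    tables = {"p_ap_vs_g_ampa": pd.DataFrame({"g_ampa_ns": curve.grid,
                                              "p_ap": curve.p_ap})}
    if g50 is not None and p["e_gaba_grid"] is not None:
        est, ecurve, base = stochastic.egaba_thr_from_pap(
            model, p["e_gaba_grid"], g_ampa=g50, freq_hz=p["freq_hz"],
            n_sweeps=p["n_sweeps"], seed=cfg.seed, g_gaba=p["g_gaba"])
        summary["egaba_thr_mv"] = est.value
        summary["baseline_p"] = base
        tables["p_ap_vs_e_gaba"] = pd.DataFrame(
            {"e_gaba_mv": ecurve.grid, "p_ap": ecurve.p_ap})
    return tables, summary


_SCANS = {
    "gaba-thr": _scan_gaba_thr,
    "ampa-shift": _scan_ampa_shift,
    "delay-scan": _scan_delay,
    "tonic-scan": _scan_tonic,
    "excitability": _scan_excitability,
    "random-network": _scan_random,
}

#: Ready-made configurations for the canonical protocols.
PRESETS = {
    "ball-excitability": RunConfig(model="ball", scan="excitability"),
    "gaba-thr-ball": RunConfig(model="ball", scan="gaba-thr"),
    "gaba-thr-ball-and-stick": RunConfig(model="ball_and_stick",
                                         scan="gaba-thr"),
    "ampa-shift-ball": RunConfig(model="ball", scan="ampa-shift"),
    "delay-scan-ball": RunConfig(model="ball", scan="delay-scan"),
    "tonic-scan-ball": RunConfig(model="ball", scan="tonic-scan"),
    "random-network": RunConfig(model="synthetic", scan="random-network",
                                geometry={"n_dendrites": 12}),
}


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the scan a config describes and return tables + summary.

    An empty scan ("none") returns a bundle with the config echo only.
    Results are written to ``config.out_dir`` when set.
    """
    if config.scan == "none":
        bundle = ResultBundle({}, {}, config)
    else:
        if config.scan not in _SCANS:
            raise ValueError(f"unknown scan {config.scan!r} "
                             f"(choose from {sorted(_SCANS)})")
        morph = config.build_morphology()
        if config.scan == "tonic-scan":
            tables, summary = _SCANS[config.scan](morph, config)
        else:
            model = CompartmentalModel(morph)
            tables, summary = _SCANS[config.scan](model, config)
        bundle = ResultBundle(tables, summary, config)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
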