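"""File I/O: SWC morphologies, CSV voltage traces and tables, HDF5 sweep
batches, JSON summaries."""
from __future__ import annotations

import json
import math
from typing import Optional

import numpy as np
import pandas as pd

from .cable import Morphology, Section, Sweep, DEFAULT_RA, DEFAULT_CM

__all__ = [
    "write_swc", "read_swc", "write_sweep_csv", "read_voltage_trace",
    "write_sweeps_hdf5", "read_sweeps_hdf5", "write_table", "write_summary",
]

_SWC_SOMA, _SWC_DEND, _SWC_AXON = 1, 3, 2
_KIND_TO_TYPE = {"soma": _SWC_SOMA, "cylinder": _SWC_DEND}


def write_swc(morph: Morphology, path):
    """Write a morphology as SWC (one sample per compartment).

    Sections are laid out deterministically in the plane (each section gets
    its own direction), so geometry on disk preserves lengths, diameters,
    segment counts and topology -- the features :func:`read_swc` restores.
    """
    rows = []
    next_id = 1
    sec_end = {}          # section id -> (swc id of distal sample, xyz)
    for s_idx, sec in enumerate(morph.sections):
        if sec.kind == "soma":
            rows.append((next_id, _SWC_SOMA, 0.0, 0.0, 0.0,
                         sec.diam / 2.0, -1))
            sec_end[sec.id] = (next_id, np.zeros(3))
            next_id += 1
            continue
        parent_id, origin = sec_end[sec.parent]
        angle = 2.0 * math.pi * (s_idx * 0.6180339887498949 % 1.0)
        direction = np.array([math.cos(angle), math.sin(angle), 0.0])
        step = sec.length / sec.nseg
        pid = parent_id
        for j in range(sec.nseg):
            xyz = origin + direction * step * (j + 1)
            rows.append((next_id, _SWC_DEND, xyz[0], xyz[1], xyz[2],
                         sec.diam / 2.0, pid))
            pid = next_id
            next_id += 1
        sec_end[sec.id] = (pid, origin + direction * sec.length)
    with open(path, "w") as fh:
        fh.write("# generated by gabathresh\n")
        for r in rows:
            fh.write("%d %d %.4f %.4f %.4f %.4f %d\n" % r)


def read_swc(path, ra: float = DEFAULT_RA, cm: float = DEFAULT_CM,
             na=None, k=None, leak=None) -> Morphology:
    """Read an SWC file into a Morphology.

    Unbranched runs of samples are collapsed into cylinder sections (one
    segment per sample); the first type-1 sample becomes the spherical
    soma.  Files with cycles or multiple roots are rejected.
    """
    samples = {}
    order = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC row at line {ln}")
            sid, typ = int(parts[0]), int(parts[1])
            x, y, z, r = map(float, parts[2:6])
            parent = int(parts[6])
            if sid in samples:
                raise ValueError(f"duplicate sample id at line {ln}")
            samples[sid] = (typ, np.array([x, y, z]), r, parent)
            order.append(sid)

    roots = [sid for sid in order if samples[sid][3] == -1]
    if len(roots) != 1:
        raise ValueError("SWC must have exactly one root sample")
    # cycle / orphan check by walking to the root
    for sid in order:
        seen = set()
        cur = sid
        while cur != -1:
            if cur in seen:
                raise ValueError("SWC contains a cycle")
            seen.add(cur)
            if cur not in samples:
                raise ValueError(f"SWC parent {cur} missing")
            cur = samples[cur][3]

    children = {sid: [] for sid in order}
    for sid in order:
        p = samples[sid][3]
        if p != -1:
            children[p].append(sid)

    root = roots[0]
    soma = Section("soma", "soma", diam=2.0 * samples[root][2],
                   mechanisms={"leak": 1.0, "na": 1.0, "k": 1.0})
    sections = [soma]
    counter = [0]

    def walk(start, parent_name):
        # collapse an unbranched chain beginning at `start`
        chain = [start]
        while len(children[chain[-1]]) == 1:
            chain.append(children[chain[-1]][0])
        pts = [samples[samples[start][3]][1]] + [samples[s][1]
                                                 for s in chain]
        length = float(sum(np.linalg.norm(pts[i + 1] - pts[i])
                           for i in range(len(pts) - 1)))
        radius = float(np.mean([samples[s][2] for s in chain]))
        name = f"dend{counter[0]:03d}"
        counter[0] += 1
        sections.append(Section(name, "cylinder", diam=2.0 * radius,
                                length=max(length, 1e-6), nseg=len(chain),
                                parent=parent_name, parent_pos=1.0,
                                mechanisms={"leak": 1.0}))
        for ch in children[chain[-1]]:
            walk(ch, name)

    for ch in children[root]:
        walk(ch, "soma")
    # soma is attached at its centre for first-order sections
    for sec in sections[1:]:
        if sec.parent == "soma":
            sec.parent_pos = 0.5
    return Morphology(sections, ra=ra, cm=cm, na=na, k=k, leak=leak)


def write_sweep_csv(sweep: Sweep, path):
    """Tidy CSV: time_ms plus one voltage column per recorded site."""
    cols = {"time_ms": sweep.t}
    for i, site in enumerate(sweep.sites):
        sec, x = site
        cols[f"v_{sec}_{x:g}_mv"] = sweep.v[i]
    if sweep.isyn is not None:
        cols["i_syn_na"] = sweep.isyn
    pd.DataFrame(cols).to_csv(path, index=False)


def read_voltage_trace(path, resample: bool = False,
                       dt: Optional[float] = None) -> Sweep:
    """Read a delimited time/voltage table into a Sweep.

    Expects a time column (ms) followed by >= 1 voltage columns (mV).
    Non-uniform sampling is rejected unless ``resample=True``, in which
    case the trace is linearly resampled at ``dt`` (default: median step).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("need a time column and at least one voltage column")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1:].to_numpy(dtype=float).T
    steps = np.diff(t)
    if len(steps) == 0 or np.any(steps <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(steps))
    uniform = np.allclose(steps, med, rtol=1e-6, atol=1e-9)
    if not uniform:
        if not resample:
            raise ValueError("non-uniform sampling; pass resample=True")
        dt = dt or med
        t_new = np.arange(t[0], t[-1] + dt / 2, dt)
        v = np.vstack([np.interp(t_new, t, vi) for vi in v])
        t = t_new
        med = dt
    sites = [(c, 0.0) for c in df.columns[1:]]
    return Sweep(t=t, v=v, sites=sites, dt=med)


def write_sweeps_hdf5(sweeps, path):
    """Store a batch of sweeps in one HDF5 file (one group per sweep)."""
    import h5py
    with h5py.File(path, "w") as f:
        for i, sw in enumerate(sweeps):
            g = f.create_group(f"sweep{i:05d}")
            g.create_dataset("t", data=sw.t)
            g.create_dataset("v", data=sw.v)
            g.attrs["dt"] = sw.dt
            g.attrs["sites"] = json.dumps([list(s) for s in sw.sites])


def read_sweeps_hdf5(path):
    import h5py
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            sites = [tuple(s) for s in json.loads(g.attrs["sites"])]
            out.append(Sweep(t=g["t"][...], v=g["v"][...], sites=sites,
                             dt=float(g.attrs["dt"])))
    return out


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None):
    """Write a tidy CSV table; provenance columns are added if given."""
    if meta:
        df = df.copy()
        for k, v in meta.items():
            df[k] = v
    df.to_csv(path, index=False)


def write_summary(summary: dict, path):
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
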