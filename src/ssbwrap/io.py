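"""File formats: trace CSV/YAML, HDF5 bundles and trajectories, PDB export,
JSON/CSV reports.

Every writer stamps a schema version, the package version, the seed and a
configuration hash into its output so any result can be traced back to the
exact inputs that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import ForceExtensionTrace
from .thermo import BindingEnergyResult

SCHEMA_VERSION = 1

TRACE_HEADER = ["time_s", "extension_nm", "force_pN"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta(seed=None, extra=None) -> dict:
    meta = {"schema_version": SCHEMA_VERSION, "package_version": __version__}
    if seed is not None:
        meta["seed"] = int(seed)
    if extra:
        meta.update(extra)
    return meta


# ---------------------------------------------------------------- trace CSV


def write_trace_csv(trace: ForceExtensionTrace, path, seed=None, extra_meta=None):
    """CSV with header time_s,extension_nm,force_pN plus a YAML sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "extension_nm": trace.extension,
            "force_pN": np.full(trace.time.size, trace.force),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    meta = _meta(
        seed,
        {
            "sampling_rate_hz": trace.sampling_rate,
            "condition": trace.condition_label,
            "force_pN": trace.force,
        },
    )
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_trace_csv(path) -> ForceExtensionTrace:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    missing = [c for c in TRACE_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    meta = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    time = df["time_s"].to_numpy()
    dt = np.diff(time)
    rate = meta.get("sampling_rate_hz") or (1.0 / dt[0] if dt.size else 1.0)
    return ForceExtensionTrace(
        time=time,
        extension=df["extension_nm"].to_numpy(),
        force=float(df["force_pN"].iloc[0]),
        sampling_rate=float(rate),
        condition_label=str(meta.get("condition", "")),
    )


# ------------------------------------------------------------- HDF5 bundles


def write_trace_bundle_h5(traces, path, seed=None, condition="", extra_meta=None):
    """Many traces in one HDF5 file (float64 columns, attrs = metadata)."""
    with h5py.File(path, "w") as h5:
        for k, v in _meta(seed, {"condition": condition}).items():
            h5.attrs[k] = v
        if extra_meta:
            for k, v in extra_meta.items():
                h5.attrs[k] = v
        for i, tr in enumerate(traces):
            g = h5.create_group(f"trace_{i:04d}")
            g.create_dataset("time_s", data=tr.time)
            g.create_dataset("extension_nm", data=tr.extension)
            g.attrs["force_pN"] = tr.force
            g.attrs["sampling_rate_hz"] = tr.sampling_rate
            g.attrs["condition"] = tr.condition_label


def read_trace_bundle_h5(path) -> list[ForceExtensionTrace]:
    out = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5):
            g = h5[name]
            out.append(
                ForceExtensionTrace(
                    time=g["time_s"][...],
                    extension=g["extension_nm"][...],
                    force=float(g.attrs["force_pN"]),
                    sampling_rate=float(g.attrs["sampling_rate_hz"]),
                    condition_label=str(g.attrs.get("condition", "")),
                )
            )
    return out


def write_trajectory_h5(traj, path, extra_meta=None):
    """Trajectory frames (float32) + energies (float64) + params snapshot."""
    from dataclasses import asdict

    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=traj.frames, dtype="f4")
        h5.create_dataset("term_energies", data=traj.term_energies, dtype="f8")
        h5.create_dataset("kinetic", data=traj.kinetic, dtype="f8")
        meta = _meta(traj.seed, {"stride": traj.stride, "dt": traj.dt,
                                 "diverged": traj.diverged})
        if extra_meta:
            meta.update(extra_meta)
        for k, v in meta.items():
            h5.attrs[k] = v
        for k, v in asdict(traj.params).items():
            if v is not None:
                h5.attrs[f"param_{k}"] = v


# ---------------------------------------------------------------- reports


def write_condition_report(result: BindingEnergyResult, path, seed=None, config=None):
    """JSON report per condition: salt, F_c +- SE, dG0 +- SE, mode data."""
    payload = {
        "meta": _meta(seed, {"config_hash": config_hash(config or {})}),
        "condition": result.condition_label,
        "salt_mM": result.salt_mM,
        "f_c_pN": result.f_c,
        "f_c_se_pN": result.f_c_se,
        "delta_g0_kT": result.delta_g0,
        "delta_g0_se_kT": result.delta_g0_se,
        "mode_count": result.mode_count,
        "mode_f_c_pN": list(map(float, result.mode_f_c)),
        "mode_delta_g0_kT": list(map(float, result.mode_delta_g0)),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def write_pmf_csv(pmf, path, seed=None):
    """PMF grid as CSV plus JSON metadata sidecar."""
    path = Path(path)
    nx = pmf.free_energy.shape[0]
    xc = 0.5 * (pmf.x_edges[:-1] + pmf.x_edges[1:])
    yc = 0.5 * (pmf.y_edges[:-1] + pmf.y_edges[1:])
    xi, yi = np.meshgrid(range(nx), range(pmf.free_energy.shape[1]), indexing="ij")
    df = pd.DataFrame(
        {
            "x_A": xc[xi.ravel()],
            "y_A": yc[yi.ravel()],
            "free_energy_kT": pmf.free_energy.ravel(),
            "count": pmf.counts.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    path.with_suffix(".json").write_text(
        json.dumps(_meta(seed, {"bin_width_A": float(np.diff(pmf.x_edges[:2])[0])}))
    )


def write_occupancy_csv(profile, path, seed=None):
    df = pd.DataFrame(
        {
            "occupancy": np.arange(profile.n_subunits + 1),
            "probability": profile.distribution,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------- PDB


def write_complex_pdb(toy, path, dna_coords=None):
    """Toy complex as a PDB file: CA pseudo-atoms + P/S/B DNA beads."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    prot = toy.protein_structure()
    dna_xyz = toy.dna_reference if dna_coords is None else dna_coords
    n_nt = len(toy.dna_sequence)
    names, resids = [], []
    for i in range(n_nt):
        if i > 0:
            names.append("P")
            resids.append(i + 1)
        names.extend(["S", "B"])
        resids.extend([i + 1, i + 1])
    dna = bst.AtomArray(len(names))
    dna.coord = np.asarray(dna_xyz, dtype=np.float32)
    dna.chain_id = np.array(["E"] * len(names))
    dna.res_id = np.array(resids)
    dna.res_name = np.array(["DT"] * len(names))
    dna.atom_name = np.array(names)
    dna.element = np.array(["P" if n == "P" else "C" for n in names])
    dna.hetero = np.zeros(len(names), dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(prot + dna)
    pdb.write(str(path))


# ---------------------------------------------------------------- topology


def write_topology_h5(topology, path, seed=None):
    """Lossless HDF5 dump of a bead topology."""
    from dataclasses import fields

    with h5py.File(path, "w") as h5:
        for k, v in _meta(seed).items():
            h5.attrs[k] = v
        for f in fields(topology):
            v = getattr(topology, f.name)
            if f.name == "resname":
                h5.create_dataset(f.name, data=np.array(v, dtype="S8"))
            else:
                h5.create_dataset(f.name, data=v)


def read_topology_h5(path):
    from dataclasses import fields

    from .cgtop import BeadTopology

    kw = {}
    with h5py.File(path, "r") as h5:
        for f in fields(BeadTopology):
            v = h5[f.name][...]
            if f.name == "resname":
                v = [s.decode() for s in v]
            kw[f.name] = v
    return BeadTopology(**kw)
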