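"""Text-format I/O: extended XYZ configurations, topology JSON, stress CSV.

Extended XYZ layout: per-frame header line with the atom count, a comment
line carrying ``Lattice=...`` (box lengths + xy tilt) and per-line
``species x y z [chain]``.  The sidecar topology JSON stores bonds, bond
kinds, angles (with per-angle parameters) and the species table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .engine import RawStressSamples
from .rheology import MaxwellFit, ModulusSpectrum, StressSeries
from .system import ParticleSystem, SimulationBox, Topology

PathLike = Union[str, Path]


def write_xyz(path: PathLike, system: ParticleSystem, append: bool = False) -> None:
    b = system.box
    lx, ly, lz = b.lengths
    comment = (
        f'Lattice="{lx:.10g} 0 0 {b.tilt_xy:.10g} {ly:.10g} 0 0 0 {lz:.10g}" '
        f"Properties=species:S:1:pos:R:3:chain:I:1 "
        f"periodic={int(b.periodic[0])}{int(b.periodic[1])}{int(b.periodic[2])}"
    )
    if b.has_walls:
        comment += f" walls={b.wall_lo:.10g},{b.wall_hi:.10g}"
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{system.n}\n{comment}\n")
        for i in range(system.n):
            x, y, z = system.positions[i]
            fh.write(
                f"T{system.type_id[i]} {x:.10g} {y:.10g} {z:.10g} {system.chain_id[i]}\n"
            )


def read_xyz(path: PathLike) -> ParticleSystem:
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline()
        rows = [fh.readline().split() for _ in range(n)]
    lat = comment.split('Lattice="')[1].split('"')[0].split()
    lx, ly, lz = float(lat[0]), float(lat[4]), float(lat[8])
    tilt = float(lat[3])
    per = np.array([True, True, True])
    wall_lo = wall_hi = None
    for tok in comment.split():
        if tok.startswith("periodic="):
            per = np.array([c == "1" for c in tok.split("=")[1]])
        if tok.startswith("walls="):
            wall_lo, wall_hi = (float(v) for v in tok.split("=")[1].split(","))
    box = SimulationBox(
        np.array([lx, ly, lz]), tilt, per, wall_lo=wall_lo, wall_hi=wall_hi
    )
    pos = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    types = np.array([int(r[0].lstrip("T")) for r in rows])
    chains = np.array([int(r[4]) for r in rows])
    return ParticleSystem(pos, np.zeros_like(pos), types, chains, box)


def write_topology(path: PathLike, topology: Topology) -> None:
    payload = {
        "bonds": topology.bonds.tolist(),
        "bond_kind": topology.bond_kind.tolist(),
        "angles": topology.angles.tolist(),
        "angle_k": topology.angle_k.tolist(),
        "angle_theta0": topology.angle_theta0.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_topology(path: PathLike) -> Topology:
    d = json.loads(Path(path).read_text())
    return Topology(
        np.array(d["bonds"]),
        np.array(d["bond_kind"]),
        np.array(d["angles"]),
        np.array(d["angle_k"]),
        np.array(d["angle_theta0"]),
    )


def stress_to_frame(raw: RawStressSamples) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": raw.times,
            "gamma_xy": raw.strain,
            "sxy": raw.sxy,
            "sxz": raw.sxz,
            "syz": raw.syz,
            "sxx": raw.sxx,
            "syy": raw.syy,
            "szz": raw.szz,
            "T_kin": raw.t_kin,
        }
    )


def write_stress_csv(path: PathLike, raw: RawStressSamples) -> None:
    df = stress_to_frame(raw)
    with open(path, "w") as fh:
        fh.write(f"# volume={raw.volume:.10g} temperature={raw.temperature:.10g}\n")
        df.to_csv(fh, index=False)


def read_stress_csv(path: PathLike) -> StressSeries:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    return StressSeries(
        times=df["t"].to_numpy(),
        sxy=df["sxy"].to_numpy(),
        sxz=df["sxz"].to_numpy(),
        syz=df["syz"].to_numpy(),
        nxy=(df["sxx"] - df["syy"]).to_numpy(),
        nxz=(df["sxx"] - df["szz"]).to_numpy(),
        nyz=(df["syy"] - df["szz"]).to_numpy(),
        volume=float(meta["volume"]),
        temperature=float(meta["temperature"]),
        strain=df["gamma_xy"].to_numpy() if df["gamma_xy"].abs().max() > 0 else None,
    )


def write_spectrum_csv(path: PathLike, spectrum: ModulusSpectrum) -> None:
    pd.DataFrame(
        {"omega": spectrum.omegas, "g_storage": spectrum.storage, "g_loss": spectrum.loss}
    ).to_csv(path, index=False)


def write_fit_json(path: PathLike, fit: MaxwellFit, extra: dict | None = None) -> None:
    payload = {
        "g_modes": fit.g_modes.tolist(),
        "tau_modes": fit.tau_modes.tolist(),
        "plateau": fit.plateau,
        "eta_star": fit.eta_star if np.isfinite(fit.eta_star) else "inf",
        "fit_residual": fit.fit_residual,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))
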