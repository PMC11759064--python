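"""End-to-end workflows mirroring the package's study designs.

Each workflow builds its systems, runs the engine, applies the rheology or
structural analysis, writes its artifacts plus a manifest (config snapshot,
seeds, output checksums).  Every workflow ships a ``reduced`` preset sized
for desk-scale runs; full-scale parameters are the same code paths with
bigger numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import __version__
from .aging import AgingConfig, corona_metrics, run_aging
from .builders import (
    ChainBlueprint,
    Composition,
    build_aging_box,
    build_melt,
    build_slab,
    build_solvated,
    crosslink_gel,
    default_forcefield,
    place_stickers,
)
from .config import validate_config
from .engine import run_nvt
from .io import write_fit_json, write_spectrum_csv
from .phase import coexistence_from_slab, fit_critical_point
from .rheology import (
    StressSeries,
    classify_response,
    crossover_frequencies,
    fit_maxwell,
    gk_complex_modulus,
)

WORKFLOW_NAMES = (
    "solvent_sweep",
    "rigidity_sweep",
    "length_compare",
    "gel_vs_melt",
    "sticker_sweep",
    "aging",
    "phase_diagram",
)


@dataclass
class RunManifest:
    workflow: str
    config: dict
    seeds: dict[str, int]
    version: str
    notes: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def verify(self) -> bool:
        return all(
            hashlib.sha256(Path(p).read_bytes()).hexdigest() == h
            for p, h in self.outputs.items()
        )

    def save(self, path: Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "workflow": self.workflow,
                    "config": self.config,
                    "seeds": self.seeds,
                    "version": self.version,
                    "notes": self.notes,
                    "outputs": self.outputs,
                },
                indent=1,
                default=str,
            )
        )


def _gk_spectrum(system, topo, ff, *, n_steps, dt, temp, seed, sample_stride=5,
                 equil_steps=10000, n_modes=None, t_min=0.5):
    """Equilibrate, sample stress, and return (series, G*(t), fit, spectrum)."""
    run_nvt(system, topo, ff, n_steps=equil_steps, dt=dt, temp=temp, seed=seed + 1)
    _, raw = run_nvt(
        system, topo, ff, n_steps=n_steps, dt=dt, temp=temp, seed=seed,
        sample_stride=sample_stride,
    )
    series = StressSeries.from_raw(raw)
    gk = gk_complex_modulus(series)
    fit = fit_maxwell(gk, n_modes=n_modes, t_min=t_min)
    w_lo = 0.01 / float(np.max(fit.tau_modes))
    w_hi = 10.0 / float(np.min(fit.tau_modes))
    spectrum = fit.spectrum(np.geomspace(w_lo, w_hi, 60))
    return raw, gk, fit, spectrum


def run_workflow(
    name: str,
    config: Optional[dict | str] = None,
    out_dir: str | Path = "runs",
    reduced: bool = True,
    seed: int = 0,
) -> RunManifest:
    """Dispatch one named workflow; returns the saved manifest."""
    if name not in WORKFLOW_NAMES:
        raise ValueError(f"unknown workflow {name!r}; choose from {WORKFLOW_NAMES}")
    cfg = validate_config(config)
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(name, cfg, {"base": seed}, __version__)
    _DISPATCH[name](cfg, out, manifest, reduced, seed)
    mpath = out / "manifest.json"
    manifest.save(mpath)
    return manifest


# --- individual workflows -------------------------------------------------


def _wf_solvent_sweep(cfg, out, manifest, reduced, seed):
    """Storage/loss spectra across polymer:solvent ratios 1:2, 1:1, 2:1, 1:0."""
    ratios = {"1:2": 2.0 / 3.0, "1:1": 0.5, "2:1": 1.0 / 3.0, "1:0": 0.0}
    n_chains = 25 if reduced else cfg["build"]["n_chains"]
    np_ = 20 if reduced else cfg["build"]["chain_length"]
    n_steps = 50000 if reduced else cfg["engine"]["n_steps"]
    summary = {}
    for label, phi_s in ratios.items():
        comp = Composition(
            n_chains=n_chains, chain_length=np_, phi_p=1 - phi_s, phi_s=phi_s,
            target_density=cfg["build"]["target_density"], seed=seed,
        )
        bp = ChainBlueprint(angle_k=10.0, angle_theta0=150.0)
        system, topo = build_solvated(comp, bp)
        ff = default_forcefield(blueprint=bp)
        raw, gk, fit, spec = _gk_spectrum(
            system, topo, ff, n_steps=n_steps, dt=cfg["engine"]["dt"],
            temp=cfg["engine"]["temperature"], seed=seed,
        )
        tag = label.replace(":", "-")
        write_spectrum_csv(out / f"spectrum_{tag}.csv", spec)
        manifest.register(out / f"spectrum_{tag}.csv")
        xs = crossover_frequencies(spec)
        summary[label] = {
            "eta_star": fit.eta_star,
            "crossovers": [x.omega for x in xs],
        }
    (out / "crossover_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.register(out / "crossover_summary.json")


def _wf_rigidity_sweep(cfg, out, manifest, reduced, seed):
    """Spectra and persistence lengths across backbone stiffness."""
    from .observables import mean_interior_angle, mean_rg_trajectory

    cases = {"flexible": None, "theta125": (10.0, 125.0), "theta150": (10.0, 150.0)}
    n_chains = 25 if reduced else cfg["build"]["n_chains"]
    np_ = 20 if reduced else cfg["build"]["chain_length"]
    n_steps = 50000 if reduced else cfg["engine"]["n_steps"]
    summary = {}
    for label, angle in cases.items():
        bp = (
            ChainBlueprint()
            if angle is None
            else ChainBlueprint(angle_k=angle[0], angle_theta0=angle[1])
        )
        comp = Composition(n_chains=n_chains, chain_length=np_, seed=seed,
                           target_density=cfg["build"]["target_density"])
        system, topo = build_melt(comp, bp)
        ff = default_forcefield(blueprint=bp)
        traj, raw = run_nvt(
            system, topo, ff, n_steps=n_steps, dt=cfg["engine"]["dt"],
            temp=cfg["engine"]["temperature"], seed=seed,
            sample_stride=5, frame_stride=max(n_steps // 50, 1),
        )
        series = StressSeries.from_raw(raw)
        fit = fit_maxwell(gk_complex_modulus(series), t_min=cfg["rheology"]["gk_t_min"])
        spec = fit.spectrum(np.geomspace(0.01 / fit.tau_modes.max(), 10 / fit.tau_modes.min(), 60))
        tag = label
        write_spectrum_csv(out / f"spectrum_{tag}.csv", spec)
        manifest.register(out / f"spectrum_{tag}.csv")
        summary[label] = {
            "mean_interior_angle_deg": mean_interior_angle(traj),
            "mean_rg": mean_rg_trajectory(traj),
            "eta_star": fit.eta_star,
        }
    (out / "rigidity_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.register(out / "rigidity_summary.json")


def _wf_length_compare(cfg, out, manifest, reduced, seed):
    """G*(t) decorrelation for short vs long chains at matched bead count."""
    lengths = (20, 50) if reduced else (20, 200)
    total_beads = 1000 if reduced else 4000
    n_steps = 50000 if reduced else cfg["engine"]["n_steps"]
    summary = {}
    for np_ in lengths:
        comp = Composition(n_chains=total_beads // np_, chain_length=np_, seed=seed,
                           target_density=cfg["build"]["target_density"])
        bp = ChainBlueprint(angle_k=10.0, angle_theta0=150.0)
        system, topo = build_melt(comp, bp)
        ff = default_forcefield(blueprint=bp)
        raw, gk, fit, spec = _gk_spectrum(
            system, topo, ff, n_steps=n_steps, dt=cfg["engine"]["dt"],
            temp=cfg["engine"]["temperature"], seed=seed,
        )
        write_spectrum_csv(out / f"spectrum_N{np_}.csv", spec)
        manifest.register(out / f"spectrum_N{np_}.csv")
        summary[f"N{np_}"] = {
            "eta_star": fit.eta_star,
            "tau_max": float(fit.tau_modes.max()),
        }
    (out / "length_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.register(out / "length_summary.json")


def _wf_gel_vs_melt(cfg, out, manifest, reduced, seed):
    """Kelvin-Voigt (cross-linked gel) vs Maxwell (melt) classification."""
    n_chains = 40 if reduced else cfg["build"]["n_chains"]
    np_ = 20 if reduced else cfg["build"]["chain_length"]
    n_steps = 40000 if reduced else cfg["engine"]["n_steps"]
    results = {}
    for label in ("melt", "gel"):
        comp = Composition(n_chains=n_chains, chain_length=np_, seed=seed,
                           target_density=cfg["build"]["target_density"])
        bp = ChainBlueprint()
        system, topo = build_melt(comp, bp)
        ff = default_forcefield(blueprint=bp)
        if label == "gel":
            topo = place_stickers(system, topo, interval=2)
            topo, report = crosslink_gel(system, topo, cutoff=1.8, seed=seed)
            results["gel_links"] = report.n_links
            results["gel_largest_component"] = report.largest_component_fraction
        _, raw = run_nvt(
            system, topo, ff, n_steps=n_steps, dt=cfg["engine"]["dt"],
            temp=cfg["engine"]["temperature"], seed=seed, sample_stride=5,
        )
        series = StressSeries.from_raw(raw)
        gk = gk_complex_modulus(series)
        fit = fit_maxwell(gk, t_min=cfg["rheology"]["gk_t_min"])
        spec = fit.spectrum(
            np.geomspace(0.001 / fit.tau_modes.max(), 10 / fit.tau_modes.min(), 80)
        )
        write_spectrum_csv(out / f"spectrum_{label}.csv", spec)
        manifest.register(out / f"spectrum_{label}.csv")
        write_fit_json(out / f"fit_{label}.json", fit)
        manifest.register(out / f"fit_{label}.json")
        results[label] = classify_response(spec).label
    (out / "classification.json").write_text(json.dumps(results, indent=1))
    manifest.register(out / "classification.json")
    return results


def _wf_sticker_sweep(cfg, out, manifest, reduced, seed):
    """Transient-sticker strength sweep: elastic modulus vs chi_ps."""
    chis = (1.0, 2.0) if reduced else (1.0, 2.0, 3.0)
    n_chains = 25 if reduced else cfg["build"]["n_chains"]
    np_ = 20 if reduced else cfg["build"]["chain_length"]
    n_steps = 40000 if reduced else cfg["engine"]["n_steps"]
    summary = {}
    for chi in chis:
        comp = Composition(
            n_chains=n_chains, chain_length=np_, sticker_interval=10,
            sticker_strength=chi, seed=seed,
            target_density=cfg["build"]["target_density"],
        )
        bp = ChainBlueprint(angle_k=10.0, angle_theta0=150.0)
        system, topo = build_melt(comp, bp)
        topo = place_stickers(system, topo, interval=10)
        ff = default_forcefield(chi_ps=chi, blueprint=bp, shifted_force=True)
        raw, gk, fit, spec = _gk_spectrum(
            system, topo, ff, n_steps=n_steps, dt=cfg["engine"]["dt"],
            temp=cfg["engine"]["temperature"], seed=seed,
        )
        write_spectrum_csv(out / f"spectrum_chi{chi:g}.csv", spec)
        manifest.register(out / f"spectrum_chi{chi:g}.csv")
        summary[f"chi{chi:g}"] = {"eta_star": fit.eta_star,
                                  "tau_max": float(fit.tau_modes.max())}
    (out / "sticker_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.register(out / "sticker_summary.json")


def _wf_aging(cfg, out, manifest, reduced, seed):
    """Nonequilibrium evaporation run with corona metrics."""
    import pandas as pd

    n_chains = 15 if reduced else 60
    np_ = 20 if reduced else 200
    duration = cfg["aging"]["duration"]
    comp = Composition(
        n_chains=n_chains, chain_length=np_, phi_p=1.0 / 3.0, phi_s=2.0 / 3.0,
        sticker_interval=10, seed=seed, target_density=0.7,
    )
    bp = ChainBlueprint(angle_k=10.0, angle_theta0=150.0)
    system, topo = build_aging_box(comp, bp)
    topo = place_stickers(system, topo, interval=10)
    ff = default_forcefield(chi_ps=cfg["build"]["sticker_strength"],
                            blueprint=bp, shifted_force=True)
    acfg = AgingConfig(
        evap_rate=cfg["aging"]["evap_rate"],
        boundary_slab=cfg["aging"]["boundary_slab"],
        shrink_mode=cfg["aging"]["shrink_mode"],
        duration=duration,
        record_every=cfg["aging"]["record_every"],
        n_bins=cfg["aging"]["n_bins"],
        seed=seed,
    )
    system, trace = run_aging(system, topo, ff, acfg)
    pd.DataFrame(trace.rho_poly).to_csv(out / "rho_poly.csv", index=False)
    pd.DataFrame(trace.rho_sol).to_csv(out / "rho_sol.csv", index=False)
    pd.DataFrame(
        {
            "t": trace.times,
            "L": trace.box_length,
            "n_evaporated": trace.n_evaporated,
            "n_solvent": trace.n_solvent,
        }
    ).to_csv(out / "aging_scalars.csv", index=False)
    for f in ("rho_poly.csv", "rho_sol.csv", "aging_scalars.csv"):
        manifest.register(out / f)
    cm = corona_metrics(trace, cfg["aging"]["shell_threshold"])
    (out / "corona.json").write_text(
        json.dumps(
            {
                "shell_onset_time": cm.shell_onset_time,
                "shell_density": cm.shell_density,
                "trapped_solvent_fraction": cm.trapped_solvent_fraction,
            },
            indent=1,
        )
    )
    manifest.register(out / "corona.json")


def _wf_phase_diagram(cfg, out, manifest, reduced, seed):
    """Slab coexistence across a temperature grid + rectilinear critical fit."""
    import pandas as pd

    temps = cfg["phase"]["temperatures"]
    if reduced:
        temps = temps[:3]
    n_chains = 40 if reduced else 100
    np_ = 10 if reduced else 50
    n_steps = 30000 if reduced else 200000
    points = []
    for t in temps:
        comp = Composition(n_chains=n_chains, chain_length=np_, seed=seed,
                           target_density=0.7)
        system, topo = build_slab(comp)
        ff = default_forcefield(attractive=True, shifted_force=True)
        traj, _ = run_nvt(
            system, topo, ff, n_steps=n_steps, dt=cfg["engine"]["dt"], temp=t,
            seed=seed, frame_stride=max(n_steps // 40, 1),
        )
        points.append(coexistence_from_slab(traj, t, n_bins=cfg["phase"]["n_bins"]))
    pd.DataFrame(
        {
            "T": [p.temperature for p in points],
            "rho_l": [p.rho_liquid for p in points],
            "rho_v": [p.rho_vapor for p in points],
        }
    ).to_csv(out / "coexistence.csv", index=False)
    manifest.register(out / "coexistence.csv")
    sub = [p for p in points if not p.supercritical]
    if len(sub) >= 3:
        fit = fit_critical_point(sub, beta=cfg["phase"]["beta"])
        (out / "critical_fit.json").write_text(
            json.dumps(
                {"Tc": fit.tc, "rho_c": fit.rho_c, "A": fit.amplitude,
                 "delta_rho0": fit.delta_rho0, "beta": fit.beta}, indent=1,
            )
        )
        manifest.register(out / "critical_fit.json")
    else:
        manifest.notes.append("fewer than 3 subcritical points; no critical fit")


_DISPATCH: dict[str, Callable] = {
    "solvent_sweep": _wf_solvent_sweep,
    "rigidity_sweep": _wf_rigidity_sweep,
    "length_compare": _wf_length_compare,
    "gel_vs_melt": _wf_gel_vs_melt,
    "sticker_sweep": _wf_sticker_sweep,
    "aging": _wf_aging,
    "phase_diagram": _wf_phase_diagram,
}
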