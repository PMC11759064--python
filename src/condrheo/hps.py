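"""Residue-level coarse-grained chains: hydropathy-scaled (HPS) model.

One bead per residue; pair attractions are scaled by the arithmetic mean of
the two residues' hydropathy weights lambda via the Ashbaugh-Hatch form
(:func:`condrheo.potentials.hps_pair`).  Electrostatics are deliberately
omitted — this model's defining approximation here — so the phase behavior
probed is hydropathy-driven only.

Explicit solvent is included as free beads with a weak attraction to
residues (encoded as a small effective lambda toward every residue type):
purely repulsive solvent demixes from the protein, so a minimal attraction
is required to keep the condensate homogeneously solvated.

A declared (length, energy, mass) scale bridges the residue parameter table
(angstroms, daltons) to the engine's reduced units, so the same integrator
drives both the sticker-spacer and the residue-level models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .builders import _grow_chain
from .potentials import hps_pair  # re-exported: scalar pair form
from .system import (
    BOND_HARMONIC,
    ForceFieldParams,
    PAIR_HPS,
    ParticleSystem,
    SimulationBox,
    Topology,
)

__all__ = [
    "ResidueParams",
    "HpsSystemSpec",
    "read_sequence",
    "load_residue_params",
    "hps_pair",
    "build_hps_condensate",
    "hps_forcefield",
]


class SequenceError(ValueError):
    pass


class ParameterTableError(ValueError):
    pass


@dataclass
class ResidueParams:
    """Per-residue-code parameters in engine (reduced) units.

    ``lam`` is the hydropathy weight in [0, 1.2]; ``sigma`` the bead
    diameter and ``mass`` the residue mass after reduction by the declared
    scales.
    """

    codes: list[str]
    lam: dict[str, float]
    sigma: dict[str, float]
    mass: dict[str, float]
    length_scale: float = 1.0
    mass_scale: float = 1.0

    def __post_init__(self) -> None:
        for c in self.codes:
            if not 0.0 <= self.lam[c] <= 1.2:
                raise ParameterTableError(
                    f"lambda for residue {c!r} is {self.lam[c]}, outside [0, 1.2]"
                )

    def validate_sequence(self, sequence: str) -> None:
        for i, c in enumerate(sequence):
            if c not in self.lam:
                raise SequenceError(
                    f"residue code {c!r} at position {i + 1} missing from the parameter table"
                )


@dataclass
class HpsSystemSpec:
    """What to build: sequence, chain count, solvent content and stiffness."""

    sequence: str
    n_chains: int = 1
    solvent_fraction: float = 0.0
    solvent_attraction: float = 0.2  # effective well depth (epsilon units)
    timestep_fs: float = 10.0
    angle_k: Optional[float] = None
    angle_theta0: float = 180.0
    target_density: float = 0.6
    rc_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError("sequence must be non-empty")
        if not 0.0 <= self.solvent_fraction < 1.0:
            raise ValueError("solvent_fraction must lie in [0, 1)")


def read_sequence(source: Union[str, Path, TextIO]) -> str:
    """First record of a FASTA file (path, handle, or literal FASTA text).

    Multi-record files use the first record and warn.
    """
    if isinstance(source, str):
        if not source.strip():
            raise SequenceError("no FASTA records found")
        if source.lstrip().startswith(">"):
            import io as _io

            source = _io.StringIO(source)
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise SequenceError("no FASTA records found")
    if len(records) > 1:
        warnings.warn(f"multiple FASTA records; using the first ({records[0].id})")
    return str(records[0].seq).upper()


def load_residue_params(
    source: Union[str, Path, TextIO, pd.DataFrame],
    length_scale: float = 6.5,
    mass_scale: float = 110.0,
) -> ResidueParams:
    """Residue parameter table from CSV columns (code, lam, sigma, mass).

    ``sigma`` is expected in angstroms and ``mass`` in daltons; they are
    divided by ``length_scale`` (A per reduced length) and ``mass_scale``
    (Da per reduced mass) on load.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"code", "lam", "sigma", "mass"}
    if not required.issubset(df.columns):
        raise ParameterTableError(
            f"parameter table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    codes = [str(c).strip().upper() for c in df["code"]]
    if len(set(codes)) != len(codes):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ParameterTableError(f"duplicate residue codes: {dup}")
    return ResidueParams(
        codes=codes,
        lam={c: float(v) for c, v in zip(codes, df["lam"])},
        sigma={c: float(v) / length_scale for c, v in zip(codes, df["sigma"])},
        mass={c: float(v) / mass_scale for c, v in zip(codes, df["mass"])},
        length_scale=length_scale,
        mass_scale=mass_scale,
    )


def hps_forcefield(
    spec: HpsSystemSpec, params: ResidueParams, sequence_types: list[str]
) -> ForceFieldParams:
    """Pair table for the residue types present plus the solvent species.

    Residue-residue pairs use mean lambda and mean sigma; solvent couples to
    residues through a small effective lambda equal to ``solvent_attraction``
    (zero makes it purely repulsive and the mixture demixes — flagged).
    """
    n = len(sequence_types) + 1  # + solvent
    eps = np.ones((n, n))
    sig = np.ones((n, n))
    lam = np.zeros((n, n))
    rc = np.zeros((n, n))
    sigmas = [params.sigma[c] for c in sequence_types] + [1.0]
    lams = [params.lam[c] for c in sequence_types] + [0.0]
    for i in range(n):
        for j in range(n):
            sig[i, j] = 0.5 * (sigmas[i] + sigmas[j])
            lam[i, j] = 0.5 * (lams[i] + lams[j])
    sol = n - 1
    lam[sol, :] = spec.solvent_attraction
    lam[:, sol] = spec.solvent_attraction
    lam[sol, sol] = 0.0
    rc[:, :] = spec.rc_factor * sig
    if spec.solvent_attraction == 0.0 and spec.solvent_fraction > 0:
        warnings.warn(
            "purely repulsive solvent leads to phase separation from the protein; "
            "a minimal attraction keeps the condensate homogeneous"
        )
    return ForceFieldParams(
        eps,
        sig,
        rc,
        pair_style=PAIR_HPS,
        hps_lambda=lam,
        harmonic_k=75.0,
        harmonic_r0=3.8 / params.length_scale,
        exclude_bonded=True,
    )


def build_hps_condensate(
    spec: HpsSystemSpec, params: ResidueParams
) -> tuple[ParticleSystem, Topology, ForceFieldParams]:
    """Residue-level chains with harmonic bonds plus weakly attractive solvent.

    Residue species ids follow the order of first appearance in the
    sequence; the solvent is the last species id.  Chains are grown as in
    the bead-spring builders and soft-pushed apart.
    """
    params.validate_sequence(spec.sequence)
    seq = spec.sequence
    res_types = sorted(set(seq), key=seq.index)
    type_of = {c: i for i, c in enumerate(res_types)}
    sol_type = len(res_types)
    np_per = len(seq)
    n_res = spec.n_chains * np_per
    n_sol = (
        int(round(spec.solvent_fraction / (1.0 - spec.solvent_fraction) * n_res))
        if spec.solvent_fraction > 0
        else 0
    )
    n_beads = n_res + n_sol
    volume = n_beads / spec.target_density
    edge = volume ** (1.0 / 3.0)
    rng = np.random.default_rng(spec.seed)
    box = SimulationBox(np.array([edge, edge, edge]))
    bond = 3.8 / params.length_scale
    theta0 = spec.angle_theta0 if spec.angle_k is not None else None
    chains = [
        _grow_chain(rng, np_per, rng.uniform(0, edge, 3), bond, theta0)
        for _ in range(spec.n_chains)
    ]
    sol = rng.uniform(0, edge, size=(n_sol, 3))
    pos = np.concatenate(chains + ([sol] if n_sol else [])) % edge
    type_id = np.concatenate(
        [
            np.tile([type_of[c] for c in seq], spec.n_chains),
            np.full(n_sol, sol_type),
        ]
    ).astype(np.int64)
    chain_id = np.concatenate(
        [np.repeat(np.arange(spec.n_chains), np_per), np.full(n_sol, -1)]
    ).astype(np.int64)
    system = ParticleSystem(pos, np.zeros((n_beads, 3)), type_id, chain_id, box)

    bonds, angles = [], []
    for c in range(spec.n_chains):
        base = c * np_per
        bonds += [(base + i, base + i + 1) for i in range(np_per - 1)]
        if spec.angle_k is not None:
            angles += [(base + i, base + i + 1, base + i + 2) for i in range(np_per - 2)]
    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    topology = Topology(
        bonds,
        np.full(len(bonds), BOND_HARMONIC),
        angles,
        np.full(len(angles), float(spec.angle_k or 0.0)),
        np.full(len(angles), math.radians(spec.angle_theta0)),
    )
    topology.validate(system.n)
    ff = hps_forcefield(spec, params, res_types)

    # relax with a temporary flexible blueprint-equivalent (soft push-off)
    from .builders import ChainBlueprint

    bp = ChainBlueprint(bead_diameter=float(np.mean([params.sigma[c] for c in seq])))
    _relax_hps(system, topology, ff, spec.seed)
    return system, topology, ff


def _relax_hps(system, topology, ff, seed):
    from .engine import make_chains_whole, soft_pushoff, thermalize_velocities

    soft_pushoff(system, topology, ff, seed=seed, n_stages=4, steps_per_stage=300)
    thermalize_velocities(system, 1.0, seed=seed + 1)
    make_chains_whole(system)


TOY_PARAM_TABLE = pd.DataFrame(
    {
        "code": list("ACDEFGHIKLMNPQRSTVWY"),
        "lam": [
            0.60, 0.68, 0.03, 0.00, 0.83, 0.57, 0.51, 0.97, 0.03, 0.98,
            0.84, 0.43, 0.68, 0.40, 0.00, 0.57, 0.47, 0.89, 0.99, 0.90,
        ],
        "sigma": [
            5.04, 5.48, 5.58, 5.92, 6.36, 4.50, 6.08, 6.18, 6.36, 6.18,
            6.18, 5.68, 5.56, 6.02, 6.56, 5.18, 5.62, 5.86, 6.78, 6.46,
        ],
        "mass": [
            71.08, 103.14, 115.09, 129.11, 147.18, 57.05, 137.14, 113.16,
            128.17, 113.16, 131.19, 114.10, 97.12, 128.13, 156.19, 87.08,
            101.10, 99.13, 186.21, 163.18,
        ],
    }
)
"""Synthetic toy parameter table (hydropathy weights of plausible magnitude,
standard residue sizes/masses) for tests and examples; real studies supply
their own reparametrized table as a CSV file."""

TOY_SEQUENCE = "GSYGQSSYSGYSQSTDTSGYGQSSYSSYGQ"
"""Synthetic 30-residue low-complexity toy sequence used in tests/examples."""
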