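"""Langevin dynamics driver: NVT runs, oscillatory shear, virial stress.

The heavy lifting happens in the numba kernels (:mod:`condrheo._kernels`);
this module owns the user-facing contracts: protocols, error reporting,
trajectory/stress bookkeeping, and the soft push-off relaxation used when
preparing dense initial configurations.

Shear is implemented as a deforming triclinic box with Lees-Edwards
remapping; the thermostat acts on peculiar velocities (the affine streaming
profile is removed before the stochastic kick and before the kinetic part of
the stress).  In the linear-response regime this produces the same moduli as
full SLLOD, which is asserted through the Green-Kubo vs oscillatory-shear
agreement test rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as K
from .system import ForceFieldParams, ParticleSystem, StressRecord, Topology
from .units import KB


class SimulationError(RuntimeError):
    pass


class BondOverstretchError(SimulationError):
    def __init__(self, bond_index: int):
        super().__init__(f"FENE bond {bond_index} reached its maximum extension R0")
        self.bond_index = bond_index


class BlowupError(SimulationError):
    def __init__(self, step: int):
        super().__init__(f"non-finite coordinates at step {step}")
        self.step = step


class ResolutionError(SimulationError):
    """The oscillation is under-resolved by the chosen time step."""


@dataclass
class ShearProtocol:
    """Sinusoidal strain gamma_xy(t) = gamma0 sin(omega t).

    ``gamma0`` should sit inside the linear viscoelastic window (checked
    separately by :func:`condrheo.rheology.linear_regime_check`); the default
    time step follows the 0.005-0.01 tau range used for these bead-spring
    models.
    """

    gamma0: float
    omega: float
    dt: float = 0.005
    n_cycles: int = 8
    thermostat_t: float = 1.0
    damping: float = 1.0
    discard_cycles: int = 1

    def __post_init__(self) -> None:
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be non-negative")
        if self.omega * self.dt > 0.1:
            raise ResolutionError(
                f"omega*dt = {self.omega * self.dt:.3g} rad/step exceeds 0.1; "
                "reduce dt or omega"
            )


@dataclass
class Trajectory:
    """Unwrapped frames captured at a fixed stride."""

    times: np.ndarray  # (F,)
    positions: np.ndarray  # (F, N, 3), unwrapped
    type_id: np.ndarray
    chain_id: np.ndarray
    box_lengths: np.ndarray  # (3,)
    tilts: np.ndarray  # (F,)

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class RawStressSamples:
    """Flat sample table straight from the kernel (one row per sample)."""

    times: np.ndarray
    strain: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    szz: np.ndarray
    sxy: np.ndarray
    sxz: np.ndarray
    syz: np.ndarray
    t_kin: np.ndarray
    pot_energy: np.ndarray
    volume: float
    temperature: float


def _pair_buffers(system: ParticleSystem, ff: ForceFieldParams, skin: float):
    n = system.n
    rho = n / system.box.volume
    cutoff = ff.rc_max + skin
    # x3 over the homogeneous estimate: attractive mixtures cluster, which
    # can multiply the local pair count during a run
    per = max(60.0, 3.0 * rho * (4.0 / 3.0) * math.pi * cutoff**3)
    cap = min(int(n * per / 2) + 4096, n * (n - 1) // 2 + 1)
    return np.empty(cap, dtype=np.int64), np.empty(cap, dtype=np.int64)


def _box_args(system: ParticleSystem):
    b = system.box
    has_walls = b.has_walls
    wall_lo = b.wall_lo if has_walls else 0.0
    wall_hi = b.wall_hi if has_walls else 0.0
    return (
        float(b.lengths[0]),
        float(b.lengths[1]),
        float(b.lengths[2]),
        float(b.tilt_xy),
        bool(b.periodic[0]),
        bool(b.periodic[1]),
        bool(b.periodic[2]),
        float(wall_lo),
        float(wall_hi),
        has_walls,
    )


def _ff_args(ff: ForceFieldParams):
    return (
        ff.lj_eps,
        ff.lj_sigma,
        ff.lj_rc,
        bool(ff.shifted_force),
        int(ff.pair_style),
        ff.hps_lambda,
        float(ff.soft_a),
    )


def _exclusion_keys(topology: Topology, ff: ForceFieldParams, n: int) -> np.ndarray:
    """Sorted i*n+j keys (i<j) of bonded pairs excluded from nonbonded sums."""
    if not ff.exclude_bonded or topology.n_bonds == 0:
        return np.zeros(0, dtype=np.int64)
    b = np.sort(topology.bonds, axis=1)
    return np.sort(b[:, 0].astype(np.int64) * n + b[:, 1])


def _topo_args(topology: Topology, ff: ForceFieldParams):
    return (
        topology.bonds,
        topology.bond_kind,
        float(ff.fene_k),
        float(ff.fene_r0),
        float(ff.harmonic_k),
        float(ff.harmonic_r0),
        topology.angles,
        topology.angle_k,
        topology.angle_theta0,
    )


def compute_forces_energy(
    system: ParticleSystem, topology: Topology, ff: ForceFieldParams, skin: float = 0.3
) -> tuple[np.ndarray, float, np.ndarray]:
    """Forces (N,3), potential energy, and virial (xx,yy,zz,xy,xz,yz)."""
    lx, ly, lz, tilt, px, py, pz, *_ = _box_args(system)
    pi, pj = _pair_buffers(system, ff, skin)
    xw = 2 if tilt != 0.0 else 1
    npairs = K.build_pairs_cells(
        system.positions, lx, ly, lz, tilt, px, py, pz, ff.rc_max, xw, pi, pj
    )
    if npairs < 0:
        raise SimulationError("pair buffer overflow")
    forces = np.zeros_like(system.positions)
    virial = np.zeros(6)
    pe, err = K.compute_forces(
        system.positions,
        system.type_id,
        pi,
        pj,
        npairs,
        _exclusion_keys(topology, ff, system.n),
        *_ff_args(ff),
        *_topo_args(topology, ff),
        lx,
        ly,
        lz,
        tilt,
        px,
        py,
        pz,
        forces,
        virial,
    )
    if err >= 0:
        raise BondOverstretchError(err)
    return forces, pe, virial


def compute_virial_stress(
    system: ParticleSystem, topology: Topology, ff: ForceFieldParams
) -> StressRecord:
    """Instantaneous kinetic + virial stress tensor, p* units.

    Sigma_ab = (sum_i m v_a v_b + sum_pairs r_a F_b) / V with diagonals in
    the pressure-tensor sign (ideal gas: Sigma_xx = +rho kB T) and
    off-diagonals negated to the material (tension-positive) convention.
    """
    _, _, virial = compute_forces_energy(system, topology, ff)
    v = system.velocities
    m = system.mass
    kin = np.array(
        [
            m * np.sum(v[:, 0] * v[:, 0]),
            m * np.sum(v[:, 1] * v[:, 1]),
            m * np.sum(v[:, 2] * v[:, 2]),
            m * np.sum(v[:, 0] * v[:, 1]),
            m * np.sum(v[:, 0] * v[:, 2]),
            m * np.sum(v[:, 1] * v[:, 2]),
        ]
    )
    s = (kin + virial) / system.box.volume
    return StressRecord(s[0], s[1], s[2], -s[3], -s[4], -s[5])


def kinetic_temperature(system: ParticleSystem) -> float:
    v = system.velocities
    return float(system.mass * np.sum(v * v) / (3.0 * system.n))


def _run_block(
    system: ParticleSystem,
    topology: Topology,
    ff: ForceFieldParams,
    n_steps: int,
    dt: float,
    temp: float,
    gamma_l: float,
    seed: int,
    gamma0: float = 0.0,
    omega: float = 0.0,
    t_start: float = 0.0,
    sample_stride: int = 0,
    skin: float = 0.3,
    buffers=None,
) -> tuple[np.ndarray, int]:
    """Run ``n_steps`` in place; returns (samples, n_samples)."""
    nsmp_cap = n_steps // sample_stride + 1 if sample_stride > 0 else 1
    out = np.zeros((nsmp_cap, 10))
    if buffers is None:
        buffers = _pair_buffers(system, ff, skin)
    pi, pj = buffers
    status, tilt, nsamp, bad = K.run_langevin(
        system.positions,
        system.velocities,
        system.images,
        system.type_id,
        float(system.mass),
        _exclusion_keys(topology, ff, system.n),
        *_topo_args(topology, ff),
        *_ff_args(ff),
        *_box_args(system),
        float(dt),
        int(n_steps),
        float(temp),
        float(gamma_l),
        int(seed) % 2**31,
        float(gamma0),
        float(omega),
        float(t_start),
        int(sample_stride),
        out,
        float(skin),
        pi,
        pj,
    )
    system.box.tilt_xy = tilt
    if status == K.STATUS_OVERSTRETCH:
        raise BondOverstretchError(bad)
    if status == K.STATUS_NONFINITE:
        raise BlowupError(bad)
    if status == K.STATUS_OVERFLOW:
        raise SimulationError("pair buffer overflow; increase skin margin")
    return out, nsamp


def langevin_step(
    system: ParticleSystem,
    topology: Topology,
    ff: ForceFieldParams,
    dt: float,
    temp: float,
    gamma_l: float,
    seed: int,
) -> ParticleSystem:
    """Advance one BAOAB Langevin step (in place; also returns the system).

    With ``gamma_l = 0`` the stochastic and friction parts vanish and the
    scheme reduces to velocity-Verlet.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _run_block(system, topology, ff, 1, dt, temp, gamma_l, seed)
    return system


def run_nvt(
    system: ParticleSystem,
    topology: Topology,
    ff: ForceFieldParams,
    n_steps: int,
    dt: float = 0.005,
    temp: float = 1.0,
    gamma_l: float = 1.0,
    seed: int = 0,
    sample_stride: int = 0,
    frame_stride: int = 0,
    t_start: float = 0.0,
    skin: float = 0.3,
) -> tuple[Optional[Trajectory], RawStressSamples]:
    """Equilibrium (unsheared) Langevin run with stress and frame sampling.

    The run is chunked so frames can be captured without leaving the jitted
    inner loop for every step; the RNG stream is reseeded per chunk from
    ``seed`` so a rerun with the same arguments is bit-identical.
    """
    chunk = frame_stride if frame_stride > 0 else n_steps
    rows = []
    frames_pos, frames_t, frames_tilt = [], [], []
    buffers = _pair_buffers(system, ff, skin)
    done = 0
    ci = 0
    while done < n_steps:
        todo = min(chunk, n_steps - done)
        out, nsamp = _run_block(
            system,
            topology,
            ff,
            todo,
            dt,
            temp,
            gamma_l,
            seed * 9973 + ci,
            t_start=t_start + done * dt,
            sample_stride=sample_stride,
            skin=skin,
            buffers=buffers,
        )
        if nsamp:
            rows.append(out[:nsamp])
        done += todo
        ci += 1
        if frame_stride > 0:
            frames_pos.append(system.unwrapped_positions())
            frames_t.append(t_start + done * dt)
            frames_tilt.append(system.box.tilt_xy)
    samples = (
        np.concatenate(rows, axis=0) if rows else np.zeros((0, 10))
    )
    raw = RawStressSamples(
        times=samples[:, 0],
        strain=samples[:, 1],
        sxx=samples[:, 2],
        syy=samples[:, 3],
        szz=samples[:, 4],
        sxy=samples[:, 5],
        sxz=samples[:, 6],
        syz=samples[:, 7],
        t_kin=samples[:, 8],
        pot_energy=samples[:, 9],
        volume=system.box.volume,
        temperature=temp,
    )
    traj = None
    if frame_stride > 0:
        traj = Trajectory(
            times=np.array(frames_t),
            positions=np.array(frames_pos),
            type_id=system.type_id.copy(),
            chain_id=system.chain_id.copy(),
            box_lengths=system.box.lengths.copy(),
            tilts=np.array(frames_tilt),
        )
    return traj, raw


def oscillatory_shear_run(
    system: ParticleSystem,
    topology: Topology,
    ff: ForceFieldParams,
    protocol: ShearProtocol,
    seed: int = 0,
    sample_stride: int = 10,
    frame_stride: int = 0,
    skin: float = 0.3,
) -> tuple[Optional[Trajectory], RawStressSamples]:
    """Oscillatory Lees-Edwards shear run recording Sigma_xy(t) and strain.

    The box tilt follows gamma(t)·Ly with an affine remap of particle
    positions each step; peculiar velocities are thermostatted.
    """
    if not system.box.periodic.all():
        raise ValueError("oscillatory shear requires a fully periodic box")
    period_steps = int(round(2.0 * math.pi / protocol.omega / protocol.dt))
    n_steps = period_steps * protocol.n_cycles
    chunk = frame_stride if frame_stride > 0 else n_steps
    rows = []
    frames_pos, frames_t, frames_tilt = [], [], []
    buffers = _pair_buffers(system, ff, skin)
    done = 0
    ci = 0
    while done < n_steps:
        todo = min(chunk, n_steps - done)
        out, nsamp = _run_block(
            system,
            topology,
            ff,
            todo,
            protocol.dt,
            protocol.thermostat_t,
            protocol.damping,
            seed * 9973 + ci,
            gamma0=protocol.gamma0,
            omega=protocol.omega,
            t_start=done * protocol.dt,
            sample_stride=sample_stride,
            skin=skin,
            buffers=buffers,
        )
        if nsamp:
            rows.append(out[:nsamp])
        done += todo
        ci += 1
        if frame_stride > 0:
            frames_pos.append(system.unwrapped_positions())
            frames_t.append(done * protocol.dt)
            frames_tilt.append(system.box.tilt_xy)
    samples = np.concatenate(rows, axis=0) if rows else np.zeros((0, 10))
    raw = RawStressSamples(
        times=samples[:, 0],
        strain=samples[:, 1],
        sxx=samples[:, 2],
        syy=samples[:, 3],
        szz=samples[:, 4],
        sxy=samples[:, 5],
        sxz=samples[:, 6],
        syz=samples[:, 7],
        t_kin=samples[:, 8],
        pot_energy=samples[:, 9],
        volume=system.box.volume,
        temperature=protocol.thermostat_t,
    )
    traj = None
    if frame_stride > 0:
        traj = Trajectory(
            times=np.array(frames_t),
            positions=np.array(frames_pos),
            type_id=system.type_id.copy(),
            chain_id=system.chain_id.copy(),
            box_lengths=system.box.lengths.copy(),
            tilts=np.array(frames_tilt),
        )
    return traj, raw


def soft_pushoff(
    system: ParticleSystem,
    topology: Topology,
    ff: ForceFieldParams,
    seed: int = 0,
    n_stages: int = 5,
    steps_per_stage: int = 400,
    a_final: float = 60.0,
    dt: float = 0.005,
    temp: float = 1.0,
) -> ParticleSystem:
    """Remove overlaps by ramping a soft cosine repulsion, then re-thermalize.

    Used after random-walk chain growth, where hard LJ cores would blow up.
    Bonded terms stay active throughout so chain connectivity is preserved.
    """
    # soft cosine range capped at the WCA distance: the force peaks at half
    # the range, so wide attractive cutoffs would leave overlaps unpushed
    soft_rc = np.minimum(ff.lj_rc, 2.0 ** (1.0 / 6.0) * ff.lj_sigma)
    soft_ff = ff.with_(pair_style=K.PAIR_SOFT, lj_rc=soft_rc)
    for stage in range(n_stages):
        soft_ff = soft_ff.with_(soft_a=a_final * (stage + 1) / n_stages)
        _run_block(
            system, topology, soft_ff, steps_per_stage, dt, temp, 2.0, seed * 131 + stage
        )
    return system


def minimum_pair_distance(system: ParticleSystem, cutoff: float = 1.0) -> float:
    """Smallest nonbonded-image pair distance below ``cutoff`` (inf if none)."""
    lx, ly, lz, tilt, px, py, pz, *_ = _box_args(system)
    n = system.n
    cap = n * 200 + 4096
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    return float(
        K.min_pair_distance(system.positions, lx, ly, lz, tilt, px, py, pz, cutoff, pi, pj)
    )


def make_chains_whole(system: ParticleSystem) -> None:
    """Seed periodic image flags so each chain unwraps to a continuous path.

    Walks every chain from its first bead, accumulating minimum-image bond
    displacements, and stores the implied image counts.  Builders call this
    after wrapping freshly grown chains into the box; without it, unwrapped
    observables (Rg, bond statistics) would see box-size jumps across the
    periodic seam.
    """
    box = system.box
    lengths = box.lengths
    system.images[:] = 0
    for cid in np.unique(system.chain_id[system.chain_id >= 0]):
        idx = np.flatnonzero(system.chain_id == cid)
        cont = system.positions[idx[0]].copy()
        for prev, cur in zip(idx[:-1], idx[1:]):
            step = box.minimum_image(system.positions[cur] - system.positions[prev])
            cont = cont + step
            delta = cont - system.positions[cur]
            iy = round(delta[1] / lengths[1]) if box.periodic[1] else 0
            iz = round(delta[2] / lengths[2]) if box.periodic[2] else 0
            ix = (
                round((delta[0] - iy * box.tilt_xy) / lengths[0])
                if box.periodic[0]
                else 0
            )
            system.images[cur] = (ix, iy, iz)


def remove_com_drift(system: ParticleSystem) -> None:
    system.velocities -= system.velocities.mean(axis=0, keepdims=True)


def thermalize_velocities(system: ParticleSystem, temp: float, seed: int = 0) -> None:
    rng = np.random.default_rng(seed)
    system.velocities = rng.normal(
        0.0, math.sqrt(KB * temp / system.mass), size=system.positions.shape
    )
    remove_com_drift(system)
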