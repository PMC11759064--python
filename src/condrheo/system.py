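"""Core simulation state: box, particles, topology, force-field parameters.

The containers here are deliberately thin wrappers over numpy arrays so the
numba kernels in :mod:`condrheo._kernels` can consume them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# bond kinds
BOND_FENE = 0
BOND_HARMONIC = 1

# pair styles
PAIR_LJ = 0
PAIR_HPS = 1
PAIR_SOFT = 2


@dataclass
class SimulationBox:
    """Periodic (optionally xy-tilted, optionally x-walled) simulation cell.

    ``tilt_xy`` is the Lees-Edwards shear offset: the image of the box one
    period up in y is displaced by ``tilt_xy`` along x.  Walls, when present,
    are reflective planes at ``wall_lo``/``wall_hi`` on the x axis and require
    the x axis to be non-periodic.
    """

    lengths: np.ndarray  # (3,)
    tilt_xy: float = 0.0
    periodic: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))
    wall_lo: Optional[float] = None
    wall_hi: Optional[float] = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if np.any(self.lengths <= 0):
            raise ValueError("box lengths must be positive")
        if (self.wall_lo is not None or self.wall_hi is not None) and self.periodic[0]:
            raise ValueError("walls are only allowed on a non-periodic x axis")
        self.remap_tilt()

    @property
    def volume(self) -> float:
        if self.has_walls:
            return float((self.wall_hi - self.wall_lo) * self.lengths[1] * self.lengths[2])
        return float(np.prod(self.lengths))

    @property
    def has_walls(self) -> bool:
        return self.wall_lo is not None and self.wall_hi is not None

    def remap_tilt(self) -> None:
        """Wrap the shear offset into [-Lx/2, Lx/2]."""
        lx = self.lengths[0]
        self.tilt_xy = float(self.tilt_xy - lx * np.round(self.tilt_xy / lx))

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Nearest-image displacement(s) for ``dr`` (…,3), honouring tilt.

        Sequential wrap (z, then y adjusting x by the tilt, then x) — the
        convention every short-ranged force evaluation uses.  Exact whenever
        the true separation is below half the smallest box dimension.
        """
        dr = np.array(dr, dtype=float, copy=True)
        lx, ly, lz = self.lengths
        if self.periodic[2]:
            dr[..., 2] -= lz * np.round(dr[..., 2] / lz)
        if self.periodic[1]:
            ny = np.round(dr[..., 1] / ly)
            dr[..., 1] -= ly * ny
            dr[..., 0] -= self.tilt_xy * ny
        if self.periodic[0]:
            dr[..., 0] -= lx * np.round(dr[..., 0] / lx)
        return dr

    def copy(self) -> "SimulationBox":
        return SimulationBox(
            self.lengths.copy(), self.tilt_xy, self.periodic.copy(), self.wall_lo, self.wall_hi
        )


@dataclass
class ParticleSystem:
    """Positions/velocities/species/chain membership in a simulation box.

    ``chain_id`` is -1 for free particles (solvent).  ``images`` counts the
    periodic wraps each particle has undergone so observables can reconstruct
    unwrapped trajectories.
    """

    positions: np.ndarray  # (N,3) float
    velocities: np.ndarray  # (N,3) float
    type_id: np.ndarray  # (N,) int
    chain_id: np.ndarray  # (N,) int
    box: SimulationBox
    mass: float = 1.0
    images: Optional[np.ndarray] = None  # (N,3) int

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.type_id = np.ascontiguousarray(self.type_id, dtype=np.int64)
        self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)
        if self.images is None:
            self.images = np.zeros_like(self.positions, dtype=np.int64)
        else:
            self.images = np.ascontiguousarray(self.images, dtype=np.int64)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("non-finite velocities")

    @property
    def n(self) -> int:
        return len(self.positions)

    def unwrapped_positions(self) -> np.ndarray:
        lx, ly, lz = self.box.lengths
        pos = self.positions.copy()
        pos[:, 0] += self.images[:, 0] * lx + self.images[:, 1] * self.box.tilt_xy
        pos[:, 1] += self.images[:, 1] * ly
        pos[:, 2] += self.images[:, 2] * lz
        return pos

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(),
            self.velocities.copy(),
            self.type_id.copy(),
            self.chain_id.copy(),
            self.box.copy(),
            self.mass,
            self.images.copy(),
        )


@dataclass
class Topology:
    """Bonded interactions: bonds (FENE or harmonic cross-links) and angles.

    Angles carry per-term (K, theta0) so sticker triplets can be stiffer
    (theta0 near 180 degrees) than the backbone.
    """

    bonds: np.ndarray  # (NB,2) int
    bond_kind: np.ndarray  # (NB,) int  BOND_FENE | BOND_HARMONIC
    angles: np.ndarray  # (NA,3) int
    angle_k: np.ndarray  # (NA,) float
    angle_theta0: np.ndarray  # (NA,) float, radians

    def __post_init__(self) -> None:
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_kind = np.ascontiguousarray(self.bond_kind, dtype=np.int64)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.angle_k = np.ascontiguousarray(self.angle_k, dtype=np.float64)
        self.angle_theta0 = np.ascontiguousarray(self.angle_theta0, dtype=np.float64)

    @classmethod
    def empty(cls) -> "Topology":
        return cls(
            np.zeros((0, 2)), np.zeros(0), np.zeros((0, 3)), np.zeros(0), np.zeros(0)
        )

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    def validate(self, n_particles: int) -> None:
        if self.n_bonds and self.bonds.max() >= n_particles:
            raise ValueError("bond index out of range")
        if self.n_angles and self.angles.max() >= n_particles:
            raise ValueError("angle index out of range")
        if self.n_bonds:
            key = np.sort(self.bonds, axis=1)
            if len(np.unique(key, axis=0)) != self.n_bonds:
                raise ValueError("duplicate bonds")

    def copy(self) -> "Topology":
        return Topology(
            self.bonds.copy(),
            self.bond_kind.copy(),
            self.angles.copy(),
            self.angle_k.copy(),
            self.angle_theta0.copy(),
        )


@dataclass
class ForceFieldParams:
    """FENE/harmonic bond, angle and pairwise nonbonded parameter set.

    Pair interactions are tabulated per species pair: ``lj_eps[i, j]``,
    ``lj_sigma[i, j]`` and ``lj_rc[i, j]``.  ``pair_style`` selects plain LJ,
    the hydropathy-scaled (Ashbaugh-Hatch) variant with mixing weights
    ``hps_lambda``, or the soft cosine push-off potential used only during
    configuration relaxation.
    """

    lj_eps: np.ndarray  # (T,T)
    lj_sigma: np.ndarray  # (T,T)
    lj_rc: np.ndarray  # (T,T)
    fene_k: float = 30.0
    fene_r0: float = 1.5
    harmonic_k: float = 300.0
    harmonic_r0: float = 1.0
    shifted_force: bool = False
    pair_style: int = PAIR_LJ
    hps_lambda: Optional[np.ndarray] = None  # (T,T)
    soft_a: float = 0.0
    exclude_bonded: bool = False  # 1-2 nonbonded exclusion (residue model)

    def __post_init__(self) -> None:
        self.lj_eps = np.ascontiguousarray(np.atleast_2d(self.lj_eps), dtype=np.float64)
        self.lj_sigma = np.ascontiguousarray(np.atleast_2d(self.lj_sigma), dtype=np.float64)
        self.lj_rc = np.ascontiguousarray(np.atleast_2d(self.lj_rc), dtype=np.float64)
        if self.hps_lambda is None:
            self.hps_lambda = np.ones_like(self.lj_eps)
        else:
            self.hps_lambda = np.ascontiguousarray(
                np.atleast_2d(self.hps_lambda), dtype=np.float64
            )
        if np.any(self.lj_eps < 0):
            raise ValueError("epsilon must be non-negative")

    @classmethod
    def uniform(
        cls,
        n_types: int = 1,
        eps: float = 1.0,
        sigma: float = 1.0,
        rc: float = 2.0 ** (1.0 / 6.0),
        **kw,
    ) -> "ForceFieldParams":
        shape = (n_types, n_types)
        return cls(
            np.full(shape, eps), np.full(shape, sigma), np.full(shape, rc), **kw
        )

    @property
    def rc_max(self) -> float:
        return float(self.lj_rc.max())

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


@dataclass
class StressRecord:
    """Instantaneous stress tensor components, in p* = epsilon sigma^-3 units.

    Sign convention: diagonals are the kinetic + virial pressure-tensor
    estimator ``Sigma_aa = (sum m v_a^2 + sum r_a F_a) / V`` (an ideal gas
    has ``Sigma_xx = rho kB T``, positive); off-diagonals carry the opposite
    (material, tension-positive) sign so that shearing an elastic solid by
    +gamma produces +G gamma.  Autocorrelations and normal-stress
    differences are unaffected by either choice.
    """

    sxx: float
    syy: float
    szz: float
    sxy: float
    sxz: float
    syz: float

    @property
    def pressure(self) -> float:
        return (self.sxx + self.syy + self.szz) / 3.0

    @property
    def normal_diffs(self) -> tuple[float, float, float]:
        """(Nxy, Nxz, Nyz) = (Sxx-Syy, Sxx-Szz, Syy-Szz)."""
        return (self.sxx - self.syy, self.sxx - self.szz, self.syy - self.szz)
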