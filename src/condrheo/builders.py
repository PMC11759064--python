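"""Initial-configuration builders: melts, solvated mixtures, stickers, gels.

Every builder is a pure function of (composition, blueprint, seed): the same
inputs reproduce the same configuration bit for bit.  Chains are grown as
directionally-correlated random walks with bond length 0.97 sigma and then
relaxed with a soft cosine push-off so that no nonbonded pair sits closer
than 0.8 sigma — the standard preparation for FENE bead-spring models, which
cannot tolerate hard-core overlaps.

Species ids: 0 = spacer/polymer bead, 1 = solvent, 2 = sticker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .engine import (
    make_chains_whole,
    minimum_pair_distance,
    soft_pushoff,
    thermalize_velocities,
)
from .system import (
    BOND_FENE,
    BOND_HARMONIC,
    ForceFieldParams,
    ParticleSystem,
    SimulationBox,
    Topology,
)

TYPE_POLYMER = 0
TYPE_SOLVENT = 1
TYPE_STICKER = 2

BOND_LENGTH = 0.97
MIN_SEPARATION = 0.8
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class PackingError(RuntimeError):
    """The requested density could not be packed without residual overlaps."""


@dataclass
class Composition:
    """What to build: chain count/length, volume fractions, sticker recipe.

    ``phi_p``/``phi_s``/``phi_g`` are the polymer, solvent and gel volume
    fractions and must sum to one.  ``sticker_interval = 0`` means no
    stickers; ``sticker_strength`` is the sticker-sticker attraction chi_ps
    in epsilon units.  ``target_density`` is the total bead number density
    in sigma^-3.
    """

    n_chains: int
    chain_length: int
    phi_p: float = 1.0
    phi_s: float = 0.0
    phi_g: float = 0.0
    sticker_interval: int = 0
    sticker_strength: float = 1.0
    crosslink_mode: str = "none"  # none | transient | irreversible
    target_density: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.chain_length < 1:
            raise ValueError("chain length Np must be >= 1")
        if abs(self.phi_p + self.phi_s + self.phi_g - 1.0) > 1e-9:
            raise ValueError("phi_p + phi_s + phi_g must sum to 1")
        if self.crosslink_mode not in ("none", "transient", "irreversible"):
            raise ValueError(f"unknown crosslink_mode {self.crosslink_mode!r}")
        if self.target_density > 1.2:
            raise ValueError("target density above 1.2 sigma^-3 is not packable")

    @property
    def n_polymer_beads(self) -> int:
        return self.n_chains * self.chain_length

    @property
    def n_solvent_beads(self) -> int:
        """Deterministic integer rounding: round(phi_s/phi_p x polymer beads)."""
        phi_chain = self.phi_p + self.phi_g
        if self.phi_s == 0:
            return 0
        return int(round(self.phi_s / phi_chain * self.n_polymer_beads))


@dataclass
class ChainBlueprint:
    """Per-chain mechanics: bead size, FENE spring, optional angular stiffness."""

    bead_diameter: float = 1.0
    fene_k: float = 30.0
    fene_r0: float = 1.5
    angle_k: Optional[float] = None  # None -> fully flexible
    angle_theta0: float = 180.0  # degrees, interior angle
    sticker_angle: float = 180.0  # degrees, sticker-triplet equilibrium

    @property
    def has_angles(self) -> bool:
        return self.angle_k is not None


def default_forcefield(
    attractive: bool = False,
    chi_ps: float = 0.0,
    eps: float = 1.0,
    sigma: float = 1.0,
    rc_attr: float = 4.0,
    shifted_force: bool = False,
    blueprint: Optional[ChainBlueprint] = None,
) -> ForceFieldParams:
    """Three-species (polymer, solvent, sticker) LJ parameter table.

    Default is athermal (WCA repulsion everywhere).  ``attractive`` extends
    the polymer-polymer cutoff to ``rc_attr`` (4 sigma by default);
    ``chi_ps > 0`` opens the transient sticker-sticker channel with well
    depth chi_ps and the attractive cutoff.
    """
    n = 3
    eps_m = np.full((n, n), eps)
    sig_m = np.full((n, n), sigma)
    rc_m = np.full((n, n), WCA_CUTOFF * sigma)
    if attractive:
        for a in (TYPE_POLYMER, TYPE_STICKER):
            for b in (TYPE_POLYMER, TYPE_STICKER):
                rc_m[a, b] = rc_attr * sigma
    if chi_ps > 0.0:
        eps_m[TYPE_STICKER, TYPE_STICKER] = chi_ps
        rc_m[TYPE_STICKER, TYPE_STICKER] = rc_attr * sigma
    kw = {}
    if blueprint is not None:
        kw = dict(fene_k=blueprint.fene_k, fene_r0=blueprint.fene_r0)
    return ForceFieldParams(eps_m, sig_m, rc_m, shifted_force=shifted_force, **kw)


def _grow_chain(
    rng: np.random.Generator,
    n_beads: int,
    start: np.ndarray,
    bond: float,
    theta0_deg: Optional[float],
) -> np.ndarray:
    """Directionally correlated random walk.

    With an angular model the deflection between successive bonds is drawn
    near the equilibrium value so the push-off does not fight the angle
    potential; without one, directions are uniform on the sphere.
    """
    pos = np.empty((n_beads, 3))
    pos[0] = start
    if n_beads == 1:
        return pos
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pos[1] = pos[0] + bond * d
    for i in range(2, n_beads):
        if theta0_deg is None:
            nd = rng.normal(size=3)
            nd /= np.linalg.norm(nd)
            # avoid immediate backfolding onto the previous bead
            if np.dot(nd, d) < -0.6:
                nd = nd - 2.0 * np.dot(nd, d) * d
        else:
            # deflection angle = pi - theta0 with a small thermal spread
            defl = math.pi - math.radians(theta0_deg) + rng.normal(0.0, 0.15)
            defl = abs(defl)
            # random azimuth around the previous bond direction
            a = rng.normal(size=3)
            a -= np.dot(a, d) * d
            a /= np.linalg.norm(a)
            nd = math.cos(defl) * d + math.sin(defl) * a
        pos[i] = pos[i - 1] + bond * nd
        d = nd
    return pos


def _fold_reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by reflection (continuous triangle
    map), so bonded beads stay adjacent after folding."""
    w = hi - lo
    y = (x - lo) % (2.0 * w)
    return lo + np.where(y < w, y, 2.0 * w - y)


def _chain_topology(
    n_chains: int, np_per: int, blueprint: ChainBlueprint, offset: int = 0
) -> Topology:
    bonds = []
    angles = []
    for c in range(n_chains):
        base = offset + c * np_per
        for i in range(np_per - 1):
            bonds.append((base + i, base + i + 1))
        if blueprint.has_angles:
            for i in range(np_per - 2):
                angles.append((base + i, base + i + 1, base + i + 2))
    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    ak = np.full(len(angles), float(blueprint.angle_k or 0.0))
    at = np.full(len(angles), math.radians(blueprint.angle_theta0))
    return Topology(bonds, np.full(len(bonds), BOND_FENE), angles, ak, at)


def _relax(
    system: ParticleSystem,
    topology: Topology,
    blueprint: ChainBlueprint,
    seed: int,
    max_retries: int = 3,
) -> ParticleSystem:
    ff = default_forcefield(blueprint=blueprint)
    for attempt in range(max_retries):
        soft_pushoff(
            system,
            topology,
            ff,
            seed=seed + 7 * attempt,
            n_stages=4 + 2 * attempt,
            steps_per_stage=300 + 200 * attempt,
            a_final=60.0 * (attempt + 1),
        )
        if minimum_pair_distance(system, cutoff=MIN_SEPARATION) >= MIN_SEPARATION:
            thermalize_velocities(system, 1.0, seed=seed + 1)
            return system
    raise PackingError(
        f"could not reach minimum separation {MIN_SEPARATION} sigma at density "
        f"{system.n / system.box.volume:.3f}"
    )


def build_melt(
    composition: Composition, blueprint: Optional[ChainBlueprint] = None
) -> tuple[ParticleSystem, Topology]:
    """Dense homopolymer melt of ``n_chains`` FENE chains at the target density.

    Chains are random-walk grown (bond length 0.97 sigma), wrapped into a
    cubic periodic box sized from the bead count and density, and soft-pushed
    apart until no nonbonded pair is closer than 0.8 sigma.
    """
    blueprint = blueprint or ChainBlueprint()
    n_beads = composition.n_polymer_beads
    volume = n_beads / composition.target_density
    edge = volume ** (1.0 / 3.0)
    if edge < 2.0 * WCA_CUTOFF * blueprint.bead_diameter:
        raise ValueError("box edge below twice the interaction cutoff")
    rng = np.random.default_rng(composition.seed)
    box = SimulationBox(np.array([edge, edge, edge]))
    bond = BOND_LENGTH * blueprint.bead_diameter
    theta0 = blueprint.angle_theta0 if blueprint.has_angles else None
    pos = np.concatenate(
        [
            _grow_chain(rng, composition.chain_length, rng.uniform(0, edge, 3), bond, theta0)
            for _ in range(composition.n_chains)
        ]
    )
    pos %= edge
    chain_id = np.repeat(np.arange(composition.n_chains), composition.chain_length)
    system = ParticleSystem(
        pos, np.zeros_like(pos), np.zeros(n_beads), chain_id, box
    )
    topology = _chain_topology(composition.n_chains, composition.chain_length, blueprint)
    topology.validate(system.n)
    thermalize_velocities(system, 1.0, seed=composition.seed)
    _relax(system, topology, blueprint, composition.seed)
    make_chains_whole(system)
    return system, topology


def build_solvated(
    composition: Composition, blueprint: Optional[ChainBlueprint] = None
) -> tuple[ParticleSystem, Topology]:
    """Polymer chains plus free solvent monomers at the phi_p:phi_s ratio.

    Solvent beads carry species id 1 and no bonded terms; their count is
    ``round(phi_s/phi_p x polymer beads)`` (deterministic rounding).  With
    ``phi_s = 0`` this is exactly :func:`build_melt`.
    """
    if composition.phi_s == 0:
        return build_melt(composition, blueprint)
    blueprint = blueprint or ChainBlueprint()
    n_poly = composition.n_polymer_beads
    n_sol = composition.n_solvent_beads
    n_beads = n_poly + n_sol
    volume = n_beads / composition.target_density
    edge = volume ** (1.0 / 3.0)
    if edge < 2.0 * WCA_CUTOFF * blueprint.bead_diameter:
        raise ValueError("box edge below twice the interaction cutoff")
    rng = np.random.default_rng(composition.seed)
    box = SimulationBox(np.array([edge, edge, edge]))
    bond = BOND_LENGTH * blueprint.bead_diameter
    theta0 = blueprint.angle_theta0 if blueprint.has_angles else None
    poly = np.concatenate(
        [
            _grow_chain(rng, composition.chain_length, rng.uniform(0, edge, 3), bond, theta0)
            for _ in range(composition.n_chains)
        ]
    )
    sol = rng.uniform(0, edge, size=(n_sol, 3))
    pos = np.concatenate([poly, sol]) % edge
    type_id = np.concatenate(
        [np.zeros(n_poly, dtype=np.int64), np.full(n_sol, TYPE_SOLVENT, dtype=np.int64)]
    )
    chain_id = np.concatenate(
        [
            np.repeat(np.arange(composition.n_chains), composition.chain_length),
            np.full(n_sol, -1, dtype=np.int64),
        ]
    )
    system = ParticleSystem(pos, np.zeros_like(pos), type_id, chain_id, box)
    topology = _chain_topology(composition.n_chains, composition.chain_length, blueprint)
    topology.validate(system.n)
    thermalize_velocities(system, 1.0, seed=composition.seed)
    _relax(system, topology, blueprint, composition.seed)
    make_chains_whole(system)
    return system, topology


def place_stickers(
    system: ParticleSystem,
    topology: Topology,
    interval: int,
    sticker_angle: float = 180.0,
    sticker_angle_k: float = 10.0,
) -> Topology:
    """Retype every ``interval``-th bead per chain as a sticker.

    Sticker triplets that follow each other along the same backbone get a
    stiff angle term with equilibrium angle ``sticker_angle`` (near 180
    degrees, producing straight, beta-strand-like sticker segments).  The
    sticker-sticker nonbonded channel itself lives in the force-field table
    (see :func:`default_forcefield` with ``chi_ps``).

    An ``interval`` longer than the chains places nothing and warns.
    """
    if interval < 2:
        raise ValueError("sticker interval must be >= 2")
    chain_ids = np.unique(system.chain_id[system.chain_id >= 0])
    placed = False
    new_angles, new_k, new_t0 = [], [], []
    for cid in chain_ids:
        beads = np.flatnonzero(system.chain_id == cid)
        if interval > len(beads):
            continue
        stickers = beads[interval - 1 :: interval]
        if len(stickers) == 0:
            continue
        placed = True
        system.type_id[stickers] = TYPE_STICKER
        for a, b, c in zip(stickers, stickers[1:], stickers[2:]):
            new_angles.append((a, b, c))
            new_k.append(sticker_angle_k)
            new_t0.append(math.radians(sticker_angle))
    if not placed:
        warnings.warn("sticker interval exceeds chain length: no stickers placed")
        return topology
    angles = np.concatenate([topology.angles, np.array(new_angles, dtype=np.int64).reshape(-1, 3)])
    ak = np.concatenate([topology.angle_k, np.array(new_k)])
    at = np.concatenate([topology.angle_theta0, np.array(new_t0)])
    return Topology(topology.bonds, topology.bond_kind, angles, ak, at)


@dataclass
class CrosslinkReport:
    n_links: int
    largest_component_fraction: float
    percolates: bool


def crosslink_gel(
    system: ParticleSystem,
    topology: Topology,
    linker_fraction: float = 1.0,
    cutoff: float = 1.3,
    seed: int = 0,
) -> tuple[Topology, CrosslinkReport]:
    """Add irreversible harmonic cross-links between nearby sticker pairs.

    One-pass greedy matching: candidate sticker pairs within ``cutoff`` are
    sorted by distance (ties by lowest index) and matched so each sticker is
    used at most once.  ``linker_fraction < 1`` keeps a random subset of the
    matched links (seeded).  Returns the augmented topology and a
    connectivity report (fraction of polymer-network beads in the largest
    bonded component).
    """
    if not 0.0 <= linker_fraction <= 1.0:
        raise ValueError("linker_fraction must lie in [0, 1]")
    stickers = np.flatnonzero(system.type_id == TYPE_STICKER)
    existing = {tuple(sorted(b)) for b in topology.bonds.tolist()}
    candidates = []
    if len(stickers) >= 2 and linker_fraction > 0:
        sub = system.positions[stickers]
        for ii in range(len(stickers) - 1):
            dr = system.box.minimum_image(sub[ii + 1 :] - sub[ii])
            d = np.linalg.norm(dr, axis=1)
            for off in np.flatnonzero(d < cutoff):
                a = int(stickers[ii])
                b = int(stickers[ii + 1 + off])
                if (min(a, b), max(a, b)) not in existing:
                    candidates.append((float(d[off]), min(a, b), max(a, b)))
    candidates.sort()
    used: set[int] = set()
    matched = []
    for d, a, b in candidates:
        if a in used or b in used:
            continue
        used.add(a)
        used.add(b)
        matched.append((a, b))
    if linker_fraction < 1.0 and matched:
        rng = np.random.default_rng(seed)
        keep = rng.choice(
            len(matched), size=int(round(linker_fraction * len(matched))), replace=False
        )
        matched = [matched[i] for i in sorted(keep)]
    if not matched:
        return topology, CrosslinkReport(0, _largest_component(system, topology), False)
    links = np.array(matched, dtype=np.int64)
    bonds = np.concatenate([topology.bonds, links])
    kind = np.concatenate(
        [topology.bond_kind, np.full(len(links), BOND_HARMONIC, dtype=np.int64)]
    )
    new_topo = Topology(bonds, kind, topology.angles, topology.angle_k, topology.angle_theta0)
    frac = _largest_component(system, new_topo)
    return new_topo, CrosslinkReport(len(links), frac, frac > 0.9)


def _largest_component(system: ParticleSystem, topology: Topology) -> float:
    """Fraction of polymer (non-solvent) beads in the largest bonded component."""
    poly = np.flatnonzero(system.type_id != TYPE_SOLVENT)
    if len(poly) == 0 or topology.n_bonds == 0:
        return 0.0
    n = system.n
    b = topology.bonds
    g = coo_matrix(
        (np.ones(len(b)), (b[:, 0], b[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(g, directed=False)
    counts = np.bincount(labels[poly])
    return float(counts.max() / len(poly))


def build_slab(
    composition: Composition,
    blueprint: Optional[ChainBlueprint] = None,
    aspect: float = 3.0,
    slab_fraction: float = 0.45,
) -> tuple[ParticleSystem, Topology]:
    """Condensed slab in an elongated periodic box for coexistence runs.

    All beads start inside the central slab occupying ``slab_fraction`` of
    the x length; the rest of the box is vacuum, into which vapor can
    evaporate at finite temperature.
    """
    blueprint = blueprint or ChainBlueprint()
    n_poly = composition.n_polymer_beads
    n_sol = composition.n_solvent_beads
    n_beads = n_poly + n_sol
    # cross-section sized so the slab itself is at the target density
    slab_volume = n_beads / composition.target_density
    ly = (slab_volume / (aspect * slab_fraction)) ** (1.0 / 3.0)
    lx = aspect * ly
    rng = np.random.default_rng(composition.seed)
    box = SimulationBox(np.array([lx, ly, ly]))
    x_lo = 0.5 * lx * (1.0 - slab_fraction)
    x_hi = 0.5 * lx * (1.0 + slab_fraction)
    bond = BOND_LENGTH * blueprint.bead_diameter
    theta0 = blueprint.angle_theta0 if blueprint.has_angles else None
    chains = []
    for _ in range(composition.n_chains):
        start = np.array(
            [rng.uniform(x_lo, x_hi), rng.uniform(0, ly), rng.uniform(0, ly)]
        )
        c = _grow_chain(rng, composition.chain_length, start, bond, theta0)
        c[:, 0] = _fold_reflect(c[:, 0], x_lo, x_hi)
        chains.append(c)
    sol = np.column_stack(
        [
            rng.uniform(x_lo, x_hi, n_sol),
            rng.uniform(0, ly, n_sol),
            rng.uniform(0, ly, n_sol),
        ]
    )
    pos = np.concatenate(chains + ([sol] if n_sol else []))
    pos[:, 1:] %= ly
    pos[:, 0] %= lx
    type_id = np.concatenate(
        [np.zeros(n_poly, dtype=np.int64), np.full(n_sol, TYPE_SOLVENT, dtype=np.int64)]
    )
    chain_id = np.concatenate(
        [
            np.repeat(np.arange(composition.n_chains), composition.chain_length),
            np.full(n_sol, -1, dtype=np.int64),
        ]
    )
    system = ParticleSystem(pos, np.zeros((n_beads, 3)), type_id, chain_id, box)
    topology = _chain_topology(composition.n_chains, composition.chain_length, blueprint)
    topology.validate(system.n)
    thermalize_velocities(system, 1.0, seed=composition.seed)
    _relax(system, topology, blueprint, composition.seed)
    make_chains_whole(system)
    return system, topology


def build_aging_box(
    composition: Composition,
    blueprint: Optional[ChainBlueprint] = None,
    aspect: float = 3.0,
) -> tuple[ParticleSystem, Topology]:
    """Elongated box with reflective x walls for evaporation-aging runs.

    The polymer/solvent mixture fills the whole walled box at the target
    density; y and z remain periodic, matching the nonequilibrium
    condensate-aging geometry (evaporation happens at the +x wall).
    """
    blueprint = blueprint or ChainBlueprint()
    n_poly = composition.n_polymer_beads
    n_sol = composition.n_solvent_beads
    n_beads = n_poly + n_sol
    volume = n_beads / composition.target_density
    ly = (volume / aspect) ** (1.0 / 3.0)
    lx = aspect * ly
    rng = np.random.default_rng(composition.seed)
    box = SimulationBox(
        np.array([lx, ly, ly]),
        periodic=np.array([False, True, True]),
        wall_lo=0.0,
        wall_hi=lx,
    )
    bond = BOND_LENGTH * blueprint.bead_diameter
    theta0 = blueprint.angle_theta0 if blueprint.has_angles else None
    margin = 1.0
    chains = []
    for _ in range(composition.n_chains):
        start = np.array(
            [rng.uniform(margin, lx - margin), rng.uniform(0, ly), rng.uniform(0, ly)]
        )
        c = _grow_chain(rng, composition.chain_length, start, bond, theta0)
        c[:, 0] = _fold_reflect(c[:, 0], margin, lx - margin)
        chains.append(c)
    sol = np.column_stack(
        [
            rng.uniform(margin, lx - margin, n_sol),
            rng.uniform(0, ly, n_sol),
            rng.uniform(0, ly, n_sol),
        ]
    )
    pos = np.concatenate(chains + ([sol] if n_sol else []))
    pos[:, 1:] %= ly
    type_id = np.concatenate(
        [np.zeros(n_poly, dtype=np.int64), np.full(n_sol, TYPE_SOLVENT, dtype=np.int64)]
    )
    chain_id = np.concatenate(
        [
            np.repeat(np.arange(composition.n_chains), composition.chain_length),
            np.full(n_sol, -1, dtype=np.int64),
        ]
    )
    system = ParticleSystem(pos, np.zeros((n_beads, 3)), type_id, chain_id, box)
    topology = _chain_topology(composition.n_chains, composition.chain_length, blueprint)
    topology.validate(system.n)
    thermalize_velocities(system, 1.0, seed=composition.seed)
    _relax(system, topology, blueprint, composition.seed)
    make_chains_whole(system)
    return system, topology
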