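import numpy as np
import pytest

from condrheo.builders import (
    ChainBlueprint,
    Composition,
    build_melt,
    default_forcefield,
)
from condrheo.system import ParticleSystem, SimulationBox, Topology


@pytest.fixture(scope="session")
def small_gel_config():
    """A small relaxed melt with stickers + cross-links, reused by force and
    topology tests (building is the slow part)."""
    from condrheo.builders import crosslink_gel, place_stickers

    comp = Composition(n_chains=4, chain_length=8, target_density=0.4, seed=5)
    bp = ChainBlueprint(angle_k=10.0, angle_theta0=150.0)
    system, topo = build_melt(comp, bp)
    topo = place_stickers(system, topo, interval=3)
    topo, _ = crosslink_gel(system, topo, cutoff=1.5, seed=1)
    return system, topo


@pytest.fixture(scope="session")
def tiny_melt():
    comp = Composition(n_chains=10, chain_length=10, target_density=0.7, seed=2)
    system, topo = build_melt(comp)
    return system, topo, default_forcefield()


def _melt_gk_run(n_chains, np_, blueprint, seed, equil, prod, frame_stride=0):
    """Build, equilibrate and sample a melt; return run products + GK curve."""
    from condrheo.engine import run_nvt
    from condrheo.rheology import (
        StressSeries,
        fit_relaxation_branches,
        gk_complex_modulus,
    )

    comp = Composition(n_chains=n_chains, chain_length=np_, seed=seed)
    system, topo = build_melt(comp, blueprint)
    ff = default_forcefield(blueprint=blueprint)
    run_nvt(system, topo, ff, n_steps=equil, dt=0.005, temp=1.0, seed=seed * 13 + 1)
    eq_state = system.copy()
    traj, raw = run_nvt(
        system, topo, ff, n_steps=prod, dt=0.005, temp=1.0, seed=seed * 13 + 2,
        sample_stride=5, frame_stride=frame_stride,
    )
    gk = gk_complex_modulus(StressSeries.from_raw(raw))
    return dict(
        system=eq_state, topo=topo, ff=ff, traj=traj, raw=raw, gk=gk,
        branches=fit_relaxation_branches(gk, t_split=0.5),
    )


@pytest.fixture(scope="session")
def reference_melt():
    """Dense semiflexible melt (~1200 beads, Np=20, lp~5 sigma, rho=0.85)."""
    bp = ChainBlueprint(angle_k=10.0, angle_theta0=150.0)
    return _melt_gk_run(60, 20, bp, seed=101, equil=20000, prod=250000,
                        frame_stride=200)


@pytest.fixture(scope="session")
def stiff_long_melt():
    """Stiff longer chains (Np=40, lp toward the rod-like end of the range)."""
    bp = ChainBlueprint(angle_k=10.0, angle_theta0=165.0)
    return _melt_gk_run(25, 40, bp, seed=103, equil=30000, prod=280000)


@pytest.fixture(scope="session")
def flexible_long_melt():
    """Fully flexible chains at the same length for the rigidity contrast."""
    return _melt_gk_run(25, 40, ChainBlueprint(), seed=104, equil=10000, prod=150000)


def ideal_gas(n=200, rho=0.3, temp=1.5, seed=0):
    rng = np.random.default_rng(seed)
    edge = (n / rho) ** (1 / 3)
    box = SimulationBox(np.array([edge] * 3))
    pos = rng.uniform(0, edge, (n, 3))
    vel = rng.normal(0, np.sqrt(temp), (n, 3))
    sys_ = ParticleSystem(pos, vel, np.zeros(n), np.full(n, -1), box)
    return sys_, Topology.empty()
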