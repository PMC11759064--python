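"""Evaporation-aging protocol: quotas, mass bookkeeping, shrinkage, corona."""

import numpy as np
import pytest

from condrheo.aging import (
    AgingConfig,
    AgingTrace,
    EvaporationClock,
    WallController,
    corona_metrics,
    evaporate_step,
    run_aging,
    shrink_box,
)
from condrheo.builders import (
    ChainBlueprint,
    Composition,
    TYPE_SOLVENT,
    build_aging_box,
    default_forcefield,
    place_stickers,
)
from condrheo.system import ParticleSystem, SimulationBox


def solvent_box(n_sol=100, lx=20.0, seed=0, n_poly=0):
    rng = np.random.default_rng(seed)
    n = n_sol + n_poly
    box = SimulationBox(
        np.array([lx, 5.0, 5.0]),
        periodic=np.array([False, True, True]),
        wall_lo=0.0,
        wall_hi=lx,
    )
    pos = rng.uniform([0.5, 0, 0], [lx - 0.5, 5, 5], (n, 3))
    types = np.concatenate([np.zeros(n_poly), np.full(n_sol, TYPE_SOLVENT)])
    chains = np.concatenate([np.zeros(n_poly), np.full(n_sol, -1)])
    vel = rng.normal(0, 1, (n, 3))
    return ParticleSystem(pos, vel, types, chains, box)


class TestEvaporation:
    def test_no_solvent_in_slab_removes_nothing(self):
        system = solvent_box()
        system.positions[:, 0] = 5.0  # everything far from the wall
        cfg = AgingConfig(evap_rate=10.0, boundary_slab=0.5)
        clock = EvaporationClock(rate=10.0)
        clock.advance(1.0)
        _, removed = evaporate_step(system, cfg, clock)
        assert removed == 0

    def test_rate_quota_exact(self):
        """25 eligible beads, rate 10/tau, one tau elapsed: exactly 10 go."""
        system = solvent_box(n_sol=100, lx=20.0, seed=1)
        system.positions[:25, 0] = 19.8  # 25 beads inside the slab
        system.positions[25:, 0] = 2.0
        cfg = AgingConfig(evap_rate=10.0, boundary_slab=0.5)
        clock = EvaporationClock(rate=10.0)
        clock.advance(1.0)
        new, removed = evaporate_step(system, cfg, clock)
        assert removed == 10
        assert new.n == 90

    def test_closest_first_ties_by_index(self):
        system = solvent_box(n_sol=10, lx=20.0, seed=2)
        system.positions[:, 0] = np.array(
            [19.9, 19.7, 19.9, 19.95, 2.0, 2.0, 19.6, 2.0, 2.0, 2.0]
        )
        cfg = AgingConfig(evap_rate=2.0, boundary_slab=0.5)
        clock = EvaporationClock(rate=2.0)
        clock.advance(1.0)
        new, removed = evaporate_step(system, cfg, clock)
        assert removed == 2
        # bead 3 (closest) and then bead 0 (tie 19.9 with index < 2) went
        remaining_x = np.sort(new.positions[:, 0])
        assert 19.95 not in remaining_x and len(new.positions) == 8

    def test_determinism(self):
        cfg = AgingConfig(evap_rate=5.0, boundary_slab=1.0)
        outs = []
        for _ in range(2):
            system = solvent_box(seed=3)
            clock = EvaporationClock(rate=5.0)
            clock.advance(2.0)
            new, _ = evaporate_step(system, cfg, clock)
            outs.append(new.positions.copy())
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_quota_never_exceeded_across_steps(self):
        system = solvent_box(n_sol=200, seed=4)
        system.positions[:, 0] = 19.9
        cfg = AgingConfig(evap_rate=7.0, boundary_slab=0.5)
        clock = EvaporationClock(rate=7.0)
        total = 0
        for k in range(5):
            clock.advance(0.5)
            system, removed = evaporate_step(system, cfg, clock)
            total += removed
            assert total <= 7.0 * 0.5 * (k + 1) + 1e-9
        assert clock.removed_total == total


class TestShrink:
    def test_no_evaporation_wall_steady(self):
        system = solvent_box(n_sol=300, seed=5)
        cfg = AgingConfig(shrink_mode="wall_follow", shrink_speed=0.05)
        ctl = WallController()
        l0 = system.box.wall_hi
        for _ in range(20):
            shrink_box(system, cfg, ctl, 1.0)
        # controller noise only: wall moves far less than the full-speed bound
        assert l0 - system.box.wall_hi < 0.5 * 0.05 * 20

    def test_pure_solvent_evaporation_shrinks_monotonically(self):
        system = solvent_box(n_sol=400, lx=20.0, seed=6)
        cfg = AgingConfig(evap_rate=20.0, boundary_slab=2.0, shrink_mode="constant",
                          shrink_speed=0.05)
        ctl = WallController()
        clock = EvaporationClock(rate=20.0)
        walls = [system.box.wall_hi]
        for _ in range(10):
            clock.advance(1.0)
            system, _ = evaporate_step(system, cfg, clock)
            shrink_box(system, cfg, ctl, 1.0)
            walls.append(system.box.wall_hi)
        assert np.all(np.diff(walls) < 0)

    def test_halts_at_polymer_extent(self):
        system = solvent_box(n_sol=5, n_poly=50, lx=10.0, seed=7)
        system.positions[:50, 0] = np.linspace(0.5, 8.0, 50)  # polymer up to 8
        cfg = AgingConfig(shrink_mode="constant", shrink_speed=5.0, wall_margin=1.0)
        ctl = WallController()
        for _ in range(5):
            shrink_box(system, cfg, ctl, 1.0)
        assert ctl.halted
        assert system.box.wall_hi >= 8.0 + 1.0 - 1e-9


@pytest.fixture(scope="module")
def small_aging_setup():
    comp = Composition(
        n_chains=6, chain_length=10, phi_p=1 / 3, phi_s=2 / 3,
        sticker_interval=5, target_density=0.6, seed=11,
    )
    bp = ChainBlueprint(angle_k=10.0, angle_theta0=150.0)
    system, topo = build_aging_box(comp, bp)
    topo = place_stickers(system, topo, interval=5)
    ff = default_forcefield(chi_ps=1.5, blueprint=bp, shifted_force=True)
    return system, topo, ff


class TestRunAging:
    def test_zero_duration_initial_state_only(self, small_aging_setup):
        system, topo, ff = small_aging_setup
        cfg = AgingConfig(duration=0.0, seed=1)
        _, trace = run_aging(system.copy(), topo, ff, cfg)
        assert len(trace.times) == 1
        assert trace.n_evaporated[0] == 0

    def test_mass_bookkeeping_exact(self, small_aging_setup):
        """Polymer count constant; solvent decreases exactly by the number
        of evaporation events."""
        system, topo, ff = small_aging_setup
        cfg = AgingConfig(duration=20.0, evap_rate=3.0, record_every=5.0, seed=2)
        _, trace = run_aging(system.copy(), topo, ff, cfg)
        assert np.all(trace.n_polymer == trace.n_polymer[0])
        np.testing.assert_array_equal(
            trace.initial_solvent - trace.n_solvent, trace.n_evaporated
        )
        assert np.all(np.diff(trace.n_evaporated) >= 0)
        assert np.all(np.diff(trace.box_length) <= 1e-12)

    def test_quota_respected_globally(self, small_aging_setup):
        system, topo, ff = small_aging_setup
        cfg = AgingConfig(duration=15.0, evap_rate=2.0, record_every=5.0, seed=3)
        _, trace = run_aging(system.copy(), topo, ff, cfg)
        assert trace.n_evaporated[-1] <= 2.0 * 15.0 + 1e-9


class TestCoronaMetrics:
    def _trace(self, rho_poly, times=None):
        rho_poly = np.asarray(rho_poly, float)
        t = np.arange(len(rho_poly), dtype=float) if times is None else times
        return AgingTrace(
            times=t,
            box_length=np.full(len(rho_poly), 10.0),
            rho_poly=rho_poly,
            rho_sol=np.full_like(rho_poly, 0.1),
            n_evaporated=np.zeros(len(rho_poly), dtype=int),
            n_solvent=np.full(len(rho_poly), 100),
            n_polymer=np.full(len(rho_poly), 100),
            initial_solvent=100,
        )

    def test_no_boundary_polymer_no_shell(self):
        trace = self._trace([[0.9, 0.9, 0.1, 0.1], [0.9, 0.9, 0.1, 0.1]])
        m = corona_metrics(trace, shell_threshold=0.5)
        assert m.shell_onset_time is None and m.trapped_solvent_fraction == 0.0

    def test_step_function_onset(self):
        """Boundary densification switched on at t=3 is detected at t=3."""
        rows = [[0.2] * 6] * 3 + [[0.2, 0.2, 0.2, 0.2, 1.0, 1.0]] * 3
        trace = self._trace(rows)
        m = corona_metrics(trace, shell_threshold=0.8)
        assert m.shell_onset_time == 3.0
        assert m.shell_width_bins == 2
        assert m.shell_density == pytest.approx(1.0)

    def test_trapped_fraction_bounded(self):
        rng = np.random.default_rng(5)
        rows = rng.uniform(0, 2, (6, 8))
        trace = self._trace(rows)
        m = corona_metrics(trace, shell_threshold=0.5)
        assert 0.0 <= m.trapped_solvent_fraction <= 1.0

    def test_threshold_above_max_no_shell(self):
        trace = self._trace([[0.5] * 4] * 3)
        m = corona_metrics(trace, shell_threshold=10.0)
        assert m.shell_width_bins == 0

    def test_two_snapshots_required(self):
        trace = self._trace([[0.5] * 4])
        with pytest.raises(ValueError):
            corona_metrics(trace, shell_threshold=0.5)
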