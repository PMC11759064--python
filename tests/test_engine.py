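"""Engine correctness: minimum image, neighbor lists, virial, integrator."""

import math

import numpy as np
import pytest

from condrheo.builders import default_forcefield
from condrheo.engine import (
    compute_forces_energy,
    compute_virial_stress,
    kinetic_temperature,
    langevin_step,
    run_nvt,
    oscillatory_shear_run,
    ShearProtocol,
    ResolutionError,
    thermalize_velocities,
)
from condrheo.potentials import lj_pair
from condrheo.system import ParticleSystem, SimulationBox, Topology

from conftest import ideal_gas


def brute_force_min_image(dr, box):
    """Exhaustive image search (tilt-aware) over neighbor cells."""
    best = None
    lx, ly, lz = box.lengths
    for nx in range(-2, 3):
        for ny in range(-2, 3):
            for nz in range(-2, 3):
                cand = dr + np.array(
                    [nx * lx + ny * box.tilt_xy, ny * ly, nz * lz]
                )
                if best is None or np.linalg.norm(cand) < np.linalg.norm(best):
                    best = cand
    return best


class TestMinimumImage:
    def test_matches_brute_force_within_cutoff(self):
        """Sequential wrap equals exhaustive image search for separations
        below half the box (the only regime forces ever probe)."""
        rng = np.random.default_rng(0)
        box = SimulationBox(np.array([6.0, 7.0, 8.0]), tilt_xy=2.5)
        for _ in range(300):
            dr = rng.uniform(-15, 15, 3)
            ref = brute_force_min_image(dr, box)
            if np.linalg.norm(ref) < 0.5 * box.lengths.min():
                got = box.minimum_image(dr)
                np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_tilt_remap(self):
        box = SimulationBox(np.array([5.0, 5.0, 5.0]), tilt_xy=4.0)
        assert abs(box.tilt_xy) <= 2.5


class TestForcesAndStress:
    def test_neighbor_list_matches_all_pairs(self, small_gel_config):
        """Cell-list force evaluation equals an O(N^2) force loop."""
        system, topo = small_gel_config
        ff = default_forcefield(attractive=True, chi_ps=1.5)
        f_fast, pe_fast, vir_fast = compute_forces_energy(system, topo, ff)
        # brute force over all pairs + bonded terms via huge skin (forces the
        # brute-force pair path in the kernel for a tiny system)
        f_ref, pe_ref, vir_ref = compute_forces_energy(system, topo, ff, skin=50.0)
        np.testing.assert_allclose(f_fast, f_ref, atol=1e-10)
        assert pe_fast == pytest.approx(pe_ref, rel=1e-12)
        np.testing.assert_allclose(vir_fast, vir_ref, atol=1e-10)

    def test_forces_equal_negative_gradient(self, small_gel_config):
        """Force = -grad U to 1e-6 across FENE, LJ (plain and shifted),
        harmonic cross-links and angle terms."""
        system, topo = small_gel_config
        for shifted in (False, True):
            ff = default_forcefield(attractive=True, chi_ps=1.5, shifted_force=shifted)
            f, _, _ = compute_forces_energy(system, topo, ff)
            h = 1e-6
            rng = np.random.default_rng(1)
            for i in rng.choice(system.n, 8, replace=False):
                for d in range(3):
                    s2 = system.copy()
                    s2.positions[i, d] += h
                    _, ep, _ = compute_forces_energy(s2, topo, ff)
                    s2.positions[i, d] -= 2 * h
                    _, em, _ = compute_forces_energy(s2, topo, ff)
                    assert f[i, d] == pytest.approx(
                        -(ep - em) / (2 * h), abs=1e-6 * max(1.0, abs(f[i, d]))
                    )

    def test_ideal_gas_pressure(self):
        """No interactions: <Sigma_xx> = rho kB T (pins the sign convention)."""
        system, topo = ideal_gas(n=4000, rho=0.3, temp=1.5, seed=1)
        ff = default_forcefield(eps=0.0)
        rec = compute_virial_stress(system, topo, ff)
        rho = system.n / system.box.volume
        t_kin = kinetic_temperature(system)
        assert rec.sxx == pytest.approx(rho * t_kin, rel=0.05)
        assert rec.pressure == pytest.approx(rho * t_kin, rel=1e-9)

    def test_zero_velocity_no_interaction_zero_stress(self):
        system, topo = ideal_gas(n=50, seed=2)
        system.velocities[:] = 0.0
        ff = default_forcefield(eps=0.0)
        rec = compute_virial_stress(system, topo, ff)
        assert rec.sxx == rec.syy == rec.szz == rec.sxy == 0.0

    def test_virial_matches_brute_force_pair_sum(self):
        """Stress from the kernel equals an independent O(N^2) virial sum."""
        rng = np.random.default_rng(2)
        n = 10
        box = SimulationBox(np.array([5.0, 5.0, 5.0]))
        pos = rng.uniform(0, 5, (n, 3))
        vel = rng.normal(0, 1, (n, 3))
        system = ParticleSystem(pos, vel, np.zeros(n), np.full(n, -1), box)
        ff = default_forcefield(attractive=True)
        rec = compute_virial_stress(system, Topology.empty(), ff)
        w = np.zeros((3, 3))
        for i in range(n):
            for j in range(i + 1, n):
                dr = box.minimum_image(pos[i] - pos[j])
                r = np.linalg.norm(dr)
                if r < 4.0:
                    _, fmag = lj_pair(r, rc=4.0)
                    w += np.outer(dr, fmag * dr / r)
        s = (vel.T @ vel + w) / box.volume
        assert rec.sxx == pytest.approx(s[0, 0], abs=1e-10)
        # off-diagonals are recorded tension-positive (negated pressure tensor)
        assert rec.sxy == pytest.approx(-s[0, 1], abs=1e-10)
        assert rec.syz == pytest.approx(-s[1, 2], abs=1e-10)


class TestIntegrator:
    def test_nve_energy_conservation(self, tiny_melt):
        """With the thermostat off, BAOAB reduces to velocity-Verlet and the
        total energy drifts < 1e-4 relative over 10^4 steps at dt=0.005."""
        system, topo, ff = tiny_melt
        system = system.copy()
        # equilibrate with the thermostat, then switch it off
        run_nvt(system, topo, ff, n_steps=5000, dt=0.005, temp=1.0, gamma_l=1.0, seed=7)
        _, raw = run_nvt(system, topo, ff, n_steps=10000, dt=0.005, gamma_l=0.0,
                         seed=0, sample_stride=10)
        e = raw.pot_energy + 1.5 * system.n * raw.t_kin
        # secular drift over the whole run (the bounded shadow-Hamiltonian
        # oscillation is not drift)
        drift = np.polyfit(np.arange(len(e)), e, 1)[0] * len(e)
        assert abs(drift) / abs(e[0]) < 1e-4

    def test_bit_identical_given_seed(self, tiny_melt):
        system, topo, ff = tiny_melt
        runs = []
        for _ in range(2):
            s = system.copy()
            run_nvt(s, topo, ff, n_steps=500, dt=0.005, temp=1.0, seed=42)
            runs.append(s.positions.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_equipartition(self, tiny_melt):
        """Kinetic temperature matches the thermostat setpoint within the
        blocked standard error of the sampled series."""
        system, topo, ff = tiny_melt
        s = system.copy()
        _, raw = run_nvt(s, topo, ff, n_steps=40000, dt=0.005, temp=1.0,
                         gamma_l=1.0, seed=3, sample_stride=20)
        t = raw.t_kin[len(raw.t_kin) // 4 :]
        blocks = np.array_split(t, 10)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(t.mean() - 1.0) < max(4 * se, 0.02)

    def test_com_momentum_stays_small(self, tiny_melt):
        system, topo, ff = tiny_melt
        s = system.copy()
        run_nvt(s, topo, ff, n_steps=5000, dt=0.005, temp=1.0, seed=5)
        p = s.velocities.mean(axis=0)
        # thermostat noise injects O(sqrt(N)/N) momentum; stays near zero
        assert np.linalg.norm(p) < 0.2

    def test_langevin_single_step_api(self, tiny_melt):
        system, topo, ff = tiny_melt
        s = system.copy()
        out = langevin_step(s, topo, ff, dt=0.005, temp=1.0, gamma_l=1.0, seed=1)
        assert out is s
        with pytest.raises(ValueError):
            langevin_step(s, topo, ff, dt=-1.0, temp=1.0, gamma_l=1.0, seed=1)


class TestShear:
    def test_resolution_guard(self):
        with pytest.raises(ResolutionError):
            ShearProtocol(gamma0=0.1, omega=30.0, dt=0.005)

    def test_zero_amplitude_matches_equilibrium_statistics(self, tiny_melt):
        system, topo, ff = tiny_melt
        s1, s2 = system.copy(), system.copy()
        proto = ShearProtocol(gamma0=0.0, omega=0.5, dt=0.005, n_cycles=2)
        _, raw_sheared = oscillatory_shear_run(s1, topo, ff, proto, seed=9,
                                               sample_stride=10)
        n_steps = int(round(2 * math.pi / 0.5 / 0.005)) * 2
        _, raw_eq = run_nvt(s2, topo, ff, n_steps=n_steps, dt=0.005, temp=1.0,
                            seed=9, sample_stride=10)
        # zero amplitude, same seed: exactly the equilibrium trajectory
        np.testing.assert_array_equal(raw_sheared.sxy, raw_eq.sxy)

    def test_elastic_network_stress_in_phase(self):
        """A purely harmonic network sheared quasi-statically responds with
        stress in phase with strain (loss angle ~ 0)."""
        from condrheo.rheology import os_moduli_from_run

        rng = np.random.default_rng(0)
        n = 64
        edge = 4.0
        # simple cubic lattice bonded to neighbors: ideal elastic solid
        g = np.mgrid[0:4, 0:4, 0:4].reshape(3, -1).T.astype(float)
        box = SimulationBox(np.array([edge] * 3))
        system = ParticleSystem(g, np.zeros((n, 3)), np.zeros(n), np.zeros(n), box)
        bonds = []
        idx = lambda i, j, k: (i % 4) * 16 + (j % 4) * 4 + (k % 4)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    bonds += [
                        (idx(i, j, k), idx(i + 1, j, k)),
                        (idx(i, j, k), idx(i, j + 1, k)),
                        (idx(i, j, k), idx(i, j, k + 1)),
                    ]
        bonds = np.array(bonds)
        topo = Topology(bonds, np.ones(len(bonds)), np.zeros((0, 3)), np.zeros(0), np.zeros(0))
        # Gaussian springs (zero rest length): affine shear is an exact
        # equilibrium map, so the response is purely elastic at first order
        ff = default_forcefield(eps=0.0).with_(harmonic_k=5.0, harmonic_r0=0.0)
        proto = ShearProtocol(gamma0=0.05, omega=0.2, dt=0.005, n_cycles=5,
                              damping=1.0, thermostat_t=1e-10)
        _, raw = oscillatory_shear_run(system, topo, ff, proto, seed=1, sample_stride=5)
        pt = os_moduli_from_run(raw, 0.2)
        assert abs(pt.delta) < 0.05
        assert pt.g_storage > 0
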