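"""Chain observables against generated ensembles with known properties."""

import math

import numpy as np
import pytest

from condrheo.engine import Trajectory
from condrheo.observables import (
    density_profile,
    mean_interior_angle,
    msd_curve,
    msd_exponent,
    persistence_length_angle,
    persistence_length_tangent,
    radius_of_gyration,
)


def wlc_ensemble(n_chains, n_beads, deflection_deg, rng, jitter=0.0):
    """Discrete worm-like chains with fixed bond deflection angle."""
    chains = []
    for _ in range(n_chains):
        pos = np.zeros((n_beads, 3))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos[1] = d
        for i in range(2, n_beads):
            defl = math.radians(deflection_deg) + jitter * rng.normal()
            a = rng.normal(size=3)
            a -= a @ d * d
            a /= np.linalg.norm(a)
            d = math.cos(defl) * d + math.sin(defl) * a
            pos[i] = pos[i - 1] + d
        chains.append(pos)
    return np.concatenate(chains)


def make_traj(positions, chain_id, times=None, type_id=None):
    pos = positions if positions.ndim == 3 else positions[None]
    f = pos.shape[0]
    return Trajectory(
        times=np.arange(f, dtype=float) if times is None else times,
        positions=pos,
        type_id=np.zeros(pos.shape[1], dtype=int) if type_id is None else type_id,
        chain_id=chain_id,
        box_lengths=np.array([1e6] * 3),
        tilts=np.zeros(f),
    )


class TestPersistenceLength:
    def test_freely_jointed_chain(self):
        """No angular correlation: lp is of the order of one bond length."""
        rng = np.random.default_rng(0)
        chains = []
        for _ in range(200):
            steps = rng.normal(size=(30, 3))
            steps /= np.linalg.norm(steps, axis=1)[:, None]
            chains.append(np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)]))
        pos = np.concatenate(chains)
        cid = np.repeat(np.arange(200), 31)
        res = persistence_length_tangent(make_traj(pos, cid))
        assert 0.1 < res.lp < 2.0

    def test_rigid_rods_flagged(self):
        rod = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
        pos = np.concatenate([rod + off for off in np.random.default_rng(1).normal(0, 50, (20, 3))])
        cid = np.repeat(np.arange(20), 20)
        res = persistence_length_tangent(make_traj(pos, cid))
        assert res.lower_bound_only

    def test_wlc_matches_angle_formula(self):
        """Tangent-correlation lp within 5% of -b/ln<cos theta> on chains
        sampled with a known deflection distribution."""
        rng = np.random.default_rng(2)
        defl = 25.0
        pos = wlc_ensemble(300, 40, defl, rng, jitter=0.05)
        cid = np.repeat(np.arange(300), 40)
        res = persistence_length_tangent(make_traj(pos, cid))
        # oracle from the generator's own deflection distribution
        samples = math.radians(defl) + 0.05 * rng.normal(size=100000)
        lp_ref = -1.0 / math.log(float(np.mean(np.cos(samples))))
        assert res.lp == pytest.approx(lp_ref, rel=0.05)

    def test_both_estimators_agree_on_wlc(self):
        """Angle-formula and tangent-correlation estimators within 15%."""
        rng = np.random.default_rng(3)
        defl = 30.0
        pos = wlc_ensemble(300, 40, defl, rng, jitter=0.05)
        cid = np.repeat(np.arange(300), 40)
        traj = make_traj(pos, cid)
        lp_t = persistence_length_tangent(traj).lp
        lp_a = persistence_length_angle(mean_interior_angle(traj))
        assert abs(lp_t - lp_a) / lp_a < 0.15

    def test_flexible_limit_value(self):
        """Interior angle 111.6 degrees maps to lp ~ 1 bond length."""
        assert persistence_length_angle(111.6) == pytest.approx(1.0, abs=0.01)

    def test_direct_evaluation_120(self):
        assert persistence_length_angle(120.0) == pytest.approx(1.0 / math.log(2.0), rel=1e-12)

    def test_straight_limit_diverges(self):
        with pytest.warns(UserWarning):
            assert math.isinf(persistence_length_angle(180.0))

    def test_deflection_over_90_rejected(self):
        with pytest.raises(ValueError):
            persistence_length_angle(89.0)


class TestRadiusOfGyration:
    def test_two_beads(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        res = radius_of_gyration(pos, np.zeros(2, dtype=int))
        assert res.mean == pytest.approx(1.5)

    def test_rigid_rod_closed_form(self):
        """N equally spaced beads, spacing b: Rg^2 = b^2 (N^2-1)/12."""
        n, b = 17, 0.7
        pos = np.column_stack([b * np.arange(n), np.zeros(n), np.zeros(n)])
        res = radius_of_gyration(pos, np.zeros(n, dtype=int))
        assert res.mean**2 == pytest.approx(b**2 * (n**2 - 1) / 12.0, rel=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pos = rng.normal(size=(30, 3))
        cid = np.zeros(30, dtype=int)
        r0 = radius_of_gyration(pos, cid).mean
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pos @ q.T + np.array([5.0, -3.0, 2.0])
        assert radius_of_gyration(moved, cid).mean == pytest.approx(r0, rel=1e-12)

    def test_single_bead_flagged(self):
        res = radius_of_gyration(np.zeros((1, 3)), np.zeros(1, dtype=int))
        assert res.mean == 0.0 and res.flagged_single_bead


class TestMsd:
    def test_ballistic_exponent(self):
        v = np.random.default_rng(5).normal(size=(50, 3))
        t = np.arange(100, dtype=float) * 0.1
        pos = t[:, None, None] * v[None]
        traj = make_traj(pos, np.full(50, -1), times=t)
        res = msd_exponent(traj)
        assert res.exponent == pytest.approx(2.0, abs=0.01)

    def test_brownian_exponent(self):
        rng = np.random.default_rng(6)
        steps = rng.normal(size=(2000, 200, 3))
        pos = np.cumsum(steps, axis=0)
        traj = make_traj(pos, np.full(200, -1))
        res = msd_exponent(traj)
        assert res.exponent == pytest.approx(1.0, abs=0.05)

    def test_fractional_brownian_exponents(self):
        """Exponent estimator recovers the generator's Hurst exponent on
        fractional-Brownian fixtures within 0.05."""
        rng = np.random.default_rng(7)
        n = 512
        for hurst in (0.25, 0.4):
            # exact fBm via Cholesky of the covariance of increments
            t = np.arange(1, n + 1, dtype=float)
            cov = 0.5 * (
                t[:, None] ** (2 * hurst)
                + t[None, :] ** (2 * hurst)
                - np.abs(t[:, None] - t[None, :]) ** (2 * hurst)
            )
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
            walks = np.einsum("ij,jkd->ikd", chol, rng.normal(size=(n, 100, 3)))
            traj = make_traj(walks, np.full(100, -1))
            res = msd_exponent(traj)
            assert res.exponent == pytest.approx(2 * hurst, abs=0.05)

    def test_msd_nondecreasing(self):
        rng = np.random.default_rng(8)
        pos = np.cumsum(rng.normal(size=(500, 50, 3)), axis=0)
        traj = make_traj(pos, np.full(50, -1))
        lags, msd = msd_curve(traj)
        assert np.all(np.diff(msd) > -1e-9)

    def test_window_outside_data_rejected(self):
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.normal(size=(50, 10, 3)), axis=0)
        traj = make_traj(pos, np.full(10, -1))
        with pytest.raises(ValueError):
            msd_exponent(traj, window=(1e6, 1e7))


class TestDensityProfile:
    def test_uniform_gas_flat(self):
        rng = np.random.default_rng(10)
        box = np.array([10.0, 5.0, 5.0])
        pos = rng.uniform(0, 1, (200000, 3)) * box
        centers, rho = density_profile(pos, box, axis=0, n_bins=10)
        expect = 200000 / np.prod(box)
        assert np.all(np.abs(rho - expect) / expect < 0.05)

    def test_profile_integrates_to_count(self):
        rng = np.random.default_rng(11)
        box = np.array([8.0, 4.0, 4.0])
        pos = rng.uniform(0, 1, (5000, 3)) * box
        centers, rho = density_profile(pos, box, axis=0, n_bins=16)
        bin_vol = box[0] / 16 * box[1] * box[2]
        assert np.sum(rho) * bin_vol == pytest.approx(5000)

    def test_slab_two_plateaus(self):
        rng = np.random.default_rng(12)
        box = np.array([10.0, 4.0, 4.0])
        dense = rng.uniform([4, 0, 0], [6, 4, 4], (8000, 3))
        dilute = rng.uniform([0, 0, 0], [10, 4, 4], (400, 3))
        pos = np.vstack([dense, dilute])
        centers, rho = density_profile(pos, box, axis=0, n_bins=20)
        inner = rho[(centers > 4.4) & (centers < 5.6)]
        outer = rho[(centers < 3.0) | (centers > 7.0)]
        assert inner.mean() > 20 * outer.mean()

    def test_empty_selection_warns(self):
        box = np.array([5.0, 5.0, 5.0])
        pos = np.random.default_rng(13).uniform(0, 5, (100, 3))
        with pytest.warns(UserWarning):
            _, rho = density_profile(pos, box, selection=np.zeros(100, dtype=bool))
        assert np.all(rho == 0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            density_profile(np.zeros((5, 3)), np.ones(3), n_bins=2)
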