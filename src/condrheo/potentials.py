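"""Scalar pair/bond/angle potentials — the reference forms the kernels mirror.

Everything is in reduced LJ units.  These functions are used directly for
single evaluations (tests, fits, diagnostics); the batched numba kernels in
:mod:`condrheo._kernels` implement the same expressions and are checked
against these in the test suite.
"""

from __future__ import annotations

import math

import numpy as np


class OverstretchError(RuntimeError):
    """A FENE bond was evaluated at or beyond its maximum extension R0."""


def fene_bond(r: float, k: float = 30.0, r0: float = 1.5) -> tuple[float, float]:
    """FENE spring energy and restoring-force magnitude at separation ``r``.

    U(r) = -1/2 k R0^2 ln(1 - r^2/R0^2); |F| = k r / (1 - r^2/R0^2).

    The force is directed so as to restore the bond toward r = 0.

    Raises
    ------
    OverstretchError
        If ``r >= r0`` (the spring is infinitely stiff there).
    """
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r >= r0:
        raise OverstretchError(f"FENE bond overstretched: r={r!r} >= R0={r0!r}")
    x = (r / r0) ** 2
    energy = -0.5 * k * r0**2 * math.log1p(-x)
    force = k * r / (1.0 - x)
    return energy, force


def lj_pair(
    r: float,
    eps: float = 1.0,
    sigma: float = 1.0,
    rc: float = 2.0 ** (1.0 / 6.0),
    shifted_force: bool = False,
) -> tuple[float, float]:
    """Lennard-Jones 12-6 energy and force magnitude (positive = repulsive).

    Plainly truncated at ``rc`` by default.  With ``shifted_force`` a linear
    term is added so both the potential and the force go continuously to zero
    at the cutoff:  U_sf(r) = U(r) - U(rc) - (r - rc) U'(rc).
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r > rc:
        return 0.0, 0.0
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r  # -dU/dr
    if shifted_force:
        src6 = (sigma / rc) ** 6
        u_rc = 4.0 * eps * (src6 * src6 - src6)
        f_rc = 24.0 * eps * (2.0 * src6 * src6 - src6) / rc
        u = u - u_rc + (r - rc) * f_rc
        f = f - f_rc
    return u, f


def angle_term(
    theta: float, k_theta: float, theta0: float
) -> tuple[float, float]:
    """Harmonic angle energy U = K (theta - theta0)^2 and generalized torque.

    ``theta``/``theta0`` in radians.  The returned torque magnitude is
    |dU/dtheta| = 2 K |theta - theta0|.
    """
    if not 0.0 < theta <= math.pi + 1e-12:
        raise ValueError("angle must lie in (0, pi]")
    d = theta - theta0
    return k_theta * d * d, abs(2.0 * k_theta * d)


def angle_forces(
    ri: np.ndarray, rj: np.ndarray, rk: np.ndarray, k_theta: float, theta0: float
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Energy and per-bead forces of the i-j-k harmonic angle (j central).

    The three forces sum to zero (no net force, no net torque).

    Raises
    ------
    ValueError
        If either bond vector has (near-)zero length.
    """
    a = np.asarray(ri, float) - np.asarray(rj, float)
    b = np.asarray(rk, float) - np.asarray(rj, float)
    la = np.linalg.norm(a)
    lb = np.linalg.norm(b)
    if la < 1e-12 or lb < 1e-12:
        raise ValueError("degenerate angle: zero-length bond")
    c = float(np.dot(a, b) / (la * lb))
    c = min(1.0, max(-1.0, c))
    s = math.sqrt(max(1.0 - c * c, 1e-16))
    theta = math.acos(c)
    du = 2.0 * k_theta * (theta - theta0)
    coef = du / s  # dU/dcos(theta) = -dU/dtheta / sin(theta)
    fi = coef * (b / (la * lb) - c * a / (la * la))
    fk = coef * (a / (la * lb) - c * b / (lb * lb))
    fj = -(fi + fk)
    energy = k_theta * (theta - theta0) ** 2
    return energy, fi, fj, fk


def hps_pair(
    r: float,
    lam: float,
    eps: float = 1.0,
    sigma: float = 1.0,
    rc: float = 3.0,
) -> tuple[float, float]:
    """Hydropathy-scaled (Ashbaugh-Hatch) pair potential.

    Inside the LJ minimum (r <= 2^{1/6} sigma) the full repulsion acts with
    the well lifted by (1 - lam) eps; beyond it the attraction is scaled by
    ``lam``.  ``lam`` is the arithmetic mean of the two residues' hydropathy
    weights.  The attractive branch is energy-shifted so U(rc) = 0.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r > rc:
        return 0.0, 0.0
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    u_lj, f_lj = lj_pair(r, eps, sigma, rc=np.inf)
    u_rc, _ = lj_pair(rc, eps, sigma, rc=np.inf)
    if r <= rmin:
        u = u_lj + (1.0 - lam) * eps - lam * u_rc
        f = f_lj
    else:
        u = lam * (u_lj - u_rc)
        f = lam * f_lj
    return u, f
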