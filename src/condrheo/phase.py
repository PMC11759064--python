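"""Liquid-vapor coexistence from slab profiles and critical-point fitting.

Coexistence densities come from time-averaged density profiles of slab
simulations fitted to a hyperbolic-tangent interface form.  The critical
point is then extrapolated with the law of rectilinear diameters,

    (rho_l + rho_v)/2 = rho_c + A (Tc - T),

combined with the universal order-parameter scaling

    rho_l - rho_v = Delta_rho0 (1 - T/Tc)^beta,   beta = 0.325,

fitted simultaneously over all subcritical state points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .engine import Trajectory
from .observables import density_profile


class PhaseFitError(RuntimeError):
    pass


@dataclass
class CoexistencePoint:
    temperature: float
    rho_liquid: float
    rho_vapor: float
    interface_width: float
    supercritical: bool = False

    def __post_init__(self) -> None:
        if not self.supercritical and self.rho_liquid < self.rho_vapor:
            raise ValueError("liquid density must exceed vapor density")


@dataclass
class CriticalFit:
    tc: float
    rho_c: float
    amplitude: float  # A, rectilinear-diameter slope
    delta_rho0: float
    beta: float
    residual: float


def _slab_profile_form(x, rho_v, rho_l, x0, half_width, w):
    """Two-interface slab: dense plateau of extent 2*half_width around x0."""
    return rho_v + 0.5 * (rho_l - rho_v) * (
        np.tanh((x - (x0 - half_width)) / w) - np.tanh((x - (x0 + half_width)) / w)
    )


def center_slab(x: np.ndarray, length: float, weights: np.ndarray) -> np.ndarray:
    """Shift wrapped coordinates so the density-weighted circular mean sits
    at the box center (keeps the dense slab away from the periodic seam)."""
    ang = 2.0 * math.pi * x / length
    mean_ang = math.atan2(
        float(np.sum(weights * np.sin(ang))), float(np.sum(weights * np.cos(ang)))
    )
    center = (mean_ang % (2.0 * math.pi)) / (2.0 * math.pi) * length
    return (x - center + 0.5 * length) % length


def coexistence_from_profile(
    centers: np.ndarray, density: np.ndarray, temperature: float
) -> CoexistencePoint:
    """Fit a tanh slab form to a (already centered) density profile."""
    rho_min = float(np.min(density))
    rho_max = float(np.max(density))
    if rho_max - rho_min < 0.05 * max(rho_max, 1e-12):
        return CoexistencePoint(temperature, rho_max, rho_max, math.inf, supercritical=True)
    length = centers[-1] - centers[0]
    span = float(np.mean(density > 0.5 * (rho_min + rho_max))) * length
    p0 = [rho_min, rho_max, centers[len(centers) // 2], max(span / 2, length / 20), length / 20]
    try:
        popt, _ = curve_fit(
            _slab_profile_form,
            centers,
            density,
            p0=p0,
            maxfev=20000,
            bounds=(
                [0.0, 0.0, centers[0], 0.0, 1e-6],
                [2.0, 2.0, centers[-1], length, length],
            ),
        )
    except RuntimeError as exc:
        raise PhaseFitError(f"interface fit failed: {exc}") from exc
    rho_v, rho_l, _, _, w = popt
    if rho_l < rho_v:
        rho_l, rho_v = rho_v, rho_l
    if (rho_l - rho_v) < 0.05 * rho_l:
        return CoexistencePoint(temperature, rho_l, rho_l, math.inf, supercritical=True)
    return CoexistencePoint(temperature, float(rho_l), float(rho_v), float(w))


def coexistence_from_slab(
    trajectory: Trajectory,
    temperature: float,
    axis: int = 0,
    n_bins: int = 60,
    equilibration_fraction: float = 0.3,
) -> CoexistencePoint:
    """Time-averaged slab density profile -> coexistence densities.

    Frames are wrapped, recentered on the dense phase (density-weighted
    circular mean) and averaged before the tanh fit.
    """
    lengths = trajectory.box_lengths
    first = int(equilibration_fraction * trajectory.n_frames)
    prof = None
    for f in range(first, trajectory.n_frames):
        pos = trajectory.positions[f].copy()
        for ax in range(3):
            pos[:, ax] %= lengths[ax]
        pos[:, axis] = center_slab(pos[:, axis], lengths[axis], np.ones(len(pos)))
        centers, rho = density_profile(pos, lengths, axis=axis, n_bins=n_bins)
        prof = rho if prof is None else prof + rho
    prof /= trajectory.n_frames - first
    return coexistence_from_profile(centers, prof, temperature)


def fit_critical_point(
    points: Sequence[CoexistencePoint], beta: float = 0.325
) -> CriticalFit:
    """Simultaneous rectilinear-diameter + scaling fit of the critical point.

    Least squares over all points of

        (rho_l + rho_v)/2 - [rho_c + A (Tc - T)]      and
        (rho_l - rho_v)   - Delta_rho0 (1 - T/Tc)^beta

    with beta held fixed.  Requires >= 3 subcritical points; the fit is
    invariant to their ordering.
    """
    pts = [p for p in points if not p.supercritical]
    if len(pts) < 3:
        raise PhaseFitError("need at least 3 subcritical coexistence points")
    t = np.array([p.temperature for p in pts])
    mid = np.array([0.5 * (p.rho_liquid + p.rho_vapor) for p in pts])
    gap = np.array([p.rho_liquid - p.rho_vapor for p in pts])
    t_max = float(t.max())

    def resid(x):
        tc, rho_c, a, d0 = x
        r1 = mid - (rho_c + a * (tc - t))
        arg = np.maximum(1.0 - t / tc, 1e-12)
        r2 = gap - d0 * arg**beta
        return np.concatenate([r1, r2])

    guess_tc = t_max * 1.1
    x0 = [guess_tc, float(mid.mean()), 0.1, float(gap.max())]
    sol = least_squares(
        resid,
        x0,
        bounds=([t_max * (1 + 1e-9), 0.0, -np.inf, 0.0], [10 * t_max, np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    tc, rho_c, a, d0 = sol.x
    if not sol.success or tc <= t_max:
        raise PhaseFitError("critical fit did not converge above the data range")
    scale = max(float(np.linalg.norm(np.concatenate([mid, gap]))), 1e-300)
    return CriticalFit(
        float(tc), float(rho_c), float(a), float(d0), beta,
        float(np.linalg.norm(resid(sol.x)) / scale),
    )


def synthetic_coexistence_curve(
    tc: float,
    rho_c: float,
    amplitude: float,
    delta_rho0: float,
    temperatures: Sequence[float],
    beta: float = 0.325,
    noise: float = 0.0,
    seed: int = 0,
) -> list[CoexistencePoint]:
    """Coexistence points generated from the rectilinear + scaling laws.

    The generator used as ground truth when validating the critical fit
    (optionally with Gaussian density noise).
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures:
        if t >= tc:
            raise ValueError("temperatures must be subcritical")
        mid = rho_c + amplitude * (tc - t)
        gap = delta_rho0 * (1.0 - t / tc) ** beta
        rl = mid + 0.5 * gap + noise * rng.normal()
        rv = max(mid - 0.5 * gap + noise * rng.normal(), 0.0)
        out.append(CoexistencePoint(t, rl, rv, 1.0))
    return out
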