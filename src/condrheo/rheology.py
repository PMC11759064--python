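"""Viscoelastic analysis: stress series -> G*(t), G'(w), G''(w), fits.

Two routes to the complex modulus:

* **Green-Kubo** (equilibrium): the isotropic-average stress-autocorrelation
  estimator

      G*(t) = V/(5 kB T) [ C_xy + C_xz + C_yz
                           + (1/6)(C_Nxy + C_Nxz + C_Nyz) ]

  where C_ab are autocorrelations of the off-diagonal stresses and the
  N_ij = Sigma_ii - Sigma_jj are normal-stress differences.  Each channel is
  correlated with a multi-tau (hierarchical block-averaging) correlator, so
  long lags come nearly free of noise.  For an isotropic system each
  normal-difference autocorrelation equals four times an off-diagonal one
  and the estimator collapses to V/(kB T) <Sxy(0) Sxy(t)>; that identity is
  what fixes the 1/6 weight (kept configurable via ``ndiff_weight``).

* **Oscillatory shear**: under strain gamma0 sin(wt) the stress responds as
  Sigma0 sin(wt + delta); a least-squares decomposition into in-phase and
  quadrature parts gives G' = A/gamma0 and G'' = B/gamma0 directly.

Frequency spectra are produced by fitting a generalized Maxwell model
G(t) = sum_i G_i exp(-t/tau_i) (optionally plus an equilibrium plateau G0
for gels) and evaluating its exact transforms, rather than numerically
Fourier-transforming noisy data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares, nnls

from .engine import RawStressSamples
from .units import KB


class RheologyError(RuntimeError):
    pass


class NonlinearResponseError(RheologyError):
    """The sinusoidal fit left too much residual: nonlinear or too noisy."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class StressSeries:
    """Uniformly sampled off-diagonal stresses and normal-stress differences."""

    times: np.ndarray
    sxy: np.ndarray
    sxz: np.ndarray
    syz: np.ndarray
    nxy: Optional[np.ndarray]  # Sxx - Syy
    nxz: Optional[np.ndarray]  # Sxx - Szz
    nyz: Optional[np.ndarray]  # Syy - Szz
    volume: float
    temperature: float
    strain: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if self.volume <= 0 or self.temperature <= 0:
            raise ValueError("volume and temperature must be positive")
        if len(self.times) > 2:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise ValueError("stress series must have a uniform time stride")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def is_equilibrium(self) -> bool:
        return self.strain is None or not np.any(self.strain)

    @classmethod
    def from_raw(cls, raw: RawStressSamples) -> "StressSeries":
        return cls(
            times=raw.times,
            sxy=raw.sxy,
            sxz=raw.sxz,
            syz=raw.syz,
            nxy=raw.sxx - raw.syy,
            nxz=raw.sxx - raw.szz,
            nyz=raw.syy - raw.szz,
            volume=raw.volume,
            temperature=raw.temperature,
            strain=raw.strain if np.any(raw.strain) else None,
        )


@dataclass
class ComplexModulusSeries:
    """Stress-relaxation modulus G*(t) on a logarithmic lag grid."""

    lag_times: np.ndarray
    g: np.ndarray
    offdiag_only: bool = False  # fallback flag when normal diffs were missing

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, float)
        self.g = np.asarray(self.g, float)


@dataclass
class ModulusPoint:
    omega: float
    g_storage: float
    g_loss: float
    sigma0: float
    delta: float
    residual: float


@dataclass
class ModulusSpectrum:
    """G'(w), G''(w) tabulated on an ascending frequency grid."""

    omegas: np.ndarray
    storage: np.ndarray
    loss: np.ndarray
    sigma0: Optional[np.ndarray] = None
    delta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, float)
        self.storage = np.asarray(self.storage, float)
        self.loss = np.asarray(self.loss, float)
        order = np.argsort(self.omegas)
        self.omegas = self.omegas[order]
        self.storage = self.storage[order]
        self.loss = self.loss[order]
        if self.sigma0 is not None:
            self.sigma0 = np.asarray(self.sigma0, float)[order]
        if self.delta is not None:
            self.delta = np.asarray(self.delta, float)[order]

    @classmethod
    def from_points(cls, points: Sequence[ModulusPoint]) -> "ModulusSpectrum":
        return cls(
            omegas=np.array([p.omega for p in points]),
            storage=np.array([p.g_storage for p in points]),
            loss=np.array([p.g_loss for p in points]),
            sigma0=np.array([p.sigma0 for p in points]),
            delta=np.array([p.delta for p in points]),
        )


@dataclass
class MaxwellFit:
    """Generalized Maxwell fit: G(t) = G0 + sum_i G_i exp(-t/tau_i).

    ``plateau`` (G0) is zero for fluids; a positive plateau marks an
    equilibrium modulus (Kelvin-Voigt-like solid) and makes the zero-shear
    viscosity infinite.  Modes are sorted by ascending relaxation time.
    """

    g_modes: np.ndarray
    tau_modes: np.ndarray
    plateau: float = 0.0
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        self.g_modes = np.asarray(self.g_modes, float)
        self.tau_modes = np.asarray(self.tau_modes, float)
        order = np.argsort(self.tau_modes)
        self.g_modes = self.g_modes[order]
        self.tau_modes = self.tau_modes[order]
        if np.any(self.g_modes < 0) or np.any(self.tau_modes <= 0):
            raise ValueError("Maxwell modes must have G_i >= 0 and tau_i > 0")

    @property
    def n_modes(self) -> int:
        return len(self.g_modes)

    @property
    def eta_star(self) -> float:
        """Zero-shear dynamic viscosity sum_i G_i tau_i (inf for solids)."""
        if self.plateau > 0:
            return math.inf
        return float(np.sum(self.g_modes * self.tau_modes))

    def g_of_t(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.plateau + np.sum(
            self.g_modes[:, None] * np.exp(-t[None, :] / self.tau_modes[:, None]), axis=0
        )

    def storage(self, omegas: np.ndarray) -> np.ndarray:
        w = np.asarray(omegas, float)
        wt2 = (w[None, :] * self.tau_modes[:, None]) ** 2
        return self.plateau + np.sum(self.g_modes[:, None] * wt2 / (1.0 + wt2), axis=0)

    def loss(self, omegas: np.ndarray) -> np.ndarray:
        w = np.asarray(omegas, float)
        wt = w[None, :] * self.tau_modes[:, None]
        return np.sum(self.g_modes[:, None] * wt / (1.0 + wt * wt), axis=0)

    def spectrum(self, omegas: np.ndarray) -> ModulusSpectrum:
        return ModulusSpectrum(omegas, self.storage(omegas), self.loss(omegas))


# --------------------------------------------------------------------------
# correlators & Green-Kubo
# --------------------------------------------------------------------------


def multitau_correlate(
    series: np.ndarray, blocks_m: int = 2, lags_per_block: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized autocorrelation on a logarithmically spaced lag grid.

    Level 0 computes lags 0..p-1 from the raw samples; each subsequent level
    first block-averages the previous level by a factor ``blocks_m`` and
    computes lags p/m..p-1 in the coarser units, so long-lag estimates are
    averaged over many samples (the multi-tau trick).  Lags are returned in
    units of the input stride.
    """
    x = np.asarray(series, float)
    p = lags_per_block
    m = blocks_m
    if m < 2:
        raise ValueError("blocks_m must be >= 2")
    if len(x) < 2 * p:
        raise ValueError(f"series too short: need at least {2 * p} samples")
    lags, corrs = [], []
    y = x
    scale = 1
    level = 0
    while len(y) >= p:
        lo = 0 if level == 0 else p // m
        for lag in range(lo, p):
            if lag >= len(y):
                break
            n_pairs = len(y) - lag
            corrs.append(float(np.dot(y[:n_pairs], y[lag:]) / n_pairs))
            lags.append(lag * scale)
        nn = (len(y) // m) * m
        if nn < m:
            break
        y = y[:nn].reshape(-1, m).mean(axis=1)
        scale *= m
        level += 1
    return np.array(lags, float), np.array(corrs)


def gk_complex_modulus(
    stress: StressSeries,
    blocks_m: int = 2,
    lags_per_block: int = 16,
    ndiff_weight: float = 1.0 / 6.0,
) -> ComplexModulusSeries:
    """Green-Kubo complex modulus from an equilibrium stress series.

    Correlations are of the raw products (no mean subtraction): a fluid's
    sample-mean shear stress contributes an offset far below the noise
    floor, while a quenched network's frozen residual stress is exactly
    what carries the equilibrium plateau of G*(t) — subtracting it would
    erase the gel signal.  When the normal-difference channels are absent
    the estimator falls back to the three off-diagonal autocorrelations
    alone and flags the result.
    """
    if not stress.is_equilibrium:
        raise ValueError("Green-Kubo needs an equilibrium (unstrained) series")
    kw = dict(blocks_m=blocks_m, lags_per_block=lags_per_block)
    off = [stress.sxy, stress.sxz, stress.syz]
    lags = None
    total = None
    for ch in off:
        lg, c = multitau_correlate(np.asarray(ch, float), **kw)
        lags = lg
        total = c if total is None else total + c
    has_ndiff = stress.nxy is not None and stress.nxz is not None and stress.nyz is not None
    if has_ndiff:
        for ch in [stress.nxy, stress.nxz, stress.nyz]:
            # normal differences carry a hydrostatic-free but nonzero mean
            # (anisotropy of the finite sample); remove it so the 1/6-weighted
            # channels measure fluctuations only
            ch = np.asarray(ch, float)
            _, c = multitau_correlate(ch - ch.mean(), **kw)
            total = total + ndiff_weight * c
        prefac = stress.volume / (5.0 * KB * stress.temperature)
    else:
        prefac = stress.volume / (3.0 * KB * stress.temperature)
    return ComplexModulusSeries(
        lag_times=lags * stress.dt, g=prefac * total, offdiag_only=not has_ndiff
    )


# --------------------------------------------------------------------------
# oscillatory shear
# --------------------------------------------------------------------------


def os_moduli(
    times: np.ndarray,
    strain: np.ndarray,
    stress: np.ndarray,
    omega: float,
    discard_cycles: int = 1,
    residual_limit: float = 0.5,
) -> ModulusPoint:
    """Storage/loss moduli at one frequency from an oscillatory-shear record.

    The applied strain must be gamma0 sin(wt); the stress is decomposed by
    least squares into A sin(wt) + B cos(wt) + offset after discarding the
    first ``discard_cycles`` cycles, giving G' = A/gamma0, G'' = B/gamma0,
    Sigma0 = sqrt(A^2+B^2) and delta = atan2(B, A).
    """
    times = np.asarray(times, float)
    strain = np.asarray(strain, float)
    stress = np.asarray(stress, float)
    period = 2.0 * math.pi / omega
    keep = times >= discard_cycles * period
    if (times[keep][-1] - times[keep][0]) < 3.0 * period - 1e-9:
        raise ValueError("need at least 3 full cycles after the discard window")
    t = times[keep]
    s = stress[keep]
    g = strain[keep]
    # the strain's own fitted phase is the reference axis, so a slightly
    # non-integer cycle count cannot bias the decomposition
    basis = np.column_stack([np.sin(omega * t), np.cos(omega * t)])
    gs, gc = np.linalg.lstsq(
        np.column_stack([basis, np.ones_like(t)]), g, rcond=None
    )[0][:2]
    gamma0 = float(math.hypot(gs, gc))
    if gamma0 <= 0:
        raise ValueError("strain amplitude is zero")
    phase = math.atan2(gc, gs)
    design = np.column_stack(
        [np.sin(omega * t + phase), np.cos(omega * t + phase), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, s, rcond=None)
    a, b, _ = coef
    resid = s - design @ coef
    sigma0 = math.hypot(a, b)
    # thermal stress noise rides on the sinusoid; what matters is the
    # standard error of the fitted amplitude relative to the amplitude
    se_amp = float(np.sqrt(np.mean(resid**2)) * math.sqrt(2.0 / len(t)))
    rel = se_amp / sigma0 if sigma0 > 0 else math.inf
    if rel > residual_limit:
        raise NonlinearResponseError(
            f"amplitude uncertainty {rel:.2f} of Sigma0 exceeds {residual_limit:.2f}"
        )
    return ModulusPoint(
        omega=omega,
        g_storage=a / gamma0,
        g_loss=b / gamma0,
        sigma0=sigma0,
        delta=math.atan2(b, a),
        residual=rel,
    )


def os_moduli_from_run(raw: RawStressSamples, omega: float, **kw) -> ModulusPoint:
    """Convenience wrapper decomposing the Sigma_xy record of a shear run."""
    return os_moduli(raw.times, raw.strain, raw.sxy, omega, **kw)


@dataclass
class LinearWindow:
    gamma_max: Optional[float]
    ok: bool
    deviations: np.ndarray


def linear_regime_check(
    points: Sequence[tuple[float, float, float]], tol: float = 0.10
) -> LinearWindow:
    """Largest strain amplitude whose moduli stay within ``tol`` of the
    smallest-amplitude reference (the linear viscoelastic window).

    ``points`` are (gamma0, G', G'') triples at a fixed frequency.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 strain amplitudes")
    pts = sorted(points)
    g0s = np.array([p[0] for p in pts])
    gp = np.array([p[1] for p in pts])
    gpp = np.array([p[2] for p in pts])
    ref = max(abs(gp[0]), abs(gpp[0]), 1e-300)
    dev = np.maximum(np.abs(gp - gp[0]), np.abs(gpp - gpp[0])) / ref
    gamma_max = None
    for i in range(1, len(pts)):
        if dev[i] < tol:
            gamma_max = float(g0s[i])
        else:
            break
    return LinearWindow(gamma_max=gamma_max, ok=gamma_max is not None, deviations=dev)


# --------------------------------------------------------------------------
# Maxwell fits, viscosity
# --------------------------------------------------------------------------


def _fit_time_domain(
    t: np.ndarray, g: np.ndarray, n_modes: int, plateau: bool
) -> MaxwellFit:
    pos = t > 0
    t = t[pos]
    g = g[pos]
    gmax = float(np.max(np.abs(g)))
    # Beyond the first zero crossing the autocorrelation is sampling noise;
    # truncate there (fluids only) and use its spread as the weight floor.
    noise = 0.0
    if not plateau:
        neg = np.flatnonzero(g <= 0)
        if len(neg) and neg[0] >= 4:
            noise = float(np.std(g[neg[0] :]))
            t, g = t[: neg[0]], g[: neg[0]]
    w = 1.0 / (np.abs(g) + max(1e-3 * gmax, 3.0 * noise))
    # NNLS on a dense log-spaced tau grid for initialization
    taus_grid = np.geomspace(max(t[0], 1e-12), t[-1] * 2.0, 40)
    design = np.exp(-t[:, None] / taus_grid[None, :])
    if plateau:
        design = np.column_stack([design, np.ones_like(t)])
    coef, _ = nnls(design * w[:, None], g * w)
    g0 = float(coef[-1]) if plateau else 0.0
    amps = coef[: len(taus_grid)]
    idx = np.argsort(amps * taus_grid)[::-1]
    idx = [i for i in idx if amps[i] > 0][:n_modes]
    if len(idx) < n_modes:
        extra = np.geomspace(t[0], t[-1], n_modes)
        tau0 = np.concatenate([taus_grid[idx], extra])[:n_modes]
        amp0 = np.concatenate([amps[idx], np.full(n_modes, gmax * 0.1)])[:n_modes]
    else:
        tau0 = taus_grid[idx]
        amp0 = amps[idx]
    amp0 = np.maximum(amp0, 1e-8 * gmax)

    def resid(x):
        gi = np.exp(x[:n_modes])
        ti = np.exp(x[n_modes : 2 * n_modes])
        p = np.exp(x[-1]) if plateau else 0.0
        model = p + np.sum(gi[:, None] * np.exp(-t[None, :] / ti[:, None]), axis=0)
        return (model - g) * w

    x0 = np.concatenate(
        [np.log(amp0), np.log(tau0), [np.log(max(g0, 1e-8 * gmax))] if plateau else []]
    )
    # keep relaxation times inside the data window (x3 margin) so no mode can
    # escape below the shortest lag with an unconstrained amplitude
    lo = np.full_like(x0, -np.inf)
    hi = np.full_like(x0, np.inf)
    lo[n_modes : 2 * n_modes] = math.log(t[0] / 3.0)
    hi[n_modes : 2 * n_modes] = math.log(t[-1] * 3.0)
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=4000)
    gi = np.exp(sol.x[:n_modes])
    ti = np.exp(sol.x[n_modes : 2 * n_modes])
    p = float(np.exp(sol.x[-1])) if plateau else 0.0
    model = p + np.sum(gi[:, None] * np.exp(-t[None, :] / ti[:, None]), axis=0)
    rel = float(np.linalg.norm((model - g) * w) / max(np.linalg.norm(g * w), 1e-300))
    # merge near-degenerate modes so tau_i stay strictly ordered
    gi, ti = _merge_modes(gi, ti)
    return MaxwellFit(gi, ti, plateau=p, fit_residual=rel)


def _fit_freq_domain(
    w: np.ndarray, gp: np.ndarray, gpp: np.ndarray, n_modes: int, plateau: bool
) -> MaxwellFit:
    scale = float(np.max(np.abs(gp)) + np.max(np.abs(gpp)))
    tau0 = np.geomspace(1.0 / w[-1], 1.0 / w[0], n_modes)
    amp0 = np.full(n_modes, max(np.max(gp), 1e-6))

    def model(x):
        gi = np.exp(x[:n_modes])
        ti = np.exp(x[n_modes : 2 * n_modes])
        p = np.exp(x[-1]) if plateau else 0.0
        wt = w[None, :] * ti[:, None]
        sp = p + np.sum(gi[:, None] * wt**2 / (1 + wt**2), axis=0)
        lp = np.sum(gi[:, None] * wt / (1 + wt**2), axis=0)
        return sp, lp

    wp = 1.0 / (np.abs(gp) + 1e-3 * scale)
    wl = 1.0 / (np.abs(gpp) + 1e-3 * scale)

    def resid(x):
        sp, lp = model(x)
        return np.concatenate([(sp - gp) * wp, (lp - gpp) * wl])

    x0 = np.concatenate(
        [np.log(amp0), np.log(tau0), [math.log(max(gp[0], 1e-8))] if plateau else []]
    )
    lo = np.full_like(x0, -np.inf)
    hi = np.full_like(x0, np.inf)
    lo[n_modes : 2 * n_modes] = math.log(1.0 / (3.0 * w[-1]))
    hi[n_modes : 2 * n_modes] = math.log(3.0 / w[0])
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=4000)
    gi = np.exp(sol.x[:n_modes])
    ti = np.exp(sol.x[n_modes : 2 * n_modes])
    p = float(np.exp(sol.x[-1])) if plateau else 0.0
    r = resid(sol.x)
    rel = float(np.linalg.norm(r) / max(np.linalg.norm(np.concatenate([gp * wp, gpp * wl])), 1e-300))
    gi, ti = _merge_modes(gi, ti)
    return MaxwellFit(gi, ti, plateau=p, fit_residual=rel)


def _merge_modes(gi: np.ndarray, ti: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Combine modes whose relaxation times collide (< 10% apart)."""
    order = np.argsort(ti)
    gi, ti = gi[order], ti[order]
    out_g, out_t = [gi[0]], [ti[0]]
    for g, t in zip(gi[1:], ti[1:]):
        if t / out_t[-1] < 1.1:
            # amplitude-weighted merge
            gt = out_g[-1] + g
            out_t[-1] = (out_g[-1] * out_t[-1] + g * t) / gt
            out_g[-1] = gt
        else:
            out_g.append(g)
            out_t.append(t)
    return np.array(out_g), np.array(out_t)


def detect_plateau(series: ComplexModulusSeries, frac: float = 0.05) -> bool:
    """True when G*(t) levels off at a finite fraction of G*(0) (a gel)."""
    g0 = float(series.g[0])
    tail = series.g[series.lag_times >= 0.25 * series.lag_times[-1]]
    return g0 > 0 and float(np.mean(tail)) > frac * g0


def fit_maxwell(
    modulus: Union[ComplexModulusSeries, ModulusSpectrum],
    n_modes: Optional[int] = None,
    plateau: Union[bool, str] = "auto",
    max_modes: int = 8,
    improvement_tol: float = 0.05,
    t_min: Optional[float] = None,
) -> MaxwellFit:
    """Fit a generalized Maxwell model to G*(t) or to (G'(w), G''(w)).

    Nonlinear least squares in log-parameters (guaranteeing G_i, tau_i > 0),
    initialized from a non-negative least-squares decomposition on a dense
    log-spaced relaxation-time grid.  With ``n_modes=None`` the mode count
    grows until the residual stops improving by ``improvement_tol``.
    ``plateau='auto'`` adds an equilibrium modulus G0 when the relaxation
    curve visibly levels off (gels).  ``t_min`` drops lags below it before
    fitting (the short-time/long-time split of the relaxation curve).
    """
    if isinstance(modulus, ComplexModulusSeries):
        t = modulus.lag_times
        g = modulus.g
        if t_min is not None:
            keep = t >= t_min
            t, g = t[keep], g[keep]
        if np.max(g) <= 0:
            raise RheologyError("modulus data is non-positive; nothing to fit")
        use_plateau = detect_plateau(modulus) if plateau == "auto" else bool(plateau)
        fitter = lambda n: _fit_time_domain(t, g, n, use_plateau)
    else:
        w, gp, gpp = modulus.omegas, modulus.storage, modulus.loss
        use_plateau = bool(plateau) if plateau != "auto" else False
        fitter = lambda n: _fit_freq_domain(w, gp, gpp, n, use_plateau)

    if n_modes is not None:
        if n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        return fitter(n_modes)
    best = fitter(1)
    for n in range(2, max_modes + 1):
        try:
            cand = fitter(n)
        except Exception:
            break
        if best.fit_residual - cand.fit_residual < improvement_tol * best.fit_residual:
            break
        best = cand
    return best


def modulus_from_relaxation(
    series: ComplexModulusSeries,
    omegas: np.ndarray,
    tail_fit: Optional[MaxwellFit] = None,
    smooth: int = 1,
) -> ModulusSpectrum:
    """Exact Fourier transform of the piecewise-linear G*(t) interpolant.

    G'(w) = w int G(t) sin(wt) dt and G''(w) = w int G(t) cos(wt) dt are
    evaluated segment by segment (Filon-type, no quadrature error for the
    interpolant), so the short-time branch contributes its full
    high-frequency loss.  Beyond the last lag the integral is continued with
    ``tail_fit`` (a Maxwell fit of the long-time branch) when given.
    Low frequencies (below a few / t_max) inherit the noise of the long-lag
    autocorrelation; prefer the fitted spectrum there.  ``smooth > 1``
    averages each modulus over that many points spread over a ~25% frequency
    neighborhood, damping the oscillatory noise of the transform.
    """
    omegas = np.asarray(omegas, float)
    if smooth > 1:
        out_p = np.empty(len(omegas))
        out_l = np.empty(len(omegas))
        for k, w in enumerate(omegas):
            sub = modulus_from_relaxation(
                series, np.geomspace(0.8 * w, 1.25 * w, smooth), tail_fit, smooth=1
            )
            out_p[k] = float(np.mean(sub.storage))
            out_l[k] = float(np.mean(sub.loss))
        return ModulusSpectrum(omegas, out_p, out_l)
    t = series.lag_times
    g = series.g
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        g = np.concatenate([[g[0]], g])
    if tail_fit is not None:
        ext = np.geomspace(t[-1], t[-1] + 20.0 * float(tail_fit.tau_modes.max()), 200)
        t = np.concatenate([t, ext[1:]])
        g = np.concatenate([g, tail_fit.g_of_t(ext[1:])])
    t0, t1 = t[:-1], t[1:]
    g0, g1 = g[:-1], g[1:]
    m = (g1 - g0) / (t1 - t0)
    gp = np.empty(len(omegas))
    gpp = np.empty(len(omegas))
    for k, w in enumerate(omegas):
        s = (1.0 / w) * (g0 * np.cos(w * t0) - g1 * np.cos(w * t1)) + (
            m / w**2
        ) * (np.sin(w * t1) - np.sin(w * t0))
        c = (1.0 / w) * (g1 * np.sin(w * t1) - g0 * np.sin(w * t0)) + (
            m / w**2
        ) * (np.cos(w * t1) - np.cos(w * t0))
        gp[k] = w * np.sum(s)
        gpp[k] = w * np.sum(c)
    return ModulusSpectrum(omegas, gp, gpp)


@dataclass
class BranchFit:
    """Two-branch decomposition of a relaxation curve.

    The short-time branch (bond/cage vibrations, not representable by a few
    positive Maxwell modes because of its ringing) and the long-time branch
    are fitted separately; ``combined`` concatenates both mode sets for
    full-band spectra, while terminal quantities (viscosity contributions,
    terminal slopes) should use ``slow`` alone.
    """

    slow: MaxwellFit
    fast: Optional[MaxwellFit]
    combined: MaxwellFit
    t_split: float


def fit_relaxation_branches(
    series: ComplexModulusSeries,
    t_split: float = 0.5,
    n_modes: Optional[int] = None,
    plateau: Union[bool, str] = "auto",
) -> BranchFit:
    """Fit Maxwell modes separately to the short- and long-time branches.

    ``t_split`` is the boundary between the vibrational short-time range and
    the configurational long-time range of G*(t).  The fast branch gets a
    single effective mode fitted to its positive envelope; if there is no
    usable short-time data the fast branch is skipped.
    """
    t, g = series.lag_times, series.g
    slow = fit_maxwell(series, n_modes=n_modes, plateau=plateau, t_min=t_split)
    sel = (t > 0) & (t < t_split) & (g > 0)
    fast = None
    if np.count_nonzero(sel) >= 3 and float(np.max(g[sel])) > 2 * slow.g_of_t(
        np.array([t_split])
    ):
        # subtract the slow branch so the fast mode fits only the excess
        resid = g[sel] - slow.g_of_t(t[sel])
        ok = resid > 0
        if np.count_nonzero(ok) >= 3:
            fast = _fit_time_domain(t[sel][ok], resid[ok], 1, False)
    if fast is not None:
        combined = MaxwellFit(
            np.concatenate([fast.g_modes, slow.g_modes]),
            np.concatenate([fast.tau_modes, slow.tau_modes]),
            plateau=slow.plateau,
            fit_residual=slow.fit_residual,
        )
    else:
        combined = slow
    return BranchFit(slow=slow, fast=fast, combined=combined, t_split=t_split)


def dynamic_viscosity(
    fit_or_series: Union[MaxwellFit, ComplexModulusSeries],
) -> float:
    """Zero-shear dynamic viscosity eta* = integral of G*(t).

    From a Maxwell fit this is exactly sum_i G_i tau_i.  From a sampled
    relaxation curve it is the trapezoidal integral plus a single-exponential
    tail extrapolation beyond the last lag.  A non-decaying curve (gel)
    yields ``inf``.
    """
    if isinstance(fit_or_series, MaxwellFit):
        return fit_or_series.eta_star
    series = fit_or_series
    t, g = series.lag_times, series.g
    if np.max(np.abs(g)) == 0:
        return 0.0
    if detect_plateau(series):
        warnings.warn("G*(t) does not decay: infinite zero-shear viscosity (gel)")
        return math.inf
    eta = float(np.trapezoid(g, t))
    # exponential tail extrapolation from the last decaying, positive stretch
    tail = (t >= 0.3 * t[-1]) & (g > 0)
    if np.count_nonzero(tail) >= 3:
        slope, intercept = np.polyfit(t[tail], np.log(g[tail]), 1)
        if slope < 0:
            tau = -1.0 / slope
            eta += float(g[tail][-1] * tau)
    return eta


# --------------------------------------------------------------------------
# crossovers & classification
# --------------------------------------------------------------------------


@dataclass
class Crossover:
    omega: float
    below: str  # dominant modulus at lower frequency: "storage" | "loss"
    above: str


def crossover_frequencies(spectrum: ModulusSpectrum) -> list[Crossover]:
    """Frequencies where G' = G'', located by log-log interpolation.

    Each crossover is tagged with which modulus dominates on either side.
    An empty list is a valid outcome (fully viscous fluid or Kelvin-Voigt
    solid with no crossing in the sampled window).
    """
    w = spectrum.omegas
    mask = (spectrum.storage > 0) & (spectrum.loss > 0)
    w, gp, gpp = w[mask], spectrum.storage[mask], spectrum.loss[mask]
    if len(w) < 2:
        return []
    d = np.log10(gp) - np.log10(gpp)
    out = []
    for i in range(len(d) - 1):
        if d[i] == 0.0:
            out.append(
                Crossover(
                    float(w[i]),
                    "loss" if (i > 0 and d[i - 1] < 0) else "storage",
                    "loss" if d[i + 1] < 0 else "storage",
                )
            )
        elif d[i] * d[i + 1] < 0:
            lw = np.log10(w[i]) + (np.log10(w[i + 1]) - np.log10(w[i])) * (
                -d[i] / (d[i + 1] - d[i])
            )
            out.append(
                Crossover(
                    float(10**lw),
                    "loss" if d[i] < 0 else "storage",
                    "loss" if d[i + 1] < 0 else "storage",
                )
            )
    return out


@dataclass
class ResponseClass:
    label: str  # maxwell_fluid | kelvin_voigt_solid | viscous_fluid | indeterminate
    low_freq_storage_slope: float
    storage_dominates_low: bool
    elastic_window: bool


def classify_response(spectrum: ModulusSpectrum) -> ResponseClass:
    """Classify a spectrum as Maxwell fluid, Kelvin-Voigt solid, or viscous.

    Terminal behavior over the lowest sampled frequency decade decides:
    G' slope ~ 2 with G'' dominating -> Maxwell fluid; flat dominant G'
    plateau -> Kelvin-Voigt solid; G'' > G' everywhere with no elastic
    window -> viscous fluid.
    """
    w = spectrum.omegas
    if len(w) < 4 or w[-1] / w[0] < 10.0:
        return ResponseClass("indeterminate", math.nan, False, False)
    low = w <= w[0] * 10.0
    gp_low = spectrum.storage[low]
    gpp_low = spectrum.loss[low]
    valid = gp_low > 0
    if np.count_nonzero(valid) >= 2:
        slope = float(
            np.polyfit(np.log10(w[low][valid]), np.log10(gp_low[valid]), 1)[0]
        )
    else:
        slope = math.nan
    storage_dom_low = bool(np.mean(gp_low) > np.mean(gpp_low))
    elastic_window = bool(np.any(spectrum.storage > spectrum.loss))
    if not math.isnan(slope) and slope < 0.5 and storage_dom_low:
        label = "kelvin_voigt_solid"
    elif not math.isnan(slope) and slope > 1.2 and not storage_dom_low:
        label = "maxwell_fluid"
    elif not elastic_window:
        label = "viscous_fluid"
    else:
        label = "indeterminate"
    return ResponseClass(label, slope, storage_dom_low, elastic_window)


def terminal_slopes(
    fit: MaxwellFit, n_points: int = 20, decade_start_factor: float = 0.1
) -> tuple[float, float, np.ndarray]:
    """Log-log slopes of G' and G'' over the lowest reliable frequency decade.

    The decade ends at ``decade_start_factor / tau_max`` — one decade below
    the slowest fitted relaxation rate, i.e. inside the terminal regime the
    fit can actually resolve.  Returns (slope_storage, slope_loss, omegas).
    """
    tau_max = float(np.max(fit.tau_modes))
    w_hi = decade_start_factor / tau_max
    omegas = np.geomspace(w_hi / 10.0, w_hi, n_points)
    sp = fit.storage(omegas)
    lp = fit.loss(omegas)
    s1 = float(np.polyfit(np.log10(omegas), np.log10(sp), 1)[0])
    s2 = float(np.polyfit(np.log10(omegas), np.log10(lp), 1)[0])
    return s1, s2, omegas
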