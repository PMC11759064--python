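"""Chain structure and dynamics: persistence length, Rg, MSD, profiles.

All routines consume unwrapped coordinates (the engine's trajectories store
periodic image counts precisely so these observables never see box jumps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import Trajectory


@dataclass
class PersistenceResult:
    lp: float  # in units of the mean bond length
    bond_length: float
    lower_bound_only: bool = False  # rigid-rod flag: correlation never decayed


def _chain_index_lists(chain_id: np.ndarray) -> list[np.ndarray]:
    ids = np.unique(chain_id[chain_id >= 0])
    return [np.flatnonzero(chain_id == cid) for cid in ids]


def persistence_length_tangent(
    trajectory: Trajectory, max_sep: Optional[int] = None
) -> PersistenceResult:
    """Persistence length from tangent-tangent correlations along the contour.

    <t(s) . t(s+ds)> is averaged over chains and frames and fitted to
    exp(-ds b / lp) over the initial decay down to 1/e^2 (b = mean bond
    length).  A correlation that never decays below 1/e^2 flags the chains
    as rod-like and returns the largest resolvable lp as a lower bound.
    """
    chains = _chain_index_lists(trajectory.chain_id)
    nb_min = min(len(c) for c in chains) - 1
    if nb_min < 10:
        raise ValueError("need chains with at least 10 bonds")
    max_sep = max_sep or nb_min - 1
    corr = np.zeros(max_sep + 1)
    cnt = np.zeros(max_sep + 1)
    blen = []
    for f in range(trajectory.n_frames):
        pos = trajectory.positions[f]
        for idx in chains:
            bonds = np.diff(pos[idx], axis=0)
            lens = np.linalg.norm(bonds, axis=1)
            blen.append(lens.mean())
            t = bonds / lens[:, None]
            nb = len(t)
            for ds in range(0, min(max_sep, nb - 1) + 1):
                dots = np.sum(t[: nb - ds] * t[ds:], axis=1)
                corr[ds] += dots.sum()
                cnt[ds] += len(dots)
    corr /= np.maximum(cnt, 1)
    b = float(np.mean(blen))
    cut = 1.0 / math.e**2
    decayed = np.flatnonzero(corr <= cut)
    if len(decayed) == 0:
        # rod-like: report a lower bound from the last separation
        ds = np.arange(1, max_sep + 1)
        pos_c = corr[1:] > 0
        if not np.any(pos_c):
            return PersistenceResult(math.inf, b, True)
        slope = np.polyfit(ds[pos_c], np.log(corr[1:][pos_c]), 1)[0]
        lp = -1.0 / slope if slope < 0 else math.inf
        return PersistenceResult(float(lp), b, True)
    # fit anchored at ds=0 (corr = 1 exactly); floor stray non-positive
    # values so an immediate decay (freely jointed limit) stays fittable
    end = max(int(decayed[0]), 1)
    ds = np.arange(0, end + 1)
    vals = np.maximum(corr[: end + 1], 1e-4)
    slope = np.polyfit(ds, np.log(vals), 1)[0]
    lp = -1.0 / slope
    return PersistenceResult(float(lp), b, False)


def persistence_length_angle(theta_interior_deg: float) -> float:
    """Persistence length from the mean interior backbone angle.

    The deflection angle between successive bonds is theta_m = 180 deg -
    theta_interior; lp = -1/ln(cos theta_m) in bond-length units.  The
    fully flexible limit theta_interior = 111.6 deg gives lp ~ 1 bond
    length; theta_interior -> 180 deg diverges (returned as inf).
    """
    if not 90.0 < theta_interior_deg <= 180.0:
        raise ValueError("interior angle must lie in (90, 180] degrees")
    theta_m = math.radians(180.0 - theta_interior_deg)
    c = math.cos(theta_m)
    if c <= 0.0:
        raise ValueError("deflection angle >= 90 degrees: formula undefined")
    if c >= 1.0 - 1e-15:
        warnings.warn("straight-rod limit: persistence length diverges")
        return math.inf
    return -1.0 / math.log(c)


def mean_interior_angle(trajectory: Trajectory) -> float:
    """Mean interior backbone angle (degrees) over chains and frames."""
    chains = _chain_index_lists(trajectory.chain_id)
    angles = []
    for f in range(trajectory.n_frames):
        pos = trajectory.positions[f]
        for idx in chains:
            if len(idx) < 3:
                continue
            a = pos[idx[:-2]] - pos[idx[1:-1]]
            b = pos[idx[2:]] - pos[idx[1:-1]]
            c = np.sum(a * b, axis=1) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
    return float(np.mean(np.concatenate(angles)))


@dataclass
class RgResult:
    per_chain: np.ndarray
    mean: float
    flagged_single_bead: bool = False


def radius_of_gyration(
    positions: np.ndarray, chain_id: np.ndarray
) -> RgResult:
    """Per-chain radius of gyration from one unwrapped frame.

    Rg^2 is the mean squared distance of beads from the chain centroid.
    Single-bead chains return Rg = 0 with a flag.
    """
    chains = _chain_index_lists(chain_id)
    if not chains:
        raise ValueError("no chains present")
    rgs = []
    flagged = False
    for idx in chains:
        sub = positions[idx]
        if len(idx) == 1:
            rgs.append(0.0)
            flagged = True
            continue
        d = sub - sub.mean(axis=0)
        rgs.append(math.sqrt(float(np.mean(np.sum(d * d, axis=1)))))
    rgs = np.array(rgs)
    return RgResult(rgs, float(rgs.mean()), flagged)


def mean_rg_trajectory(trajectory: Trajectory) -> float:
    vals = [
        radius_of_gyration(trajectory.positions[f], trajectory.chain_id).mean
        for f in range(trajectory.n_frames)
    ]
    return float(np.mean(vals))


@dataclass
class MsdResult:
    lags: np.ndarray
    msd: np.ndarray
    exponent: float
    window: tuple[float, float]


def msd_curve(
    trajectory: Trajectory,
    per_chain_center: bool = False,
    max_origins: int = 64,
    species: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-squared displacement on a log-spaced lag grid, multi-origin.

    ``per_chain_center=False`` averages over monomers (the default used for
    the subdiffusion exponent); True uses chain centroids instead.
    """
    pos = trajectory.positions
    if species is not None:
        sel = trajectory.type_id == species
        pos = pos[:, sel]
        cid = trajectory.chain_id[sel]
    else:
        cid = trajectory.chain_id
    if per_chain_center:
        chains = _chain_index_lists(cid)
        pos = np.stack([pos[:, idx].mean(axis=1) for idx in chains], axis=1)
    nf = pos.shape[0]
    if nf < 4:
        raise ValueError("need at least 4 frames")
    lag_idx = np.unique(
        np.round(np.geomspace(1, nf - 1, min(40, nf - 1))).astype(int)
    )
    dt = trajectory.times[1] - trajectory.times[0]
    msd = np.empty(len(lag_idx))
    for k, lag in enumerate(lag_idx):
        origins = np.unique(np.linspace(0, nf - 1 - lag, min(max_origins, nf - lag)).astype(int))
        d = pos[origins + lag] - pos[origins]
        msd[k] = float(np.mean(np.sum(d * d, axis=-1)))
    return lag_idx * dt, msd


def msd_exponent(
    trajectory: Trajectory,
    window: Optional[tuple[float, float]] = None,
    per_chain_center: bool = False,
) -> MsdResult:
    """MSD curve plus the log-log slope alpha over ``window`` (lag times).

    Without an explicit window the central two decades (or what exists) of
    the lag grid are used.
    """
    lags, msd = msd_curve(trajectory, per_chain_center=per_chain_center)
    if window is None:
        lo = lags[0] * (lags[-1] / lags[0]) ** 0.25
        hi = lags[0] * (lags[-1] / lags[0]) ** 0.75
        window = (float(lo), float(hi))
    sel = (lags >= window[0]) & (lags <= window[1]) & (msd > 0)
    if np.count_nonzero(sel) < 3:
        raise ValueError("MSD window outside the available lag range")
    alpha = float(np.polyfit(np.log10(lags[sel]), np.log10(msd[sel]), 1)[0])
    return MsdResult(lags, msd, alpha, window)


def density_profile(
    positions: np.ndarray,
    box_lengths: np.ndarray,
    axis: int = 0,
    n_bins: int = 50,
    selection: Optional[np.ndarray] = None,
    x_range: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin number density along one axis (wrapped coordinates).

    Returns (bin_centers, density).  ``selection`` restricts to a species
    mask; an empty selection yields a zero profile (with a warning).
    The profile integrates back to the particle count exactly.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    x = positions[:, axis]
    if selection is not None:
        x = x[selection]
    lo, hi = x_range if x_range is not None else (0.0, float(box_lengths[axis]))
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    cross = float(np.prod(np.delete(box_lengths, axis)))
    bin_vol = (hi - lo) / n_bins * cross
    if len(x) == 0:
        warnings.warn("empty selection: zero density profile")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / bin_vol
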