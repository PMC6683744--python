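"""Basal-plane detection, projection, ingression depth and curve alignment.

The basal actomyosin network sits at the leading edge of the invaginating
membrane; its plane is found as the most prominent local maximum of the
apicobasal mean-intensity profile beyond an apical exclusion zone (the
cortical signal at the surface would otherwise win).  A short window of
slices centered at that peak is summed to give the top-view projection on
which openings are segmented.  Ingression depth is the apical-to-basal
peak distance; per-sample depth-versus-time curves are aligned by shifting
them along the time axis to minimize their squared differences, and the
average trend is zeroed where it crosses a reference depth (4 µm by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import peak_prominences

from .stack_io import PipelineConfig, VoxelGrid, logger

__all__ = [
    "AxialProfile",
    "IngressionCurve",
    "BasalProjection",
    "axial_profile",
    "locate_basal_peak",
    "project_basal",
    "ingression_depth",
    "align_ingression_curves",
]


@dataclass
class AxialProfile:
    """Mean intensity per z slice, with physical depth positions (µm)."""

    z_positions: np.ndarray
    mean_intensity: np.ndarray
    channel: str = "ch0"

    def __post_init__(self) -> None:
        z = np.asarray(self.z_positions, dtype=float)
        i = np.asarray(self.mean_intensity, dtype=float)
        if z.shape != i.shape or z.ndim != 1:
            raise ValueError("z_positions and mean_intensity must be equal-length 1-D")
        if not np.all(np.diff(z) > 0):
            raise ValueError("z_positions must be strictly increasing")
        self.z_positions, self.mean_intensity = z, i


@dataclass
class IngressionCurve:
    """Furrow depth (µm) versus time (minutes) for one sample."""

    time: np.ndarray
    depth: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.depth, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("time and depth must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        self.time, self.depth = t, d


class BasalProjection(NamedTuple):
    frame: np.ndarray
    z_range: tuple[int, int]  # [lo, hi) slice window actually summed
    truncated: bool


def axial_profile(grid: VoxelGrid, channel: int | str = 0,
                  time_index: int = 0) -> AxialProfile:
    """Mean over (y, x) per z slice, in µm via the z calibration."""
    if grid.shape[1] < 3:
        raise ValueError(f"need a z extent of at least 3 slices, got {grid.shape[1]}")
    c = grid.channel_index(channel)
    prof = grid.intensities[time_index, :, :, :, c].mean(axis=(1, 2))
    name = grid.channel_names[c]
    return AxialProfile(grid.z_positions, prof, channel=name)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of regional maxima, boundary slices included.

    Plateaus report their deepest (last) index; prominences are computed
    on a padded copy so boundary peaks get a finite prominence.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            idx.append(j)  # deepest index of a plateau
        i = j + 1
    return np.asarray(idx, dtype=int)


def locate_basal_peak(profile: AxialProfile,
                      exclusion_apical: float = 2.0) -> tuple[int, float]:
    """Most prominent axial maximum deeper than the apical exclusion zone.

    Returns ``(z_index, depth_um)``.  Ties in prominence break to the
    deepest candidate.  Raises when no local maximum exists beyond the
    exclusion zone ("no basal peak").
    """
    v = profile.mean_intensity
    if v.size < 3:
        raise ValueError("profile must have at least 3 points")
    maxima = _local_maxima(v)
    maxima = maxima[profile.z_positions[maxima] > exclusion_apical]
    if maxima.size == 0:
        raise ValueError(
            f"no basal peak: no local maximum deeper than {exclusion_apical} µm")
    padded = np.concatenate([[v.min() - 1.0], v, [v.min() - 1.0]])
    prom = peak_prominences(padded, maxima + 1)[0]
    best = np.max(prom)
    candidates = maxima[np.isclose(prom, best)]
    z_idx = int(candidates.max())  # deepest of equals
    return z_idx, float(profile.z_positions[z_idx])


def project_basal(grid: VoxelGrid, z_peak: int, n_slices: int = 3,
                  channel: int | str = 0, time_index: int = 0,
                  allow_out_of_range: bool = False) -> BasalProjection:
    """Sum of ``n_slices`` slices centered at the basal peak.

    The window is truncated (and flagged) at stack boundaries.  The
    protocol uses 3–5 slices; other values require an explicit override
    and are logged.
    """
    if not 3 <= n_slices <= 5:
        if not allow_out_of_range:
            raise ValueError("n_slices must be within 3..5 (set allow_out_of_range "
                             "to override)")
        logger.warning("projection window of %d slices overrides the 3-5 protocol",
                       n_slices)
    nz = grid.shape[1]
    if not 0 <= z_peak < nz:
        raise ValueError(f"z_peak {z_peak} outside stack of {nz} slices")
    half = n_slices // 2
    lo = z_peak - half
    hi = lo + n_slices
    truncated = lo < 0 or hi > nz
    lo, hi = max(lo, 0), min(hi, nz)
    c = grid.channel_index(channel)
    frame = grid.intensities[time_index, lo:hi, :, :, c].sum(axis=0)
    if truncated:
        logger.warning("basal projection window truncated to slices [%d, %d)", lo, hi)
    return BasalProjection(frame=frame, z_range=(lo, hi), truncated=truncated)


def ingression_depth(grid: VoxelGrid, channel: int | str = 0,
                     time_index: int = 0,
                     apical_exclusion: float = 2.0) -> float:
    """Apical-to-basal peak distance along z, in µm.

    The apical cortex is the most superficial local maximum of the axial
    profile; the cell base is the most prominent maximum beyond the
    exclusion zone.  Invariant to global intensity scaling.
    """
    prof = axial_profile(grid, channel, time_index)
    maxima = _local_maxima(prof.mean_intensity)
    if maxima.size == 0:
        raise ValueError("no apical peak: profile has no local maximum")
    apical_idx = int(maxima.min())
    basal_idx, basal_z = locate_basal_peak(prof, exclusion_apical=apical_exclusion)
    if basal_idx <= apical_idx:
        raise ValueError("apical peak not superficial to the basal peak")
    return float(basal_z - prof.z_positions[apical_idx])


# ---------------------------------------------------------------------------
# ingression-curve alignment
# ---------------------------------------------------------------------------

def _pair_shift_cost(ref: IngressionCurve, cur: IngressionCurve,
                     shift: float) -> float | None:
    """Mean squared depth difference on the overlapping time support."""
    t0 = max(ref.time[0], cur.time[0] + shift)
    t1 = min(ref.time[-1], cur.time[-1] + shift)
    if t1 <= t0:
        return None
    t = np.linspace(t0, t1, 50)
    d_ref = np.interp(t, ref.time, ref.depth)
    d_cur = np.interp(t, cur.time + shift, cur.depth)
    return float(np.mean((d_ref - d_cur) ** 2))


def _best_shift(ref: IngressionCurve, cur: IngressionCurve, step: float,
                max_shift: float) -> float:
    """Grid search at frame resolution, then parabolic refinement."""
    lo = max(ref.time[0] - cur.time[-1], -max_shift)
    hi = min(ref.time[-1] - cur.time[0], max_shift)
    shifts = np.arange(lo + step, hi - step / 2, step)
    if shifts.size == 0:
        raise ValueError("curves share no overlapping time support at any shift")
    costs = np.array([np.inf if (c := _pair_shift_cost(ref, cur, s)) is None else c
                      for s in shifts])
    if not np.isfinite(costs).any():
        raise ValueError("curves share no overlapping time support at any shift")
    k = int(np.argmin(costs))
    best = shifts[k]
    if 0 < k < len(shifts) - 1 and np.isfinite(costs[k - 1]) and np.isfinite(costs[k + 1]):
        y0, y1, y2 = costs[k - 1], costs[k], costs[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            best = shifts[k] + 0.5 * step * (y0 - y2) / denom
    return float(best)


def align_ingression_curves(
    curves: Sequence[IngressionCurve],
    zero_depth: float = 4.0,
    config: PipelineConfig | None = None,
    max_shift: float | None = None,
) -> tuple[list[float], IngressionCurve, np.ndarray]:
    """Time-align ingression curves and average them.

    Each curve is shifted along the time axis to minimize its squared
    depth difference to the first curve over their overlap; the aligned
    curves are averaged on a common grid, and the output time axis is
    zeroed where the mean curve crosses ``zero_depth`` (linear
    interpolation).  Returns ``(shifts, mean_curve, sd_per_point)``; the
    shift of curve i is the amount added to its time axis.

    A single curve is simply re-zeroed.  Curves that never reach
    ``zero_depth``, or that share no overlap at any shift, raise.
    """
    if config is not None:
        zero_depth = config.zero_depth
    curves = list(curves)
    if not curves:
        raise ValueError("no curves given")
    for c in curves:
        if c.depth.max() < zero_depth or c.depth.min() > zero_depth:
            raise ValueError(
                f"curve {c.sample_id!r} never crosses the zero depth {zero_depth} µm")
    ref = curves[0]
    step = float(np.median(np.diff(ref.time)))
    if max_shift is None:
        max_shift = float(ref.time[-1] - ref.time[0])  # bounded by the record
    shifts = [0.0]
    for cur in curves[1:]:
        shifts.append(_best_shift(ref, cur, step, max_shift))

    t0 = max(c.time[0] + s for c, s in zip(curves, shifts))
    t1 = min(c.time[-1] + s for c, s in zip(curves, shifts))
    if t1 <= t0:
        raise ValueError("no common time support after alignment")
    t = np.arange(t0, t1 + step / 2, step)
    depths = np.stack([np.interp(t, c.time + s, c.depth)
                       for c, s in zip(curves, shifts)])
    mean = depths.mean(axis=0)
    sd = depths.std(axis=0, ddof=0)

    # zero the time axis where the mean curve crosses zero_depth
    above = mean >= zero_depth
    if not above.any() or above.all():
        raise ValueError(f"mean curve does not cross the zero depth {zero_depth} µm")
    k = int(np.argmax(above))
    if k == 0:
        t_zero = t[0]
    else:
        frac = (zero_depth - mean[k - 1]) / (mean[k] - mean[k - 1])
        t_zero = t[k - 1] + frac * (t[k] - t[k - 1])
    mean_curve = IngressionCurve(time=t - t_zero, depth=mean, sample_id="mean")
    return shifts, mean_curve, sd
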