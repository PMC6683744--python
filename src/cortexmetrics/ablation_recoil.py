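"""Post-ablation recoil analysis: mean displacement, saturation, velocity.

A laser cut severs the tensed actomyosin network and the flanking
interfaces recoil; their displacement-versus-time records carry the
mechanical read-outs.  Time zero is anchored to the ablation frame and
displacement is relative to the pre-cut position (identically zero at
t <= 0).  The initial recoil velocity — the slope of a line fitted to the
displacement in the 1–4 s window after the cut — is proportional to the
tension borne by the network before ablation; the maximum displacement is
read where the curve has saturated (125 s by default).

Interpolation onto a common time grid is always linear and never
extrapolates beyond a track's own range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecoilTrack",
    "tracks_from_table",
    "mean_displacement",
    "max_displacement",
    "initial_recoil_velocity",
]


@dataclass
class RecoilTrack:
    """One interface's displacement record after ablation (µm vs s)."""

    track_id: int | str
    times: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.displacement, dtype=float)
        if t.shape != d.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and displacement must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d[t <= 0] != 0):
            raise ValueError("displacement must be 0 at t <= 0 (pre-cut reference)")
        self.times, self.displacement = t, d

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation within the track's range; no extrapolation."""
        t = np.asarray(t, dtype=float)
        if t.min() < self.times[0] - 1e-9 or t.max() > self.times[-1] + 1e-9:
            raise ValueError(
                f"track {self.track_id}: evaluation time outside [{self.times[0]}, "
                f"{self.times[-1]}] s")
        return np.interp(t, self.times, self.displacement)


def tracks_from_table(table: pd.DataFrame) -> list[RecoilTrack]:
    """Build tracks from a (track_id, time_s, displacement_um) table."""
    required = {"track_id", "time_s", "displacement_um"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    tracks = []
    for tid, sub in table.groupby("track_id", sort=True):
        sub = sub.sort_values("time_s")
        tracks.append(RecoilTrack(tid, sub["time_s"].to_numpy(),
                                  sub["displacement_um"].to_numpy()))
    return tracks


class MeanCurve(NamedTuple):
    time: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray


def mean_displacement(tracks: Sequence[RecoilTrack],
                      t_grid: Sequence[float]) -> MeanCurve:
    """Pointwise mean and SD of displacement over tracks on ``t_grid``.

    Each grid point uses the tracks whose time range covers it; ``n``
    records how many.  Tracks whose ranges are pairwise disjoint (no
    common support at all) are rejected.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track list")
    t = np.asarray(t_grid, dtype=float)
    common_lo = max(tr.times[0] for tr in tracks)
    common_hi = min(tr.times[-1] for tr in tracks)
    if common_hi < common_lo:
        raise ValueError("tracks have disjoint time ranges")
    vals = np.full((len(tracks), t.size), np.nan)
    for i, tr in enumerate(tracks):
        inside = (t >= tr.times[0] - 1e-9) & (t <= tr.times[-1] + 1e-9)
        if inside.any():
            vals[i, inside] = np.interp(t[inside], tr.times, tr.displacement)
    n = np.sum(~np.isnan(vals), axis=0)
    if (n == 0).any():
        raise ValueError("some grid points are covered by no track")
    mean = np.nanmean(vals, axis=0)
    sd = np.where(n > 1, np.nanstd(vals, axis=0, ddof=0), 0.0)
    return MeanCurve(time=t, mean=mean, sd=sd, n=n)


def max_displacement(tracks: Sequence[RecoilTrack],
                     t_eval: float = 125.0) -> tuple[np.ndarray, dict]:
    """Displacement of each track at the saturation read-out time.

    Every track must span ``t_eval`` (interpolation within range only).
    Returns per-track values plus a mean/SD/n summary.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track list")
    values = np.array([float(tr.at(t_eval)) for tr in tracks])
    summary = {"t_eval_s": float(t_eval), "mean_um": float(values.mean()),
               "sd_um": float(values.std(ddof=0)), "n": len(values)}
    return values, summary


def initial_recoil_velocity(tracks: Sequence[RecoilTrack],
                            fit_window: tuple[float, float] = (1.0, 4.0),
                            per_track: bool = False) -> float:
    """Initial recoil velocity (µm/s) of one embryo's pooled tracks.

    Least-squares slope of all (t, d) samples falling inside the fit
    window, pooled across the embryo's tracks.  ``per_track`` instead
    averages per-track slopes (each track then needs >= 2 in-window
    samples).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track list")
    lo, hi = fit_window
    if not lo < hi:
        raise ValueError("fit window start must precede its end")

    def window_points(tr: RecoilTrack) -> tuple[np.ndarray, np.ndarray]:
        sel = (tr.times >= lo) & (tr.times <= hi)
        return tr.times[sel], tr.displacement[sel]

    if per_track:
        slopes = []
        for tr in tracks:
            t, d = window_points(tr)
            if t.size < 2:
                raise ValueError(f"track {tr.track_id} has fewer than 2 samples "
                                 f"in [{lo}, {hi}] s")
            slopes.append(np.polyfit(t, d, 1)[0])
        return float(np.mean(slopes))

    ts = np.concatenate([window_points(tr)[0] for tr in tracks])
    ds = np.concatenate([window_points(tr)[1] for tr in tracks])
    if ts.size < 2 or np.unique(ts).size < 2:
        raise ValueError(f"fewer than 2 distinct samples inside [{lo}, {hi}] s")
    return float(np.polyfit(ts, ds, 1)[0])
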