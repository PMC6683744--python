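"""Ground-truth-annotated synthetic scenes for every pipeline stage.

The generators emulate the imaging regimes the pipeline quantifies:

* a 2-D basal network of bright fibers enclosing dark polygonal openings,
  in the three stagings seen during cellularization — diffuse ``priming``,
  angular ``hexagonal``, round ``ring`` — plus a randomized ``meshwork``;
* time-lapse constriction at controlled area rates inside an activated
  sub-region, against a control remainder;
* an embryo z-stack with an apical cortical signal and a basally peaked
  axial intensity profile;
* post-ablation interface displacement tracks with saturating
  single-exponential kinetics;
* high-resolution fiber images of known width and intensity.

Every scene returns its :class:`~cortexmetrics.stack_io.SceneTruth`:
analytic areas, angularity, rates, velocities and widths computed from the
exact vector geometry before rasterization.  Openings are rendered as
anti-aliased polygons (supersampled coverage) so sub-pixel truth areas are
meaningful.  Noise layering order is fixed: Poisson shot noise, then
additive Gaussian noise, then Gaussian blur; with all three disabled the
image is exactly the analytic scene.  All stochastic draws flow from a
single ``numpy`` generator seeded per call, so identical (params, seed)
give bit-identical outputs.
"""

from __future__ import annotations

import math
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely.affinity
from scipy.ndimage import gaussian_filter
from scipy.special import ellipe
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .stack_io import SceneTruth, VoxelGrid

__all__ = [
    "make_network_frame",
    "make_constriction_movie",
    "make_embryo_zstack",
    "make_recoil_tracks",
    "make_fiber_image",
    "polygon_angularity",
    "apply_noise",
]

PHASES = ("priming", "hexagonal", "ring", "meshwork")
_SUPERSAMPLE = 4
_CIRCLE_VERTICES = 256


# ---------------------------------------------------------------------------
# exact geometry helpers (vector truth, independent of any raster)
# ---------------------------------------------------------------------------

def _polygon_moments(verts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and per-area central second moments of a polygon.

    Closed-form Green's-theorem sums over the vertex list (y, x); returns
    (area, centroid, covariance) with covariance the 2x2 matrix of
    normalized central second moments [[myy, myx], [myx, mxx]].
    """
    v = np.asarray(verts, dtype=float)
    y, x = v[:, 0], v[:, 1]
    y1, x1 = np.roll(y, -1), np.roll(x, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    if area < 0:  # normalize orientation
        return _polygon_moments(v[::-1])
    cx = ((x + x1) * cross).sum() / (6 * area)
    cy = ((y + y1) * cross).sum() / (6 * area)
    # second moments about the origin
    ixx = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0  # integral y^2 dA
    iyy = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0  # integral x^2 dA
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    myy = ixx / area - cy * cy
    mxx = iyy / area - cx * cx
    myx = ixy / area - cx * cy
    return float(area), np.array([cy, cx]), np.array([[myy, myx], [myx, mxx]])


def _ellipse_perimeter_exact(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes a >= b (elliptic integral)."""
    if a == 0:
        return 0.0
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m))


def polygon_angularity(poly: Polygon | np.ndarray) -> float:
    """Analytic angularity of a polygonal opening.

    The squared ratio of the convex-hull perimeter to the perimeter of the
    ellipse sharing the region's moment-equivalent major and minor axes.
    Exactly 1 for a circle; larger for angular shapes.
    """
    if isinstance(poly, Polygon):
        verts = np.asarray(poly.exterior.coords)[:-1][:, ::-1]  # (x,y)->(y,x)
        hull_perimeter = poly.convex_hull.exterior.length
    else:
        verts = np.asarray(poly, dtype=float)
        hull_perimeter = Polygon(verts[:, ::-1]).convex_hull.exterior.length
    _, _, cov = _polygon_moments(verts)
    eigvals = np.linalg.eigvalsh(cov)
    b, a = 2.0 * np.sqrt(np.maximum(eigvals, 0.0))
    return (hull_perimeter / _ellipse_perimeter_exact(a, b)) ** 2


def _regular_polygon(center_yx: tuple[float, float], circumradius: float,
                     n_sides: int, phase_deg: float = 0.0) -> np.ndarray:
    cy, cx = center_yx
    ang = np.deg2rad(phase_deg) + 2 * np.pi * np.arange(n_sides) / n_sides
    return np.column_stack([cy + circumradius * np.sin(ang),
                            cx + circumradius * np.cos(ang)])


# ---------------------------------------------------------------------------
# rasterization and noise
# ---------------------------------------------------------------------------

def _render_polygons(shape_yx: tuple[int, int], polys: Sequence[np.ndarray],
                     fill: float, base: float, pixel_size: float) -> np.ndarray:
    """Rasterize filled polygons (µm coords) with supersampled coverage."""
    s = _SUPERSAMPLE
    ny, nx = shape_yx
    canvas = np.full((ny * s, nx * s), base, dtype=float)
    for verts in polys:
        vy = (np.asarray(verts)[:, 0] / pixel_size + 0.5) * s - 0.5
        vx = (np.asarray(verts)[:, 1] / pixel_size + 0.5) * s - 0.5
        rr, cc = draw_polygon(vy, vx, shape=canvas.shape)
        canvas[rr, cc] = fill
    return canvas.reshape(ny, s, nx, s).mean(axis=(1, 3))


def apply_noise(image: np.ndarray, noise: Mapping[str, Any] | None,
                rng: np.random.Generator, pixel_size: float) -> np.ndarray:
    """Poisson shot noise, then additive Gaussian noise, then Gaussian blur.

    ``noise`` keys (all optional; absent or falsy disables the layer):
    ``peak_photons`` — Poisson scale such that the image maximum maps to
    this expected photon count (peak SNR = sqrt(peak_photons));
    ``gaussian_sd`` — additive read-noise SD as a fraction of the image
    maximum; ``blur_sigma_um`` — PSF sigma in µm.
    """
    out = np.asarray(image, dtype=float)
    if not noise:
        return out
    peak = float(out.max()) if out.size else 0.0
    photons = noise.get("peak_photons")
    if photons:
        if photons <= 0:
            raise ValueError("peak_photons must be > 0")
        if peak > 0:
            out = rng.poisson(out / peak * photons).astype(float) * (peak / photons)
    gsd = noise.get("gaussian_sd")
    if gsd:
        if gsd <= 0:
            raise ValueError("gaussian_sd must be > 0")
        out = out + rng.normal(0.0, gsd * peak, size=out.shape)
    blur = noise.get("blur_sigma_um")
    if blur:
        out = gaussian_filter(out, sigma=blur / pixel_size)
    return np.clip(out, 0.0, None)


def _single_frame_grid(frame: np.ndarray, pixel_size: float,
                       channel: str = "myosin") -> VoxelGrid:
    return VoxelGrid(frame[np.newaxis, np.newaxis, :, :, np.newaxis],
                     pixel_size_xy=pixel_size, channel_names=[channel])


# ---------------------------------------------------------------------------
# network scenes
# ---------------------------------------------------------------------------

def _lattice_geometry(phase: str, grid_pitch: float, opening_scale: float,
                      fiber_width: float, n_cells: tuple[int, int],
                      rng: np.random.Generator | None = None,
                      jitter: float = 0.15) -> tuple[list[Polygon], tuple[float, float]]:
    """Opening polygons (µm) on a honeycomb lattice, plus field size (µm).

    Cells are pointy-top hexagons with apothem ``grid_pitch / 2``; the
    opening inscribed in each cell has apothem
    ``opening_scale * (grid_pitch - fiber_width) / 2`` so adjacent openings
    are separated by one fiber width at ``opening_scale = 1``.
    """
    n_rows, n_cols = n_cells
    pitch = grid_pitch
    cell_r = pitch / math.sqrt(3.0)  # cell circumradius
    margin = pitch  # bright cortex band so no opening touches the border
    row_step = 1.5 * cell_r
    centers = []
    for r in range(n_rows):
        for c in range(n_cols):
            cy = margin + cell_r + r * row_step
            cx = margin + pitch / 2 + c * pitch + (pitch / 2 if r % 2 else 0.0)
            centers.append((cy, cx))
    height = margin + cell_r + (n_rows - 1) * row_step + cell_r + margin
    width = margin + pitch * n_cols + pitch / 2 + margin

    apothem = opening_scale * (pitch - fiber_width) / 2.0
    open_r = apothem * 2.0 / math.sqrt(3.0)
    polys: list[Polygon] = []
    if phase == "hexagonal":
        for cen in centers:
            polys.append(Polygon(_regular_polygon(cen, open_r, 6, 90.0)[:, ::-1]))
    elif phase == "ring":
        for cen in centers:
            polys.append(Polygon(
                _regular_polygon(cen, apothem, _CIRCLE_VERTICES)[:, ::-1]))
    elif phase == "meshwork":
        assert rng is not None
        # jitter the shared lattice vertices once, then shrink each cell
        vert_map: dict[tuple[int, int], np.ndarray] = {}

        def jittered(v: np.ndarray) -> np.ndarray:
            key = (round(v[0] * 1e6), round(v[1] * 1e6))
            if key not in vert_map:
                vert_map[key] = v + rng.uniform(-jitter * cell_r, jitter * cell_r, 2)
            return vert_map[key]

        for cen in centers:
            cell = _regular_polygon(cen, cell_r, 6, 90.0)
            jit = np.array([jittered(v) for v in cell])
            poly = Polygon(jit[:, ::-1]).buffer(-fiber_width / 2.0, join_style=2)
            if opening_scale != 1.0:
                poly = shapely.affinity.scale(poly, opening_scale, opening_scale)
            polys.append(poly)
    else:
        raise ValueError(f"phase {phase!r} has no lattice geometry")
    return polys, (height, width)


def make_network_frame(
    phase: str,
    grid_pitch: float = 8.0,
    opening_scale: float = 1.0,
    fiber_width: float = 1.0,
    image_size: tuple[int, int] | None = None,
    noise_params: Mapping[str, Any] | None = None,
    seed: int = 0,
    n_cells: tuple[int, int] = (8, 8),
    pixel_size_xy: float = 0.1,
    fiber_intensity: float = 1.0,
    opening_intensity: float = 0.05,
) -> tuple[VoxelGrid, SceneTruth]:
    """One basal-network frame plus per-opening ground truth.

    ``hexagonal`` renders a honeycomb of hexagonal openings, ``ring``
    circles on the same lattice, ``meshwork`` a vertex-jittered thin mesh,
    and ``priming`` low-contrast filtered noise without openings.  Units:
    µm for pitch/width, intensities arbitrary.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    if not grid_pitch > 2 * fiber_width:
        raise ValueError(
            f"grid_pitch ({grid_pitch}) must exceed twice the fiber width "
            f"({fiber_width}): lattice geometrically infeasible")
    if min(n_cells) < 3:
        raise ValueError("need at least a 3x3 block of interior cells")
    rng = np.random.default_rng(seed)

    if phase == "priming":
        ny, nx = image_size or (256, 256)
        base = gaussian_filter(rng.standard_normal((ny, nx)), sigma=2.0 / pixel_size_xy * 0.1)
        span = base.max() - base.min()
        frame = fiber_intensity * (0.45 + 0.1 * (base - base.min()) / (span or 1.0))
        frame = apply_noise(frame, noise_params, rng, pixel_size_xy)
        truth = SceneTruth(seed=seed, phase=phase,
                           params={"pixel_size_xy": pixel_size_xy})
        return _single_frame_grid(frame, pixel_size_xy), truth

    polys, (h_um, w_um) = _lattice_geometry(phase, grid_pitch, opening_scale,
                                            fiber_width, n_cells, rng)
    ny = image_size[0] if image_size else int(round(h_um / pixel_size_xy))
    nx = image_size[1] if image_size else int(round(w_um / pixel_size_xy))
    verts = [np.asarray(p.exterior.coords)[:-1][:, ::-1] for p in polys]
    frame = _render_polygons((ny, nx), verts, fill=opening_intensity,
                             base=fiber_intensity, pixel_size=pixel_size_xy)
    frame = apply_noise(frame, noise_params, rng, pixel_size_xy)

    if phase == "ring":
        apothem = opening_scale * (grid_pitch - fiber_width) / 2.0
        areas = [math.pi * apothem ** 2] * len(polys)
        angularity = [1.0] * len(polys)
    else:
        areas = [p.area for p in polys]
        angularity = [polygon_angularity(p) for p in polys]
    centers = [(p.centroid.y, p.centroid.x) for p in polys]
    truth = SceneTruth(
        seed=seed, phase=phase,
        opening_centers=centers,
        true_areas=[areas],
        true_angularity=angularity,
        params={"grid_pitch": grid_pitch, "opening_scale": opening_scale,
                "fiber_width": fiber_width, "n_cells": list(n_cells),
                "pixel_size_xy": pixel_size_xy},
    )
    return _single_frame_grid(frame, pixel_size_xy), truth


def make_constriction_movie(
    phase: str = "ring",
    base_params: Mapping[str, Any] | None = None,
    control_rate: float = 0.0,
    activated_rate: float = 0.65,
    activated_region: tuple[float, float, float, float] | None = None,
    n_frames: int = 5,
    frame_interval: float = 30.0,
    seed: int = 0,
    noise_params: Mapping[str, Any] | None = None,
) -> tuple[VoxelGrid, SceneTruth]:
    """Time-lapse of openings constricting at controlled area rates.

    Each opening's truth area follows ``A(t) = A0 - rate * t`` with the
    rate (µm²/min) chosen by whether its center lies inside
    ``activated_region`` (a (y0, x0, y1, x1) rectangle in µm; default the
    left half of the field).  Openings shrink isotropically about their
    centers; generation refuses movies in which any area would reach zero.
    """
    if control_rate < 0 or activated_rate < 0:
        raise ValueError("constriction rates must be >= 0")
    params = dict(base_params or {})
    params.setdefault("grid_pitch", 8.0)
    params.setdefault("fiber_width", 1.0)
    params.setdefault("n_cells", (6, 6))
    params.setdefault("pixel_size_xy", 0.15)
    px = params["pixel_size_xy"]
    rng = np.random.default_rng(seed)

    polys, (h_um, w_um) = _lattice_geometry(
        phase, params["grid_pitch"], params.get("opening_scale", 1.0),
        params["fiber_width"], tuple(params["n_cells"]),
        rng if phase == "meshwork" else None)
    if activated_region is None:
        activated_region = (0.0, 0.0, h_um, w_um / 2.0)
    y0, x0, y1, x1 = activated_region

    centers = [(p.centroid.y, p.centroid.x) for p in polys]
    if phase == "ring":
        apothem = params.get("opening_scale", 1.0) * (params["grid_pitch"] - params["fiber_width"]) / 2.0
        areas0 = [math.pi * apothem ** 2] * len(polys)
    else:
        areas0 = [p.area for p in polys]
    rates = [activated_rate if (y0 <= cy <= y1 and x0 <= cx <= x1) else control_rate
             for cy, cx in centers]

    t_last_min = (n_frames - 1) * frame_interval / 60.0
    for a0, rate in zip(areas0, rates):
        if a0 - rate * t_last_min <= 0:
            raise ValueError(
                f"opening area would reach zero before the last frame "
                f"(A0={a0:.2f} µm², rate={rate} µm²/min, t={t_last_min:.2f} min)")

    ny, nx = int(round(h_um / px)), int(round(w_um / px))
    frames, true_areas = [], []
    fiber_int = params.get("fiber_intensity", 1.0)
    open_int = params.get("opening_intensity", 0.05)
    for k in range(n_frames):
        t_min = k * frame_interval / 60.0
        frame_polys, frame_areas = [], []
        for poly, (cy, cx), a0, rate in zip(polys, centers, areas0, rates):
            a_t = a0 - rate * t_min
            s = math.sqrt(a_t / a0)
            scaled = shapely.affinity.scale(poly, s, s, origin=(cx, cy))
            frame_polys.append(np.asarray(scaled.exterior.coords)[:-1][:, ::-1])
            frame_areas.append(a_t)
        img = _render_polygons((ny, nx), frame_polys, fill=open_int,
                               base=fiber_int, pixel_size=px)
        frames.append(apply_noise(img, noise_params, rng, px))
        true_areas.append(frame_areas)

    stack = np.stack(frames)[:, np.newaxis, :, :, np.newaxis]
    grid = VoxelGrid(stack, pixel_size_xy=px, frame_interval=frame_interval,
                     channel_names=["myosin"])
    truth = SceneTruth(
        seed=seed, phase=phase, opening_centers=centers, true_areas=true_areas,
        true_angularity=[polygon_angularity(p) if phase != "ring" else 1.0
                         for p in polys],
        constriction_rate={"control": control_rate, "activated": activated_rate},
        activated_region=tuple(activated_region),
        params={**params, "n_frames": n_frames, "frame_interval": frame_interval},
    )
    return grid, truth


# ---------------------------------------------------------------------------
# embryo z-stack
# ---------------------------------------------------------------------------

def make_embryo_zstack(
    basal_depth: float,
    apical_amp: float = 1.0,
    basal_amp: float = 3.0,
    axial_sigma: float = 1.0,
    z_step: float = 0.5,
    n_slices: int = 30,
    noise: Mapping[str, Any] | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (64, 64),
    pixel_size_xy: float = 0.3,
) -> tuple[VoxelGrid, SceneTruth]:
    """Axial two-peak stack: apical cortex at z = 0, basal network deeper.

    The mean axial profile is a sum of two Gaussians of width
    ``axial_sigma`` (µm): an apical one centered at z = 0 and a basal one
    at ``basal_depth``.  The noiseless profile's local maximum falls within
    half a z-step of the planted depth.
    """
    z = np.arange(n_slices) * z_step
    if not 0 < basal_depth <= z[-1]:
        raise ValueError(f"basal_depth {basal_depth} µm outside stack range (0, {z[-1]}]")
    profile = (apical_amp * np.exp(-z ** 2 / (2 * axial_sigma ** 2))
               + basal_amp * np.exp(-(z - basal_depth) ** 2 / (2 * axial_sigma ** 2)))
    interior = (z > axial_sigma) & (z < z[-1])
    peak_idx = np.argmax(np.where(interior, profile, -np.inf))
    if abs(z[peak_idx] - basal_depth) > z_step / 2 + 1e-9:
        raise ValueError("basal amplitude too low: basal peak not resolvable "
                         "against the apical tail")
    rng = np.random.default_rng(seed)
    ny, nx = image_size
    stack = np.broadcast_to(profile[:, None, None], (n_slices, ny, nx)).copy()
    noisy = np.stack([apply_noise(stack[i], noise, rng, pixel_size_xy)
                      for i in range(n_slices)])
    grid = VoxelGrid(noisy[np.newaxis, :, :, :, np.newaxis],
                     pixel_size_xy=pixel_size_xy, z_step=z_step,
                     channel_names=["myosin"])
    truth = SceneTruth(seed=seed, basal_depth=basal_depth,
                       params={"apical_amp": apical_amp, "basal_amp": basal_amp,
                               "axial_sigma": axial_sigma, "z_step": z_step,
                               "n_slices": n_slices})
    return grid, truth


# ---------------------------------------------------------------------------
# recoil tracks
# ---------------------------------------------------------------------------

def make_recoil_tracks(
    d_max: float,
    tau: float,
    n_tracks: int = 10,
    t_grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    saturation_time: float = 125.0,
) -> tuple[pd.DataFrame, SceneTruth]:
    """Post-ablation displacement tracks with saturating kinetics.

    Each track follows ``d(t) = d_max * (1 - exp(-t / tau))`` plus i.i.d.
    Gaussian noise of SD ``noise_sd`` (µm) at t > 0; displacement at
    t <= 0 is identically 0 (pre-cut reference).  Truth records the initial
    recoil velocity ``v0 = d_max / tau`` and the displacement at the
    saturation read-out time.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if n_tracks < 1:
        raise ValueError("need at least one track")
    if t_grid is None:
        t_grid = np.arange(0.0, saturation_time + 1.0, 1.0)
    t = np.asarray(t_grid, dtype=float)
    if 0.0 not in t:
        raise ValueError("t_grid must include 0")
    if t.max() < saturation_time:
        raise ValueError(
            f"t_grid must extend to the saturation time ({saturation_time} s)")
    rng = np.random.default_rng(seed)
    rows = []
    for tid in range(n_tracks):
        d = d_max * (1.0 - np.exp(-np.maximum(t, 0.0) / tau))
        if noise_sd > 0:
            eps = rng.normal(0.0, noise_sd, size=t.shape)
            d = np.where(t > 0, d + eps, 0.0)
        d[t <= 0] = 0.0
        for ti, di in zip(t, d):
            rows.append({"track_id": tid, "time_s": ti, "displacement_um": di})
    table = pd.DataFrame(rows)
    truth = SceneTruth(
        seed=seed,
        recoil={"d_max": d_max, "tau": tau, "v0": d_max / tau,
                "d_saturation": d_max * (1.0 - math.exp(-saturation_time / tau)),
                "saturation_time": saturation_time},
        params={"n_tracks": n_tracks, "noise_sd": noise_sd},
    )
    return table, truth


# ---------------------------------------------------------------------------
# fiber images
# ---------------------------------------------------------------------------

def make_fiber_image(
    widths: Sequence[float],
    intensities: Sequence[float] | None = None,
    background_level: float = 0.1,
    reference_intensity: float | None = None,
    image_size: tuple[int, int] = (256, 256),
    noise: Mapping[str, Any] | None = None,
    seed: int = 0,
    pixel_size_xy: float = 0.015,
    angles_deg: Sequence[float] | None = None,
    overlap_tolerance: float = 0.0,
) -> tuple[VoxelGrid, SceneTruth]:
    """Straight fibers of known width and peak intensity over a background.

    Fibers are rectangles of the stated width (µm) at the stated angles,
    evenly spaced down the field; the first fiber is the designated single
    reference unless ``reference_intensity`` is given explicitly.  Default
    calibration is 15 nm/px, the sampling of the high-resolution regime.
    """
    widths = list(widths)
    if not widths:
        raise ValueError("need at least one fiber width")
    intensities = list(intensities) if intensities is not None else [1.0] * len(widths)
    if len(intensities) != len(widths):
        raise ValueError("widths and intensities must have equal length")
    for w in widths:
        if w < 2 * pixel_size_xy:
            raise ValueError(
                f"fiber width {w} µm is below 2 px at {pixel_size_xy} µm/px")
    angles = list(angles_deg) if angles_deg is not None else [0.0] * len(widths)
    if len(angles) != len(widths):
        raise ValueError("angles_deg must match widths length")
    rng = np.random.default_rng(seed)
    ny, nx = image_size
    h_um, w_um = ny * pixel_size_xy, nx * pixel_size_xy

    n = len(widths)
    row_centers = [(i + 1) * h_um / (n + 1) for i in range(n)]
    length = 0.8 * min(h_um, w_um)
    polys = []
    for cy, w, ang in zip(row_centers, widths, angles):
        rect = Polygon([(-length / 2, -w / 2), (length / 2, -w / 2),
                        (length / 2, w / 2), (-length / 2, w / 2)])
        rect = shapely.affinity.rotate(rect, ang, origin=(0, 0))
        polys.append(shapely.affinity.translate(rect, xoff=w_um / 2, yoff=cy))
    for i in range(n):
        for j in range(i + 1, n):
            if polys[i].intersection(polys[j]).area > overlap_tolerance:
                raise ValueError(f"fibers {i} and {j} overlap beyond tolerance")

    frame = np.full((ny, nx), background_level, dtype=float)
    s = _SUPERSAMPLE
    canvas = np.zeros((ny * s, nx * s))
    for poly, inten in zip(polys, intensities):
        verts = np.asarray(poly.exterior.coords)[:-1]
        vy = (verts[:, 1] / pixel_size_xy + 0.5) * s - 0.5
        vx = (verts[:, 0] / pixel_size_xy + 0.5) * s - 0.5
        rr, cc = draw_polygon(vy, vx, shape=canvas.shape)
        canvas[rr, cc] = inten
    frame = frame + canvas.reshape(ny, s, nx, s).mean(axis=(1, 3))
    frame = apply_noise(frame, noise, rng, pixel_size_xy)

    ref = reference_intensity if reference_intensity is not None else intensities[0]
    truth = SceneTruth(
        seed=seed,
        fibers={"widths_um": widths, "intensities": intensities,
                "angles_deg": angles, "background_level": background_level,
                "reference_intensity": ref, "reference_index":
                    None if reference_intensity is not None else 0,
                "row_centers_um": row_centers},
        params={"pixel_size_xy": pixel_size_xy, "image_size": list(image_size)},
    )
    return _single_frame_grid(frame, pixel_size_xy, channel="actin"), truth
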