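"""Per-opening shape statistics and time-resolved contractility measures.

The central shape descriptor is *angularity*: the square of the ratio of
the convex-hull perimeter of an opening to the perimeter of the ellipse
that shares the opening's moment-equivalent major and minor axes.  A
circle scores exactly 1; angular shapes score higher (regular hexagon
≈ 1.094, square ≈ 1.216), making the statistic a sensitive detector of
the hexagonal-to-ring transition of the basal network.

Contractility is read out from segmented time-lapse frames: mean opening
area per region over time, the control/activated fold change, linear
constriction rates, and the basal myosin-II intensity fold change after
photoactivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ellipe
from shapely.geometry import MultiPoint
from skimage import measure, morphology

from . import basal_geometry
from .stack_io import LabelImage, PipelineConfig, VoxelGrid, logger

__all__ = [
    "OpeningShape",
    "KineticsSeries",
    "opening_shape",
    "all_opening_shapes",
    "ellipse_perimeter",
    "area_series",
    "constriction_fold_change",
    "constriction_rate",
    "myosin_fold_change",
    "shape_vs_depth",
]


@dataclass
class OpeningShape:
    """Morphometrics of one segmented basal opening (physical units)."""

    label: int
    area: float                 # µm²
    convex_perimeter: float     # µm, perimeter of the convex hull
    major_axis: float           # µm, full moment-ellipse major axis
    minor_axis: float           # µm
    ellipse_perimeter: float    # µm
    angularity: float           # (convex_perimeter / ellipse_perimeter)²
    centroid: tuple[float, float]  # (y, x) µm

    def __post_init__(self) -> None:
        if not (self.area > 0 and self.convex_perimeter > 0
                and self.ellipse_perimeter > 0):
            raise ValueError("area and perimeters must be > 0")
        if not self.major_axis >= self.minor_axis > 0:
            raise ValueError("require major_axis >= minor_axis > 0")

    def as_record(self) -> dict:
        return {"label": self.label, "area_um2": self.area,
                "convex_perimeter_um": self.convex_perimeter,
                "major_axis_um": self.major_axis, "minor_axis_um": self.minor_axis,
                "ellipse_perimeter_um": self.ellipse_perimeter,
                "angularity": self.angularity,
                "centroid_y_um": self.centroid[0], "centroid_x_um": self.centroid[1]}


@dataclass
class KineticsSeries:
    """A time series of a contractility read-out.

    ``kind`` is one of mean_area, normalized_area, fold_change, intensity;
    ``n_regions`` counts the openings (or stacks) entering each point.
    """

    time: np.ndarray
    value: np.ndarray
    kind: str
    n_regions: np.ndarray = field(default=None)  # type: ignore[assignment]
    time_unit: str = "min"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.n_regions is None:
            self.n_regions = np.ones_like(self.time, dtype=int)
        self.n_regions = np.asarray(self.n_regions, dtype=int)
        if not (self.time.shape == self.value.shape == self.n_regions.shape):
            raise ValueError("time, value and n_regions must have equal lengths")
        if (self.n_regions < 1).any():
            raise ValueError("n_regions must be >= 1 wherever defined")

    def normalized(self) -> "KineticsSeries":
        """Series divided by its initial value."""
        if self.value[0] == 0:
            raise ValueError("cannot normalize: initial value is zero")
        return KineticsSeries(self.time, self.value / self.value[0],
                              kind="normalized_area", n_regions=self.n_regions,
                              time_unit=self.time_unit)


# ---------------------------------------------------------------------------
# shape statistics
# ---------------------------------------------------------------------------

def ellipse_perimeter(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes ``a >= b >= 0`` (µm).

    Evaluated via the complete elliptic integral of the second kind;
    reduces to 2πa for a circle and to 4a for the degenerate flat ellipse.
    """
    if b < 0 or a < b:
        raise ValueError("require a >= b >= 0")
    if a == 0:
        raise ValueError("semi-major axis must be > 0")
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m))


def _subpixel_hull_perimeter(mask: np.ndarray, pixel_size: float) -> float:
    """Convex-hull perimeter of the iso-level-0.5 boundary contour, µm.

    The hull is taken over the sub-pixel contour rather than pixel centers
    to cut rasterization bias in the perimeter.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("empty region: no boundary contour")
    pts = np.vstack(contours) - 1.0  # undo padding
    hull = MultiPoint([(p[1], p[0]) for p in pts]).convex_hull
    return float(hull.exterior.length * pixel_size)


def opening_shape(labels: LabelImage, label_id: int) -> OpeningShape:
    """Area, hull perimeter, moment-ellipse axes and angularity of one opening.

    The major and minor axes are those of the ellipse with the same
    normalized second central moments as the pixel region (the standard
    region-properties convention).
    """
    arr = labels.labels
    if labels.border_excluded and label_id in labels.border_labels:
        raise ValueError(f"label {label_id} touches the frame border and is excluded")
    mask = arr == label_id
    n_px = int(mask.sum())
    if n_px == 0:
        raise KeyError(f"label {label_id} not present")
    if n_px < 5:
        raise ValueError(f"label {label_id} is degenerate ({n_px} px)")
    px = labels.pixel_size_xy
    props = measure.regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length * px
    minor = props.axis_minor_length * px
    if minor <= 0:
        raise ValueError(f"label {label_id} is degenerate (zero minor axis)")
    hull_p = _subpixel_hull_perimeter(mask, px)
    ell_p = ellipse_perimeter(major / 2.0, minor / 2.0)
    cy, cx = props.centroid
    return OpeningShape(
        label=int(label_id), area=n_px * px * px, convex_perimeter=hull_p,
        major_axis=major, minor_axis=minor, ellipse_perimeter=ell_p,
        angularity=(hull_p / ell_p) ** 2, centroid=(cy * px, cx * px))


def all_opening_shapes(labels: LabelImage) -> list[OpeningShape]:
    """Shapes of every non-border (or all, if not excluded) opening."""
    shapes = []
    for lid in labels.label_ids:
        try:
            shapes.append(opening_shape(labels, lid))
        except ValueError as exc:
            logger.warning("skipping label %d: %s", lid, exc)
    return shapes


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def area_series(label_maps: Sequence[LabelImage],
                region: tuple[float, float, float, float] | None,
                times: Sequence[float],
                normalize: bool = False,
                time_unit: str = "min") -> KineticsSeries:
    """Mean opening area per frame for openings centered inside ``region``.

    ``region`` is a (y0, x0, y1, x1) rectangle in µm (None selects all
    openings); membership is by centroid.  With ``normalize`` the series
    is divided by its initial value, so it starts at exactly 1.
    """
    times = np.asarray(times, dtype=float)
    if len(label_maps) != times.size:
        raise ValueError("one time point per label map required")
    means, counts = [], []
    for k, lab in enumerate(label_maps):
        px = lab.pixel_size_xy
        areas = []
        for lid in lab.label_ids:
            mask = lab.labels == lid
            cy, cx = (np.argwhere(mask).mean(axis=0)) * px
            if region is None or (region[0] <= cy <= region[2]
                                  and region[1] <= cx <= region[3]):
                areas.append(mask.sum() * px * px)
        if not areas:
            if k == 0:
                raise ValueError("no openings inside the region at the first frame")
            logger.warning("no openings inside region at frame %d", k)
            areas = [np.nan]
        means.append(float(np.mean(areas)))
        counts.append(max(len(areas), 1))
    series = KineticsSeries(times, means, kind="mean_area",
                            n_regions=counts, time_unit=time_unit)
    return series.normalized() if normalize else series


def constriction_fold_change(control: KineticsSeries,
                             activated: KineticsSeries) -> KineticsSeries:
    """Per-time-point mean area in the control region over the activated one."""
    if not np.allclose(control.time, activated.time):
        raise ValueError("control and activated series must share one time axis")
    if np.any(activated.value == 0):
        raise ValueError("activated mean area is zero at some time point")
    return KineticsSeries(control.time, control.value / activated.value,
                          kind="fold_change",
                          n_regions=np.minimum(control.n_regions, activated.n_regions),
                          time_unit=control.time_unit)


def constriction_rate(series: KineticsSeries, window: float = 1.0,
                      mode: str = "area") -> float:
    """Initial constriction rate from a linear fit over the first ``window``.

    ``window`` is in the series' time unit (minutes by default).  Mode
    ``area`` fits the mean area directly and reports µm²/min (positive for
    shrinkage); ``effective_diameter`` fits 2·sqrt(area/π) and reports
    µm/min.
    """
    if mode not in ("area", "effective_diameter"):
        raise ValueError(f"unknown mode {mode!r}")
    t = series.time
    sel = t <= t[0] + window + 1e-9
    if sel.sum() < 2:
        raise ValueError("fewer than 2 samples inside the rate window")
    y = series.value[sel]
    if mode == "effective_diameter":
        y = 2.0 * np.sqrt(y / np.pi)
    slope = float(np.polyfit(t[sel], y, 1)[0])
    return -slope


def myosin_fold_change(pre_stack: VoxelGrid, post_stacks: Sequence[VoxelGrid],
                       labels: LabelImage, channel: int | str = 0,
                       config: PipelineConfig | None = None) -> float:
    """Basal myosin-II intensity fold change after photoactivation.

    For each stack the basal signal peak is located, the mean of three
    slices centered on it taken, and the background — the mean intensity
    inside opening interiors eroded by 2 px (ridge bleed-through avoidance)
    — subtracted.  The fold change is the post-activation maximum over the
    pre-activation value.
    """
    config = config or PipelineConfig()
    if not post_stacks:
        raise ValueError("need at least one post-activation stack")
    interiors = morphology.erosion(labels.labels > 0, morphology.disk(2))
    if not interiors.any():
        raise ValueError("opening interiors vanish after erosion; cannot "
                         "estimate background")

    def level(grid: VoxelGrid) -> float:
        prof = basal_geometry.axial_profile(grid, channel)
        z_idx, _ = basal_geometry.locate_basal_peak(prof, config.apical_exclusion)
        proj = basal_geometry.project_basal(grid, z_idx, 3, channel)
        n = proj.z_range[1] - proj.z_range[0]
        mean_slice = proj.frame / n
        return float(mean_slice.mean() - mean_slice[interiors].mean())

    pre = level(pre_stack)
    if pre <= 0:
        raise ValueError("background exceeds signal in the pre-activation stack")
    return max(level(g) for g in post_stacks) / pre


def shape_vs_depth(samples: Sequence[tuple[VoxelGrid, LabelImage]],
                   channel: int | str = 0,
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """Mean angularity and area of the basal network versus ingression depth.

    One row per sample: the furrow depth from the stack's axial profile
    and the mean, SEM and count of the per-opening statistics over
    non-border openings.  Samples without usable openings are skipped with
    a warning.
    """
    config = config or PipelineConfig()
    rows = []
    for i, (grid, labels) in enumerate(samples):
        depth = basal_geometry.ingression_depth(grid, channel,
                                                apical_exclusion=config.apical_exclusion)
        shapes = all_opening_shapes(labels)
        if not shapes:
            logger.warning("sample %d has no usable openings; row skipped", i)
            continue
        ang = np.array([s.angularity for s in shapes])
        area = np.array([s.area for s in shapes])
        n = len(shapes)
        rows.append({"depth_um": depth,
                     "mean_angularity": float(ang.mean()),
                     "sem_angularity": float(ang.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                     "mean_area_um2": float(area.mean()),
                     "sem_area_um2": float(area.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                     "n_openings": n})
    return pd.DataFrame(rows,
                        columns=["depth_um", "mean_angularity", "sem_angularity",
                                 "mean_area_um2", "sem_area_um2", "n_openings"])
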