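"""Calibrated stack, label-map, table and ground-truth I/O.

Image data move through the pipeline as :class:`VoxelGrid` objects — a
five-axis intensity array ordered ``(time, z, y, x, channel)`` with the
physical calibration (lateral pixel size, axial step, frame interval)
attached.  Stacks are stored as plain multi-page TIFF with the calibration
recorded as JSON in the ImageDescription tag; a sidecar config can supply
calibration for files that lack it, but nothing is ever silently defaulted.

Conventions: indices are 0-based, pixel centers sit at integer coordinates,
z index 0 is the apical-most slice, and every reported length or area is in
physical units (µm, µm²) derived from the calibration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("cortexmetrics")

AXES = "TZYXC"  # canonical axis order of VoxelGrid.intensities

__all__ = [
    "VoxelGrid",
    "LabelImage",
    "PipelineConfig",
    "SceneTruth",
    "read_stack",
    "write_stack",
    "write_table",
    "write_truth",
    "read_truth",
    "read_config",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Calibrated multi-dimensional intensity data.

    Parameters
    ----------
    intensities
        Non-negative array indexed ``(time, z, y, x, channel)``.
    pixel_size_xy
        Lateral calibration, µm per pixel.
    z_step
        Axial calibration, µm per slice (required when the z extent > 1).
    frame_interval
        Seconds between frames.
    channel_names
        One text label per channel.
    time_origin
        Seconds; event-relative zero (e.g. ablation or photoactivation at 0).
    """

    intensities: np.ndarray
    pixel_size_xy: float
    z_step: float = 1.0
    frame_interval: float = 1.0
    channel_names: Sequence[str] = field(default_factory=lambda: ["ch0"])
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 5:
            raise ValueError(
                f"intensities must be 5-D (time, z, y, x, channel); got {arr.ndim}-D"
            )
        if any(s < 1 for s in arr.shape):
            raise ValueError(f"all dimension extents must be >= 1; got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be > 0")
        if arr.shape[1] > 1 and not self.z_step > 0:
            raise ValueError("z_step must be > 0 when the z extent is > 1")
        if len(self.channel_names) != arr.shape[4]:
            raise ValueError(
                f"channel_names length {len(self.channel_names)} does not match "
                f"channel extent {arr.shape[4]}"
            )
        self.intensities = arr
        self.channel_names = list(self.channel_names)

    # -- convenience ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(f"channel {channel!r} not in {self.channel_names}") from None
        if not 0 <= channel < self.shape[4]:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def frame(self, t: int = 0, z: int = 0, channel: int | str = 0) -> np.ndarray:
        """One (y, x) plane."""
        return self.intensities[t, z, :, :, self.channel_index(channel)]

    @property
    def z_positions(self) -> np.ndarray:
        """Depth of each slice below the apical surface, µm."""
        return np.arange(self.shape[1]) * self.z_step


@dataclass
class LabelImage:
    """Integer-labelled segmentation of basal openings on one frame.

    ``labels`` is a (y, x) integer array; 0 is background (including
    watershed ridge pixels).  ``border_labels`` lists labels whose opening
    touches the frame border; these are excluded from shape statistics when
    ``border_excluded`` is set (their areas are truncation artifacts).
    """

    labels: np.ndarray
    pixel_size_xy: float
    border_excluded: bool = True
    border_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("labels must be a 2-D (y, x) array")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if arr.size and arr.min() < 0:
            raise ValueError("labels must be >= 0")
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be > 0")
        self.labels = arr
        self.border_labels = frozenset(int(b) for b in self.border_labels)

    @property
    def label_ids(self) -> list[int]:
        """Positive labels, border-flagged ones removed when excluded."""
        ids = [int(v) for v in np.unique(self.labels) if v > 0]
        if self.border_excluded:
            ids = [v for v in ids if v not in self.border_labels]
        return ids

    @property
    def pixel_area(self) -> float:
        return self.pixel_size_xy ** 2


@dataclass
class PipelineConfig:
    """Fixed analysis constants shared across the pipeline.

    Defaults encode the standard protocol: 3-slice basal projections summed
    at the basal signal peak, a 1-minute constriction-rate window, the
    1–4 s post-ablation velocity fit, saturation read-out at 125 s, and
    ingression curves zeroed at 4 µm depth.
    """

    n_projection_slices: int = 3
    marker_radius_range: tuple[int, ...] = (6, 10, 14, 18, 22, 26)
    marker_radius: int | None = None  # fixed radius; None -> optimize over range
    clahe_clip_limit: float = 0.01
    clahe_kernel_size: int | None = None
    cleanup_footprint: int = 3
    rate_window: float = 60.0  # seconds
    velocity_fit_window: tuple[float, float] = (1.0, 4.0)  # seconds
    saturation_time: float = 125.0  # seconds
    zero_depth: float = 4.0  # µm
    apical_exclusion: float = 2.0  # µm, apical zone ignored when locating the basal peak
    min_fiber_length: float = 0.5  # µm
    seed: int = 0
    # simulation noise/blur defaults
    peak_photons: float = 100.0  # Poisson scale; peak SNR = sqrt(peak_photons)
    gaussian_noise_sd: float = 0.01  # additive, relative to peak intensity
    blur_sigma: float = 0.1  # µm, PSF approximation

    def __post_init__(self) -> None:
        if not 3 <= self.n_projection_slices <= 5:
            raise ValueError("n_projection_slices must be in 3..5")
        lo, hi = self.velocity_fit_window
        if not lo < hi:
            raise ValueError("velocity_fit_window start must be < end")
        for name in ("rate_window", "saturation_time", "zero_depth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        self.marker_radius_range = tuple(int(r) for r in self.marker_radius_range)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        known = {k: v for k, v in data.items() if k in fields}
        for key in ("marker_radius_range", "velocity_fit_window"):
            if key in known and known[key] is not None:
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass
class SceneTruth:
    """Generator parameters plus per-object ground truth for one scene.

    Only the fields relevant to the generated scene kind are populated;
    everything round-trips through JSON including the seed.
    """

    seed: int
    phase: str | None = None  # priming | hexagonal | ring | meshwork
    opening_centers: list[tuple[float, float]] | None = None  # (y, x) µm
    true_areas: list[list[float]] | None = None  # per frame, per opening, µm²
    true_angularity: list[float] | None = None
    constriction_rate: dict[str, float] | None = None  # region -> µm²/min
    activated_region: tuple[float, float, float, float] | None = None  # y0,x0,y1,x1 µm
    basal_depth: float | None = None  # µm
    recoil: dict[str, float] | None = None  # d_max, tau, v0, d_saturation
    fibers: dict[str, Any] | None = None  # widths_um, intensities, reference_intensity
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_areas is not None:
            for frame_areas in self.true_areas:
                if any(not (a > 0 and np.isfinite(a)) for a in frame_areas):
                    raise ValueError("true_areas must be finite and > 0")
        if self.recoil is not None:
            d_max, tau = self.recoil["d_max"], self.recoil["tau"]
            if d_max < 0 or not tau > 0:
                raise ValueError("recoil requires d_max >= 0 and tau > 0")
            v0 = self.recoil.get("v0")
            if v0 is not None and not np.isclose(v0, d_max / tau):
                raise ValueError("recoil v0 must equal d_max / tau")


# ---------------------------------------------------------------------------
# TIFF stack I/O
# ---------------------------------------------------------------------------

_CALIBRATION_FIELDS = ("pixel_size_xy", "z_step", "frame_interval")


def write_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a VoxelGrid as a plain multi-page TIFF.

    The page axis order is TZC with (y, x) pages; calibration and axis
    metadata are stored as JSON in the ImageDescription tag so that
    :func:`read_stack` round-trips bit-exactly for integer data.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    meta = {
        "axes": AXES,
        "shape": list(grid.shape),
        "pixel_size_xy": grid.pixel_size_xy,
        "z_step": grid.z_step,
        "frame_interval": grid.frame_interval,
        "channel_names": list(grid.channel_names),
        "time_origin": grid.time_origin,
    }
    # pages ordered T, Z, C
    pages = np.transpose(grid.intensities, (0, 1, 4, 2, 3))
    pages = pages.reshape((-1,) + grid.shape[2:4])
    tifffile.imwrite(path, pages, description=json.dumps(meta))
    return path


def _parse_metadata(path: Path) -> dict[str, Any]:
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        if not isinstance(meta, dict):
            return {}
        return meta
    except (json.JSONDecodeError, TypeError):
        return {}


def read_stack(
    path: str | Path,
    config: PipelineConfig | Mapping[str, Any] | None = None,
    channel_names: Sequence[str] | None = None,
) -> VoxelGrid:
    """Read a TIFF into a VoxelGrid, promoting missing axes to singletons.

    Calibration is taken from the file's JSON metadata when present and
    otherwise from ``config``; a calibration field available from neither
    source raises an error naming the field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as our contract error
        raise ValueError(f"unreadable TIFF: {path}: {exc}") from exc
    if not 2 <= data.ndim <= 5:
        raise ValueError(f"expected a 2-5 dimensional TIFF, got {data.ndim}-D")
    meta = _parse_metadata(path)

    if "shape" in meta and "axes" in meta and meta.get("axes") == AXES:
        arr = np.asarray(data).reshape(meta["shape"][0], meta["shape"][1],
                                       meta["shape"][4], meta["shape"][2],
                                       meta["shape"][3])
        arr = np.transpose(arr, (0, 1, 3, 4, 2))
    else:
        arr = np.asarray(data)
        # bare TIFF: interpret trailing axes as (y, x), leading as z (3-D)
        # then time (4-D); promote the rest to singletons
        while arr.ndim < 4:
            arr = arr[np.newaxis]
        if arr.ndim == 4:
            arr = arr[..., np.newaxis]

    cfg: dict[str, Any] = {}
    if isinstance(config, PipelineConfig):
        cfg = dataclasses.asdict(config)
    elif config is not None:
        cfg = dict(config)

    calib: dict[str, Any] = {}
    for name in _CALIBRATION_FIELDS:
        if name in meta:
            calib[name] = meta[name]
        elif name in cfg:
            calib[name] = cfg[name]
        elif name == "pixel_size_xy" or (name == "z_step" and arr.shape[1] > 1):
            raise ValueError(
                f"missing calibration: {name} found neither in TIFF metadata nor config"
            )
        else:
            calib[name] = 1.0

    names = meta.get("channel_names") or channel_names or [
        f"ch{i}" for i in range(arr.shape[4])
    ]
    return VoxelGrid(
        intensities=arr,
        pixel_size_xy=float(calib["pixel_size_xy"]),
        z_step=float(calib["z_step"]),
        frame_interval=float(calib["frame_interval"]),
        channel_names=list(names),
        time_origin=float(meta.get("time_origin", 0.0)),
    )


def write_labels(labels: LabelImage, path: str | Path) -> Path:
    """Write a label map as a 16-bit TIFF with calibration metadata."""
    path = Path(path)
    if labels.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed 16-bit range")
    meta = {
        "pixel_size_xy": labels.pixel_size_xy,
        "border_excluded": labels.border_excluded,
        "border_labels": sorted(labels.border_labels),
    }
    tifffile.imwrite(path, labels.labels.astype(np.uint16), description=json.dumps(meta))
    return path


def read_labels(path: str | Path, pixel_size_xy: float | None = None) -> LabelImage:
    path = Path(path)
    arr = tifffile.imread(path).astype(np.int32)
    meta = _parse_metadata(path)
    px = meta.get("pixel_size_xy", pixel_size_xy)
    if px is None:
        raise ValueError("missing calibration: pixel_size_xy")
    return LabelImage(
        labels=arr,
        pixel_size_xy=float(px),
        border_excluded=bool(meta.get("border_excluded", True)),
        border_labels=frozenset(meta.get("border_labels", ())),
    )


# ---------------------------------------------------------------------------
# tables and ground truth
# ---------------------------------------------------------------------------

def write_table(records: Sequence[Mapping[str, Any]], path: str | Path,
                columns: Sequence[str] | None = None) -> Path:
    """Write keyed measurement rows as CSV with a header.

    All rows must share one key set; an empty record list yields a
    header-only CSV (``columns`` then supplies the header).
    """
    path = Path(path)
    records = list(records)
    if records:
        keys = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != keys:
                raise ValueError(f"heterogeneous keys in record {i}: {list(rec.keys())} vs {keys}")
        df = pd.DataFrame.from_records(records, columns=keys)
    else:
        df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, index=False)
    return path


def write_truth(truth: SceneTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(truth), indent=2))
    return path


def read_truth(path: str | Path) -> SceneTruth:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed SceneTruth JSON: {exc}") from exc
    fields = {f.name for f in dataclasses.fields(SceneTruth)}
    known = {k: v for k, v in data.items() if k in fields}
    if "opening_centers" in known and known["opening_centers"] is not None:
        known["opening_centers"] = [tuple(c) for c in known["opening_centers"]]
    if "activated_region" in known and known["activated_region"] is not None:
        known["activated_region"] = tuple(known["activated_region"])
    return SceneTruth(**known)


def read_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_json(path)
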