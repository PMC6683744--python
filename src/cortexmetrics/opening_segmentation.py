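"""Marker-controlled watershed segmentation of dark basal openings.

The openings appear as black holes in the bright fiber network, so the
frame is inverted first.  The operator chain then runs: tile-based local
contrast enhancement (CLAHE), Sobel gradient magnitude, foreground markers
from regional maxima of the morphologically opened image (disk structuring
element whose radius is chosen on a marker-count stability plateau),
marker cleanup by closing then erosion, background markers from the
skeleton of the thresholded complement, and finally a watershed of the
gradient image with its minima imposed at the combined markers.  Watershed
ridge pixels are assigned to background; openings touching the frame
border are flagged so shape statistics can exclude their truncated areas.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage import measure, morphology
from skimage.exposure import equalize_adapthist
from skimage.filters import sobel, threshold_otsu
from skimage.segmentation import watershed

from .stack_io import LabelImage, PipelineConfig, VoxelGrid, logger

__all__ = ["segment_openings", "optimize_marker_radius"]


def _as_frame(frame: np.ndarray | VoxelGrid) -> np.ndarray:
    if isinstance(frame, VoxelGrid):
        return frame.frame(0, 0, 0)
    arr = np.asarray(frame, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D frame, got {arr.ndim}-D")
    return arr


def _enhanced_inverted(frame: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Steps 1-2: invert so openings are bright, then CLAHE on [0, 1].

    The min-max rescale before equalization makes the whole chain
    invariant to affine intensity rescaling of the input.
    """
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    lo, hi = float(frame.min()), float(frame.max())
    if hi == lo:
        raise ValueError("constant frame: nothing to segment")
    inverted = (hi - frame) / (hi - lo)
    return equalize_adapthist(inverted, kernel_size=config.clahe_kernel_size,
                              clip_limit=config.clahe_clip_limit)


def _marker_stage(enhanced: np.ndarray, radius: int,
                  config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """Step 4-5 core: cleaned foreground markers and the opened image.

    Foreground = regional maxima of the disk-opened image restricted to
    its Otsu foreground (maxima of the dark margin's residual texture are
    not openings), then binary closing followed by erosion.
    """
    footprint = morphology.disk(radius, decomposition="sequence")
    opened = morphology.opening(enhanced, footprint)
    thresh = threshold_otsu(opened)
    maxima = morphology.local_maxima(opened) & (opened > thresh)
    clean = morphology.footprint_rectangle(
        (config.cleanup_footprint, config.cleanup_footprint))
    markers = morphology.erosion(morphology.closing(maxima, clean), clean)
    return markers, opened


def optimize_marker_radius(frame: np.ndarray | VoxelGrid,
                           radii: Sequence[int] | None = None,
                           config: PipelineConfig | None = None) -> int:
    """Disk radius for the marker stage, chosen on a stability plateau.

    The marker stage is run at each candidate radius and the marker count
    recorded; the returned radius is the midpoint of the longest run of
    consecutive radii yielding an identical count (ties break to the
    smaller radius).  When every count differs the smallest radius of the
    first length-1 plateau is returned with a warning.
    """
    config = config or PipelineConfig()
    radii = list(radii if radii is not None else config.marker_radius_range)
    if len(radii) < 3:
        raise ValueError("need at least 3 candidate radii")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("candidate radii must be strictly ascending")
    enhanced = _enhanced_inverted(_as_frame(frame), config)
    counts = []
    for r in radii:
        markers, _ = _marker_stage(enhanced, r, config)
        counts.append(int(measure.label(markers).max()))
    if all(c == 0 for c in counts):
        raise ValueError("all candidate radii yield zero markers")

    best_start, best_len = None, 0
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            # zero markers is a failure of the radius, never a stability plateau
            if counts[start] > 0 and i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    if best_start is None:
        best_start = next(i for i, c in enumerate(counts) if c > 0)
        best_len = 1
    if best_len == 1:
        logger.warning("marker counts %s have no stability plateau over radii %s; "
                       "falling back to the smallest usable radius", counts, radii)
        return radii[best_start]
    mid = best_start + (best_len - 1) // 2  # even-length runs take the smaller middle
    return radii[mid]


def segment_openings(frame: np.ndarray | VoxelGrid,
                     config: PipelineConfig | None = None,
                     pixel_size_xy: float | None = None,
                     border_excluded: bool = True) -> LabelImage:
    """Segment dark basal openings from one projected network frame.

    Runs the full inversion / enhancement / gradient / marker / watershed
    chain (module docstring).  The marker disk radius comes from
    ``config.marker_radius`` when set, otherwise from
    :func:`optimize_marker_radius` over ``config.marker_radius_range``.
    Identical frame and config give an identical label map.
    """
    config = config or PipelineConfig()
    if isinstance(frame, VoxelGrid) and pixel_size_xy is None:
        pixel_size_xy = frame.pixel_size_xy
    img = _as_frame(frame)
    px = pixel_size_xy if pixel_size_xy is not None else 1.0

    enhanced = _enhanced_inverted(img, config)           # steps 1-2
    gradient = sobel(enhanced)                           # step 3
    radius = config.marker_radius
    if radius is None:
        radius = optimize_marker_radius(img, config.marker_radius_range, config)
    fg, opened = _marker_stage(enhanced, radius, config)  # step 4
    if not fg.any():
        raise ValueError("no foreground markers found")

    background = opened <= threshold_otsu(opened)         # step 5
    bg_skeleton = morphology.skeletonize(background) & ~fg
    if not bg_skeleton.any():
        raise ValueError("no background markers found")

    marker_labels = measure.label(fg)                     # step 6: minima imposition
    n_fg = int(marker_labels.max())
    marker_labels[bg_skeleton] = n_fg + 1
    ws = watershed(gradient, markers=marker_labels,       # step 7
                   connectivity=1, watershed_line=True)

    labels = np.where((ws > 0) & (ws <= n_fg), ws, 0)     # step 8: ridge+bg -> 0
    labels = measure.label(labels > 0, connectivity=1)
    # openings flooded from distinct markers can merge in the relabel above
    # only if they were never separated by a ridge; keep the watershed ids
    # where they disagree
    if labels.max() != n_fg:
        labels = np.where((ws > 0) & (ws <= n_fg), ws, 0)
        labels = _relabel_sequential(labels)

    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = frozenset(int(v) for v in np.unique(labels[border]) if v > 0)
    return LabelImage(labels=labels.astype(np.int32), pixel_size_xy=px,
                      border_excluded=border_excluded, border_labels=border_labels)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]
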