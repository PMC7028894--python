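"""Automatic region-of-interest extraction from false-colour thermograms.

The camera exports a 320x240 false-colour frame decorated with a vertical
temperature-scale bar and text overlays.  Only the posterior-thigh area
carries diagnostic texture, so preprocessing (a) strips the annotations,
(b) stretches contrast, (c) finds the thigh outline with a Sobel edge
detector, (d) removes small noise components, and (e) crops to the bounding
box of the thigh region(s), finally resizing to a fixed 210x240 grayscale
raster in [0, 1].  The approach is purely morphological: pixel values are
treated as intensities, never converted back to temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .io import RawThermogram

logger = logging.getLogger(__name__)

#: Rec. 601 luminance weights for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class ROIExtractionError(RuntimeError):
    """No usable thigh foreground could be located in the image."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the ROI-extraction chain.

    target_height / target_width
        Output raster size; 210x240 matches the downstream feature
        extractors' expectations.
    contrast_low / contrast_high
        Percentiles of the linear histogram stretch.
    edge_threshold
        Threshold on the Sobel magnitude in (0, 1); ``None`` selects Otsu's
        threshold per image.
    min_component_area
        Connected components (8-connectivity) below this pixel area are
        treated as noise.
    annotation_margin_fraction
        Maximum fraction of each dimension that annotation removal may
        excise from any one border.
    """

    target_height: int = 210
    target_width: int = 240
    contrast_low: float = 2.0
    contrast_high: float = 98.0
    edge_threshold: float | None = None
    min_component_area: int = 64
    annotation_margin_fraction: float = 0.2

    def __post_init__(self):
        if self.target_height <= 0 or self.target_width <= 0:
            raise ValueError("target dimensions must be positive")
        if not (0 <= self.contrast_low < self.contrast_high <= 100):
            raise ValueError("need 0 <= contrast_low < contrast_high <= 100")
        if self.edge_threshold is not None and not (0 < self.edge_threshold < 1):
            raise ValueError("edge_threshold must lie in (0, 1)")


@dataclass
class ROIImage:
    """Preprocessed posterior-thigh region: float grayscale in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""
    stage: int | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"ROI must be single-channel, got shape {px.shape}")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ValueError("ROI values must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Convert an RGB or grayscale raster to float grayscale in [0, 1]."""
    px = np.asarray(pixels, dtype=float)
    if px.ndim == 3:
        px = px @ np.asarray(LUMA_WEIGHTS)
    if px.max() > 1.0:
        px = px / 255.0
    return np.clip(px, 0.0, 1.0)


def enhance_contrast(image: np.ndarray, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Linear percentile stretch of a grayscale image onto [0, 1].

    Values at or below the low percentile map to 0, at or above the high
    percentile to 1, linearly in between.  A constant image is returned
    unchanged (there is nothing to stretch).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("enhance_contrast expects a single-channel image")
    lo = np.percentile(img, config.contrast_low)
    hi = np.percentile(img, config.contrast_high)
    if hi - lo <= 0:
        logger.warning("enhance_contrast: zero dynamic range, image unchanged")
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Per-pixel gradient magnitude sqrt(Gx^2 + Gy^2) with 3x3 Sobel kernels.

    Borders are handled by reflection.  A constant image yields an all-zero
    magnitude raster.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("sobel_edges expects a single-channel image")
    if min(img.shape) < 3:
        raise ValueError(f"image {img.shape} smaller than the 3x3 Sobel kernel")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def _strip_depth(profile: np.ndarray, limit: int, threshold: float,
                 presence: int = 12) -> int:
    """Depth of a high-edge-density annotation strip at the profile's start.

    A strip must announce itself near the border: unless some entry within
    the first `presence` rows/columns exceeds the threshold, nothing is
    trimmed (so interior structure, e.g. a thigh outline inside the margin,
    cannot trigger a cut).  Otherwise trim past the deepest above-threshold
    entry within `limit`, with a 3-px blur margin.
    """
    limit = min(limit, len(profile))
    if limit < 1:
        return 0
    if not np.any(profile[: min(presence, limit)] > threshold):
        return 0
    idx = np.flatnonzero(profile[:limit] > threshold)
    if idx.size == 0:
        return 0
    return min(int(idx[-1]) + 3, limit)


def remove_annotations(
    image: RawThermogram | np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
    return_offsets: bool = False,
):
    """Excise the temperature bar and text strips from a thermogram.

    The colour-scale bar is a tall, thin strip of dense edges abutting the
    left or right border; text overlays form dense-edge strips along the top
    and bottom.  Both are located by profiling mean Sobel edge density per
    border row/column against 3x the image-wide median (falling back to the
    mean when the median vanishes), and clipped at
    ``annotation_margin_fraction`` of each dimension.  If nothing qualifies
    the image is returned unchanged.
    """
    if isinstance(image, RawThermogram):
        gray = to_grayscale(image.pixels)
    else:
        gray = to_grayscale(image)
    edges = sobel_edges(gray)

    row_profile = edges.mean(axis=1)
    col_profile = edges.mean(axis=0)

    def _cutoff(profile):
        med = float(np.median(profile))
        base = med if med > 1e-12 else float(profile.mean())
        return 3.0 * base

    h, w = gray.shape
    row_limit = int(config.annotation_margin_fraction * h)
    col_limit = int(config.annotation_margin_fraction * w)

    thr_rows = _cutoff(row_profile)
    top = _strip_depth(row_profile, row_limit, thr_rows)
    bottom = _strip_depth(row_profile[::-1], row_limit, thr_rows)
    trimmed = gray[top : h - bottom, :]
    # recompute the column profile on the row-trimmed image so text strips
    # spanning the full width do not mask the bar columns
    col_profile = edges[top : h - bottom, :].mean(axis=0)
    thr_cols = _cutoff(col_profile)
    left = _strip_depth(col_profile, col_limit, thr_cols)
    right = _strip_depth(col_profile[::-1], col_limit, thr_cols)
    trimmed = trimmed[:, left : w - right]

    if top == bottom == left == right == 0:
        logger.info("remove_annotations: no annotation strips detected")
    if return_offsets:
        return trimmed, (top, left)
    return trimmed


def remove_noise(
    mask: np.ndarray, config: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Drop small components from a boolean mask, then close 1-px gaps.

    Components (8-connectivity) with area below ``min_component_area`` are
    removed; a morphological closing with a 3x3 square element then fuses
    components separated by single-pixel gaps.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return m.copy()
    labels = measure.label(m, connectivity=2)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < config.min_component_area)
    m = m & ~np.isin(labels, small[small > 0])
    return morphology.closing(m, morphology.footprint_rectangle((3, 3)))


def _foreground_bbox(mask: np.ndarray, min_area: int) -> tuple[int, int, int, int]:
    """Union bounding box of the dominant component(s) of a boolean mask.

    Both thighs usually survive as two components of comparable area (or one
    merged component after closing); components below 20% of the largest
    area are ignored as residue.  Returns (row0, row1, col0, col1), half-open.
    """
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    if not props:
        raise ROIExtractionError("no foreground component found")
    largest = max(p.area for p in props)
    keep = [p for p in props if p.area >= max(min_area, 0.2 * largest)]
    r0 = min(p.bbox[0] for p in keep)
    c0 = min(p.bbox[1] for p in keep)
    r1 = max(p.bbox[2] for p in keep)
    c1 = max(p.bbox[3] for p in keep)
    return r0, r1, c0, c1


def extract_roi(
    raw: RawThermogram,
    config: PreprocessConfig = PreprocessConfig(),
    return_debug: bool = False,
):
    """Run the full ROI-extraction chain on one thermogram.

    grayscale -> annotation removal -> percentile contrast stretch -> Sobel
    edges -> threshold (Otsu by default) -> noise removal -> bounding box of
    the thigh component(s) -> crop -> resize to ``target_height x
    target_width`` (bilinear, anti-aliased) -> values in [0, 1].  The stage
    label rides along unchanged.

    With ``return_debug=True`` also returns a dict of intermediates,
    including ``crop_box`` as (row0, row1, col0, col1) half-open in the
    *original* image coordinates.
    """
    trimmed, (top, left) = remove_annotations(raw, config, return_offsets=True)
    enhanced = enhance_contrast(trimmed, config)
    edges = sobel_edges(enhanced)

    if config.edge_threshold is not None:
        thr = config.edge_threshold * edges.max()
    else:
        if edges.max() <= 0:
            raise ROIExtractionError(
                f"{raw.source_id}: flat image, no edges to segment"
            )
        thr = threshold_otsu(edges)
    mask = remove_noise(edges > thr, config)
    if not mask.any():
        raise ROIExtractionError(
            f"{raw.source_id}: no foreground component after noise removal"
        )
    try:
        r0, r1, c0, c1 = _foreground_bbox(mask, config.min_component_area)
    except ROIExtractionError as exc:
        raise ROIExtractionError(f"{raw.source_id}: {exc}") from exc
    if r1 - r0 < 16 or c1 - c0 < 16:
        raise ROIExtractionError(
            f"{raw.source_id}: degenerate bounding box "
            f"({r1 - r0}x{c1 - c0} px, need >= 16 px a side)"
        )

    crop = enhanced[r0:r1, c0:c1]
    out = resize(
        crop,
        (config.target_height, config.target_width),
        order=1,
        mode="reflect",
        anti_aliasing=(
            crop.shape[0] > config.target_height or crop.shape[1] > config.target_width
        ),
        preserve_range=True,
    )
    span = out.max() - out.min()
    out = (out - out.min()) / span if span > 0 else out
    roi = ROIImage(pixels=np.clip(out, 0, 1), source_id=raw.source_id, stage=raw.stage)
    if return_debug:
        debug = {
            "trimmed": trimmed,
            "enhanced": enhanced,
            "edges": edges,
            "mask": mask,
            "crop_box": (r0 + top, r1 + top, c0 + left, c1 + left),
        }
        return roi, debug
    return roi


def preprocess_config_override(config: PreprocessConfig, **kwargs) -> PreprocessConfig:
    return replace(config, **kwargs)
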