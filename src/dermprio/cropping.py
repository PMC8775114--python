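"""Lesion localisation and square cropping.

A coarse lesion mask is extracted from a class-activation (saliency)
map by mean-intensity thresholding; it is then reconciled with an
externally supplied segmentation mask (e.g. from a DeepLab-style
segmenter) by an overlap decision rule, and the surviving mask is
turned into a square crop window around the lesion, optionally dilated
by a tolerance expressed as a percentage of the approximate lesion
radius.  When both masks are rejected the original image is used
unchanged (the "empty mask" outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage import measure, transform

__all__ = [
    "ActivationMap",
    "LesionMask",
    "CropBox",
    "CropConfig",
    "gradcam_mask",
    "fuse_masks",
    "square_patch",
    "crop_and_resize",
]


@dataclass(frozen=True)
class ActivationMap:
    """H x W grayscale saliency grid with intensities in [0, 1]."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", g)
        if g.ndim != 2 or min(g.shape) < 8:
            raise ValueError("activation map must be 2-D with H, W >= 8")
        if not np.all(np.isfinite(g)):
            raise ValueError("activation map must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask with its provenance."""

    grid: np.ndarray
    provenance: str = "gradcam"  # "gradcam" | "deeplab" | "empty"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", g)
        if g.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.provenance not in ("gradcam", "deeplab", "empty"):
            raise ValueError(f"unknown provenance: {self.provenance!r}")

    @property
    def area(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return self.area == 0

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "LesionMask":
        return cls(grid=np.zeros(shape, dtype=bool), provenance="empty")


@dataclass(frozen=True)
class CropBox:
    """0-based, half-open crop window [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("crop box must have positive extent")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("crop box must start inside the image")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.row_start, self.row_stop, self.col_start, self.col_stop)


@dataclass(frozen=True)
class CropConfig:
    """Cropping parameters.

    tolerance_pct: extra margin as a percent of the approximate lesion
        radius (half the larger bounding-box dimension); the studied
        settings are 0, 10, 30 and 50 but any nonnegative value works.
    corner_patch_frac: side of the corner patches silenced before
        thresholding, as a fraction of min(H, W).
    threshold_factor: multiplier c on the mean intensity; pixels
        strictly above c * mean are kept.
    output_size: side of the square output image in pixels.
    """

    tolerance_pct: float = 0.0
    corner_patch_frac: float = 0.10
    threshold_factor: float = 1.0
    output_size: int = 300

    def __post_init__(self) -> None:
        if self.tolerance_pct < 0:
            raise ValueError("tolerance_pct must be nonnegative")
        if not (0 < self.corner_patch_frac < 0.5):
            raise ValueError("corner_patch_frac must be in (0, 0.5)")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.output_size < 1:
            raise ValueError("output_size must be >= 1")


def gradcam_mask(amap: ActivationMap, cfg: Optional[CropConfig] = None) -> LesionMask:
    """Threshold a saliency map into a single central lesion blob.

    Corner squares are first replaced by the global mean intensity to
    silence the border noise these maps typically show; the map is then
    binarized strictly above ``threshold_factor * mean`` and, among the
    8-connected foreground components, the one whose centroid is
    nearest the image centre is kept (lesions sit near the centre of
    referral photographs).  No surviving pixel yields an empty mask.
    """
    cfg = cfg or CropConfig()
    g = amap.grid.copy()
    h, w = g.shape
    mu = float(g.mean())
    side = max(1, int(round(cfg.corner_patch_frac * min(h, w))))
    for rows in (slice(0, side), slice(h - side, h)):
        for cols in (slice(0, side), slice(w - side, w)):
            g[rows, cols] = mu
    binary = g > cfg.threshold_factor * mu
    if not binary.any():
        return LesionMask.empty((h, w))
    labels = measure.label(binary, connectivity=2)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    best_label, best_dist = 0, math.inf
    for region in measure.regionprops(labels):
        dist = float(np.hypot(*(np.array(region.centroid) - center)))
        if dist < best_dist:
            best_label, best_dist = region.label, dist
    return LesionMask(grid=labels == best_label, provenance="gradcam")


def fuse_masks(gc: LesionMask, dl: LesionMask) -> LesionMask:
    """Choose between the activation-derived and segmenter masks.

    The segmenter mask is first resampled (nearest neighbour) to the
    activation mask's shape.  If the overlap exceeds 50% of the
    activation mask's area the activation mask is accepted; failing
    that, if it exceeds 60% of the segmenter mask's area the segmenter
    mask is taken; otherwise the empty mask is returned.  The selected
    mask is returned unchanged, never blended.
    """
    dl_grid = dl.grid
    if dl_grid.shape != gc.shape:
        dl_grid = transform.resize(
            dl_grid.astype(float), gc.shape, order=0, preserve_range=True, anti_aliasing=False
        ) > 0.5
    if dl_grid.shape != gc.shape:
        raise ValueError("mask shapes differ after alignment")
    overlap = int(np.logical_and(gc.grid, dl_grid).sum())
    if gc.area > 0 and overlap > 0.5 * gc.area:
        return gc
    dl_area = int(dl_grid.sum())
    if dl_area > 0 and overlap > 0.6 * dl_area:
        return LesionMask(grid=dl_grid, provenance="deeplab")
    return LesionMask.empty(gc.shape)


def square_patch(
    mask: LesionMask,
    cfg: Optional[CropConfig] = None,
    image_shape: Optional[Tuple[int, int]] = None,
) -> Optional[CropBox]:
    """Square crop window around the mask's bounding box.

    The tight bounding box is squared by adding half the side
    difference to both ends of the smaller dimension (odd differences
    put the extra pixel on the far side), then all four sides are
    dilated by ``tolerance_pct/100 * r`` where ``r`` is half the larger
    bounding-box dimension.  The window is finally shifted back inside
    the image and clipped only along axes where it exceeds the image
    itself.  An empty mask returns ``None``, the use-original-image
    sentinel.
    """
    cfg = cfg or CropConfig()
    if mask.is_empty:
        return None
    shape = image_shape if image_shape is not None else mask.shape
    rows, cols = np.nonzero(mask.grid)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    height, width = r1 - r0, c1 - c0
    d = abs(height - width)
    if height < width:
        r0 -= d // 2
        r1 += d - d // 2
    elif width < height:
        c0 -= d // 2
        c1 += d - d // 2
    r = max(r1 - r0, c1 - c0) / 2.0
    margin = int(math.floor(cfg.tolerance_pct / 100.0 * r + 0.5))
    r0, r1 = r0 - margin, r1 + margin
    c0, c1 = c0 - margin, c1 + margin
    r0, r1 = _shift_into(r0, r1, shape[0])
    c0, c1 = _shift_into(c0, c1, shape[1])
    return CropBox(row_start=r0, row_stop=r1, col_start=c0, col_stop=c1)


def _shift_into(start: int, stop: int, size: int) -> Tuple[int, int]:
    """Shift a window inside [0, size); clip only if it is larger than size."""
    if stop - start >= size:
        return 0, size
    if start < 0:
        stop -= start
        start = 0
    if stop > size:
        start -= stop - size
        stop = size
    return start, stop


def crop_and_resize(
    image: np.ndarray,
    box: Optional[CropBox],
    cfg: Optional[CropConfig] = None,
) -> np.ndarray:
    """Crop to ``box`` (or keep the whole image on the sentinel) and
    resize to ``output_size`` squared with nearest-neighbour sampling,
    which introduces no new intensity values."""
    cfg = cfg or CropConfig()
    img = np.asarray(image)
    if img.ndim not in (2, 3):
        raise ValueError("image must be 2-D or 3-D (H, W[, C])")
    if box is not None:
        if box.row_stop > img.shape[0] or box.col_stop > img.shape[1]:
            raise ValueError("crop box exceeds image bounds")
        img = img[box.row_start : box.row_stop, box.col_start : box.col_stop]
    out_shape = (cfg.output_size, cfg.output_size) + img.shape[2:]
    out = transform.resize(
        img.astype(float), out_shape, order=0, preserve_range=True, anti_aliasing=False
    )
    return out.astype(image.dtype) if np.issubdtype(np.asarray(image).dtype, np.integer) else out
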