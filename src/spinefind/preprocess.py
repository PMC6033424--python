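"""Grayscale image to binary tissue mask.

The segmentation strategy: median-denoise, estimate the background with a
deliberately lowered global Otsu threshold (lowered so no dim tissue is
lost), subtract the mean background level, then binarize against a local
first-order (mean) threshold over a 10x10 um neighborhood so that dendrites
are segmented regardless of absolute brightness. Small holes in the mask are
filled.

Because intensities are min-max normalized upstream, the whole pipeline is
invariant to affine rescaling of the raw input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .calibration_io import CalibratedImage

__all__ = [
    "BinaryMask",
    "denoise_median",
    "global_background_threshold",
    "subtract_background",
    "adaptive_binarize",
    "fill_small_holes",
    "binarize_pipeline",
]

# strictly-greater comparisons against a box-filtered mean need a guard for
# floating-point noise in the filter (a constant image must stay background)
_MEAN_EPS = 1e-12

_S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground (tissue) mask with the source image's scale."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise ValueError("mask must be 2D")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def denoise_median(img: CalibratedImage, kernel_px: int = 3) -> CalibratedImage:
    """Standard 2D median filter (replicate-padded at the border)."""
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError(f"kernel must be an odd integer >= 3, got {kernel_px}")
    out = ndi.median_filter(img.pixels, size=kernel_px, mode="nearest")
    return CalibratedImage(np.clip(out, 0.0, 1.0), img.scale, img.source_id)


def global_background_threshold(
    img: CalibratedImage, reduction: float = 0.70
) -> float:
    """Otsu's global threshold reduced by ``reduction`` (default 70%).

    The lowered threshold marks *certain* background rather than the Otsu
    foreground/background split, so no dim tissue pixels are discarded.
    Returns ``(1 - reduction) * otsu``. A constant image has no threshold;
    0 is returned with a warning.
    """
    px = img.pixels
    if np.ptp(px) == 0:
        warnings.warn("constant image: background threshold set to 0")
        return 0.0
    return float((1.0 - reduction) * threshold_otsu(px))


def subtract_background(img: CalibratedImage, threshold: float) -> CalibratedImage:
    """Subtract the mean of pixels strictly below ``threshold``; clip at 0.

    If no pixel lies below the threshold the image is returned unchanged.
    """
    px = img.pixels
    below = px < threshold
    if not below.any():
        return img
    offset = float(px[below].mean())
    out = np.clip(px - offset, 0.0, 1.0)
    return CalibratedImage(out, img.scale, img.source_id)


def adaptive_window_px(scale: float, window_um: float, shape: tuple[int, int]) -> int:
    """Neighborhood size in pixels: round(window_um * scale), forced odd and
    clamped to the image size."""
    w = int(round(window_um * scale))
    if w % 2 == 0:
        w += 1
    limit = min(shape)
    if w > limit:
        w = limit if limit % 2 == 1 else limit - 1
    return max(w, 3)


def adaptive_binarize(
    img: CalibratedImage,
    sensitivity: float = 1.0,
    window_um: float = 10.0,
    floor: float = 0.0,
) -> BinaryMask:
    """Binarize against a local mean over a ``window_um`` square neighborhood.

    A pixel is foreground iff its intensity exceeds ``sensitivity`` times the
    local mean (replicated-edge padding) and exceeds ``floor`` (an optional
    global background floor; 0 disables it).
    """
    px = img.pixels
    w = adaptive_window_px(img.scale, window_um, px.shape)
    local = ndi.uniform_filter(px, size=w, mode="nearest")
    fg = (px - sensitivity * local) > _MEAN_EPS
    if floor > 0.0:
        fg &= px > floor
    return BinaryMask(fg, img.scale)


def fill_small_holes(mask: BinaryMask, max_area_um2: float = 0.5) -> BinaryMask:
    """Fill background holes strictly smaller than ``max_area_um2``.

    A hole is a 4-connected background component that does not touch the
    image border (4-connectivity for background keeps the 8-connected
    foreground topology intact).
    """
    px = mask.pixels
    lab, n = ndi.label(~px, structure=_S4)
    if n == 0:
        return mask
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    limit_px = max_area_um2 * mask.scale**2
    fill = np.zeros(n + 1, dtype=bool)
    fill[1:] = sizes[1:] < limit_px
    fill[border[border > 0]] = False
    out = px | fill[lab]
    return BinaryMask(out, mask.scale)


def binarize_pipeline(
    img: CalibratedImage,
    median_kernel: int = 3,
    otsu_reduction: float = 0.70,
    adaptive_window_um: float = 10.0,
    adaptive_sensitivity: float = 1.0,
    hole_max_um2: float = 0.5,
    apply_global_floor: bool = True,
) -> tuple[BinaryMask, dict]:
    """Full segmentation: median -> lowered Otsu -> subtract -> adaptive -> fill.

    The lowered global threshold is reused as a floor during binarization
    (shifted by the subtracted background level) so that near-zero residual
    background noise cannot exceed its own tiny local mean.

    Returns the mask plus a bundle of intermediates for inspection.
    """
    den = denoise_median(img, median_kernel)
    thr = global_background_threshold(den, otsu_reduction)
    below = den.pixels < thr
    offset = float(den.pixels[below].mean()) if below.any() else 0.0
    sub = subtract_background(den, thr)
    floor = max(0.0, thr - offset) if apply_global_floor else 0.0
    bw = adaptive_binarize(
        sub, sensitivity=adaptive_sensitivity, window_um=adaptive_window_um,
        floor=floor,
    )
    filled = fill_small_holes(bw, hole_max_um2)
    intermediates = {
        "denoised": den,
        "global_threshold": thr,
        "background_offset": offset,
        "subtracted": sub,
        "floor": floor,
        "binary": bw,
    }
    return filled, intermediates
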