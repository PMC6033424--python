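"""Triage of objects disconnected from the dendrite.

Surface smoothing can detach small objects (often real spines whose necks
fell below the segmentation) from the main dendrite component. Objects lying
within distance M of the backbone are kept for reporting and classified
spine / non-spine by exact two-cluster k-means on their signal-to-noise
ratios, but all detached objects are removed from the working mask: the
perimeter features and the training data only ever describe protrusions that
are visibly attached to the dendrite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .backbone import Backbone, BackboneParams
from .calibration_io import CalibratedImage
from .surface import SmoothMask

__all__ = [
    "DetachedObject",
    "find_detached",
    "object_snr",
    "classify_detached",
    "mask_out_detached",
]

_S8 = np.ones((3, 3), dtype=bool)

SNR_INF = np.finfo(np.float64).max


@dataclass
class DetachedObject:
    """One connected component separated from the dendrite."""

    coords: np.ndarray                      # (n, 2) pixel coordinates
    bbox: tuple[int, int, int, int]         # (rmin, cmin, rmax, cmax) inclusive
    snr: float | None = None
    cluster_label: str = "unclassified"     # spine | non_spine | unclassified

    @property
    def size(self) -> int:
        return len(self.coords)


def find_detached(
    mask: SmoothMask, backbone: Backbone, params: BackboneParams
) -> list[DetachedObject]:
    """Connected components that contain no backbone pixel but lie within
    Euclidean distance M (pixels) of the backbone; farther objects are
    dropped entirely."""
    if backbone.is_empty:
        raise ValueError("backbone is empty; detached objects are undefined")
    px = mask.pixels
    lab, n = ndi.label(px, structure=_S8)
    if n == 0:
        return []
    dist = ndi.distance_transform_edt(~backbone.pixels)
    out: list[DetachedObject] = []
    for i in range(1, n + 1):
        comp = lab == i
        if (comp & backbone.pixels).any():
            continue
        if dist[comp].min() > params.M:
            continue
        coords = np.argwhere(comp)
        rmin, cmin = coords.min(axis=0)
        rmax, cmax = coords.max(axis=0)
        out.append(DetachedObject(coords, (int(rmin), int(cmin), int(rmax), int(cmax))))
    return out


def object_snr(obj: DetachedObject, img: CalibratedImage) -> float:
    """Mean intensity over the object divided by mean intensity over its
    bounding box minus the object.

    A bounding box equal to the object is expanded by one pixel (within the
    image) until a surround exists. A zero-mean surround yields the largest
    representable float as an infinity sentinel.
    """
    px = img.pixels
    H, W = px.shape
    rmin, cmin, rmax, cmax = obj.bbox
    inside = np.zeros((H, W), dtype=bool)
    inside[obj.coords[:, 0], obj.coords[:, 1]] = True
    while True:
        box = np.zeros((H, W), dtype=bool)
        box[rmin : rmax + 1, cmin : cmax + 1] = True
        surround = box & ~inside
        if surround.any() or (rmin == 0 and cmin == 0 and rmax == H - 1 and cmax == W - 1):
            break
        rmin, cmin = max(rmin - 1, 0), max(cmin - 1, 0)
        rmax, cmax = min(rmax + 1, H - 1), min(cmax + 1, W - 1)
    signal = float(px[inside].mean())
    if not surround.any():
        return SNR_INF
    noise = float(px[surround].mean())
    if noise == 0.0:
        return SNR_INF
    return signal / noise


def _best_split(sorted_vals: np.ndarray) -> int:
    """Index k of the globally optimal 1-D 2-partition (low = vals[:k])."""
    n = len(sorted_vals)
    csum = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    csq = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def sse(i, j):  # within-cluster sum of squares for vals[i:j]
        cnt = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / cnt

    best_k, best = 1, np.inf
    for k in range(1, n):
        total = sse(0, k) + sse(k, n)
        if total < best - 1e-15:
            best, best_k = total, k
    return best_k


def classify_detached(
    objects: list[DetachedObject], seed: int | None = None
) -> list[DetachedObject]:
    """Label detached objects spine / non-spine by their SNR.

    With more than two objects, the SNRs are split into two clusters by the
    globally optimal 1-D 2-means partition (an exhaustive split over the
    sorted values, so the result is deterministic and ``seed`` is
    irrelevant); the cluster with the larger mean SNR is the spine group.
    With two or fewer objects no clustering is attempted and all stay
    ``unclassified``. If all SNRs are equal the split is degenerate and the
    whole set is labeled spine.
    """
    if len(objects) <= 2:
        for obj in objects:
            obj.cluster_label = "unclassified"
        return objects
    snrs = np.array([obj.snr for obj in objects], dtype=np.float64)
    if np.any(snrs == None):  # noqa: E711 - explicit None check on object dtype
        raise ValueError("all objects need an snr before classification")
    if np.ptp(snrs) == 0:
        for obj in objects:
            obj.cluster_label = "spine"
        return objects
    order = np.argsort(snrs, kind="stable")
    k = _best_split(snrs[order])
    low = set(order[:k].tolist())
    for i, obj in enumerate(objects):
        obj.cluster_label = "non_spine" if i in low else "spine"
    return objects


def mask_out_detached(
    mask: SmoothMask, objects: list[DetachedObject]
) -> SmoothMask:
    """Remove every detached object's pixels from the working mask."""
    if not objects:
        return mask
    px = mask.pixels.copy()
    for obj in objects:
        px[obj.coords[:, 0], obj.coords[:, 1]] = False
    return SmoothMask(px, mask.scale)
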