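"""Synthetic fluorescence images of dendrites with ground-truth spines.

Each image emulates a single-plane two-photon view of a GFP-filled dendrite:
a bright, gently curved tubular dendrite crossing the frame, spine-like
protrusions (a thin stalk ending in a brighter bulbous head), shallow
non-spine bumps on the tube surface (membrane blebs / noise lobes), Gaussian
PSF blur, a constant background offset, and shot-like noise whose variance
grows with the mean plus additive read noise. The generator returns the
rendered image, a ground-truth record (centerline, spine tips/bases, bump
apexes, per-pixel class map), and a LabelSet of spine-tip clicks emulating
manual labeling.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .calibration_io import CalibratedImage, LabelSet, save_image, save_labels

__all__ = ["SynthSpec", "GroundTruth", "generate", "generate_corpus"]


@dataclass(frozen=True)
class SynthSpec:
    """Geometry, optics, and noise of one synthetic image.

    Lengths are um; intensities are fractions of the brightest structure.
    Ranges ``(lo, hi)`` are sampled uniformly per structure.
    """

    size: int = 128
    scale: float = 15.0                 # px per um
    tube_radius_um: float = 0.35
    # inclusive range per image; a realistic density for an ~8.5 um field.
    # Placement respects hard geometry (tips in frame and apart), so the
    # occasional image carries one spine fewer than sampled.
    n_spines: tuple[int, int] = (2, 5)
    stalk_um: tuple[float, float] = (0.5, 2.5)
    stalk_radius_um: float = 0.15
    head_radius_um: tuple[float, float] = (0.2, 0.5)
    n_bumps: tuple[int, int] = (2, 5)
    bump_radius_um: tuple[float, float] = (0.15, 0.30)
    tube_intensity: float = 0.85
    stalk_intensity: float = 0.70
    head_intensity: float = 1.0
    background: float = 0.08
    psf_sigma_um: float = 0.15
    noise_gain: float = 0.005           # variance proportional to mean
    read_noise: float = 0.02            # additive Gaussian sigma
    trainable: bool = True              # keep spine tips away from borders
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale", "tube_radius_um", "stalk_radius_um", "psf_sigma_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What the generator drew, in pixel coordinates."""

    centerline: np.ndarray                 # (n, 2) float (row, col)
    spine_tips: list[tuple[int, int]] = field(default_factory=list)
    spine_bases: list[tuple[int, int]] = field(default_factory=list)
    bump_apexes: list[tuple[int, int]] = field(default_factory=list)
    class_map: np.ndarray | None = None    # 0 bg, 1 dendrite, 2 spine, 3 bump

    @property
    def n_spines(self) -> int:
        return len(self.spine_tips)


def _centerline(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random path crossing the full frame left to right."""
    H = W = spec.size
    n = 6 * W
    t = np.linspace(0.0, 1.0, n)
    cols = -6.0 + t * (W + 11.0)
    a1 = rng.uniform(4.0, 12.0)
    a2 = rng.uniform(2.0, 6.0)
    f1 = rng.uniform(0.5, 1.0)
    f2 = rng.uniform(1.4, 2.4)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    slope = rng.uniform(-0.12, 0.12) * H
    rows = (
        H / 2.0
        + slope * (t - 0.5)
        + a1 * np.sin(2 * np.pi * f1 * t + ph1)
        + a2 * np.sin(2 * np.pi * f2 * t + ph2)
    )
    margin = 0.30 * H
    rows = np.clip(rows, margin, H - 1 - margin)
    return np.column_stack([rows, cols])


def _normals(center: np.ndarray) -> np.ndarray:
    tang = np.gradient(center, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def _dist_to_points(shape: tuple[int, int], pts: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the nearest of ``pts`` (px)."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, _ = cKDTree(pts).query(grid, k=1)
    return d.reshape(shape)


def _segment_points(p: np.ndarray, q: np.ndarray, step: float = 0.3) -> np.ndarray:
    n = max(2, int(np.ceil(np.linalg.norm(q - p) / step)) + 1)
    return p + (q - p) * np.linspace(0.0, 1.0, n)[:, None]


def generate(spec: SynthSpec) -> tuple[CalibratedImage, GroundTruth, LabelSet]:
    """Render one synthetic dendrite image with ground truth and labels."""
    rng = np.random.default_rng(spec.seed)
    H = W = spec.size
    s = spec.scale
    center = _centerline(spec, rng)
    normals = _normals(center)
    seglen = np.linalg.norm(np.diff(center, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])

    r_tube = spec.tube_radius_um * s
    d_center = _dist_to_points((H, W), center)
    tube = d_center <= r_tube

    # anchors usable for protrusions: inside the frame with working margin
    inframe = (center[:, 1] > 8) & (center[:, 1] < W - 9)

    # --- spines ---------------------------------------------------------
    n_spines = int(rng.integers(spec.n_spines[0], spec.n_spines[1] + 1))
    tip_margin = (1.5 + 0.5 + 0.2) * s if spec.trainable else 4.0
    # anchor spacing along the dendrite; tips additionally keep 1.6 um apart
    # so 1x1 um label boxes never overlap two spines
    min_sep_um = 1.2
    used_arcs: list[float] = []
    spine_masks: list[np.ndarray] = []
    head_masks: list[np.ndarray] = []
    gt = GroundTruth(centerline=center.copy())
    tree = cKDTree(center)
    placed = 0
    attempts = 0
    while placed < n_spines and attempts < 80 * n_spines:
        attempts += 1
        i = int(rng.integers(len(center)))
        if not inframe[i]:
            continue
        if any(abs(arc[i] - a) < min_sep_um * s for a in used_arcs):
            continue
        base = center[i]
        # several protrusion draws per anchor: a long spine that would leave
        # the frame is re-drawn rather than wasting the anchor
        for _ in range(12):
            side = 1.0 if rng.random() < 0.5 else -1.0
            stalk_um = rng.uniform(*spec.stalk_um)
            head_um = rng.uniform(*spec.head_radius_um)
            nhat = side * normals[i]
            head_c = base + (r_tube + stalk_um * s) * nhat
            tip = head_c + head_um * s * nhat
            if min(tip[0], tip[1], H - 1 - tip[0], W - 1 - tip[1]) < tip_margin:
                continue
            # tip must protrude from its own stalk, not graze the dendrite
            if float(tree.query(tip)[0]) < r_tube + stalk_um * s + head_um * s - 1.5:
                continue
            if any(
                np.linalg.norm(tip - np.array(t)) < 1.6 * s
                for t in gt.spine_tips
            ):
                continue
            stalk_pts = _segment_points(base, head_c)
            stalk = _dist_to_points((H, W), stalk_pts) <= spec.stalk_radius_um * s
            head = _dist_to_points((H, W), np.atleast_2d(head_c)) <= head_um * s
            spine_masks.append(stalk)
            head_masks.append(head)
            gt.spine_tips.append((int(round(tip[0])), int(round(tip[1]))))
            gt.spine_bases.append((int(round(base[0])), int(round(base[1]))))
            used_arcs.append(float(arc[i]))
            placed += 1
            break

    # --- non-spine bumps ------------------------------------------------
    n_bumps = int(rng.integers(spec.n_bumps[0], spec.n_bumps[1] + 1))
    bump_masks: list[np.ndarray] = []
    placed_b = 0
    attempts = 0
    while placed_b < n_bumps and attempts < 60 * n_bumps:
        attempts += 1
        i = int(rng.integers(len(center)))
        if not inframe[i]:
            continue
        if any(abs(arc[i] - a) < min_sep_um * s for a in used_arcs):
            continue
        side = 1.0 if rng.random() < 0.5 else -1.0
        rb = rng.uniform(*spec.bump_radius_um)
        nhat = side * normals[i]
        bc = center[i] + r_tube * nhat
        apex = center[i] + (r_tube + rb * s) * nhat
        if min(apex[0], apex[1], H - 1 - apex[0], W - 1 - apex[1]) < 6:
            continue
        bump = _dist_to_points((H, W), np.atleast_2d(bc)) <= rb * s
        bump_masks.append(bump)
        gt.bump_apexes.append((int(round(apex[0])), int(round(apex[1]))))
        used_arcs.append(float(arc[i]))
        placed_b += 1

    # --- render ---------------------------------------------------------
    pre = np.full((H, W), spec.background, dtype=np.float64)
    pre = np.maximum(pre, np.where(tube, spec.tube_intensity, 0.0))
    class_map = np.zeros((H, W), dtype=np.uint8)
    class_map[tube] = 1
    for bump in bump_masks:
        pre = np.maximum(pre, np.where(bump, spec.tube_intensity, 0.0))
        class_map[bump & (class_map == 0)] = 3
    for stalk in spine_masks:
        pre = np.maximum(pre, np.where(stalk, spec.stalk_intensity, 0.0))
        class_map[stalk & (class_map == 0)] = 2
    for head in head_masks:
        pre = np.maximum(pre, np.where(head, spec.head_intensity, 0.0))
        class_map[head & (class_map == 0)] = 2
    gt.class_map = class_map

    blurred = ndi.gaussian_filter(pre, sigma=spec.psf_sigma_um * s)
    noise_sd = np.sqrt(spec.noise_gain * blurred + spec.read_noise**2)
    noisy = blurred + rng.normal(0.0, 1.0, size=(H, W)) * noise_sd
    noisy = np.clip(noisy, 0.0, None)
    lo, hi = noisy.min(), noisy.max()
    pixels = (noisy - lo) / (hi - lo) if hi > lo else np.zeros_like(noisy)

    img = CalibratedImage(pixels, s, source_id=f"synth-{spec.seed:08d}")
    labels = LabelSet(img.source_id, list(gt.spine_tips))
    return img, gt, labels


def generate_corpus(
    n_images: int,
    seed: int = 0,
    spec: SynthSpec | None = None,
    out_dir: str | Path | None = None,
) -> list[tuple[CalibratedImage, GroundTruth, LabelSet]]:
    """Generate ``n_images`` independent images from per-image child seeds.

    If ``out_dir`` is given, writes ``<id>.tif`` (16-bit), a combined
    ``labels.csv``, a ``ground_truth.json`` (tips / bases / apexes per
    image), and a ``summary.json`` with corpus counts.
    """
    base = spec if spec is not None else SynthSpec()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    corpus = [generate(replace(base, seed=int(cs))) for cs in child_seeds]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gt_payload = {}
        for img, gt, labels in corpus:
            save_image(img.pixels, out / f"{img.source_id}.tif")
            gt_payload[img.source_id] = {
                "spine_tips": [list(p) for p in gt.spine_tips],
                "spine_bases": [list(p) for p in gt.spine_bases],
                "bump_apexes": [list(p) for p in gt.bump_apexes],
            }
        save_labels([labels for _, _, labels in corpus], out / "labels.csv")
        (out / "ground_truth.json").write_text(json.dumps(gt_payload, indent=1))
        summary = {
            "n_images": n_images,
            "seed": seed,
            "scale": base.scale,
            "n_spines_total": sum(gt.n_spines for _, gt, _ in corpus),
            "n_bumps_total": sum(len(gt.bump_apexes) for _, gt, _ in corpus),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return corpus
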