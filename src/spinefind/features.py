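"""Candidate spine detection and PD/PS/IS perimeter feature extraction.

The geometry of a spine is captured relative to the dendrite rather than in
absolute image coordinates:

* a geodesic distance transform of the tissue mask seeded at the dendrite
  backbone assigns each foreground pixel its within-tissue distance from the
  centerline; local maxima of that map along the component perimeter are the
  candidate spine tips;
* for each candidate, a 5 um perimeter window centered on the tip is read
  out twice -- once against the dendrite-seeded map (PD: the protrusion
  profile) and once against a map seeded at the candidate's own spine
  backbone (PS: how tightly the perimeter hugs the spine) -- each resampled
  to 100 values and min-shifted to 0 so dendrite thickness cancels;
* the spine backbone (shortest within-tissue path from tip to dendrite
  backbone) contributes 20 interpolated image intensities plus its length in
  um (IS).

Together: 100 + 100 + 20 + 1 = 221 values per candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.graph import MCP_Geometric

from .backbone import Backbone, BackboneParams, extract_backbone
from .calibration_io import CalibratedImage, N_FEATURES, N_IS, N_PD, N_PS
from .detached import classify_detached, find_detached, mask_out_detached, object_snr
from .preprocess import binarize_pipeline, denoise_median
from .surface import SmoothMask, smooth_surface

__all__ = [
    "GeodesicMap",
    "PerimeterTrace",
    "PerimeterError",
    "CandidatePoint",
    "CandidateFeature",
    "geodesic_transform",
    "GeodesicPathFinder",
    "trace_perimeter",
    "find_candidates",
    "spine_backbone_path",
    "pd_vector",
    "ps_vector",
    "is_vector",
    "extract_all",
    "run_pipeline",
    "PipelineResult",
]

_S8 = np.ones((3, 3), dtype=bool)
_S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

UNDEFINED = np.inf  # sentinel for off-foreground / unreachable pixels


class PerimeterError(ValueError):
    """Raised when a component's perimeter is not a simple closed curve."""


@dataclass(frozen=True)
class GeodesicMap:
    """Per-pixel geodesic distance (um) from a seed set, within the mask."""

    values: np.ndarray          # um; UNDEFINED off-foreground/unreachable
    scale: float
    n_seeds: int

    def at(self, point) -> float:
        return float(self.values[int(point[0]), int(point[1])])


@dataclass(frozen=True)
class PerimeterTrace:
    """Ordered perimeter pixels of one component with travel-distance
    positions (um) from a cut point, following a single direction."""

    pixels: np.ndarray          # (n, 2) ordered
    positions: np.ndarray       # (n,) strictly increasing, starts at 0
    total_length: float         # um, closing the loop
    scale: float

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class CandidatePoint:
    """A potential spine tip: a local maximum of the dendrite-seeded geodesic
    map along the perimeter."""

    origin: tuple[int, int]
    trace_index: int
    dendrite_distance: float    # um


@dataclass
class CandidateFeature:
    """The 221-value feature vector of one candidate plus its provenance."""

    origin: tuple[int, int]
    pd: np.ndarray
    ps: np.ndarray
    is_intensity: np.ndarray
    is_length: float
    spine_backbone: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    dendrite_distance: float = 0.0
    image_id: str = ""
    label: str = ""

    @property
    def combined(self) -> np.ndarray:
        vec = np.concatenate([self.pd, self.ps, self.is_intensity, [self.is_length]])
        if vec.shape != (N_FEATURES,):
            raise ValueError(f"feature vector has {len(vec)} values, expected {N_FEATURES}")
        return vec


# ---------------------------------------------------------------------------
# geodesic transforms


def _seed_list(seeds) -> list[tuple[int, int]]:
    arr = np.asarray(seeds)
    if arr.dtype == bool:
        arr = np.argwhere(arr)
    return [tuple(int(v) for v in p) for p in arr]


def geodesic_transform(mask, seeds, scale: float | None = None) -> GeodesicMap:
    """Shortest-path distance within the foreground, in um.

    8-connected with quasi-Euclidean edge weights (1 axial, sqrt(2)
    diagonal). Seeds must lie on the foreground. Off-foreground and
    unreachable foreground pixels get the UNDEFINED (inf) sentinel.
    """
    px = np.asarray(mask.pixels if hasattr(mask, "pixels") else mask, dtype=bool)
    s = float(scale if scale is not None else mask.scale)
    pts = _seed_list(seeds)
    if not pts:
        raise ValueError("empty seed set")
    for r, c in pts:
        if not px[r, c]:
            raise ValueError(f"seed ({r}, {c}) is not on the foreground")
    costs = np.where(px, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    cum, _ = mcp.find_costs(pts)
    values = np.where(px & np.isfinite(cum), cum / s, UNDEFINED)
    return GeodesicMap(values, s, len(pts))


class GeodesicPathFinder:
    """Geodesic distances plus minimal paths from a fixed seed set.

    One Dijkstra front is shared by all path queries, so per-candidate spine
    backbones cost one traceback each instead of one transform each.
    """

    def __init__(self, mask, seeds, scale: float | None = None):
        px = np.asarray(mask.pixels if hasattr(mask, "pixels") else mask, dtype=bool)
        self.scale = float(scale if scale is not None else mask.scale)
        self._px = px
        pts = _seed_list(seeds)
        if not pts:
            raise ValueError("empty seed set")
        self._seeds = set(pts)
        costs = np.where(px, 1.0, np.inf)
        self._mcp = MCP_Geometric(costs, fully_connected=True)
        cum, _ = self._mcp.find_costs(pts)
        self._cum = cum

    def distance_um(self, point) -> float:
        d = self._cum[int(point[0]), int(point[1])]
        return float(d / self.scale) if np.isfinite(d) else UNDEFINED

    def path_from_seed(self, point) -> np.ndarray | None:
        """Minimal path as (n, 2) int array ordered seed -> point, or None
        if the point is unreachable."""
        r, c = int(point[0]), int(point[1])
        if not np.isfinite(self._cum[r, c]):
            return None
        path = np.array(self._mcp.traceback((r, c)), dtype=int)
        if tuple(path[0]) not in self._seeds:
            path = path[::-1]
        return path


def path_length_um(path: np.ndarray, scale: float) -> float:
    """Quasi-Euclidean length of an 8-connected pixel path, in um."""
    if len(path) < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(np.asarray(path, float), axis=0), axis=1)
    return float(steps.sum() / scale)


# ---------------------------------------------------------------------------
# perimeter tracing

# clockwise Moore neighborhood starting north (row -1)
_CW = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_CW_INDEX = {off: i for i, off in enumerate(_CW)}


def _moore_trace(comp: np.ndarray) -> list[tuple[int, int]]:
    """Closed clockwise boundary contour of one 8-connected component."""
    rs, cs = np.nonzero(comp)
    start = (int(rs[0]), int(cs[0]))  # topmost, then leftmost
    H, W = comp.shape

    def fg(p):
        return 0 <= p[0] < H and 0 <= p[1] < W and comp[p]

    p = start
    back = (start[0] - 1, start[1])  # north of topmost pixel is background
    contour = [start]
    state0 = None
    for _ in range(8 * comp.sum() + 8):
        bi = _CW_INDEX[(back[0] - p[0], back[1] - p[1])]
        nxt = None
        for k in range(1, 9):
            off = _CW[(bi + k) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if fg(q):
                prev_off = _CW[(bi + k - 1) % 8]
                nxt = q
                back = (p[0] + prev_off[0], p[1] + prev_off[1])
                break
        if nxt is None:
            return contour  # isolated pixel
        state = (p, nxt)
        if state0 is None:
            state0 = state
        elif state == state0:
            break
        p = nxt
        contour.append(p)
    # the loop re-enters the start; drop the duplicated closing pixel
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    # the stopping state re-appends the first step; trim the re-entered start
    while len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def _perimeter4(comp: np.ndarray) -> np.ndarray:
    """Pixels of the component with a 4-neighbor outside the foreground
    (image border counts as background)."""
    return comp & ~ndi.binary_erosion(comp, structure=_S4, border_value=0)


def trace_perimeter(
    mask,
    rng_seed: int = 0,
    contain: tuple[int, int] | None = None,
) -> PerimeterTrace:
    """Order the perimeter of one component and assign travel positions.

    The closed perimeter is cut at a pixel chosen by the seeded RNG and
    walked in a single direction; each pixel's position is its cumulative
    quasi-Euclidean travel distance (um) from the cut. The component is the
    one containing ``contain``, or the largest.

    The perimeter is the component's *outer* boundary: interior holes that
    survive smoothing (obstacles for the geodesic transform, but not part of
    the spine-facing surface) contribute no positions.

    Raises :class:`PerimeterError`, naming the offending pixels, if the
    perimeter is not a simple closed curve (the failure mode that surface
    smoothing exists to prevent: duplicate position values).
    """
    px = np.asarray(mask.pixels if hasattr(mask, "pixels") else mask, dtype=bool)
    scale = float(mask.scale) if hasattr(mask, "scale") else 1.0
    lab, n = ndi.label(px, structure=_S8)
    if n == 0:
        raise PerimeterError("empty mask has no perimeter")
    if contain is not None:
        lbl = lab[int(contain[0]), int(contain[1])]
        if lbl == 0:
            raise PerimeterError(f"point {contain} is not on the foreground")
    else:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        lbl = int(sizes.argmax())
    comp = lab == lbl
    filled = ndi.binary_fill_holes(comp)
    contour = _moore_trace(filled)
    dups = [p for p, cnt in _count(contour).items() if cnt > 1]
    if dups:
        raise PerimeterError(
            f"perimeter is not a simple closed curve; duplicated pixels: {dups[:5]}"
        )
    missing = set(map(tuple, np.argwhere(_perimeter4(filled)))) - set(contour)
    if missing:
        raise PerimeterError(
            "perimeter is not a simple closed curve; boundary pixels missed "
            f"by the trace: {sorted(missing)[:5]}"
        )
    stray = [p for p in contour if not comp[p]]
    if stray:
        raise PerimeterError(
            f"outer boundary crosses an interior hole at: {stray[:5]}"
        )
    if len(contour) < 4:
        raise PerimeterError(f"perimeter too small to trace ({len(contour)} px)")
    rng = np.random.default_rng(rng_seed)
    k = int(rng.integers(len(contour)))
    contour = contour[k:] + contour[:k]
    pts = np.array(contour, dtype=int)
    diffs = np.diff(pts, axis=0)
    steps = np.linalg.norm(diffs, axis=1)
    positions = np.concatenate([[0.0], np.cumsum(steps)]) / scale
    closing = float(np.linalg.norm(pts[0] - pts[-1])) / scale
    return PerimeterTrace(pts, positions, float(positions[-1] + closing), scale)


def _count(items):
    out: dict = {}
    for it in items:
        out[it] = out.get(it, 0) + 1
    return out


# ---------------------------------------------------------------------------
# candidates


def find_candidates(
    gmap: GeodesicMap,
    trace: PerimeterTrace,
    border_margin_um: float = 1.5,
    shape: tuple[int, int] | None = None,
) -> list[CandidatePoint]:
    """Local maxima of the dendrite-distance map along the perimeter.

    The perimeter sequence is circular; plateaus of equal value yield their
    middle pixel (the first of the two middles for even plateaus). Maxima
    within ``border_margin_um`` of the image border are dropped, matching
    the margin used when labeling, so training and inference see the same
    candidate set.
    """
    vals = gmap.values[trace.pixels[:, 0], trace.pixels[:, 1]]
    n = len(vals)
    if n == 0 or not np.all(np.isfinite(vals)):
        bad = trace.pixels[~np.isfinite(vals)]
        raise ValueError(
            f"perimeter pixels unreachable from the seeds: {bad[:5].tolist()}"
        )
    # circular run-length encoding of equal values
    runs: list[tuple[int, int]] = []  # (start, length)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        runs.append((i, j - i + 1))
        i = j + 1
    if len(runs) > 1 and vals[0] == vals[-1]:
        # merge the wrap-around run
        s_last, l_last = runs.pop()
        s_first, l_first = runs.pop(0)
        runs.append((s_last, l_last + l_first))
    if len(runs) < 2:
        return []
    if shape is None:
        shape = gmap.values.shape
    margin = border_margin_um * gmap.scale
    H, W = shape
    out: list[CandidatePoint] = []
    m = len(runs)
    for k, (s, ln) in enumerate(runs):
        v = vals[s]
        vp = vals[runs[k - 1][0]]
        vn = vals[runs[(k + 1) % m][0]]
        if not (v > vp and v > vn):
            continue
        idx = (s + (ln - 1) // 2) % n
        r, c = trace.pixels[idx]
        if min(r, c, H - 1 - r, W - 1 - c) < margin:
            continue
        out.append(CandidatePoint((int(r), int(c)), int(idx), float(v)))
    out.sort(key=lambda cp: cp.trace_index)
    return out


def spine_backbone_path(origin, backbone, mask) -> np.ndarray | None:
    """Minimal within-tissue path from ``origin`` to the nearest backbone
    pixel, ordered backbone -> origin. Convenience wrapper; pipelines share
    one :class:`GeodesicPathFinder` instead."""
    seeds = backbone.pixels if hasattr(backbone, "pixels") else backbone
    finder = GeodesicPathFinder(mask, seeds)
    path = finder.path_from_seed(origin)
    if path is None:
        warnings.warn(f"candidate {tuple(origin)} cannot reach the backbone")
    return path


# ---------------------------------------------------------------------------
# feature vectors


def _window_values(
    trace: PerimeterTrace,
    origin_idx: int,
    values: np.ndarray,
    window_um: float,
    n_out: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample perimeter ``values`` over a window centered on the origin.

    The window spans exactly [-window/2, +window/2] um of travel distance
    around the origin, unwrapped circularly across the cut so the random cut
    position never corrupts a window. Returns (resampled values, absolute
    arc positions of the resampling grid). If the perimeter is shorter than
    the window the whole perimeter is used (flagged with a warning).
    """
    pos = trace.positions
    L = trace.total_length
    p0 = pos[origin_idx]
    if L < window_um:
        warnings.warn(
            f"perimeter ({L:.2f} um) shorter than the {window_um} um window; "
            "using the whole perimeter"
        )
        half = L / 2.0
    else:
        half = window_um / 2.0
    rel = (pos - p0 + L / 2.0) % L - L / 2.0
    order = np.argsort(rel, kind="stable")
    relo = rel[order]
    valo = values[order]
    # pad one wrapped sample on each side so the grid endpoints interpolate
    relx = np.concatenate([[relo[-1] - L], relo, [relo[0] + L]])
    valx = np.concatenate([[valo[-1]], valo, [valo[0]]])
    grid = np.linspace(-half, half, n_out)
    out = np.interp(grid, relx, valx)
    return out, grid + p0


def pd_vector(
    origin_idx: int,
    gmap: GeodesicMap,
    trace: PerimeterTrace,
    window_um: float = 5.0,
    n_out: int = N_PD,
    return_grid: bool = False,
):
    """Perimeter-distance-from-dendrite profile: dendrite-seeded geodesic
    values over a 5 um perimeter window, resampled to 100 values and
    min-shifted to 0 (so dendrite thickness drops out)."""
    vals = gmap.values[trace.pixels[:, 0], trace.pixels[:, 1]]
    vec, grid = _window_values(trace, origin_idx, vals, window_um, n_out)
    vec = vec - vec.min()
    return (vec, grid) if return_grid else vec


def ps_vector(
    origin_idx: int,
    spine_path: np.ndarray,
    mask,
    trace: PerimeterTrace,
    window_um: float = 5.0,
    n_out: int = N_PS,
    return_grid: bool = False,
):
    """Perimeter-distance-from-spine-backbone profile over the same 5 um
    window: a geodesic transform seeded at the candidate's spine backbone,
    read along the perimeter, resampled to 100 values, min-shifted to 0."""
    g = geodesic_transform(mask, np.asarray(spine_path, dtype=int))
    vals = g.values[trace.pixels[:, 0], trace.pixels[:, 1]]
    vec, grid = _window_values(trace, origin_idx, vals, window_um, n_out)
    vec = vec - vec.min()
    return (vec, grid) if return_grid else vec


def is_vector(
    spine_path: np.ndarray,
    img: CalibratedImage,
    n_out: int = N_IS,
) -> tuple[np.ndarray, float]:
    """Image intensities along the spine backbone, dendrite end -> tip,
    interpolated to 20 values; plus the backbone length in um."""
    path = np.asarray(spine_path, dtype=int)
    if len(path) < 2:
        raise ValueError("spine backbone must have at least 2 pixels")
    vals = img.pixels[path[:, 0], path[:, 1]]
    steps = np.linalg.norm(np.diff(path.astype(float), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)]) / img.scale
    grid = np.linspace(0.0, arc[-1], n_out)
    return np.interp(grid, arc, vals), float(arc[-1])


# ---------------------------------------------------------------------------
# pipeline composition


@dataclass
class PipelineResult:
    """Everything the full pipeline computed for one image."""

    image: CalibratedImage
    mask: object
    smooth: SmoothMask
    working_mask: SmoothMask
    backbone: Backbone
    detached: list
    trace: PerimeterTrace | None
    gmap: GeodesicMap | None
    candidates: list[CandidatePoint]
    features: list[CandidateFeature]
    intermediates: dict


def run_pipeline(
    img: CalibratedImage,
    rng_seed: int = 0,
    window_um: float = 5.0,
    border_margin_um: float = 1.5,
    min_branch_um: float = 2.0,
    intensity_source: str = "median",
    **binarize_kwargs,
) -> PipelineResult:
    """Segment, extract the backbone, smooth, drop detached objects, and
    compute every candidate's 221-value feature vector.

    ``intensity_source`` selects the image the IS intensities are sampled
    from: ``"median"`` (median-filtered, normalized; default for noise
    robustness) or ``"raw"`` (the normalized input).
    """
    mask, inter = binarize_pipeline(img, **binarize_kwargs)
    params = BackboneParams(
        img.scale, min_branch_um=min_branch_um, border_margin_um=border_margin_um
    )
    empty = PipelineResult(
        img, mask, SmoothMask(np.zeros_like(mask.pixels), img.scale),
        SmoothMask(np.zeros_like(mask.pixels), img.scale),
        Backbone(np.zeros_like(mask.pixels), [], params), [], None, None, [], [],
        inter,
    )
    if not mask.pixels.any():
        return empty
    bb = extract_backbone(mask, params)
    smooth = smooth_surface(mask)
    empty.smooth = smooth
    if bb.is_empty or not smooth.pixels.any():
        return empty
    objs = find_detached(smooth, bb, params)
    for obj in objs:
        obj.snr = object_snr(obj, img)
    classify_detached(objs)
    work = mask_out_detached(smooth, objs)
    empty.detached = objs
    empty.working_mask = work
    bb_px = bb.pixels & work.pixels
    if not bb_px.any():
        warnings.warn("backbone lost during surface smoothing; no candidates")
        return empty
    # restrict to the component holding the most backbone pixels
    lab, n = ndi.label(work.pixels, structure=_S8)
    counts = np.bincount(lab[bb_px], minlength=n + 1)
    main_lbl = int(counts.argmax())
    seeds = bb_px & (lab == main_lbl)
    comp_point = tuple(np.argwhere(seeds)[0])
    finder = GeodesicPathFinder(work, seeds)
    gvals = np.where(
        work.pixels & np.isfinite(finder._cum), finder._cum / img.scale, UNDEFINED
    )
    gmap = GeodesicMap(gvals, img.scale, int(seeds.sum()))
    trace = trace_perimeter(work, rng_seed=rng_seed, contain=comp_point)
    cands = find_candidates(gmap, trace, border_margin_um=border_margin_um)
    source = denoise_median(img) if intensity_source == "median" else img
    feats: list[CandidateFeature] = []
    for cp in cands:
        path = finder.path_from_seed(cp.origin)
        if path is None or len(path) < 2:
            warnings.warn(f"candidate {cp.origin} unreachable or degenerate; dropped")
            continue
        pd = pd_vector(cp.trace_index, gmap, trace, window_um=window_um)
        ps = ps_vector(cp.trace_index, path, work, trace, window_um=window_um)
        isv, length = is_vector(path, source)
        feats.append(
            CandidateFeature(
                origin=cp.origin,
                pd=pd,
                ps=ps,
                is_intensity=isv,
                is_length=length,
                spine_backbone=path,
                dendrite_distance=cp.dendrite_distance,
                image_id=img.source_id,
            )
        )
    return PipelineResult(
        img, mask, smooth, work, bb, objs, trace, gmap, cands, feats, inter
    )


def extract_all(
    img: CalibratedImage, rng_seed: int = 0, **kwargs
) -> list[CandidateFeature]:
    """Full pipeline; returns only the candidate feature vectors."""
    return run_pipeline(img, rng_seed=rng_seed, **kwargs).features
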