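"""Geodesic transform vs a uniform-cost-search oracle, perimeter tracing
properties, candidate detection, and the PD/PS/IS vectors."""

import heapq

import numpy as np
import pytest
from scipy import ndimage as ndi

from spinefind.backbone import BackboneParams, extract_backbone
from spinefind.calibration_io import CalibratedImage
from spinefind.features import (
    GeodesicMap,
    GeodesicPathFinder,
    PerimeterError,
    extract_all,
    find_candidates,
    geodesic_transform,
    is_vector,
    pd_vector,
    ps_vector,
    run_pipeline,
    spine_backbone_path,
    trace_perimeter,
)
from spinefind.preprocess import BinaryMask, binarize_pipeline
from spinefind.surface import SmoothMask, smooth_surface

SCALE = 15.0


# ---------------------------------------------------------------------------
# geodesic transform


def _ucs_oracle(mask, seeds, scale):
    """Plain Dijkstra over the 8-connected pixel graph, weights 1 / sqrt2."""
    H, W = mask.shape
    dist = np.full((H, W), np.inf)
    heap = []
    for r, c in seeds:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[rr, cc]:
                    nd = d + np.hypot(dr, dc)
                    if nd < dist[rr, cc] - 1e-15:
                        dist[rr, cc] = nd
                        heapq.heappush(heap, (nd, rr, cc))
    return dist / scale


def test_straight_line_distances():
    mask = np.zeros((8, 32), dtype=bool)
    mask[4, 2:30] = True
    g = geodesic_transform(mask, [(4, 2)], scale=SCALE)
    got = g.values[4, 2:30]
    assert np.allclose(got, np.arange(28) / SCALE)


def test_seeds_are_exactly_zero():
    rng = np.random.default_rng(0)
    mask = ndi.binary_dilation(rng.random((20, 20)) > 0.7)
    seeds = [tuple(p) for p in np.argwhere(mask)[:3]]
    g = geodesic_transform(mask, seeds, scale=SCALE)
    for r, c in seeds:
        assert g.values[r, c] == 0.0


def test_matches_uniform_cost_search_oracle():
    rng = np.random.default_rng(1)
    for trial in range(10):
        mask = ndi.binary_dilation(rng.random((20, 20)) > 0.75)
        if not mask.any():
            continue
        fg = np.argwhere(mask)
        seeds = [tuple(fg[i]) for i in rng.integers(0, len(fg), size=2)]
        g = geodesic_transform(mask, seeds, scale=SCALE)
        oracle = _ucs_oracle(mask, seeds, SCALE)
        reachable = np.isfinite(oracle) & mask
        assert np.allclose(g.values[reachable], oracle[reachable], atol=1e-9)
        assert np.all(np.isinf(g.values[~reachable]))


def test_l_corridor_matches_oracle():
    mask = np.zeros((20, 20), dtype=bool)
    mask[3, 3:17] = True
    mask[3:17, 16] = True
    g = geodesic_transform(mask, [(3, 3)], scale=1.0)
    oracle = _ucs_oracle(mask, [(3, 3)], 1.0)
    assert np.allclose(g.values[mask], oracle[mask], atol=1e-9)


def test_empty_and_invalid_seeds_rejected():
    mask = np.ones((8, 8), dtype=bool)
    mask[0, 0] = False
    with pytest.raises(ValueError):
        geodesic_transform(mask, [], scale=SCALE)
    with pytest.raises(ValueError):
        geodesic_transform(mask, [(0, 0)], scale=SCALE)


# ---------------------------------------------------------------------------
# perimeter tracing


def _rect_mask(shape=(40, 40), r0=10, r1=30, c0=8, c1=32):
    px = np.zeros(shape, dtype=bool)
    px[r0:r1, c0:c1] = True
    return SmoothMask(px, SCALE)


def test_rectangle_trace_increments():
    trace = trace_perimeter(_rect_mask(), rng_seed=0)
    assert trace.positions[0] == 0.0
    d = np.diff(trace.positions) * SCALE
    assert np.all(np.isclose(d, 1.0) | np.isclose(d, np.sqrt(2)))
    assert len(np.unique(trace.positions)) == len(trace)


def test_cut_invariance_up_to_cyclic_shift():
    t1 = trace_perimeter(_rect_mask(), rng_seed=1)
    t2 = trace_perimeter(_rect_mask(), rng_seed=99)
    assert t1.total_length == pytest.approx(t2.total_length)
    p1 = {tuple(p): q for p, q in zip(t1.pixels, t1.positions)}
    p2 = {tuple(p): q for p, q in zip(t2.pixels, t2.positions)}
    assert set(p1) == set(p2)
    L = t1.total_length
    shifts = {round((p1[k] - p2[k]) % L, 9) for k in p1}
    assert len(shifts) == 1


def test_spur_raises_perimeter_error():
    px = _rect_mask().pixels.copy()
    px[8:10, 20] = True  # 2 px spur: the trace must walk it twice
    with pytest.raises(PerimeterError):
        trace_perimeter(SmoothMask(px, SCALE), rng_seed=0)


# ---------------------------------------------------------------------------
# candidates


def _fake_gmap_on_trace(trace, values, shape=(40, 40)):
    arr = np.full(shape, np.inf)
    arr[trace.pixels[:, 0], trace.pixels[:, 1]] = values
    return GeodesicMap(arr, SCALE, 1)


def test_single_maximum_found():
    trace = trace_perimeter(_rect_mask(), rng_seed=0)
    vals = np.ones(len(trace))
    vals[10] = 5.0
    gmap = _fake_gmap_on_trace(trace, vals)
    cands = find_candidates(gmap, trace, border_margin_um=0.0)
    assert len(cands) == 1
    assert cands[0].trace_index == 10
    assert cands[0].dendrite_distance == 5.0


def test_plateau_yields_middle_pixel_first_of_two():
    trace = trace_perimeter(_rect_mask(), rng_seed=0)
    vals = np.ones(len(trace))
    vals[12:14] = 4.0  # plateau of two -> first of the two middles
    vals[30:33] = 4.0  # plateau of three -> center
    gmap = _fake_gmap_on_trace(trace, vals)
    idx = sorted(c.trace_index for c in find_candidates(gmap, trace, 0.0))
    assert idx == [12, 31]


def test_wraparound_maximum():
    trace = trace_perimeter(_rect_mask(), rng_seed=0)
    vals = np.ones(len(trace))
    vals[0] = 3.0
    vals[-1] = 3.0  # plateau across the cut
    gmap = _fake_gmap_on_trace(trace, vals)
    idx = [c.trace_index for c in find_candidates(gmap, trace, 0.0)]
    assert idx in ([0], [len(trace) - 1])


def test_border_margin_drops_candidates():
    trace = trace_perimeter(_rect_mask(r0=2, r1=38, c0=2, c1=38), rng_seed=0)
    vals = np.ones(len(trace))
    vals[5] = 9.0
    gmap = _fake_gmap_on_trace(trace, vals)
    # every perimeter pixel of this rectangle is within 1.5 um = 22.5 px of
    # the border of a 40 px image
    assert find_candidates(gmap, trace, border_margin_um=1.5) == []


def test_bare_tube_candidates_stay_low(short_spine_image):
    img, gt, _ = short_spine_image
    res = run_pipeline(img, rng_seed=0)
    tips = np.array(gt.spine_tips, dtype=float)
    for f in res.features:
        d = np.linalg.norm(tips - np.array(f.origin), axis=1) / SCALE
        if d.min() > 0.7:  # not a spine candidate: tube-edge ripple or bump
            assert f.dendrite_distance < 1.3


def test_spine_tips_recovered(short_spine_image):
    img, gt, _ = short_spine_image
    res = run_pipeline(img, rng_seed=0)
    origins = np.array([f.origin for f in res.features], dtype=float)
    for tip in gt.spine_tips:
        d = np.linalg.norm(origins - np.array(tip, float), axis=1) / SCALE
        assert d.min() <= 0.5


# ---------------------------------------------------------------------------
# spine backbone path


def _prepped(img):
    mask, _ = binarize_pipeline(img)
    params = BackboneParams(img.scale)
    bb = extract_backbone(mask, params)
    sm = smooth_surface(mask)
    return mask, bb, sm


def test_adjacent_origin_two_pixel_path():
    mask = np.zeros((64, 64), dtype=bool)
    mask[30:34, :] = True
    bb = np.zeros_like(mask)
    bb[31, :] = True
    finder = GeodesicPathFinder(mask, bb, scale=SCALE)
    path = finder.path_from_seed((32, 40))
    assert len(path) == 2
    assert bb[tuple(path[0])]
    assert tuple(path[-1]) == (32, 40)


def test_path_length_equals_gmap_value(short_spine_image):
    img, _, _ = short_spine_image
    res = run_pipeline(img, rng_seed=0)
    for f in res.features:
        g_at = res.gmap.at(f.origin)
        assert f.is_length == pytest.approx(g_at, abs=1e-9)


def test_path_length_near_ground_truth(short_spine_image):
    img, gt, _ = short_spine_image
    spec_stalks = {}
    res = run_pipeline(img, rng_seed=0)
    origins = np.array([f.origin for f in res.features], dtype=float)
    for tip, base in zip(gt.spine_tips, gt.spine_bases):
        d = np.linalg.norm(origins - np.array(tip, float), axis=1) / SCALE
        f = res.features[int(d.argmin())]
        truth = np.linalg.norm(np.array(tip) - np.array(base)) / SCALE
        assert f.is_length == pytest.approx(truth, rel=0.25, abs=0.25)


# ---------------------------------------------------------------------------
# feature vectors


def _spine_candidates(res, gt, max_um=0.5):
    origins = np.array([f.origin for f in res.features], dtype=float)
    out = []
    for tip in gt.spine_tips:
        d = np.linalg.norm(origins - np.array(tip, float), axis=1) / SCALE
        if d.min() <= max_um:
            out.append(res.features[int(d.argmin())])
    return out


def test_pd_properties(short_spine_image):
    img, gt, _ = short_spine_image
    res = run_pipeline(img, rng_seed=0)
    for f in res.features:
        assert len(f.pd) == 100
        assert f.pd.min() == 0.0
    for f in _spine_candidates(res, gt):
        interior = f.pd[33:67].max()
        assert interior > f.pd[0] and interior > f.pd[-1]  # rise then fall


def test_pd_window_arc_is_5um(short_spine_image):
    img, _, _ = short_spine_image
    res = run_pipeline(img, rng_seed=0)
    f = res.candidates[len(res.candidates) // 2]
    _, grid = pd_vector(f.trace_index, res.gmap, res.trace, return_grid=True)
    assert grid[-1] - grid[0] == pytest.approx(5.0)


def test_ps_properties(short_spine_image):
    img, gt, _ = short_spine_image
    res = run_pipeline(img, rng_seed=0)
    for f in res.features:
        assert len(f.ps) == 100
        assert f.ps.min() == 0.0
    for f in _spine_candidates(res, gt):
        assert f.ps[40:60].mean() < (f.ps[:20].mean() + f.ps[-20:].mean()) / 2


def test_is_properties(short_spine_image):
    img, gt, _ = short_spine_image
    res = run_pipeline(img, rng_seed=0)
    for f in res.features:
        assert len(f.is_intensity) == 20
        assert f.is_length > 0
    # bright head: along the path the intensity dips over the stalk, rises
    # again over the head, and falls off at the tip (interior bump)
    spines = _spine_candidates(res, gt)
    mean_profile = np.mean([f.is_intensity for f in spines], axis=0)
    dip = int(mean_profile[:15].argmin())          # darker stalk
    bump = mean_profile[dip:].max()                # brighter head
    assert bump > mean_profile[dip] + 0.02         # rise after the dip
    assert bump > mean_profile[-1]                 # fall toward the tip


def test_is_two_pixel_path_interpolation():
    px = np.zeros((64, 64))
    px[10, 10] = 0.2
    px[10, 11] = 0.8
    img = CalibratedImage(px, SCALE)
    vec, length = is_vector(np.array([[10, 10], [10, 11]]), img)
    assert np.allclose(vec, np.linspace(0.2, 0.8, 20))
    assert length == pytest.approx(1 / SCALE)


# ---------------------------------------------------------------------------
# extract_all


def test_empty_image_yields_no_candidates():
    img = CalibratedImage(np.zeros((64, 64)), SCALE)
    assert extract_all(img) == []


def test_extraction_deterministic(short_spine_image):
    img, _, _ = short_spine_image
    a = extract_all(img, rng_seed=5)
    b = extract_all(img, rng_seed=5)
    assert len(a) == len(b)
    for fa, fb in zip(a, b):
        assert fa.origin == fb.origin
        assert np.array_equal(fa.combined, fb.combined)


def _render_two_scale(scale, size):
    """One straight tube + one spine rendered analytically at a given scale."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    row = size / 2.0
    tube = np.abs(yy - row) <= 0.35 * scale
    base = (row, size / 2.0)
    stalk = (
        (np.abs(xx - base[1]) <= 0.15 * scale)
        & (yy < row)
        & (yy >= row - (0.35 + 1.0) * scale)
    )
    head_c = (row - (0.35 + 1.0) * scale, base[1])
    head = (yy - head_c[0]) ** 2 + (xx - head_c[1]) ** 2 <= (0.3 * scale) ** 2
    pre = np.where(tube | head, 0.9, np.where(stalk, 0.7, 0.05))
    pre = ndi.gaussian_filter(pre, 0.1 * scale)
    return CalibratedImage((pre - pre.min()) / np.ptp(pre), scale)


def test_scale_standardization_15_vs_30():
    feats = {}
    for scale, size in ((15.0, 128), (30.0, 256)):
        img = _render_two_scale(scale, size)
        res = run_pipeline(img, rng_seed=0)
        tip_row = size / 2.0 - (0.35 + 1.0 + 0.3) * scale
        origins = np.array([f.origin for f in res.features], dtype=float)
        d = np.hypot(origins[:, 0] - tip_row, origins[:, 1] - size / 2) / scale
        feats[scale] = res.features[int(d.argmin())]
    a, b = feats[15.0].combined, feats[30.0].combined
    pd_range = max(np.ptp(a[:100]), np.ptp(b[:100]))
    assert np.abs(a[:100] - b[:100]).max() <= 0.15 * pd_range
    assert np.abs(a[100:200] - b[100:200]).max() <= 0.15 * pd_range
    assert abs(a[220] - b[220]) <= 0.15 * max(a[220], b[220])
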