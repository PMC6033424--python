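"""Skeletonization and backbone cleanup: unit thickness, loop removal,
isolated-segment and branch trimming against an enumeration oracle, and kink
smoothing."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from spinefind.backbone import (
    Backbone,
    BackboneParams,
    Skeleton,
    branch_points,
    endpoints,
    extract_backbone,
    remove_loops,
    remove_short_isolated,
    skeletonize,
    smooth_kinks,
    trim_spurious_branches,
)
from spinefind.preprocess import BinaryMask, binarize_pipeline

SCALE = 15.0
_S8 = np.ones((3, 3), dtype=bool)


def no_2x2_block(px: np.ndarray) -> bool:
    return not (px[:-1, :-1] & px[:-1, 1:] & px[1:, :-1] & px[1:, 1:]).any()


# ---------------------------------------------------------------------------
# skeletonize


def test_bar_thins_to_line():
    mask = np.zeros((32, 64), dtype=bool)
    mask[14:19, 4:60] = True  # 5 px wide horizontal bar
    sk = skeletonize(BinaryMask(mask, SCALE))
    assert sk.pixels.sum() > 0
    # one pixel per column in the bar interior
    cols = sk.pixels[:, 10:54]
    assert np.all(cols.sum(axis=0) == 1)
    assert no_2x2_block(sk.pixels)


def test_disk_thins_to_center():
    yy, xx = np.mgrid[0:64, 0:64]
    mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
    sk = skeletonize(BinaryMask(mask, SCALE))
    assert no_2x2_block(sk.pixels)
    assert np.all(mask[sk.pixels])  # containment
    assert sk.pixels.sum() <= 20


def test_unit_thickness_invariant_random():
    rng = np.random.default_rng(0)
    for _ in range(5):
        mask = ndi.binary_dilation(rng.random((48, 48)) > 0.9, iterations=2)
        sk = skeletonize(BinaryMask(mask, SCALE))
        assert no_2x2_block(sk.pixels)
        assert np.all(mask[sk.pixels])


# ---------------------------------------------------------------------------
# loop removal


def _circle_skeleton(radius, shape=(64, 64)):
    t = np.linspace(0, 2 * np.pi, 3000)
    rr = np.clip((shape[0] // 2 + radius * np.sin(t)).round().astype(int), 0, shape[0] - 1)
    cc = np.clip((shape[1] // 2 + radius * np.cos(t)).round().astype(int), 0, shape[1] - 1)
    px = np.zeros(shape, dtype=bool)
    px[rr, cc] = True
    from skimage.morphology import thin

    return Skeleton(thin(px), SCALE)


def _holes(px):
    lab, n = ndi.label(~px, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool))
    border = set(np.unique(np.r_[lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])) - {0}
    return n - len(border)


def test_small_loop_removed():
    sk = _circle_skeleton(radius=2.0)  # encloses ~12 px << 0.5 um^2 = 112.5 px
    assert _holes(sk.pixels) == 1
    out = remove_loops(sk)
    assert _holes(out.pixels) == 0
    assert no_2x2_block(out.pixels)


def test_large_loop_preserved():
    sk = _circle_skeleton(radius=20.0)  # ~1250 px >> 112.5 px
    out = remove_loops(sk)
    assert _holes(out.pixels) == 1


def test_loopfree_unchanged():
    px = np.zeros((32, 32), dtype=bool)
    px[16, 4:28] = True
    out = remove_loops(Skeleton(px, SCALE))
    assert np.array_equal(out.pixels, px)


# ---------------------------------------------------------------------------
# isolated-segment removal


def _segment(length, row=16, col0=4, shape=(32, 96)):
    px = np.zeros(shape, dtype=bool)
    px[row, col0 : col0 + length] = True
    return px


@pytest.mark.parametrize(
    "length,kept", [(10, False), (29, False), (30, True), (45, True)]
)
def test_isolated_segment_boundary(length, kept):
    params = BackboneParams(SCALE)  # M = 30
    assert params.M == 30
    out = remove_short_isolated(Skeleton(_segment(length), SCALE), params)
    assert out.pixels.any() == kept


def test_retention_boundary_in_um_is_2():
    params = BackboneParams(SCALE)
    kept_lengths = [
        L for L in range(15, 46)
        if remove_short_isolated(Skeleton(_segment(L), SCALE), params).pixels.any()
    ]
    assert min(kept_lengths) / SCALE == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# branch trimming


def _line_with_branch(shape=(100, 160), row=50, branch_col=80, branch_len=10):
    px = np.zeros(shape, dtype=bool)
    px[row, :] = True  # spans the full width: endpoints are border-protected
    px[row - branch_len : row, branch_col] = True
    return px


def test_short_side_branch_removed_line_intact():
    # the branch endpoint must lie outside the 23 px protected border margin
    px = _line_with_branch(branch_len=10)
    params = BackboneParams(SCALE)  # M = 30, margin 23 px
    out = trim_spurious_branches(Skeleton(px, SCALE), params)
    expected = np.zeros_like(px)
    expected[50, :] = True
    assert np.array_equal(out.pixels, expected)


def test_branchless_line_unchanged():
    px = np.zeros((100, 160), dtype=bool)
    px[50, :] = True
    params = BackboneParams(SCALE)
    out = trim_spurious_branches(Skeleton(px, SCALE), params)
    assert np.array_equal(out.pixels, px)


def test_t_shape_with_long_arms_kept():
    # interior T: all three arms longer than M survive via the restore rule
    px = np.zeros((100, 100), dtype=bool)
    px[50, 15:85] = True   # two horizontal arms of ~35 px
    px[15:50, 50] = True   # vertical arm of 35 px
    params = BackboneParams(SCALE, border_margin_um=0.5)  # margin 8 px
    out = trim_spurious_branches(Skeleton(px, SCALE), params)
    assert np.array_equal(out.pixels, px)


def _random_tree_skeleton(rng, shape=(24, 24), M=8, margin=2):
    """Main path spanning the grid + straight side branches, pairwise clear."""
    H, W = shape
    px = np.zeros(shape, dtype=bool)
    row = int(rng.integers(8, H - 8))
    px[row, :] = True
    branches = []
    cols = rng.permutation(np.arange(margin + 2, W - margin - 2))
    for col in cols[: rng.integers(1, 4)]:
        if any(abs(col - c) < 4 for c, _, _ in branches):
            continue
        up = bool(rng.integers(2))
        length = int(rng.integers(1, 13))
        if up:
            length = min(length, row - margin - 1)
        else:
            length = min(length, H - margin - 2 - row)
        if length < 1:
            continue
        if up:
            px[row - length : row, col] = True
        else:
            px[row + 1 : row + 1 + length, col] = True
        branches.append((col, up, length))
    return px, row, branches


def _trim_oracle(px, row, branches, M):
    """Delete each endpoint-terminated branch with fewer than M pixels."""
    out = px.copy()
    for col, up, length in branches:
        if length < M:
            if up:
                out[row - length : row, col] = False
            else:
                out[row + 1 : row + 1 + length, col] = False
    return out


def test_trimming_matches_branch_enumeration_oracle():
    params = BackboneParams(scale=4.0, border_margin_um=0.5)  # M=8, margin 2px
    assert params.M == 8
    rng = np.random.default_rng(42)
    for _ in range(200):
        px, row, branches = _random_tree_skeleton(rng, M=params.M)
        got = trim_spurious_branches(Skeleton(px, params.scale), params)
        want = _trim_oracle(px, row, branches, params.M)
        assert np.array_equal(got.pixels, want)


def test_trimming_is_fixed_point():
    params = BackboneParams(scale=4.0, border_margin_um=0.5)
    rng = np.random.default_rng(7)
    for _ in range(20):
        px, _, _ = _random_tree_skeleton(rng, M=params.M)
        once = trim_spurious_branches(Skeleton(px, params.scale), params)
        twice = trim_spurious_branches(once, params)
        assert np.array_equal(once.pixels, twice.pixels)


# ---------------------------------------------------------------------------
# kink smoothing


def _kinked_line(shape=(24, 48)):
    """Horizontal path with a 2-px-high zigzag kink at col 22-26; the
    untrimmed skeleton also has a vertical branch at the kink apex."""
    trimmed = np.zeros(shape, dtype=bool)
    row = 12
    cols = np.arange(shape[1])
    rows = np.full(shape[1], row)
    rows[22] = row - 1
    rows[23] = row - 2
    rows[24] = row - 2
    rows[25] = row - 1
    trimmed[rows, cols] = True
    untrimmed = trimmed.copy()
    untrimmed[4 : row - 2, 23] = True  # former spine branch
    return trimmed, untrimmed, row


def test_kink_straightened():
    trimmed, untrimmed, row = _kinked_line()
    params = BackboneParams(scale=6.0)  # M=12, dilation radius 3
    out = smooth_kinks(
        Skeleton(trimmed, 6.0), Skeleton(untrimmed, 6.0), params
    )
    assert out.pixels.sum() > 0
    rows_used = np.nonzero(out.pixels.any(axis=1))[0]
    assert rows_used.min() >= row - 1  # the 2-px kink apex is gone
    lab, n = ndi.label(out.pixels, structure=_S8)
    assert n == 1
    assert endpoints(out.pixels).sum() == 2


def test_no_branchpoints_is_identity():
    px = np.zeros((24, 48), dtype=bool)
    px[12, 2:46] = True
    params = BackboneParams(scale=6.0)
    out = smooth_kinks(Skeleton(px, 6.0), Skeleton(px, 6.0), params)
    assert np.array_equal(out.pixels, px)


def test_repair_not_longer_than_original():
    trimmed, untrimmed, _ = _kinked_line()
    params = BackboneParams(scale=6.0)
    out = smooth_kinks(Skeleton(trimmed, 6.0), Skeleton(untrimmed, 6.0), params)
    assert out.pixels.sum() <= trimmed.sum()  # straight line is shortest


# ---------------------------------------------------------------------------
# full extraction


def test_backbone_on_synthetic_dendrite(short_spine_image):
    img, gt, _ = short_spine_image
    mask, _ = binarize_pipeline(img)
    params = BackboneParams(img.scale)
    bb = extract_backbone(mask, params)
    assert len(bb.components) == 1
    assert endpoints(bb.pixels).sum() == 2
    assert branch_points(bb.pixels).sum() == 0
    # mean distance to the true centerline
    pts = np.argwhere(bb.pixels)
    d, _ = cKDTree(gt.centerline).query(pts)
    assert d.mean() <= 1.5
    # backbone stays inside (the 1-px dilation of) the mask
    grown = ndi.binary_dilation(mask.pixels, structure=_S8)
    assert np.all(grown[bb.pixels])


def test_empty_mask_flagged():
    params = BackboneParams(SCALE)
    with pytest.warns(UserWarning):
        import warnings

        warnings.simplefilter("always")
        bb = extract_backbone(np.zeros((64, 64), dtype=bool), params)
    assert bb.is_empty


def test_two_parallel_dendrites():
    mask = np.zeros((96, 96), dtype=bool)
    mask[28:33, :] = True
    mask[68:73, :] = True
    params = BackboneParams(SCALE)
    bb = extract_backbone(BinaryMask(mask, SCALE), params)
    assert len(bb.components) == 2
    assert all(len(c) >= params.M for c in bb.components)
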