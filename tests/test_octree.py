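"""Unit and property tests for the linear oct-tree."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from treemd.octree import (EmptyTreeError, OctreeConfig, OutOfBoxError,
                           QueryCounters, build, compute_box_id,
                           nearest_within, nearest_within_batch,
                           neighbors_within, root_box_for)

UNIT = OctreeConfig(max_depth=5, origin=np.zeros(3), side=1.0)


def brute_neighbors(positions, point, r_max):
    d2 = ((positions - point) ** 2).sum(axis=1)
    return np.flatnonzero(d2 <= r_max * r_max)


def brute_nearest(positions, point, r_max):
    d2 = ((positions - point) ** 2).sum(axis=1)
    hit = d2 <= r_max * r_max
    if not hit.any():
        return None
    d2m = np.where(hit, d2, np.inf)
    k = int(np.argmin(d2m))        # first minimum = smallest-index tie-break
    return k, float(np.sqrt(d2[k]))


# -- box identifiers ----------------------------------------------------------

def test_min_corner_id_zero():
    assert compute_box_id(np.zeros(3), UNIT) == 0


def test_depth5_ids_are_15_bit():
    assert UNIT.id_bits == 15
    rng = np.random.default_rng(0)
    ids = compute_box_id(rng.random((1000, 3)), UNIT)
    assert ids.min() >= 0 and ids.max() < 2 ** 15
    # the inclusive upper face maps to the all-ones id
    assert compute_box_id(np.ones(3), UNIT) == 2 ** 15 - 1


def test_center_is_octant_seven_at_depth_one():
    cfg = OctreeConfig(max_depth=1, origin=np.zeros(3), side=1.0)
    assert compute_box_id(np.full(3, 0.5), cfg) == 7


def test_outside_box_raises():
    with pytest.raises(OutOfBoxError):
        compute_box_id(np.array([1.5, 0.5, 0.5]), UNIT)
    with pytest.raises(OutOfBoxError):
        compute_box_id(np.array([-0.1, 0.5, 0.5]), UNIT)


def test_same_box_shares_id_prefix():
    cfg = OctreeConfig(max_depth=3, origin=np.zeros(3), side=8.0)
    # both points lie in the depth-1 octant [4,8)³ -> same top 3 bits
    a = compute_box_id(np.array([4.1, 4.1, 4.1]), cfg)
    b = compute_box_id(np.array([7.9, 7.9, 7.9]), cfg)
    assert a >> 6 == b >> 6 == 7


# -- build --------------------------------------------------------------------

def test_build_single_particle():
    tree = build(np.array([[0.3, 0.3, 0.3]]), max_depth=4)
    assert tree.n == 1 and list(tree.perm) == [0]


def test_build_empty_raises():
    with pytest.raises(EmptyTreeError):
        build(np.empty((0, 3)))


def test_octant_centers_sort_to_codes_0_to_7():
    centers = np.array([[0.25 + 0.5 * bx, 0.25 + 0.5 * by, 0.25 + 0.5 * bz]
                        for bx in (0, 1) for by in (0, 1) for bz in (0, 1)])
    cfg = OctreeConfig(max_depth=1, origin=np.zeros(3), side=1.0)
    tree = build(centers, config=cfg)
    assert list(tree.ids) == list(range(8))


@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 400))
def test_build_invariants(seed, n):
    pos = np.random.default_rng(seed).random((n, 3)) * 10
    tree = build(pos, max_depth=6)
    assert np.all(np.diff(tree.ids) >= 0)
    assert sorted(tree.perm) == list(range(n))
    # stable tie-break: equal ids keep ascending original order
    same = np.diff(tree.ids) == 0
    assert np.all(np.diff(tree.perm)[same] > 0)


def test_root_box_contains_all():
    rng = np.random.default_rng(3)
    pos = rng.normal(size=(500, 3)) * 7
    cfg = root_box_for(pos)
    ids = compute_box_id(pos, cfg)     # raises if any point falls outside
    assert len(ids) == 500


# -- queries ------------------------------------------------------------------

def test_neighbors_within_trivial_radii():
    rng = np.random.default_rng(1)
    pos = rng.random((200, 3))
    tree = build(pos, max_depth=5)
    all_idx = neighbors_within(tree, np.full(3, 0.5), 10.0)
    assert list(all_idx) == list(range(200))
    assert len(neighbors_within(tree, np.full(3, 0.123456), 0.0)) == 0


def test_neighbors_within_matches_brute():
    rng = np.random.default_rng(7)
    pos = rng.uniform(0, 20, (1000, 3))
    tree = build(pos, max_depth=6)
    for point in rng.uniform(0, 20, (100, 3)):
        got = neighbors_within(tree, point, 5.0)
        want = brute_neighbors(pos, point, 5.0)
        assert np.array_equal(got, want)


def test_nearest_within_coincident_point():
    rng = np.random.default_rng(9)
    pos = rng.random((50, 3))
    tree = build(pos, max_depth=5)
    idx, dist = nearest_within(tree, pos[17], 1.0)
    assert idx == 17 and dist == 0.0


def test_nearest_within_none():
    tree = build(np.array([[0.0, 0.0, 0.0]]), max_depth=3)
    assert nearest_within(tree, np.array([5.0, 5.0, 5.0]), 1.0) is None


def test_nearest_within_tie_break_smallest_index():
    # two particles exactly equidistant from the query point
    pos = np.array([[2.0, 0.0, 0.0], [0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
    tree = build(pos, max_depth=4)
    idx, dist = nearest_within(tree, np.array([3.0, 0.0, 0.0]), 10.0)
    assert idx == 0 and dist == 1.0


def test_nearest_batch_matches_brute():
    rng = np.random.default_rng(11)
    pos = rng.uniform(0, 15, (2000, 3))
    tree = build(pos, max_depth=7)
    pts = rng.uniform(0, 15, (500, 3))
    r = rng.uniform(0.1, 3.0, 500)
    idx, d2 = nearest_within_batch(tree, pts, r)
    for k in range(500):
        want = brute_nearest(pos, pts[k], r[k])
        if want is None:
            assert idx[k] == -1
        else:
            assert idx[k] == want[0]
            assert np.sqrt(d2[k]) == want[1]


def test_query_counters_advance():
    rng = np.random.default_rng(13)
    pos = rng.random((500, 3))
    tree = build(pos, max_depth=6)
    ctr = QueryCounters()
    neighbors_within(tree, np.full(3, 0.5), 0.2, counters=ctr)
    assert ctr.dist_evals > 0 and ctr.total == ctr.box_tests + ctr.dist_evals
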