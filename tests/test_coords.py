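"""Coordinate store contract: equivalence, merging, costs, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imflow.coords import (OctreeStore, PointListStore, QuadtreeStore,
                           store_from_mask, store_to_mask)
from imflow.errors import BoundsError, ConfigurationError

from .conftest import octree_oracle, quadtree_oracle, random_mask

METHODS = ("pointlist", "quadtree", "octree")


def walk_is_maximally_merged(node) -> bool:
    """Tree-walk audit: no subdivided node has uniform same-state children."""
    if node.is_leaf():
        return True
    states = {child.state for child in node.children}
    if states in ({True}, {False}):
        return False
    return all(walk_is_maximally_merged(c) for c in node.children)


# ---------------------------------------------------------------------------
# construction


def test_uniform_foreground_region_needs_no_subdivision():
    mask = np.ones((1, 256, 256), dtype=bool)
    store = store_from_mask(mask, "quadtree")
    assert store.node_count() == 1
    assert store.leaf_count() == 1
    assert len(store) == 256 * 256


@pytest.mark.parametrize("k", range(1, 9))
def test_single_pixel_quadtree_law(k):
    """One foreground pixel in a 2^k square: 4k+1 nodes, 3k+1 leaves,
    matching the brute-force subdivision oracle."""
    size = 2 ** k
    mask = np.zeros((1, size, size), dtype=bool)
    mask[0, 0, 0] = True
    store = store_from_mask(mask, "quadtree")
    o_nodes, o_leaves, o_fg = quadtree_oracle(mask[0])
    assert (o_nodes, o_leaves, o_fg) == (4 * k + 1, 3 * k + 1, 1)
    assert store.node_count() == o_nodes
    assert store.leaf_count() == o_leaves
    assert len(store) == 1


def test_single_voxel_octree_law():
    mask = np.zeros((64, 64, 64), dtype=bool)
    mask[0, 0, 0] = True
    store = store_from_mask(mask, "octree")
    o_nodes, o_leaves, _ = octree_oracle(mask)
    assert o_nodes == 49  # 1 root + 6 levels x 8 children
    assert store.node_count() == o_nodes
    assert store.leaf_count() == o_leaves


def test_empty_mask_yields_valid_empty_store():
    mask = np.zeros((2, 8, 8), dtype=bool)
    for method in METHODS:
        store = store_from_mask(mask, method)
        assert len(store) == 0
        assert store.is_empty()
        assert np.array_equal(store_to_mask(store, 8, 8, 2), mask)


def test_unknown_method_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        store_from_mask(np.zeros((1, 4, 4), bool), "rle")


def test_non_power_of_two_extents_pad_with_background():
    mask = np.ones((1, 5, 7), dtype=bool)  # root square is 8x8
    store = store_from_mask(mask, "quadtree")
    assert len(store) == 35
    assert np.array_equal(store_to_mask(store, 7, 5, 1), mask)
    o_nodes, _, o_fg = quadtree_oracle(mask[0])
    assert store.node_count() == o_nodes
    assert o_fg == 35


# ---------------------------------------------------------------------------
# round trips, membership, counts


def test_round_trip_many_random_masks():
    rng = np.random.default_rng(7)
    for _ in range(15):
        mask = random_mask(rng)
        nz, h, w = mask.shape
        for method in METHODS:
            store = store_from_mask(mask, method)
            assert len(store) == int(mask.sum()), method
            assert np.array_equal(store_to_mask(store, w, h, nz), mask), method


def test_membership_matches_dense_mask():
    rng = np.random.default_rng(11)
    mask = random_mask(rng)
    nz, h, w = mask.shape
    stores = [store_from_mask(mask, m) for m in METHODS]
    probes = rng.integers(0, (w, h, nz), size=(200, 3))
    for x, y, z in probes:
        expected = bool(mask[z, y, x])
        for store in stores:
            assert store.contains(int(x), int(y), int(z)) == expected


def test_single_pixel_membership_and_neighbours():
    for method in METHODS:
        mask = np.zeros((1, 16, 16), dtype=bool)
        mask[0, 5, 6] = True
        store = store_from_mask(mask, method)
        assert (6, 5, 0) in store
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert (6 + dx, 5 + dy, 0) not in store


def test_solid_square_count_is_area_for_all_methods():
    mask = np.zeros((1, 16, 16), dtype=bool)
    mask[0, 3:13, 2:12] = True
    for method in METHODS:
        assert len(store_from_mask(mask, method)) == 100


def test_to_mask_bounds_error_when_extents_too_small():
    store = PointListStore([(9, 0, 0)])
    with pytest.raises(BoundsError):
        store_to_mask(store, 5, 5, 1)


# ---------------------------------------------------------------------------
# maximal merging and incremental insertion


def test_trees_are_maximally_merged_after_construction():
    rng = np.random.default_rng(3)
    for _ in range(10):
        mask = random_mask(rng)
        qt = store_from_mask(mask, "quadtree")
        for root in qt.roots().values():
            assert walk_is_maximally_merged(root)
        oc = store_from_mask(mask, "octree")
        assert walk_is_maximally_merged(oc.root())


def test_add_voxel_re_merges_immediately():
    # fill a 4x4 slice pixel by pixel: the final tree must be a single node
    qt = QuadtreeStore(4, 4)
    for y in range(4):
        for x in range(4):
            qt.add(x, y, 0)
            for root in qt.roots().values():
                assert walk_is_maximally_merged(root)
    assert qt.node_count() == 1
    assert len(qt) == 16

    oc = OctreeStore(2, 2, 2)
    for z in range(2):
        for y in range(2):
            for x in range(2):
                oc.add(x, y, z)
    assert oc.node_count() == 1
    assert len(oc) == 8


def test_duplicate_insertion_changes_nothing():
    for method in METHODS:
        mask = np.zeros((1, 8, 8), dtype=bool)
        mask[0, 2, 2] = True
        store = store_from_mask(mask, method)
        before = (len(store), store.cost)
        store.add(2, 2, 0)
        assert (len(store), store.cost) == before


def test_negative_coordinates_rejected():
    store = PointListStore()
    with pytest.raises(BoundsError):
        store.add(-1, 0, 0)


# ---------------------------------------------------------------------------
# cost model


def test_cost_single_pixel_pointlist_beats_quadtree():
    mask = np.zeros((1, 256, 256), dtype=bool)
    mask[0, 128, 128] = True
    pl = store_from_mask(mask, "pointlist")
    qt = store_from_mask(mask, "quadtree")
    assert pl.cost == 3
    assert qt.cost == 4 * quadtree_oracle(mask[0])[0]
    assert pl.cost < qt.cost


def test_cost_solid_disk_quadtree_beats_pointlist():
    yy, xx = np.ogrid[0:256, 0:256]
    mask = (((yy - 128) ** 2 + (xx - 128) ** 2) <= 100 ** 2)[np.newaxis]
    pl = store_from_mask(mask, "pointlist")
    qt = store_from_mask(mask, "quadtree")
    assert pl.cost == 3 * int(mask.sum())
    assert qt.cost < pl.cost


def test_cost_all_foreground_extreme():
    mask = np.ones((1, 256, 256), dtype=bool)
    assert store_from_mask(mask, "quadtree").cost == 4
    assert store_from_mask(mask, "pointlist").cost == 196_608


def test_cost_ordering_thin_skeleton_favours_pointlist():
    # a 1-pixel-wide diagonal forces subdivision to pixel level
    mask = np.zeros((1, 256, 256), dtype=bool)
    idx = np.arange(256)
    mask[0, idx, idx] = True
    pl = store_from_mask(mask, "pointlist")
    qt = store_from_mask(mask, "quadtree")
    assert pl.cost < qt.cost


def test_nonempty_store_cost_at_least_one():
    mask = np.zeros((1, 2, 2), dtype=bool)
    mask[0, 0, 0] = True
    for method in METHODS:
        assert store_from_mask(mask, method).cost >= 1


# ---------------------------------------------------------------------------
# property tests


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_equivalence_property_all_methods_agree(seed):
    """Pointlist, quadtree and octree stores of the same mask expose the same
    voxel set, count and round-trip mask."""
    rng = np.random.default_rng(seed)
    mask = random_mask(rng, max_side=32, max_slices=3)
    nz, h, w = mask.shape
    stores = [store_from_mask(mask, m) for m in METHODS]
    counts = {len(s) for s in stores}
    assert counts == {int(mask.sum())}
    reference = store_to_mask(stores[0], w, h, nz)
    for store in stores[1:]:
        assert np.array_equal(store_to_mask(store, w, h, nz), reference)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_tree_counts_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = random_mask(rng, max_side=16, max_slices=2)
    qt = store_from_mask(mask, "quadtree")
    expected_nodes = sum(
        quadtree_oracle(mask[z])[0] for z in range(mask.shape[0]) if mask[z].any()
    )
    assert qt.node_count() == expected_nodes
    oc = store_from_mask(mask, "octree")
    o_nodes, o_leaves, o_fg = octree_oracle(mask)
    if mask.any():
        assert oc.node_count() == o_nodes
        assert len(oc) == o_fg
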