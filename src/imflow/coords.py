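"""Object coordinate stores: pointlists, quadtrees and octrees.

An identified object is a set of foreground voxels. Small or sparse objects
(spots, skeletons) are cheapest to keep as an explicit list of (x, y, z)
coordinates — a *pointlist*. Large solid regions compress far better as
recursive spatial subdivisions: a *quadtree* splits each z-slice into
quadrants until every node is uniformly foreground or background, and an
*octree* does the same over the full 3D volume with octants. All three
implementations satisfy one contract (membership, count, iteration, mask
round-trip), so downstream measurements are identical whichever store holds
the region; only the memory footprint differs.

Memory is modelled in abstract units rather than bytes so the trade-offs are
hardware independent: a pointlist costs 3 units per voxel (x, y, z), a tree
costs 4 units per node (corner coordinates, side length, state). Users with a
concrete byte layout can recalibrate by scaling these two constants.

Masks are numpy arrays indexed ``[z, y, x]``; voxels are ``(x, y, z)``
integer tuples.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Iterable, Iterator

import numpy as np

from .errors import BoundsError, ConfigurationError

__all__ = [
    "CoordinateStore",
    "PointListStore",
    "QuadtreeStore",
    "OctreeStore",
    "store_from_mask",
    "store_to_mask",
    "STORE_METHODS",
]

STORE_METHODS = ("pointlist", "quadtree", "octree")

# Abstract memory-cost model (units, not bytes).
POINTLIST_UNITS_PER_VOXEL = 3
TREE_UNITS_PER_NODE = 4

Voxel = tuple[int, int, int]


def _next_pow2(n: int) -> int:
    n = max(1, int(n))
    p = 1
    while p < n:
        p *= 2
    return p


def _as_mask3d(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    if arr.ndim != 3:
        raise ConfigurationError(f"mask must be 2D or 3D, got ndim={arr.ndim}")
    if min(arr.shape) < 1:
        raise ConfigurationError("mask must be non-empty in every axis")
    return arr.astype(bool, copy=False)


class CoordinateStore(ABC):
    """Common contract for all coordinate storage methods."""

    method: str

    @abstractmethod
    def add(self, x: int, y: int, z: int) -> None:
        """Insert one voxel; duplicates are a no-op."""

    @abstractmethod
    def contains(self, x: int, y: int, z: int) -> bool:
        """Membership test."""

    @abstractmethod
    def __len__(self) -> int:
        """Number of stored foreground voxels."""

    @abstractmethod
    def _iter_unordered(self) -> Iterable[Voxel]: ...

    def __iter__(self) -> Iterator[Voxel]:
        # Deterministic (z, y, x) scan order regardless of storage method, so
        # every downstream measurement is bit-identical across methods.
        return iter(sorted(self._iter_unordered(), key=lambda v: (v[2], v[1], v[0])))

    def __contains__(self, voxel) -> bool:
        x, y, z = voxel
        return self.contains(int(x), int(y), int(z))

    @property
    @abstractmethod
    def cost(self) -> int:
        """Abstract memory units occupied by this store."""

    def is_empty(self) -> bool:
        return len(self) == 0

    def coordinate_array(self) -> np.ndarray:
        """(n, 3) int array of voxels as columns x, y, z, in scan order."""
        vox = list(self)
        if not vox:
            return np.zeros((0, 3), dtype=np.int64)
        return np.asarray(vox, dtype=np.int64)


class PointListStore(CoordinateStore):
    """Explicit set of (x, y, z) voxel coordinates."""

    method = "pointlist"

    def __init__(self, voxels: Iterable[Voxel] = ()):
        self._voxels: set[Voxel] = set()
        for x, y, z in voxels:
            self.add(x, y, z)

    def add(self, x: int, y: int, z: int) -> None:
        if x < 0 or y < 0 or z < 0:
            raise BoundsError(f"voxel components must be >= 0, got {(x, y, z)}")
        self._voxels.add((int(x), int(y), int(z)))

    def contains(self, x: int, y: int, z: int) -> bool:
        return (x, y, z) in self._voxels

    def __len__(self) -> int:
        return len(self._voxels)

    def _iter_unordered(self):
        return self._voxels

    @property
    def cost(self) -> int:
        return POINTLIST_UNITS_PER_VOXEL * len(self._voxels)

    @classmethod
    def from_mask(cls, mask) -> "PointListStore":
        arr = _as_mask3d(mask)
        z, y, x = np.nonzero(arr)
        store = cls()
        store._voxels = {(int(a), int(b), int(c)) for a, b, c in zip(x, y, z)}
        return store


class _Node:
    """One square/cube of a subdivision tree.

    ``state`` is True (uniform foreground), False (uniform background) or
    None (subdivided, in which case ``children`` holds the sub-nodes).
    """

    __slots__ = ("state", "children")

    def __init__(self, state: bool | None, children=None):
        self.state = state
        self.children = children

    def is_leaf(self) -> bool:
        return self.children is None


def _merge(node: _Node) -> None:
    """Collapse a node whose children are all uniform leaves of one state."""
    kids = node.children
    if kids is None:
        return
    first = kids[0].state
    if first is None:
        return
    for child in kids[1:]:
        if child.state is not first:
            return
    node.state = first
    node.children = None


class QuadtreeStore(CoordinateStore):
    """Per-z-slice quadtrees over a power-of-two square.

    Each occupied slice holds one tree; the root square is the smallest power
    of two covering the slice extent, and the area padded beyond the image is
    uniform background (it is never emitted as coordinates). Subdivision stops
    as soon as a quadrant is uniformly foreground or background, and the tree
    is kept maximally merged: no subdivided node ever has four uniform
    children of the same state.
    """

    method = "quadtree"

    _OFFSETS = ((0, 0), (1, 0), (0, 1), (1, 1))  # (dx, dy) half-multiples

    def __init__(self, width: int = 1, height: int = 1):
        self.width = int(width)
        self.height = int(height)
        self.root_size = _next_pow2(max(self.width, self.height))
        self._trees: dict[int, _Node] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_mask(cls, mask) -> "QuadtreeStore":
        arr = _as_mask3d(mask)
        nz, ny, nx = arr.shape
        store = cls(nx, ny)
        for z in range(nz):
            sl = arr[z]
            if not sl.any():
                continue
            integral = np.zeros((ny + 1, nx + 1), dtype=np.int64)
            np.cumsum(np.cumsum(sl, axis=0), axis=1, out=integral[1:, 1:])
            store._trees[z] = cls._build(integral, nx, ny, 0, 0, store.root_size)
        return store

    @staticmethod
    def _build(integral: np.ndarray, nx: int, ny: int, x0: int, y0: int, size: int) -> _Node:
        # Region sum clipped to the real extent; padding contributes zero and
        # can therefore never be part of a uniform-foreground node.
        x1 = min(x0 + size, nx)
        y1 = min(y0 + size, ny)
        xa = min(x0, nx)
        ya = min(y0, ny)
        total = int(integral[y1, x1] - integral[ya, x1] - integral[y1, xa] + integral[ya, xa])
        if total == 0:
            return _Node(False)
        if total == size * size:
            return _Node(True)
        half = size // 2
        children = [
            QuadtreeStore._build(integral, nx, ny, x0 + dx * half, y0 + dy * half, half)
            for dx, dy in QuadtreeStore._OFFSETS
        ]
        return _Node(None, children)

    # -- mutation ----------------------------------------------------------

    def add(self, x: int, y: int, z: int) -> None:
        if x < 0 or y < 0 or z < 0:
            raise BoundsError(f"voxel components must be >= 0, got {(x, y, z)}")
        if x >= self.root_size or y >= self.root_size:
            raise BoundsError(
                f"voxel {(x, y, z)} outside root square of size {self.root_size}"
            )
        self.width = max(self.width, x + 1)
        self.height = max(self.height, y + 1)
        root = self._trees.setdefault(z, _Node(False))
        self._set_pixel(root, 0, 0, self.root_size, x, y)

    def _set_pixel(self, node: _Node, x0: int, y0: int, size: int, x: int, y: int) -> None:
        if node.is_leaf():
            if node.state is True:
                return
            if size == 1:
                node.state = True
                return
            node.state, node.children = None, [_Node(False) for _ in range(4)]
        half = size // 2
        idx = (1 if x >= x0 + half else 0) + 2 * (1 if y >= y0 + half else 0)
        self._set_pixel(
            node.children[idx],
            x0 + self._OFFSETS[idx][0] * half,
            y0 + self._OFFSETS[idx][1] * half,
            half,
            x,
            y,
        )
        _merge(node)  # re-merge ancestors immediately: invariant holds always

    # -- queries -----------------------------------------------------------

    def contains(self, x: int, y: int, z: int) -> bool:
        node = self._trees.get(z)
        if node is None or x < 0 or y < 0 or x >= self.root_size or y >= self.root_size:
            return False
        x0 = y0 = 0
        size = self.root_size
        while not node.is_leaf():
            half = size // 2
            idx = (1 if x >= x0 + half else 0) + 2 * (1 if y >= y0 + half else 0)
            x0 += self._OFFSETS[idx][0] * half
            y0 += self._OFFSETS[idx][1] * half
            size = half
            node = node.children[idx]
        return bool(node.state)

    def _leaf_regions(self):
        """Yield (z, x0, y0, size) for every uniform-foreground leaf."""
        for z in sorted(self._trees):
            stack = [(self._trees[z], 0, 0, self.root_size)]
            while stack:
                node, x0, y0, size = stack.pop()
                if node.is_leaf():
                    if node.state:
                        yield z, x0, y0, size
                else:
                    half = size // 2
                    for i, (dx, dy) in enumerate(self._OFFSETS):
                        stack.append((node.children[i], x0 + dx * half, y0 + dy * half, half))

    def __len__(self) -> int:
        return sum(size * size for _, _, _, size in self._leaf_regions())

    def _iter_unordered(self):
        for z, x0, y0, size in self._leaf_regions():
            for y in range(y0, y0 + size):
                for x in range(x0, x0 + size):
                    yield (x, y, z)

    # -- structure metrics ---------------------------------------------------

    def node_count(self) -> int:
        return sum(self._count_nodes(root) for root in self._trees.values())

    def leaf_count(self) -> int:
        return sum(self._count_nodes(root, leaves_only=True) for root in self._trees.values())

    @staticmethod
    def _count_nodes(node: _Node, leaves_only: bool = False) -> int:
        if node.is_leaf():
            return 1
        n = 0 if leaves_only else 1
        return n + sum(
            QuadtreeStore._count_nodes(c, leaves_only) for c in node.children
        )

    @property
    def cost(self) -> int:
        return TREE_UNITS_PER_NODE * self.node_count()

    def roots(self) -> dict[int, _Node]:
        """z -> root node map (read-only use: tree-walk audits)."""
        return dict(self._trees)


class OctreeStore(CoordinateStore):
    """Single 3D subdivision tree over a power-of-two cube.

    Same merging and equivalence behaviour as :class:`QuadtreeStore`, but one
    tree subdivides the whole (x, y, z) volume into octants. Best suited to
    stacks with isotropic voxels.
    """

    method = "octree"

    _OFFSETS = (
        (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
        (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1),
    )

    def __init__(self, width: int = 1, height: int = 1, n_slices: int = 1):
        self.width = int(width)
        self.height = int(height)
        self.n_slices = int(n_slices)
        self.root_size = _next_pow2(max(self.width, self.height, self.n_slices))
        self._root = _Node(False)

    @classmethod
    def from_mask(cls, mask) -> "OctreeStore":
        arr = _as_mask3d(mask)
        nz, ny, nx = arr.shape
        store = cls(nx, ny, nz)
        if arr.any():
            integral = np.zeros((nz + 1, ny + 1, nx + 1), dtype=np.int64)
            np.cumsum(
                np.cumsum(np.cumsum(arr, axis=0), axis=1), axis=2, out=integral[1:, 1:, 1:]
            )
            store._root = cls._build(integral, nx, ny, nz, 0, 0, 0, store.root_size)
        return store

    @staticmethod
    def _build(integral, nx, ny, nz, x0, y0, z0, size) -> _Node:
        x1, y1, z1 = min(x0 + size, nx), min(y0 + size, ny), min(z0 + size, nz)
        xa, ya, za = min(x0, nx), min(y0, ny), min(z0, nz)
        # inclusion-exclusion over the 8 corners of the clipped box
        total = int(
            integral[z1, y1, x1] - integral[za, y1, x1] - integral[z1, ya, x1]
            - integral[z1, y1, xa] + integral[za, ya, x1] + integral[za, y1, xa]
            + integral[z1, ya, xa] - integral[za, ya, xa]
        )
        if total == 0:
            return _Node(False)
        if total == size * size * size:
            return _Node(True)
        half = size // 2
        children = [
            OctreeStore._build(
                integral, nx, ny, nz, x0 + dx * half, y0 + dy * half, z0 + dz * half, half
            )
            for dx, dy, dz in OctreeStore._OFFSETS
        ]
        return _Node(None, children)

    def add(self, x: int, y: int, z: int) -> None:
        if x < 0 or y < 0 or z < 0:
            raise BoundsError(f"voxel components must be >= 0, got {(x, y, z)}")
        if max(x, y, z) >= self.root_size:
            raise BoundsError(
                f"voxel {(x, y, z)} outside root cube of size {self.root_size}"
            )
        self.width = max(self.width, x + 1)
        self.height = max(self.height, y + 1)
        self.n_slices = max(self.n_slices, z + 1)
        self._set_voxel(self._root, 0, 0, 0, self.root_size, x, y, z)

    def _set_voxel(self, node, x0, y0, z0, size, x, y, z) -> None:
        if node.is_leaf():
            if node.state is True:
                return
            if size == 1:
                node.state = True
                return
            node.state, node.children = None, [_Node(False) for _ in range(8)]
        half = size // 2
        idx = (
            (1 if x >= x0 + half else 0)
            + 2 * (1 if y >= y0 + half else 0)
            + 4 * (1 if z >= z0 + half else 0)
        )
        dx, dy, dz = self._OFFSETS[idx]
        self._set_voxel(
            node.children[idx], x0 + dx * half, y0 + dy * half, z0 + dz * half, half, x, y, z
        )
        _merge(node)

    def contains(self, x: int, y: int, z: int) -> bool:
        if min(x, y, z) < 0 or max(x, y, z) >= self.root_size:
            return False
        node = self._root
        x0 = y0 = z0 = 0
        size = self.root_size
        while not node.is_leaf():
            half = size // 2
            idx = (
                (1 if x >= x0 + half else 0)
                + 2 * (1 if y >= y0 + half else 0)
                + 4 * (1 if z >= z0 + half else 0)
            )
            dx, dy, dz = self._OFFSETS[idx]
            x0, y0, z0, size = x0 + dx * half, y0 + dy * half, z0 + dz * half, half
            node = node.children[idx]
        return bool(node.state)

    def _leaf_regions(self):
        stack = [(self._root, 0, 0, 0, self.root_size)]
        while stack:
            node, x0, y0, z0, size = stack.pop()
            if node.is_leaf():
                if node.state:
                    yield x0, y0, z0, size
            else:
                half = size // 2
                for i, (dx, dy, dz) in enumerate(self._OFFSETS):
                    stack.append(
                        (node.children[i], x0 + dx * half, y0 + dy * half, z0 + dz * half, half)
                    )

    def __len__(self) -> int:
        return sum(size ** 3 for _, _, _, size in self._leaf_regions())

    def _iter_unordered(self):
        for x0, y0, z0, size in self._leaf_regions():
            for z in range(z0, z0 + size):
                for y in range(y0, y0 + size):
                    for x in range(x0, x0 + size):
                        yield (x, y, z)

    def node_count(self) -> int:
        return QuadtreeStore._count_nodes(self._root)

    def leaf_count(self) -> int:
        return QuadtreeStore._count_nodes(self._root, leaves_only=True)

    @property
    def cost(self) -> int:
        return TREE_UNITS_PER_NODE * self.node_count()

    def root(self) -> _Node:
        return self._root


_STORE_CLASSES = {
    "pointlist": PointListStore,
    "quadtree": QuadtreeStore,
    "octree": OctreeStore,
}


def store_from_mask(mask, method: str = "pointlist") -> CoordinateStore:
    """Build a coordinate store from a binary mask indexed ``[z, y, x]``.

    An all-background mask yields a valid empty store. Unknown ``method``
    raises :class:`ConfigurationError`.
    """
    try:
        cls = _STORE_CLASSES[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown store method {method!r}; expected one of {STORE_METHODS}"
        ) from None
    return cls.from_mask(mask)


def store_from_coords(coords: Iterable[Voxel], method: str, width: int, height: int,
                      n_slices: int) -> CoordinateStore:
    """Build a store of the given extents from explicit voxel coordinates."""
    if method == "pointlist":
        return PointListStore(coords)
    if method == "quadtree":
        store = QuadtreeStore(width, height)
    elif method == "octree":
        store = OctreeStore(width, height, n_slices)
    else:
        raise ConfigurationError(
            f"unknown store method {method!r}; expected one of {STORE_METHODS}"
        )
    for x, y, z in coords:
        store.add(x, y, z)
    return store


def store_to_mask(store: CoordinateStore, width: int, height: int, n_slices: int) -> np.ndarray:
    """Render a store back to a dense boolean mask of shape (n_slices, height, width)."""
    mask = np.zeros((n_slices, height, width), dtype=bool)
    for x, y, z in store._iter_unordered():
        if x >= width or y >= height or z >= n_slices:
            raise BoundsError(
                f"voxel {(x, y, z)} does not fit extents "
                f"({width}, {height}, {n_slices})"
            )
        mask[z, y, x] = True
    return mask
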