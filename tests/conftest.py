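"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from imflow import JobMetadata, Workspace
from imflow.engine import Workflow, create_module_spec


# ---------------------------------------------------------------------------
# independent brute-force subdivision oracles (no imflow tree code involved)


def _pad_value(mask2d: np.ndarray, y: int, x: int) -> bool:
    h, w = mask2d.shape
    if 0 <= y < h and 0 <= x < w:
        return bool(mask2d[y, x])
    return False  # padding beyond the image is background


def quadtree_oracle(mask2d: np.ndarray):
    """Recursive subdivision by direct pixel inspection.

    Returns (total_nodes, leaves, foreground_voxel_count) for the maximally
    merged quadtree over the smallest power-of-two square covering the mask.
    """
    h, w = mask2d.shape
    size = 1
    while size < max(h, w):
        size *= 2

    def recurse(x0, y0, s):
        values = {
            _pad_value(mask2d, y, x)
            for y in range(y0, y0 + s)
            for x in range(x0, x0 + s)
        }
        if len(values) == 1:
            fg = s * s if values == {True} else 0
            return 1, 1, fg
        half = s // 2
        nodes, leaves, fg = 1, 0, 0
        for dx, dy in ((0, 0), (1, 0), (0, 1), (1, 1)):
            n, l, f = recurse(x0 + dx * half, y0 + dy * half, half)
            nodes += n
            leaves += l
            fg += f
        return nodes, leaves, fg

    return recurse(0, 0, size)


def octree_oracle(mask3d: np.ndarray):
    """3D analogue of :func:`quadtree_oracle` (octants)."""
    nz, h, w = mask3d.shape
    size = 1
    while size < max(nz, h, w):
        size *= 2

    def value(z, y, x):
        if 0 <= z < nz and 0 <= y < h and 0 <= x < w:
            return bool(mask3d[z, y, x])
        return False

    def recurse(x0, y0, z0, s):
        values = {
            value(z, y, x)
            for z in range(z0, z0 + s)
            for y in range(y0, y0 + s)
            for x in range(x0, x0 + s)
        }
        if len(values) == 1:
            fg = s ** 3 if values == {True} else 0
            return 1, 1, fg
        half = s // 2
        nodes, leaves, fg = 1, 0, 0
        for dx, dy, dz in ((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                           (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)):
            n, l, f = recurse(x0 + dx * half, y0 + dy * half, z0 + dz * half, half)
            nodes += n
            leaves += l
            fg += f
        return nodes, leaves, fg

    return recurse(0, 0, 0, size)


def random_mask(rng: np.random.Generator, max_side: int = 64,
                max_slices: int = 4) -> np.ndarray:
    """A random binary volume mixing noise and blobby structure."""
    w = int(rng.integers(8, max_side + 1))
    h = int(rng.integers(8, max_side + 1))
    nz = int(rng.integers(1, max_slices + 1))
    kind = int(rng.integers(0, 3))
    if kind == 0:
        return rng.random((nz, h, w)) < rng.uniform(0.05, 0.9)
    if kind == 1:
        mask = np.zeros((nz, h, w), dtype=bool)
        yy, xx = np.ogrid[0:h, 0:w]
        for _ in range(int(rng.integers(1, 6))):
            cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
            r = int(rng.integers(2, max(3, min(h, w) // 4)))
            mask[int(rng.integers(0, nz))] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        return mask
    return rng.random((nz, h, w)) < 0.5


# ---------------------------------------------------------------------------
# workflow fixtures


def nucleus_workflow(save_dir: str | None = None,
                     area_threshold: float = 50.0) -> Workflow:
    """The canonical six-stage segmentation workflow: load, threshold,
    fill holes, identify, measure, filter (+ overlay and save when a
    directory is given)."""
    wf = Workflow()
    wf.add(create_module_spec("load_image", nickname="Load image"))
    wf.add(create_module_spec("apply_threshold", nickname="Apply threshold",
                              input="Raw", output="Binary"))
    wf.add(create_module_spec("fill_holes", nickname="Fill holes", input="Binary"))
    wf.add(create_module_spec("identify_objects", nickname="Identify objects",
                              input="Binary", output="Nuclei"))
    wf.add(create_module_spec("measure_object_shape", nickname="Measure object shape",
                              input="Nuclei"))
    wf.add(create_module_spec("filter_objects", nickname="Filter objects",
                              input="Nuclei", measurement="AREA_PX",
                              predicate="<", threshold=area_threshold))
    if save_dir is not None:
        wf.add(create_module_spec("add_outline_overlay", nickname="Add overlay",
                                  input="Raw", objects="Nuclei", output="Overlay"))
        wf.add(create_module_spec("save_image", nickname="Save image",
                                  input="Overlay", path="{stem}_overlay.tif"))
    return wf


@pytest.fixture
def workspace() -> Workspace:
    return Workspace(JobMetadata(source_path="/data/in.tif", filename="in.tif",
                                 folder="/data"))
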