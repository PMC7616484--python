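"""Object-level operations: connected-component identification, shape
measurement, measurement-based filtering, and skeleton edge/junction
decomposition with partner links.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .coords import store_from_coords
from .errors import ConfigurationError, ValidationError
from .image_ops import as_bool
from .model import ImageStack, Obj, ObjectSet, assign_partners, object_centroid

__all__ = [
    "identify_objects",
    "measure_object_shape",
    "filter_objects",
    "skeleton_decompose",
    "prune_terminal_edges",
]


def _label_structure(in_plane: int, volumetric: int, n_slices: int) -> np.ndarray:
    """3D structuring element for connected-component labelling."""
    if in_plane not in (4, 8):
        raise ConfigurationError(f"in-plane connectivity must be 4 or 8, got {in_plane}")
    if volumetric not in (6, 26):
        raise ConfigurationError(f"volumetric connectivity must be 6 or 26, got {volumetric}")
    if n_slices == 1:
        plane = ndimage.generate_binary_structure(2, 1 if in_plane == 4 else 2)
        s = np.zeros((3, 3, 3), dtype=bool)
        s[1] = plane
        s[1, 1, 1] = True
        return s
    return ndimage.generate_binary_structure(3, 1 if volumetric == 6 else 3)


def identify_objects(image: ImageStack, output_name: str,
                     in_plane: int = 8, volumetric: int = 26,
                     store_method: str = "pointlist") -> ObjectSet:
    """Connected-component labelling of a binary single-channel image.

    One object per connected foreground component *within* each timepoint
    (objects never span frames; temporal structure comes from tracking).
    IDs run sequentially in scan order across frames.
    """
    if image.n_channels != 1:
        raise ValidationError("identify_objects expects a single-channel image")
    mask = as_bool(image.data, "identify_objects input")[:, :, 0]  # (t, z, y, x)
    structure = _label_structure(in_plane, volumetric, image.n_slices)
    objects = ObjectSet(
        output_name, image.calibration.copy(),
        width=image.width, height=image.height, n_slices=image.n_slices,
    )
    for t in range(image.n_frames):
        labels, n = ndimage.label(mask[t], structure=structure)
        for component in range(1, n + 1):
            z, y, x = np.nonzero(labels == component)
            coords = list(zip(x.tolist(), y.tolist(), z.tolist()))
            store = store_from_coords(
                coords, store_method, image.width, image.height, image.n_slices
            )
            objects.new_object(timepoint=t, store=store)
    return objects


def measure_object_shape(objects: ObjectSet) -> ObjectSet:
    """Attach voxel-count, area/volume, centroid and bounding-box measurements.

    2D sets (one slice) get AREA_*; 3D sets get VOLUME_*. Calibrated values
    scale by dx*dy (*dz). Empty-store members get missing values.
    """
    cal = objects.calibration
    is_3d = objects.n_slices > 1
    for obj in objects:
        coords = obj.store.coordinate_array()
        n = coords.shape[0]
        if n == 0:
            for name in ("N_VOXELS", "AREA_PX", "AREA_CAL", "VOLUME_PX", "VOLUME_CAL",
                         "CENTROID_X_PX", "CENTROID_Y_PX", "CENTROID_Z_PX",
                         "CENTROID_X_CAL", "CENTROID_Y_CAL", "CENTROID_Z_CAL"):
                obj.add_measurement(name, None)
            continue
        obj.add_measurement("N_VOXELS", float(n))
        if is_3d:
            obj.add_measurement("VOLUME_PX", float(n))
            obj.add_measurement("VOLUME_CAL", float(n) * cal.dx * cal.dy * cal.dz)
        else:
            obj.add_measurement("AREA_PX", float(n))
            obj.add_measurement("AREA_CAL", float(n) * cal.dx * cal.dy)
        px, phys = object_centroid(obj, cal)
        obj.add_measurement("CENTROID_X_PX", px[0])
        obj.add_measurement("CENTROID_Y_PX", px[1])
        obj.add_measurement("CENTROID_Z_PX", px[2])
        obj.add_measurement("CENTROID_X_CAL", phys[0])
        obj.add_measurement("CENTROID_Y_CAL", phys[1])
        obj.add_measurement("CENTROID_Z_CAL", phys[2])
        mins = coords.min(axis=0)
        maxs = coords.max(axis=0)
        obj.add_measurement("BBOX_MIN_X_PX", float(mins[0]))
        obj.add_measurement("BBOX_MIN_Y_PX", float(mins[1]))
        obj.add_measurement("BBOX_MIN_Z_PX", float(mins[2]))
        obj.add_measurement("BBOX_WIDTH_PX", float(maxs[0] - mins[0] + 1))
        obj.add_measurement("BBOX_HEIGHT_PX", float(maxs[1] - mins[1] + 1))
        obj.add_measurement("BBOX_DEPTH_PX", float(maxs[2] - mins[2] + 1))
    return objects


_PREDICATES = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def filter_objects(objects: ObjectSet, measurement: str, predicate: str,
                   threshold: float, mode: str = "remove",
                   missing_policy: str = "retain") -> ObjectSet:
    """Remove (or keep) objects whose measurement satisfies the predicate.

    ``mode="remove"`` deletes matching objects; ``mode="keep"`` deletes the
    non-matching ones. Removed objects are unlinked from all relationships;
    survivor ids are unchanged. Objects with a missing value follow
    ``missing_policy`` ("retain" or "remove").
    """
    if predicate not in _PREDICATES:
        raise ConfigurationError(f"unknown predicate {predicate!r}")
    if mode not in ("remove", "keep"):
        raise ConfigurationError(f"unknown filter mode {mode!r}")
    if missing_policy not in ("retain", "remove"):
        raise ConfigurationError(f"unknown missing policy {missing_policy!r}")
    if len(objects) and measurement not in objects.measurement_names():
        raise ValidationError(
            f"no object in {objects.class_name!r} carries measurement "
            f"{measurement!r}"
        )
    threshold = float(threshold)
    for obj_id in objects.ids():
        obj = objects.get(obj_id)
        value = obj.measurements.get(measurement)
        if value is None:
            drop = missing_policy == "remove"
        else:
            matches = _PREDICATES[predicate](float(value), threshold)
            drop = matches if mode == "remove" else not matches
        if drop:
            objects.remove(obj_id)
    return objects


# ---------------------------------------------------------------------------
# skeleton decomposition


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    """8-neighbour counts for every pixel of a 2D skeleton mask."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant", cval=0)


def skeleton_decompose(image: ImageStack, edge_name: str = "Edges",
                       junction_name: str = "Junctions",
                       skeletonise: bool = True) -> tuple[ObjectSet, ObjectSet]:
    """Split a (skeletonised) binary image into edge and junction objects.

    Skeleton pixels with more than two 8-neighbours are junction pixels;
    8-connected groups of them form Junction objects and the remaining
    skeleton pixels form Edge objects. An edge and a junction are partnered
    iff any of their pixels touch (8-adjacency). Both sets use pointlist
    stores, the natural choice for one-pixel-wide structures.
    """
    if image.n_channels != 1:
        raise ValidationError("skeleton_decompose expects a single-channel image")
    mask = as_bool(image.data, "skeleton_decompose input")[:, :, 0]
    common = dict(width=image.width, height=image.height, n_slices=image.n_slices)
    edges = ObjectSet(edge_name, image.calibration.copy(), **common)
    junctions = ObjectSet(junction_name, image.calibration.copy(), **common)
    eight = ndimage.generate_binary_structure(2, 2)

    for t in range(image.n_frames):
        for z in range(image.n_slices):
            plane = mask[t, z]
            if not plane.any():
                continue
            skel = skeletonize(plane) if skeletonise else plane
            counts = _neighbour_counts(skel)
            junction_mask = skel & (counts > 2)
            edge_mask = skel & ~junction_mask

            j_labels, n_j = ndimage.label(junction_mask, structure=eight)
            e_labels, n_e = ndimage.label(edge_mask, structure=eight)

            j_objs = {}
            for j in range(1, n_j + 1):
                ys, xs = np.nonzero(j_labels == j)
                obj = junctions.new_object(timepoint=t)
                for x, y in zip(xs.tolist(), ys.tolist()):
                    obj.store.add(x, y, z)
                j_objs[j] = obj
            for e in range(1, n_e + 1):
                ys, xs = np.nonzero(e_labels == e)
                obj = edges.new_object(timepoint=t)
                touching: set[int] = set()
                for x, y in zip(xs.tolist(), ys.tolist()):
                    obj.store.add(x, y, z)
                    # junction labels in this pixel's 8-neighbourhood
                    window = j_labels[max(y - 1, 0):y + 2, max(x - 1, 0):x + 2]
                    touching.update(int(v) for v in np.unique(window) if v > 0)
                for j in sorted(touching):
                    assign_partners(obj, j_objs[j])
    return edges, junctions


def prune_terminal_edges(edges: ObjectSet, junctions: ObjectSet) -> ObjectSet:
    """Remove skeleton branches: edges partnered with exactly one junction.

    Edges with zero junctions (isolated lines or closed loops) or two
    junctions (spanning segments) are retained. Junction partner lists are
    updated by the removal.
    """
    for edge_id in edges.ids():
        edge = edges.get(edge_id)
        n_junctions = len(edge.partners.get(junctions.class_name, {}))
        if n_junctions == 1:
            edges.remove(edge_id)
    return edges
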