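"""Core data model: calibrated images, objects, object sets and relationships.

Objects are purely spatial (XYZ) regions; anything that spans time or
channels — a trajectory, the same structure seen in two channels — is
expressed through relationships rather than extra axes on the object itself.
Two relationship flavours exist:

* parent-child (one-to-many): a child holds at most one parent per parent
  class but may have parents in many different classes, and parents of one
  class may themselves be children of another, giving grandparent chains.
* partner (many-to-many): a symmetric link, e.g. skeleton edges and the
  junctions they meet.

Both directions of every link are kept consistent at all times, and parent
links can never form a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import CoordinateStore, PointListStore
from .errors import RelationshipError, ValidationError

__all__ = [
    "SpatialCalibration",
    "ImageStack",
    "Obj",
    "ObjectSet",
    "assign_parent",
    "remove_parent",
    "assign_partners",
    "remove_partners",
    "resolve_hierarchy",
    "object_centroid",
    "unlink_object",
]


@dataclass
class SpatialCalibration:
    """Physical scale of an image or object set.

    dx, dy, dz are length per pixel/slice (e.g. µm/px); frame_interval is the
    time between consecutive frames. All must be positive.
    """

    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0
    spatial_unit: str = "pixel"
    frame_interval: float = 1.0
    time_unit: str = "s"

    def __post_init__(self):
        for name in ("dx", "dy", "dz", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"calibration {name} must be > 0")

    def copy(self) -> "SpatialCalibration":
        return SpatialCalibration(
            self.dx, self.dy, self.dz, self.spatial_unit,
            self.frame_interval, self.time_unit,
        )


class ImageStack:
    """Named 5D image with axes (t, z, c, y, x) and per-image measurements."""

    def __init__(self, name: str, data: np.ndarray,
                 calibration: SpatialCalibration | None = None):
        data = np.asarray(data)
        if data.ndim != 5:
            raise ValidationError(
                f"image data must be 5D (t, z, c, y, x); got ndim={data.ndim}"
            )
        if min(data.shape) < 1:
            raise ValidationError("every image axis must have length >= 1")
        self.name = name
        self.data = data
        self.calibration = calibration or SpatialCalibration()
        self.measurements: dict[str, float | None] = {}

    # axis accessors
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def height(self) -> int:
        return self.data.shape[3]

    @property
    def width(self) -> int:
        return self.data.shape[4]

    def add_measurement(self, name: str, value: float | None) -> None:
        self.measurements[name] = value

    def __repr__(self):
        return f"ImageStack({self.name!r}, shape={self.data.shape}, dtype={self.data.dtype})"


class Obj:
    """One identified region: an ID, a timepoint, coordinates, measurements
    and its relationship links. Linking objects (e.g. tracks) carry an empty
    coordinate store."""

    def __init__(self, id: int, class_name: str, timepoint: int = 0,
                 store: CoordinateStore | None = None):
        if id < 1:
            raise ValidationError("object ids are positive integers")
        self.id = int(id)
        self.class_name = class_name
        self.timepoint = int(timepoint)
        self.store: CoordinateStore = store if store is not None else PointListStore()
        self.measurements: dict[str, float | None] = {}
        self.parents: dict[str, "Obj"] = {}
        self.children: dict[str, dict[int, "Obj"]] = {}
        self.partners: dict[str, dict[int, "Obj"]] = {}

    def add_measurement(self, name: str, value: float | None) -> None:
        self.measurements[name] = value

    def get_parent(self, class_name: str) -> "Obj | None":
        return self.parents.get(class_name)

    def get_children(self, class_name: str) -> list["Obj"]:
        return [self.children[class_name][i] for i in sorted(self.children.get(class_name, {}))]

    def get_partners(self, class_name: str) -> list["Obj"]:
        return [self.partners[class_name][i] for i in sorted(self.partners.get(class_name, {}))]

    def ancestors(self):
        """All objects reachable through parent links (cycle guard uses this)."""
        seen: set[tuple[str, int]] = set()
        stack = list(self.parents.values())
        while stack:
            p = stack.pop()
            key = (p.class_name, p.id)
            if key in seen:
                continue
            seen.add(key)
            yield p
            stack.extend(p.parents.values())

    def __repr__(self):
        return f"Obj({self.class_name}#{self.id}, t={self.timepoint}, n={len(self.store)})"


class ObjectSet:
    """Named collection of objects sharing a class and calibration."""

    def __init__(self, class_name: str, calibration: SpatialCalibration | None = None,
                 width: int = 1, height: int = 1, n_slices: int = 1):
        self.class_name = class_name
        self.calibration = calibration or SpatialCalibration()
        # spatial extents of the image the objects were found in
        self.width = int(width)
        self.height = int(height)
        self.n_slices = int(n_slices)
        self._objects: dict[int, Obj] = {}
        self._next_id = 1

    def new_object(self, timepoint: int = 0, store: CoordinateStore | None = None) -> Obj:
        obj = Obj(self._next_id, self.class_name, timepoint, store)
        self._objects[obj.id] = obj
        self._next_id += 1
        return obj

    def add(self, obj: Obj) -> None:
        if obj.class_name != self.class_name:
            raise ValidationError(
                f"object class {obj.class_name!r} does not match set {self.class_name!r}"
            )
        if obj.id in self._objects:
            raise ValidationError(f"duplicate object id {obj.id} in set {self.class_name!r}")
        self._objects[obj.id] = obj
        self._next_id = max(self._next_id, obj.id + 1)

    def remove(self, obj_id: int) -> Obj:
        """Remove one object and drop every link other objects held to it."""
        obj = self._objects.pop(obj_id)
        unlink_object(obj)
        return obj

    def get(self, obj_id: int) -> Obj:
        return self._objects[obj_id]

    def __contains__(self, obj_id: int) -> bool:
        return obj_id in self._objects

    def __len__(self) -> int:
        return len(self._objects)

    def __iter__(self):
        return iter([self._objects[i] for i in sorted(self._objects)])

    def ids(self) -> list[int]:
        return sorted(self._objects)

    def by_timepoint(self) -> dict[int, list[Obj]]:
        frames: dict[int, list[Obj]] = {}
        for obj in self:
            frames.setdefault(obj.timepoint, []).append(obj)
        return frames

    def measurement_names(self) -> list[str]:
        names: set[str] = set()
        for obj in self:
            names.update(obj.measurements)
        return sorted(names)

    def __repr__(self):
        return f"ObjectSet({self.class_name!r}, n={len(self)})"


# ---------------------------------------------------------------------------
# relationships


def assign_parent(child: Obj, parent: Obj) -> None:
    """Make ``parent`` the child's (single) parent of its class.

    Any previous parent of the same class is unlinked first. Self-parenting
    and ancestry cycles are rejected.
    """
    if child is parent:
        raise RelationshipError("an object cannot be its own parent")
    for anc in parent.ancestors():
        if anc is child:
            raise RelationshipError(
                f"{child!r} is an ancestor of {parent!r}; cyclic ancestry forbidden"
            )
    previous = child.parents.get(parent.class_name)
    if previous is not None:
        previous.children.get(child.class_name, {}).pop(child.id, None)
    child.parents[parent.class_name] = parent
    parent.children.setdefault(child.class_name, {})[child.id] = child


def remove_parent(child: Obj, parent_class: str) -> None:
    parent = child.parents.pop(parent_class, None)
    if parent is not None:
        parent.children.get(child.class_name, {}).pop(child.id, None)


def assign_partners(a: Obj, b: Obj) -> None:
    """Create a symmetric partner link between two distinct objects (idempotent)."""
    if a is b:
        raise RelationshipError("an object cannot be its own partner")
    a.partners.setdefault(b.class_name, {})[b.id] = b
    b.partners.setdefault(a.class_name, {})[a.id] = a


def remove_partners(a: Obj, b: Obj) -> None:
    a.partners.get(b.class_name, {}).pop(b.id, None)
    b.partners.get(a.class_name, {}).pop(a.id, None)


def unlink_object(obj: Obj) -> None:
    """Drop every link between ``obj`` and other objects, on both sides."""
    for parent in list(obj.parents.values()):
        parent.children.get(obj.class_name, {}).pop(obj.id, None)
    obj.parents.clear()
    for kids in obj.children.values():
        for kid in list(kids.values()):
            kid.parents.pop(obj.class_name, None)
    obj.children.clear()
    for ps in obj.partners.values():
        for p in list(ps.values()):
            p.partners.get(obj.class_name, {}).pop(obj.id, None)
    obj.partners.clear()


def resolve_hierarchy(obj: Obj, path: list[str]) -> list[Obj]:
    """Follow a chain of relationship hops from ``obj``.

    Each hop names a class: if the current object has a parent of that class
    the hop goes up (yielding at most one object); otherwise if it has
    children of that class the hop goes down (yielding a set). An empty path
    returns the object itself. Hops to classes with no registered
    relationship raise :class:`RelationshipError`.
    """
    current: list[Obj] = [obj]
    for class_name in path:
        nxt: list[Obj] = []
        seen: set[int] = set()
        any_hop = False
        for o in current:
            if class_name in o.parents:
                any_hop = True
                p = o.parents[class_name]
                if id(p) not in seen:
                    seen.add(id(p))
                    nxt.append(p)
            elif class_name in o.children:
                any_hop = True
                for kid in o.get_children(class_name):
                    if id(kid) not in seen:
                        seen.add(id(kid))
                        nxt.append(kid)
        if current and not any_hop:
            raise RelationshipError(
                f"no parent or child relationship to class {class_name!r} on path"
            )
        current = sorted(nxt, key=lambda o: (o.class_name, o.id))
    return current


def object_centroid(obj: Obj, calibration: SpatialCalibration | None = None):
    """Mean voxel position, in pixels and (if calibration given) physical units.

    Returns ``(px, cal)`` where each is an (x, y, z) tuple; both are ``None``
    for an empty (linking) object rather than raising.
    """
    coords = obj.store.coordinate_array()
    if coords.shape[0] == 0:
        return None, None
    px = coords.mean(axis=0)
    px_t = (float(px[0]), float(px[1]), float(px[2]))
    if calibration is None:
        return px_t, None
    cal_t = (px_t[0] * calibration.dx, px_t[1] * calibration.dy, px_t[2] * calibration.dz)
    return px_t, cal_t
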