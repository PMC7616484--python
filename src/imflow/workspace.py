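"""Per-job workspace: named images and object sets plus job metadata.

Each analysis run (one file, or one job of a batch) owns a private workspace.
Modules read items by name and write results back under new names or update
an existing entry in place. Workspaces never interact; batch mode simply
creates one per job and discards it after export.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .errors import WorkspaceError
from .model import ImageStack, ObjectSet, unlink_object

__all__ = ["JobMetadata", "Workspace"]


@dataclass
class JobMetadata:
    """Provenance of the input behind one job."""

    source_path: str = ""
    filename: str = ""
    folder: str = ""
    series_name: str = ""  # empty for single-series formats such as TIFF
    job_index: int = 0

    @classmethod
    def from_path(cls, path: str, job_index: int = 0, series_name: str = "") -> "JobMetadata":
        path = os.fspath(path)
        return cls(
            source_path=path,
            filename=os.path.basename(path),
            folder=os.path.dirname(path),
            series_name=series_name,
            job_index=job_index,
        )


class Workspace:
    """Named store for the images and object sets of a single job.

    Image names and object-set names live in separate namespaces; within a
    namespace names are unique.
    """

    def __init__(self, metadata: JobMetadata | None = None):
        self.metadata = metadata or JobMetadata()
        self.images: dict[str, ImageStack] = {}
        self.objectsets: dict[str, ObjectSet] = {}

    # -- generic put per the create/update contract -------------------------

    def put_item(self, item, mode: str = "create", name: str | None = None) -> None:
        if isinstance(item, ImageStack):
            target, key = self.images, name or item.name
        elif isinstance(item, ObjectSet):
            target, key = self.objectsets, name or item.class_name
        else:
            raise WorkspaceError(f"cannot store items of type {type(item).__name__}")
        if mode == "create":
            if key in target:
                raise WorkspaceError(f"name {key!r} already present; use mode='update'")
        elif mode == "update":
            if key not in target:
                raise WorkspaceError(f"cannot update missing name {key!r}")
        else:
            raise WorkspaceError(f"unknown put mode {mode!r}")
        target[key] = item

    def put_image(self, image: ImageStack, mode: str = "create") -> None:
        self.put_item(image, mode)

    def put_objects(self, objects: ObjectSet, mode: str = "create") -> None:
        self.put_item(objects, mode)

    # -- retrieval -----------------------------------------------------------

    def get_image(self, name: str) -> ImageStack:
        try:
            return self.images[name]
        except KeyError:
            raise WorkspaceError(f"no image named {name!r} in workspace") from None

    def get_objects(self, name: str) -> ObjectSet:
        try:
            return self.objectsets[name]
        except KeyError:
            raise WorkspaceError(f"no object set named {name!r} in workspace") from None

    def has_image(self, name: str) -> bool:
        return name in self.images

    def has_objects(self, name: str) -> bool:
        return name in self.objectsets

    # -- removal ---------------------------------------------------------------

    def remove_item(self, name: str, kind: str) -> None:
        """Delete a named item; object removal also severs all links held by
        surviving objects to members of the removed set."""
        if kind == "image":
            if name not in self.images:
                raise WorkspaceError(f"no image named {name!r} to remove")
            del self.images[name]
        elif kind == "objects":
            if name not in self.objectsets:
                raise WorkspaceError(f"no object set named {name!r} to remove")
            removed = self.objectsets.pop(name)
            for obj in list(removed):
                unlink_object(obj)
        else:
            raise WorkspaceError(f"unknown item kind {kind!r}")

    def remove_image(self, name: str) -> None:
        self.remove_item(name, "image")

    def remove_objects(self, name: str) -> None:
        self.remove_item(name, "objects")
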