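"""Built-in workflow modules.

Each class wraps one library operation behind the module contract so it can
appear in serialized workflows. Output-name parameters left empty mean
"update the input in place" (the named entity keeps its identity and its
measurements). Importing this package registers every built-in module;
third-party code extends the system by registering further
:class:`~imflow.engine.WorkflowModule` subclasses.
"""

from __future__ import annotations

import os

from . import image_ops, object_ops, tracking
from .engine import (ControlAction, ModuleSpec, Parameter, WorkflowModule,
                     evaluate_condition, register_module)
from .workspace import Workspace

__all__ = ["BUILTIN_MODULE_IDS"]


def _p(name, kind, value=None, visible=False, options=None) -> Parameter:
    return Parameter(name, kind, value, visible, tuple(options) if options else None)


@register_module
class LoadImage(WorkflowModule):
    """Read a TIFF from disk into the workspace.

    With an empty path the module loads the job's own input file, which is
    what makes a workflow batch-ready with no edits.
    """

    module_id = "load_image"

    @classmethod
    def defaults(cls):
        return [
            _p("path", "file-path", ""),
            _p("output", "output-image", "Raw"),
        ]

    def run(self, spec: ModuleSpec, ws: Workspace, context: dict):
        path = str(spec.get("path") or "") or ws.metadata.source_path
        image = image_ops.load_image(path, name=str(spec.get("output")))
        ws.put_image(image)
        return None


def _store_image(ws: Workspace, spec: ModuleSpec, input_name: str, result) -> None:
    """Create under the output name, or update the input image in place."""
    output = str(spec.get("output") or "")
    if output and output != input_name:
        result.name = output
        ws.put_image(result)
    else:
        existing = ws.get_image(input_name)
        existing.data = result.data  # in-place update keeps measurements


@register_module
class ApplyThreshold(WorkflowModule):
    """Binarise an image (Otsu over a 256-bin histogram, or a manual level)."""

    module_id = "apply_threshold"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-image", "Raw"),
            _p("algorithm", "choice", "otsu", options=("otsu", "manual")),
            _p("manual_value", "number", 128),
            _p("scope", "choice", "global", options=("global", "per-slice")),
            _p("output", "output-image", "Binary"),
        ]

    def run(self, spec, ws, context):
        input_name = str(spec.get("input"))
        image = ws.get_image(input_name)
        algorithm = str(spec.get("algorithm"))
        result = image_ops.apply_threshold(
            image,
            algorithm=algorithm,
            manual_value=float(spec.get("manual_value")) if algorithm == "manual" else None,
            scope=str(spec.get("scope")),
        )
        _store_image(ws, spec, input_name, result)
        return None


@register_module
class FillHoles(WorkflowModule):
    """Fill enclosed background regions, slice by slice."""

    module_id = "fill_holes"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-image", "Binary"),
            _p("output", "output-image", ""),  # default: update in place
        ]

    def run(self, spec, ws, context):
        input_name = str(spec.get("input"))
        result = image_ops.fill_holes(ws.get_image(input_name))
        _store_image(ws, spec, input_name, result)
        return None


@register_module
class IdentifyObjects(WorkflowModule):
    """Connected-components labelling of a binary image into an object set."""

    module_id = "identify_objects"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-image", "Binary"),
            _p("output", "output-objects", "Objects"),
            _p("in_plane_connectivity", "choice", "8", options=("4", "8")),
            _p("volumetric_connectivity", "choice", "26", options=("6", "26")),
            _p("store_method", "choice", "pointlist",
               options=("pointlist", "quadtree", "octree")),
        ]

    def run(self, spec, ws, context):
        objects = object_ops.identify_objects(
            ws.get_image(str(spec.get("input"))),
            output_name=str(spec.get("output")),
            in_plane=int(spec.get("in_plane_connectivity")),
            volumetric=int(spec.get("volumetric_connectivity")),
            store_method=str(spec.get("store_method")),
        )
        ws.put_objects(objects)
        return None


@register_module
class MeasureObjectShape(WorkflowModule):
    """Add voxel count, area/volume, centroid and bounding-box measurements."""

    module_id = "measure_object_shape"

    @classmethod
    def defaults(cls):
        return [_p("input", "input-objects", "Objects")]

    def run(self, spec, ws, context):
        object_ops.measure_object_shape(ws.get_objects(str(spec.get("input"))))
        return None


@register_module
class FilterObjects(WorkflowModule):
    """Remove (or keep) objects by comparing a measurement to a threshold."""

    module_id = "filter_objects"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-objects", "Objects"),
            _p("measurement", "text", "AREA_PX", visible=True),
            _p("predicate", "choice", "<", options=("<", "<=", ">", ">=")),
            _p("threshold", "number", 0, visible=True),
            _p("mode", "choice", "remove", options=("remove", "keep")),
        ]

    def run(self, spec, ws, context):
        object_ops.filter_objects(
            ws.get_objects(str(spec.get("input"))),
            measurement=str(spec.get("measurement")),
            predicate=str(spec.get("predicate")),
            threshold=float(spec.get("threshold")),
            mode=str(spec.get("mode")),
        )
        return None


@register_module
class TrackObjects(WorkflowModule):
    """Frame-to-frame linking of detections into coordinate-less tracks."""

    module_id = "track_objects"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-objects", "Objects"),
            _p("output", "output-objects", "Tracks"),
            _p("max_linking_distance", "number", 10.0, visible=True),
            _p("alternative_cost_factor", "number", 1.05),
        ]

    def run(self, spec, ws, context):
        tracks = tracking.track_objects(
            ws.get_objects(str(spec.get("input"))),
            tracking.LinkingSpec(
                max_linking_distance=float(spec.get("max_linking_distance")),
                alternative_cost_factor=float(spec.get("alternative_cost_factor")),
            ),
            track_name=str(spec.get("output")),
        )
        ws.put_objects(tracks)
        return None


@register_module
class MeasureTrackMotion(WorkflowModule):
    """Path length, displacement, directionality, velocity per track."""

    module_id = "measure_track_motion"

    @classmethod
    def defaults(cls):
        return [
            _p("tracks", "input-objects", "Tracks"),
            _p("children", "input-objects", "Objects"),
        ]

    def run(self, spec, ws, context):
        tracking.measure_track_motion(
            ws.get_objects(str(spec.get("tracks"))),
            child_class=str(spec.get("children")),
        )
        return None


@register_module
class SkeletonDecompose(WorkflowModule):
    """Split a skeleton into partnered edge and junction objects."""

    module_id = "skeleton_decompose"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-image", "Binary"),
            _p("edges", "output-objects", "Edges"),
            _p("junctions", "output-objects", "Junctions"),
            _p("skeletonise", "boolean", True),
        ]

    def run(self, spec, ws, context):
        edges, junctions = object_ops.skeleton_decompose(
            ws.get_image(str(spec.get("input"))),
            edge_name=str(spec.get("edges")),
            junction_name=str(spec.get("junctions")),
            skeletonise=bool(spec.get("skeletonise")),
        )
        ws.put_objects(edges)
        ws.put_objects(junctions)
        return None


@register_module
class PruneTerminalEdges(WorkflowModule):
    """Drop skeleton edges attached to exactly one junction (branches)."""

    module_id = "prune_terminal_edges"

    @classmethod
    def defaults(cls):
        return [
            _p("edges", "input-objects", "Edges"),
            _p("junctions", "input-objects", "Junctions"),
        ]

    def run(self, spec, ws, context):
        object_ops.prune_terminal_edges(
            ws.get_objects(str(spec.get("edges"))),
            ws.get_objects(str(spec.get("junctions"))),
        )
        return None


@register_module
class AddOutlineOverlay(WorkflowModule):
    """Colour object outlines over the image with a seeded palette."""

    module_id = "add_outline_overlay"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-image", "Raw"),
            _p("objects", "input-objects", "Objects"),
            _p("seed", "number", 42),
            _p("output", "output-image", "Overlay"),
        ]

    def run(self, spec, ws, context):
        seed = spec.get("seed")
        seed = int(seed) if seed is not None else int(context.get("seed", 42))
        overlay = image_ops.add_outline_overlay(
            ws.get_image(str(spec.get("input"))),
            ws.get_objects(str(spec.get("objects"))),
            seed=seed,
            output_name=str(spec.get("output")),
        )
        ws.put_image(overlay)
        return None


@register_module
class SaveImage(WorkflowModule):
    """Write an image to TIFF.

    The path may contain ``{stem}`` (input file stem) and is resolved against
    the run's output directory when relative, so one workflow serves a whole
    batch without per-job edits.
    """

    module_id = "save_image"

    @classmethod
    def defaults(cls):
        return [
            _p("input", "input-image", "Overlay"),
            _p("path", "file-path", "{stem}_out.tif", visible=True),
        ]

    def run(self, spec, ws, context):
        path = str(spec.get("path"))
        stem = os.path.splitext(ws.metadata.filename)[0] if ws.metadata.filename else "image"
        path = path.format(stem=stem)
        if not os.path.isabs(path):
            path = os.path.join(str(context.get("output_dir", ".")), path)
        image_ops.save_image(ws.get_image(str(spec.get("input"))), path)
        context.setdefault("saved_paths", []).append(path)
        return None


@register_module
class RemoveImage(WorkflowModule):
    """Free an image that later modules no longer need."""

    module_id = "remove_image"
    removes_inputs = True

    @classmethod
    def defaults(cls):
        return [_p("name", "input-image", "")]

    def run(self, spec, ws, context):
        ws.remove_image(str(spec.get("name")))
        return None


@register_module
class RemoveObjects(WorkflowModule):
    """Free an object set that later modules no longer need."""

    module_id = "remove_objects"
    removes_inputs = True

    @classmethod
    def defaults(cls):
        return [_p("name", "input-objects", "")]

    def run(self, spec, ws, context):
        ws.remove_objects(str(spec.get("name")))
        return None


@register_module
class WorkflowHandling(WorkflowModule):
    """Skip forward or terminate when a workspace condition holds.

    The target is looked up at run time; a missing reference fails the job,
    matching how unattended batch runs must surface configuration mistakes.
    """

    module_id = "workflow_handling"

    @classmethod
    def defaults(cls):
        return [
            _p("test", "choice", "object-count",
               options=("object-count", "image-measurement")),
            _p("target", "text", ""),
            _p("measurement", "text", ""),
            _p("comparison", "choice", "==",
               options=("<", "<=", ">", ">=", "==", "!=")),
            _p("value", "number", 0),
            _p("action", "choice", "terminate", options=("terminate", "skip_to")),
            _p("label", "text", ""),
        ]

    def run(self, spec, ws, context) -> ControlAction:
        cond = {
            "test": spec.get("test"),
            "target": spec.get("target"),
            "measurement": spec.get("measurement"),
            "comparison": spec.get("comparison"),
            "value": spec.get("value"),
            "action": spec.get("action"),
            "label": spec.get("label"),
        }
        return evaluate_condition(cond, ws)


BUILTIN_MODULE_IDS = (
    "load_image", "apply_threshold", "fill_holes", "identify_objects",
    "measure_object_shape", "filter_objects", "track_objects",
    "measure_track_motion", "skeleton_decompose", "prune_terminal_edges",
    "add_outline_overlay", "save_image", "remove_image", "remove_objects",
    "workflow_handling",
)
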