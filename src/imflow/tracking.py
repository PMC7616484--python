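"""Frame-to-frame object tracking and track motion measurements.

Linking follows the standard linear-assignment formulation used for particle
tracking: for every pair of consecutive frames an assignment problem is
solved over squared centroid distances, with per-object "no link" alternatives
costed at a fixed multiple (default 1.05) of the largest admissible link
cost. Chained links become coordinate-less Track objects, each the parent of
its per-frame detections. Gap closing, splitting and merging are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .model import Obj, ObjectSet, assign_parent, object_centroid

__all__ = ["LinkingSpec", "link_frame_pair", "track_objects", "measure_track_motion"]

_BLOCKED = 1e12  # stand-in for an inadmissible assignment


@dataclass
class LinkingSpec:
    """Parameters of the frame-to-frame linker.

    max_linking_distance is in calibrated units; alternative_cost_factor
    scales the cost of leaving an object unlinked relative to the maximum
    admissible link cost.
    """

    max_linking_distance: float = 10.0
    alternative_cost_factor: float = 1.05

    def __post_init__(self):
        if self.max_linking_distance <= 0:
            raise ValidationError("max_linking_distance must be > 0")


def _calibrated_centroids(objs: list[Obj], calibration) -> np.ndarray:
    pts = []
    for obj in objs:
        _, phys = object_centroid(obj, calibration)
        if phys is None:
            raise ValidationError(
                f"object {obj.class_name}#{obj.id} has no coordinates to track"
            )
        pts.append(phys)
    return np.asarray(pts, dtype=float)


def link_frame_pair(sources: list[Obj], targets: list[Obj], calibration,
                    spec: LinkingSpec) -> list[tuple[int, int]]:
    """Optimal links between two frames as (source_index, target_index) pairs.

    Solves the augmented assignment problem: link costs are squared centroid
    distances (inadmissible beyond max_linking_distance); each object may
    instead take its "no link" alternative.
    """
    n, m = len(sources), len(targets)
    if n == 0 or m == 0:
        return []
    a = _calibrated_centroids(sources, calibration)
    b = _calibrated_centroids(targets, calibration)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    admissible = d2 <= spec.max_linking_distance ** 2
    if not admissible.any():
        return []
    cost = np.where(admissible, d2, _BLOCKED)
    alt = spec.alternative_cost_factor * float(d2[admissible].max())
    if alt == 0.0:
        alt = spec.alternative_cost_factor  # all candidates coincide exactly

    size = n + m
    full = np.full((size, size), _BLOCKED)
    full[:n, :m] = cost
    # completion block: free at transposed admissible positions, so the total
    # objective is exactly (sum of link costs) + alt * (number unlinked)
    full[n:, m:] = np.where(admissible.T, 0.0, _BLOCKED)
    full[np.arange(n), m + np.arange(n)] = alt  # source takes no link
    full[n + np.arange(m), np.arange(m)] = alt  # target starts a new track
    rows, cols = linear_sum_assignment(full)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and admissible[r, c]
    ]


def track_objects(objects: ObjectSet, spec: LinkingSpec,
                  track_name: str = "Tracks") -> ObjectSet:
    """Link detections across consecutive frames into Track objects.

    Every input object receives exactly one Track parent; objects with no
    admissible link start tracks of their own. Track objects hold no
    coordinates — they are pure linking objects.
    """
    tracks = ObjectSet(
        track_name, objects.calibration.copy(),
        width=objects.width, height=objects.height, n_slices=objects.n_slices,
    )
    frames = objects.by_timepoint()
    if not frames:
        return tracks

    track_of: dict[int, Obj] = {}  # object id -> track object

    def track_for(obj: Obj) -> Obj:
        track = track_of.get(obj.id)
        if track is None:
            track = tracks.new_object(timepoint=obj.timepoint)
            track_of[obj.id] = track
            assign_parent(obj, track)
        return track

    times = sorted(frames)
    for t in times:
        for obj in frames[t]:
            # materialise tracks in scan order for deterministic ids
            if obj.id not in track_of and (t - 1 not in frames):
                track_for(obj)
        if t - 1 in frames:
            sources = frames[t - 1]
            targets = frames[t]
            links = link_frame_pair(sources, targets, objects.calibration, spec)
            linked_targets = set()
            for si, ti in links:
                track = track_for(sources[si])
                target = targets[ti]
                track_of[target.id] = track
                assign_parent(target, track)
                linked_targets.add(ti)
            for ti, target in enumerate(targets):
                if ti not in linked_targets:
                    track_for(target)
        else:
            for obj in frames[t]:
                track_for(obj)
    return tracks


def measure_track_motion(tracks: ObjectSet, child_class: str) -> ObjectSet:
    """Per-track motion statistics from calibrated child centroids.

    Adds PATH_LENGTH_CAL (sum of step lengths), DISPLACEMENT_CAL (first to
    last), DIRECTIONALITY (displacement / path length, missing when the path
    length is zero), MEAN_VELOCITY (path length / elapsed time) and
    DURATION_FRAMES. Each child after the first gets its instantaneous
    STEP_SPEED.
    """
    cal = tracks.calibration
    for track in tracks:
        children = sorted(track.get_children(child_class), key=lambda o: o.timepoint)
        timepoints = [c.timepoint for c in children]
        if len(set(timepoints)) != len(timepoints):
            raise ValidationError(
                f"track {track.id} has children sharing a timepoint"
            )
        if not children:
            for name in ("PATH_LENGTH_CAL", "DISPLACEMENT_CAL", "DIRECTIONALITY",
                         "MEAN_VELOCITY", "DURATION_FRAMES"):
                track.add_measurement(name, None)
            continue
        pts = _calibrated_centroids(children, cal)
        duration = timepoints[-1] - timepoints[0] + 1
        track.add_measurement("DURATION_FRAMES", float(duration))
        if len(children) < 2:
            track.add_measurement("PATH_LENGTH_CAL", 0.0)
            track.add_measurement("DISPLACEMENT_CAL", 0.0)
            track.add_measurement("DIRECTIONALITY", None)
            track.add_measurement("MEAN_VELOCITY", None)
            continue
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        path = float(steps.sum())
        displacement = float(np.linalg.norm(pts[-1] - pts[0]))
        elapsed = (timepoints[-1] - timepoints[0]) * cal.frame_interval
        track.add_measurement("PATH_LENGTH_CAL", path)
        track.add_measurement("DISPLACEMENT_CAL", displacement)
        track.add_measurement("DIRECTIONALITY", displacement / path if path > 0 else None)
        track.add_measurement("MEAN_VELOCITY", path / elapsed if elapsed > 0 else None)
        for child, speed, dt in zip(
                children[1:], steps,
                np.diff(np.asarray(timepoints)) * cal.frame_interval):
            child.add_measurement("STEP_SPEED", float(speed) / float(dt))
    return tracks
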