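"""Seeded synthetic image generators with ground truth.

Every generator is a pure function of its parameters and seed, and returns
both the image and a :class:`GroundTruth` describing exactly what was drawn,
so tests and demonstrations never need external data. The images emulate the
geometry of common microscopy content (fluorescent nuclei, moving spots,
skeletonised networks) but not its optics: there is no point-spread function
and noise is kept strictly below the object/background contrast so that
segmentation truth is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .model import ImageStack, SpatialCalibration

__all__ = [
    "GroundTruth",
    "make_blob_image",
    "make_moving_spots",
    "make_skeleton_image",
    "make_morphology_trio",
]

BACKGROUND_LEVEL = 20
FOREGROUND_LEVEL = 200
NOISE_SIGMA = 5.0  # well below (foreground - background) / 2


@dataclass
class GroundTruth:
    """Label grids and true per-object properties for a generated image."""

    labels: np.ndarray | None = None  # matches image (t, z, y, x) or (z, y, x)
    properties: dict = field(default_factory=dict)
    seed: int | None = None


def _disk_mask(height: int, width: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def make_blob_image(n_blobs: int = 5, width: int = 256, height: int = 256,
                    radius_range: tuple[float, float] = (8.0, 16.0),
                    seed: int = 42,
                    calibration: SpatialCalibration | None = None,
                    extra_radii: tuple[float, ...] = ()) -> tuple[ImageStack, GroundTruth]:
    """Bright, non-overlapping disks on a dark noisy background.

    ``extra_radii`` appends blobs with explicit radii (e.g. one deliberately
    tiny blob for size-filter tests). Placement uses rejection sampling; an
    infeasible packing raises :class:`GenerationError` after bounded retries.
    """
    rng = np.random.default_rng(seed)
    radii = list(rng.uniform(*radius_range, size=n_blobs)) + list(extra_radii)
    centres: list[tuple[float, float]] = []
    placed_radii: list[float] = []
    for r in radii:
        for _ in range(1000):
            cy = rng.uniform(r + 2, height - r - 2)
            cx = rng.uniform(r + 2, width - r - 2)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orr + 4) ** 2
                for (oy, ox), orr in zip(centres, placed_radii)
            ):
                centres.append((cy, cx))
                placed_radii.append(r)
                break
        else:
            raise GenerationError(
                f"could not place {len(radii)} non-overlapping blobs in "
                f"{width}x{height}"
            )
    labels = np.zeros((height, width), dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centres, placed_radii), start=1):
        labels[_disk_mask(height, width, cy, cx, r)] = i
    image = np.full((height, width), BACKGROUND_LEVEL, dtype=float)
    image[labels > 0] = FOREGROUND_LEVEL
    image += rng.normal(0.0, NOISE_SIGMA, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    data = image[np.newaxis, np.newaxis, np.newaxis]  # (t, z, c, y, x)
    stack = ImageStack("Raw", data, calibration or SpatialCalibration())
    truth = GroundTruth(
        labels=labels[np.newaxis],  # (z, y, x)
        properties={
            "n_blobs": len(placed_radii),
            "radii": placed_radii,
            "centres": centres,  # (y, x) order
            "areas_px": [int((labels == i).sum()) for i in range(1, len(placed_radii) + 1)],
        },
        seed=seed,
    )
    return stack, truth


def make_moving_spots(n_spots: int = 2, n_frames: int = 5,
                      velocity: tuple[int, int] = (3, 4), noise_sigma: float = 0.0,
                      spot_radius: int = 2, seed: int = 42,
                      calibration: SpatialCalibration | None = None,
                      ) -> tuple[ImageStack, GroundTruth]:
    """Spots advancing with constant velocity (plus optional integer jitter).

    Spots are solid disks whose centroids sit exactly on the (integer)
    generated positions, so motion statistics are exact; tracks run on
    parallel lines separated by more than four times the per-frame step so
    the ground-truth linking is unambiguous.
    """
    rng = np.random.default_rng(seed)
    step = float(np.hypot(*velocity))
    spacing = int(np.ceil(4 * (step + 3 * noise_sigma))) + 4 * spot_radius + 4
    margin = spot_radius + 2 + int(np.ceil(3 * noise_sigma))
    height = margin * 2 + spacing * max(n_spots - 1, 0) + 1
    width = margin * 2 + abs(velocity[0]) * (n_frames - 1) + 1
    height += abs(velocity[1]) * (n_frames - 1)

    positions = np.zeros((n_spots, n_frames, 2), dtype=int)  # (x, y)
    for s in range(n_spots):
        x0, y0 = margin, margin + s * spacing
        for t in range(n_frames):
            jx = jy = 0
            if noise_sigma > 0:
                jx = int(np.rint(rng.normal(0, noise_sigma)))
                jy = int(np.rint(rng.normal(0, noise_sigma)))
            positions[s, t] = (x0 + velocity[0] * t + jx, y0 + velocity[1] * t + jy)
    if (positions[:, :, 0].min() < spot_radius or positions[:, :, 1].min() < spot_radius
            or positions[:, :, 0].max() >= width - spot_radius
            or positions[:, :, 1].max() >= height - spot_radius):
        raise GenerationError("spot trajectories leave the image; reduce noise or step")
    # enforce the separation precondition between distinct tracks
    for t in range(n_frames):
        pts = positions[:, t]
        for i in range(n_spots):
            for j in range(i + 1, n_spots):
                if np.hypot(*(pts[i] - pts[j])) <= 4 * (step + 3 * noise_sigma):
                    raise GenerationError("tracks too close for unambiguous linking")

    data = np.full((n_frames, 1, 1, height, width), BACKGROUND_LEVEL, dtype=np.uint8)
    labels = np.zeros((n_frames, 1, height, width), dtype=np.int32)
    for t in range(n_frames):
        for s in range(n_spots):
            x, y = positions[s, t]
            disk = _disk_mask(height, width, y, x, spot_radius)
            data[t, 0, 0][disk] = FOREGROUND_LEVEL
            labels[t, 0][disk] = s + 1
    stack = ImageStack("Spots", data, calibration or SpatialCalibration())
    truth = GroundTruth(
        labels=labels,
        properties={
            "positions": positions,  # (spot, frame, xy)
            "velocity": velocity,
            "step_length": step,
        },
        seed=seed,
    )
    return stack, truth


def _draw_line(mask: np.ndarray, y0: int, x0: int, y1: int, x1: int) -> None:
    """Rasterise an axis-aligned 1-pixel line (inclusive endpoints)."""
    if y0 == y1:
        mask[y0, min(x0, x1):max(x0, x1) + 1] = True
    elif x0 == x1:
        mask[min(y0, y1):max(y0, y1) + 1, x0] = True
    else:
        raise GenerationError("skeleton lines must be axis-aligned")


def make_skeleton_image(shape: str = "plus", width: int = 64, height: int = 64,
                        ) -> tuple[ImageStack, GroundTruth]:
    """One-pixel-wide polyline rasters with known junction/edge counts.

    Shapes: "line" (0 junctions, 1 edge), "plus" (1 junction, 4 edges),
    "H" (2 junctions, 5 edges), "grid" (4 junctions, 12 edges: a 2x2 lattice
    of crossings with protruding arms).
    """
    mask = np.zeros((height, width), dtype=bool)
    cy, cx = height // 2, width // 2
    arm = min(height, width) // 4
    if shape == "line":
        _draw_line(mask, cy, cx - arm, cy, cx + arm)
        counts = {"junctions": 0, "edges": 1}
    elif shape == "plus":
        _draw_line(mask, cy, cx - arm, cy, cx + arm)
        _draw_line(mask, cy - arm, cx, cy + arm, cx)
        counts = {"junctions": 1, "edges": 4}
    elif shape == "H":
        xl, xr = cx - arm, cx + arm
        _draw_line(mask, cy - arm, xl, cy + arm, xl)
        _draw_line(mask, cy - arm, xr, cy + arm, xr)
        _draw_line(mask, cy, xl, cy, xr)
        counts = {"junctions": 2, "edges": 5}
    elif shape == "grid":
        xs = (cx - arm, cx + arm)
        ys = (cy - arm, cy + arm)
        for y in ys:
            _draw_line(mask, y, cx - 2 * arm, y, cx + 2 * arm)
        for x in xs:
            _draw_line(mask, cy - 2 * arm, x, cy + 2 * arm, x)
        counts = {"junctions": 4, "edges": 12}
    else:
        raise GenerationError(f"unknown skeleton shape {shape!r}")
    data = mask[np.newaxis, np.newaxis, np.newaxis].astype(np.uint8) * 255
    stack = ImageStack(f"Skeleton_{shape}", data)
    return stack, GroundTruth(labels=mask[np.newaxis], properties=counts)


def make_morphology_trio(extent: int = 256, seed: int = 42) -> dict[str, np.ndarray]:
    """Three binary masks spanning the morphology classes that stress
    coordinate stores differently.

    * ``"pixel"`` — a single foreground pixel (tiny bacterium-like spot);
    * ``"curve"`` — a one-pixel-wide meandering curve (skeletonised
      DNA-molecule-like strand);
    * ``"ellipse"`` — a large solid ellipse (nucleus-like region).

    Masks are (1, extent, extent) boolean arrays indexed [z, y, x].
    """
    if extent & (extent - 1):
        raise GenerationError("extent must be a power of two")
    rng = np.random.default_rng(seed)

    pixel = np.zeros((extent, extent), dtype=bool)
    pixel[extent // 2, extent // 2] = True

    # meandering 1-px random walk: axis-aligned unit steps with persistence
    curve = np.zeros((extent, extent), dtype=bool)
    y, x = extent // 2, extent // 8
    heading = (0, 1)  # mostly rightwards drift
    curve[y, x] = True
    for _ in range(3 * extent):
        if rng.random() < 0.25:
            heading = (rng.choice((-1, 1)), 0) if heading[0] == 0 else (0, 1)
        ny, nx = y + heading[0], x + heading[1]
        if not (extent // 8 <= ny < 7 * extent // 8 and nx < 7 * extent // 8):
            heading = (0, 1) if heading[1] == 0 else (-heading[0] or 1, 0)
            continue
        y, x = ny, nx
        curve[y, x] = True
        if x >= 7 * extent // 8 - 1:
            break

    ellipse = np.zeros((extent, extent), dtype=bool)
    yy, xx = np.mgrid[0:extent, 0:extent]
    cy = cx = extent / 2 - 0.5
    ry, rx = extent * 0.33, extent * 0.40
    ellipse[((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0] = True

    return {
        "pixel": pixel[np.newaxis],
        "curve": curve[np.newaxis],
        "ellipse": ellipse[np.newaxis],
    }
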