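"""Image-level operations: TIFF loading/saving, thresholding, hole filling
and object outline overlays.

Images are 5D throughout (t, z, c, y, x); absent dimensions are singleton
axes. Binary images use the convention ``{0, 255}`` in uint8 (boolean input
is accepted and normalised).
"""

from __future__ import annotations

import colorsys
import logging
import os

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ValidationError
from .model import ImageStack, ObjectSet, SpatialCalibration

__all__ = [
    "load_image",
    "save_image",
    "apply_threshold",
    "fill_holes",
    "add_outline_overlay",
    "is_binary",
    "as_bool",
    "BINARY_MAX",
]

logger = logging.getLogger(__name__)

BINARY_MAX = 255

_AXIS_ORDER = "TZCYX"


def is_binary(data: np.ndarray) -> bool:
    """True when the image holds only {0, 255} (or is boolean)."""
    if data.dtype == bool:
        return True
    values = np.unique(data)
    return bool(np.isin(values, (0, BINARY_MAX)).all())


def as_bool(data: np.ndarray, what: str = "input") -> np.ndarray:
    if not is_binary(data):
        raise ValidationError(f"{what} must be binary (values 0/{BINARY_MAX})")
    return data.astype(bool)


def _to_5d(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder an array with tifffile-style axes into (t, z, c, y, x)."""
    axes = axes.upper()
    # sample axis (RGB) behaves as channels; unknown page axes default to Z
    translate = {"S": "C", "Q": "Z", "I": "Z"}
    axes = "".join(translate.get(a, a) for a in axes)
    if len(set(axes)) != len(axes):
        raise ValidationError(f"cannot map duplicate image axes {axes!r}")
    for a in axes:
        if a not in _AXIS_ORDER:
            raise ValidationError(f"unsupported image axis {a!r}")
    # add missing singleton axes then transpose to canonical order
    for a in _AXIS_ORDER:
        if a not in axes:
            data = data[np.newaxis]
            axes = a + axes
    order = [axes.index(a) for a in _AXIS_ORDER]
    return np.transpose(data, order)


def _resolution_to_scale(tag_value) -> float | None:
    try:
        num, den = tag_value
        if num:
            return den / num
    except TypeError:
        if tag_value:
            return 1.0 / float(tag_value)
    return None


def load_image(path: str, name: str | None = None) -> ImageStack:
    """Read a (multi-page) TIFF into a calibrated 5D stack.

    Resolution tags and ImageJ-style metadata (spacing, unit, finterval) are
    honoured when present; otherwise the calibration defaults to 1 pixel with
    a logged warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = _to_5d(series.asarray(), series.axes)
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            ij = tf.imagej_metadata or {}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValidationError(f"not a readable TIFF: {path} ({exc})") from None

    cal = SpatialCalibration()
    calibrated = False
    if xres is not None:
        dx = _resolution_to_scale(xres.value)
        if dx:
            cal.dx = dx
            calibrated = True
    if yres is not None:
        dy = _resolution_to_scale(yres.value)
        if dy:
            cal.dy = dy
            calibrated = True
    if "spacing" in ij:
        cal.dz = float(ij["spacing"])
        calibrated = True
    if ij.get("unit"):
        cal.spatial_unit = str(ij["unit"])
    if ij.get("finterval"):
        cal.frame_interval = float(ij["finterval"])
    if not calibrated:
        logger.warning("%s: no calibration metadata; using 1 %s per pixel",
                       path, cal.spatial_unit)
    return ImageStack(name or os.path.basename(path), data, cal)


def save_image(image: ImageStack, path: str) -> str:
    """Write an ImageJ-compatible TIFF (axes TZCYX, calibration embedded).

    Integer pixel data round-trips exactly. The target folder is created if
    needed.
    """
    path = os.fspath(path)
    folder = os.path.dirname(path)
    if folder:
        os.makedirs(folder, exist_ok=True)
    data = image.data
    if data.dtype == bool:
        data = data.astype(np.uint8) * BINARY_MAX
    elif data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    cal = image.calibration
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / cal.dx, 1.0 / cal.dy),
        metadata={
            "spacing": cal.dz,
            "unit": cal.spatial_unit,
            "finterval": cal.frame_interval,
            "axes": _AXIS_ORDER,
        },
    )
    return path


def compute_otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram of the given intensities.

    Bins span the data's min-max range, which for non-8-bit data is the same
    as min-max scaling before a fixed 256-level search.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    lo, hi = float(values.min()), float(values.max())
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(threshold_otsu(hist=(counts, centers)))


def apply_threshold(image: ImageStack, algorithm: str = "otsu",
                    manual_value: float | None = None, scope: str = "global",
                    output_name: str | None = None) -> ImageStack:
    """Binarise a single-channel image; foreground = intensity above threshold.

    ``scope`` is "global" (one threshold for the whole stack) or "per-slice".
    A constant image under Otsu yields an all-background result with a logged
    warning rather than an error.
    """
    if image.n_channels != 1:
        raise ValidationError("thresholding expects a single-channel image")
    if algorithm not in ("otsu", "manual"):
        raise ValidationError(f"unknown threshold algorithm {algorithm!r}")
    if scope not in ("global", "per-slice"):
        raise ValidationError(f"unknown threshold scope {scope!r}")
    data = image.data
    out = np.zeros(data.shape, dtype=np.uint8)

    def threshold_block(block: np.ndarray) -> np.ndarray:
        if algorithm == "manual":
            if manual_value is None:
                raise ValidationError("manual thresholding requires manual_value")
            lo, hi = float(block.min()), float(block.max())
            if not (lo <= float(manual_value) <= hi) and lo != hi:
                raise ValidationError(
                    f"manual threshold {manual_value} outside intensity range "
                    f"[{lo}, {hi}]"
                )
            thr = float(manual_value)
        else:
            if float(block.min()) == float(block.max()):
                logger.warning(
                    "%s: constant intensities; Otsu threshold undefined, "
                    "output is all background", image.name,
                )
                return np.zeros(block.shape, dtype=np.uint8)
            thr = compute_otsu_threshold(block)
        return (block > thr).astype(np.uint8) * BINARY_MAX

    if scope == "global":
        out[:] = threshold_block(data)
    else:
        for t in range(image.n_frames):
            for z in range(image.n_slices):
                out[t, z, 0] = threshold_block(data[t, z, 0])
    result = ImageStack(output_name or image.name, out, image.calibration.copy())
    return result


def fill_holes(image: ImageStack, output_name: str | None = None) -> ImageStack:
    """Fill background regions not connected to the slice border (2D, per
    slice, per channel, per timepoint)."""
    mask = as_bool(image.data, "fill_holes input")
    out = np.zeros(mask.shape, dtype=bool)
    for t in range(image.n_frames):
        for z in range(image.n_slices):
            for c in range(image.n_channels):
                out[t, z, c] = ndimage.binary_fill_holes(mask[t, z, c])
    data = out.astype(np.uint8) * BINARY_MAX
    return ImageStack(output_name or image.name, data, image.calibration.copy())


def _distinct_colors(n: int, seed: int) -> list[tuple[int, int, int]]:
    """n visually distinct RGB colours in a seeded random order."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    colors = []
    for i in order:
        r, g, b = colorsys.hsv_to_rgb(i / n, 1.0, 1.0)
        colors.append((int(r * 255), int(g * 255), int(b * 255)))
    return colors


def _grayscale_base(data: np.ndarray) -> np.ndarray:
    """First channel of the stack as uint8 for overlay rendering."""
    base = data[:, :, 0].astype(np.float64)
    lo, hi = base.min(), base.max()
    if data.dtype == np.uint8:
        return data[:, :, 0].copy()
    if hi > lo:
        base = (base - lo) / (hi - lo) * 255.0
    else:
        base = np.zeros_like(base)
    return base.astype(np.uint8)


def add_outline_overlay(image: ImageStack, objects: ObjectSet, seed: int = 42,
                        output_name: str = "Overlay") -> ImageStack:
    """Render object outlines in per-object random colours over the image.

    Boundary pixels are foreground voxels with at least one in-slice
     4-neighbour outside the object. Colours are drawn from a seeded shuffle,
    so the same seed always produces the same overlay.
    """
    if (objects.width, objects.height, objects.n_slices) != (
            image.width, image.height, image.n_slices):
        raise ValidationError(
            "object set extents do not match the image extents"
        )
    c_img, c_obj = image.calibration, objects.calibration
    if (c_img.dx, c_img.dy, c_img.dz) != (c_obj.dx, c_obj.dy, c_obj.dz):
        raise ValidationError("object set calibration does not match the image")

    base = _grayscale_base(image.data)  # (t, z, y, x) uint8
    out = np.repeat(base[:, :, np.newaxis], 3, axis=2)  # (t, z, 3, y, x)

    obj_list = list(objects)
    colors = _distinct_colors(len(obj_list), seed)
    for obj, color in zip(obj_list, colors):
        voxels = set(obj.store)
        t = obj.timepoint
        for x, y, z in voxels:
            neighbours = ((x - 1, y, z), (x + 1, y, z), (x, y - 1, z), (x, y + 1, z))
            on_edge = any(
                n not in voxels
                or not (0 <= n[0] < image.width and 0 <= n[1] < image.height)
                for n in neighbours
            )
            if on_edge:
                out[t, z, :, y, x] = color
    return ImageStack(output_name, out, image.calibration.copy())
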