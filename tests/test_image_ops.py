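"""Image operations: thresholding, hole filling, overlays, TIFF round trips."""

import logging
import os

import numpy as np
import pytest

from imflow.errors import ValidationError
from imflow.image_ops import (add_outline_overlay, apply_threshold,
                              compute_otsu_threshold, fill_holes, is_binary,
                              load_image, save_image)
from imflow.model import ImageStack, ObjectSet, SpatialCalibration
from imflow.object_ops import identify_objects


def stack2d(arr2d, dtype=np.uint8, calibration=None, name="Img"):
    data = np.asarray(arr2d, dtype=dtype)[np.newaxis, np.newaxis, np.newaxis]
    return ImageStack(name, data, calibration)


def otsu_oracle(values: np.ndarray) -> np.ndarray:
    """Exhaustive between-class-variance search over 256 histogram bins;
    returns the binary classification (foreground = above threshold)."""
    values = values.astype(float).ravel()
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_thr = -1.0, lo
    total = hist.sum()
    for cut in range(1, 256):
        w0 = hist[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut] * centers[:cut]).sum() / w0
        mu1 = (hist[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[cut - 1]
    return values > best_thr


# ---------------------------------------------------------------------------
# thresholding


def test_two_level_image_split_between_levels():
    arr = np.zeros((10, 10), np.uint8)
    arr[:, 5:] = 200
    arr[:, :5] = 10
    out = apply_threshold(stack2d(arr), "otsu")
    fg = out.data[0, 0, 0] > 0
    assert fg.sum() == 50
    assert fg[:, 5:].all() and not fg[:, :5].any()


@pytest.mark.parametrize("seed", range(5))
def test_otsu_matches_exhaustive_variance_search(seed):
    rng = np.random.default_rng(seed)
    arr = np.concatenate([
        rng.normal(40, 8, 500), rng.normal(180, 12, 300)
    ]).clip(0, 255).astype(np.uint8).reshape(20, 40)
    out = apply_threshold(stack2d(arr), "otsu")
    expected = otsu_oracle(arr).reshape(arr.shape)
    assert np.array_equal(out.data[0, 0, 0] > 0, expected)


def test_manual_threshold_selects_strictly_above():
    arr = np.array([[100, 130]], np.uint8)
    out = apply_threshold(stack2d(arr), "manual", manual_value=128)
    assert list(out.data[0, 0, 0, 0]) == [0, 255]


def test_constant_image_otsu_warns_and_returns_background(caplog):
    arr = np.full((8, 8), 77, np.uint8)
    with caplog.at_level(logging.WARNING):
        out = apply_threshold(stack2d(arr), "otsu")
    assert out.data.max() == 0
    assert any("constant" in rec.message for rec in caplog.records)


def test_threshold_idempotent_on_binary_image():
    arr = (np.indices((6, 6)).sum(axis=0) % 2 * 255).astype(np.uint8)
    once = apply_threshold(stack2d(arr), "manual", manual_value=128)
    twice = apply_threshold(once, "manual", manual_value=128)
    assert np.array_equal(once.data, twice.data)


def test_per_slice_scope_thresholds_each_slice():
    data = np.zeros((1, 2, 1, 8, 8), np.uint8)
    data[0, 0, 0, :, 4:] = 100  # slice 0: levels 0/100
    data[0, 1, 0, :, 4:] = 250  # slice 1: levels 0/250
    data[0, 1, 0, :, :4] = 150
    img = ImageStack("X", data)
    out = apply_threshold(img, "otsu", scope="per-slice")
    assert (out.data[0, 0, 0] > 0).sum() == 32
    assert (out.data[0, 1, 0] > 0).sum() == 32


def test_multichannel_input_rejected():
    img = ImageStack("X", np.zeros((1, 1, 2, 4, 4), np.uint8))
    with pytest.raises(ValidationError):
        apply_threshold(img, "otsu")


# ---------------------------------------------------------------------------
# hole filling


def test_ring_becomes_solid_disk():
    yy, xx = np.ogrid[0:32, 0:32]
    r2 = (yy - 16) ** 2 + (xx - 16) ** 2
    ring = ((r2 <= 100) & (r2 >= 36)).astype(np.uint8) * 255
    out = fill_holes(stack2d(ring))
    assert np.array_equal(out.data[0, 0, 0] > 0, r2 <= 100)


def test_solid_square_unchanged_and_border_background_kept():
    arr = np.zeros((10, 10), np.uint8)
    arr[2:8, 2:8] = 255
    out = fill_holes(stack2d(arr))
    assert np.array_equal(out.data, stack2d(arr).data)


def test_fill_holes_rejects_grayscale():
    with pytest.raises(ValidationError):
        fill_holes(stack2d(np.arange(16, dtype=np.uint8).reshape(4, 4)))


# ---------------------------------------------------------------------------
# overlays


def _square_objects(img):
    binary = apply_threshold(img, "manual", manual_value=128, output_name="B")
    return identify_objects(binary, "Objs")


def test_outline_overlay_colours_border_only():
    arr = np.zeros((9, 9), np.uint8)
    arr[3:6, 3:6] = 255  # one 3x3 square
    img = stack2d(arr)
    objs = _square_objects(img)
    out = add_outline_overlay(img, objs, seed=1)
    assert out.n_channels == 3
    rgb = out.data[0, 0]
    centre = rgb[:, 4, 4]
    assert np.array_equal(centre, [255, 255, 255])  # untouched grayscale
    border = [(3, 3), (3, 4), (3, 5), (4, 3), (4, 5), (5, 3), (5, 4), (5, 5)]
    colours = {tuple(rgb[:, y, x]) for y, x in border}
    assert len(colours) == 1
    assert colours != {(255, 255, 255)}


def test_overlay_two_objects_distinct_colours_and_deterministic():
    arr = np.zeros((12, 12), np.uint8)
    arr[1:4, 1:4] = 255
    arr[7:10, 7:10] = 255
    img = stack2d(arr)
    objs = _square_objects(img)
    out1 = add_outline_overlay(img, objs, seed=9)
    out2 = add_outline_overlay(img, objs, seed=9)
    assert np.array_equal(out1.data, out2.data)
    c1 = tuple(out1.data[0, 0, :, 1, 1])
    c2 = tuple(out1.data[0, 0, :, 7, 7])
    assert c1 != c2


def test_overlay_empty_object_set_is_plain_rgb_render():
    arr = np.arange(16, dtype=np.uint8).reshape(4, 4)
    img = stack2d(arr)
    objs = ObjectSet("Empty", width=4, height=4, n_slices=1)
    out = add_outline_overlay(img, objs)
    for c in range(3):
        assert np.array_equal(out.data[0, 0, c], arr)


def test_overlay_extent_mismatch_rejected():
    img = stack2d(np.zeros((4, 4), np.uint8))
    objs = ObjectSet("Objs", width=8, height=8, n_slices=1)
    with pytest.raises(ValidationError):
        add_outline_overlay(img, objs)


# ---------------------------------------------------------------------------
# TIFF I/O


def test_save_load_round_trip_5d_with_calibration(tmp_path):
    cal = SpatialCalibration(dx=0.5, dy=0.5, dz=2.0, spatial_unit="micron",
                             frame_interval=0.25)
    rng = np.random.default_rng(0)
    data = rng.integers(0, 65535, size=(2, 3, 1, 16, 16), dtype=np.uint16)
    img = ImageStack("Raw", data, cal)
    path = save_image(img, str(tmp_path / "sub" / "x.tif"))  # auto-created folder
    back = load_image(path)
    assert np.array_equal(back.data, data)
    assert back.calibration.dx == pytest.approx(0.5)
    assert back.calibration.dz == pytest.approx(2.0)
    assert back.calibration.frame_interval == pytest.approx(0.25)
    assert back.calibration.spatial_unit == "micron"


def test_load_2d_and_multipage_shapes(tmp_path):
    import tifffile

    p2d = tmp_path / "flat.tif"
    tifffile.imwrite(p2d, np.zeros((64, 64), np.uint8))
    img = load_image(str(p2d))
    assert img.data.shape == (1, 1, 1, 64, 64)

    p3d = tmp_path / "stack.tif"
    tifffile.imwrite(p3d, np.zeros((10, 64, 64), np.uint8), imagej=True,
                     metadata={"axes": "ZYX"})
    img = load_image(str(p3d))
    assert img.data.shape == (1, 10, 1, 64, 64)


def test_missing_file_raises_io_error_naming_path():
    with pytest.raises(IOError, match="no/such"):
        load_image("no/such/file.tif")


def test_non_image_file_raises_format_error(tmp_path):
    bad = tmp_path / "fake.tif"
    bad.write_text("this is not a tiff")
    with pytest.raises(ValidationError):
        load_image(str(bad))


def test_rgb_overlay_saves_as_three_channel_tiff(tmp_path):
    arr = np.zeros((8, 8), np.uint8)
    arr[2:5, 2:5] = 255
    img = stack2d(arr)
    objs = _square_objects(img)
    out = add_outline_overlay(img, objs, seed=3)
    path = save_image(out, str(tmp_path / "ov.tif"))
    back = load_image(path)
    assert back.n_channels == 3
    assert np.array_equal(back.data, out.data)


def test_uncalibrated_load_warns_and_defaults(tmp_path, caplog):
    import tifffile

    p = tmp_path / "plain.tif"
    tifffile.imwrite(p, np.zeros((8, 8), np.uint8))
    with caplog.at_level(logging.WARNING):
        img = load_image(str(p))
    assert img.calibration.dx == 1.0


def test_is_binary_convention():
    assert is_binary(np.array([0, 255], np.uint8))
    assert is_binary(np.zeros(4, bool))
    assert not is_binary(np.array([0, 7], np.uint8))
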