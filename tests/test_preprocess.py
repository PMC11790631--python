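"""The five preprocessing steps, each against a closed-form or brute-force
oracle: Canny on analytic shapes, minimal-square crop vs exhaustive search,
resize/rotate/normalize arithmetic, and full-pipeline determinism."""

import numpy as np
import pytest

from duostream.preprocess import (
    MIN_CROP_SIDE,
    PreprocessConfig,
    crop_window,
    augment_rotation,
    detect_edges,
    min_square_crop,
    normalize_image,
    preprocess_pipeline,
    resize_image,
)
from duostream.synthetic_data import FrontCues, render_flower


@pytest.fixture()
def cfg():
    return PreprocessConfig(target_size=32)


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

def test_constant_image_has_no_edges(cfg):
    img = np.full((40, 40, 3), 97, dtype=np.uint8)
    mask = detect_edges(img, cfg)
    assert mask.shape == (40, 40)
    assert not mask.any()


def test_disk_edges_lie_on_annulus(cfg):
    """Every Canny edge pixel of a white disk sits within 2 px of the circle."""
    s, r = 64, 20
    yy, xx = np.mgrid[0:s, 0:s]
    dist = np.hypot(yy - s / 2, xx - s / 2)
    img = np.where(dist[..., None] <= r, 255, 0).astype(np.uint8).repeat(3, axis=2)
    mask = detect_edges(img, cfg)
    assert mask.sum() > 20  # outline found
    assert np.all(np.abs(dist[mask] - r) <= 2.0)


def test_synthetic_flower_edges_cover_petal_outline(cfg):
    img, meta = render_flower("front", FrontCues(8, 1, 1), 64, np.random.default_rng(0))
    mask = detect_edges(img, cfg)
    assert mask.any()
    # edge pixels stay inside a slightly dilated flower bounding box
    r0, r1, c0, c1 = meta.bbox
    rows, cols = np.nonzero(mask)
    assert rows.min() >= r0 - 3 and rows.max() <= r1 + 3
    assert cols.min() >= c0 - 3 and cols.max() <= c1 + 3


# ---------------------------------------------------------------------------
# minimal-square crop
# ---------------------------------------------------------------------------

def test_crop_known_bounding_box():
    img = np.arange(40 * 40 * 3, dtype=np.uint8).reshape(40, 40, 3)
    mask = np.zeros((40, 40), dtype=bool)
    mask[10, 10] = mask[20, 30] = True
    out = min_square_crop(img, mask)
    assert out.shape == (21, 21, 3)
    np.testing.assert_array_equal(out, img[5:26, 10:31])  # rows 5..25, cols 10..30


def test_crop_empty_mask_returns_input():
    img = np.zeros((30, 30, 3), dtype=np.uint8)
    out = min_square_crop(img, np.zeros((30, 30), dtype=bool))
    assert out is img


def test_crop_single_pixel_uses_min_side():
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    mask = np.zeros((64, 64), dtype=bool)
    mask[31, 31] = True
    out = min_square_crop(img, mask)
    assert out.shape == (MIN_CROP_SIDE, MIN_CROP_SIDE, 3)


def _brute_force_min_side(mask):
    """Smallest square side that can contain all true pixels."""
    rows, cols = np.nonzero(mask)
    return max(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)


@pytest.mark.parametrize("trial", range(30))
def test_crop_minimality_random_sparse_masks(trial):
    rng = np.random.default_rng(1000 + trial)
    h = w = int(rng.integers(20, 60))  # square frame: a covering square always exists
    mask = np.zeros((h, w), dtype=bool)
    k = rng.integers(1, 8)
    mask[rng.integers(0, h, k), rng.integers(0, w, k)] = True
    window = crop_window(mask)
    top, left, side = window
    rows, cols = np.nonzero(mask)
    # contains all edge pixels
    assert rows.min() >= top and rows.max() < top + side
    assert cols.min() >= left and cols.max() < left + side
    # no strictly smaller square could (above the speckle-guard floor)
    assert side == min(max(_brute_force_min_side(mask), MIN_CROP_SIDE), h, w)


# ---------------------------------------------------------------------------
# resize / rotate / normalize
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("in_shape", [(448, 448), (224, 224), (100, 300)])
def test_resize_output_shape(in_shape):
    img = np.random.default_rng(0).integers(0, 255, size=(*in_shape, 3)).astype(np.uint8)
    out = resize_image(img, 224)
    assert out.shape == (224, 224, 3)
    if in_shape == (224, 224):
        np.testing.assert_array_equal(out, img)


def test_rotation_zero_degrees_is_identity(rng):
    img = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
    np.testing.assert_array_equal(augment_rotation(img, 0.0, rng), img)


def test_rotation_reproducible_under_seed():
    img = np.random.default_rng(1).integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
    out1 = augment_rotation(img, 15.0, np.random.default_rng(42))
    out2 = augment_rotation(img, 15.0, np.random.default_rng(42))
    np.testing.assert_array_equal(out1, out2)
    out3 = augment_rotation(img, 15.0, np.random.default_rng(43))
    assert not np.array_equal(out1, out3)


def test_rotation_of_centered_disk_is_near_identity(rng):
    s = 65
    yy, xx = np.mgrid[0:s, 0:s]
    disk = (np.hypot(yy - s // 2, xx - s // 2) <= 20).astype(np.float64) * 200
    img = np.stack([disk] * 3, axis=-1)
    out = augment_rotation(img, 15.0, rng)
    # rotational symmetry: differences only from interpolation at the rim
    assert np.mean(np.abs(out - img)) < 0.02 * 200


def test_normalize_closed_form():
    img = np.full((2, 2, 3), 255.0)
    np.testing.assert_allclose(normalize_image(img, (0, 0, 0), (1, 1, 1)), np.ones((2, 2, 3)))
    img = np.full((2, 2, 3), 127.0)
    np.testing.assert_allclose(
        normalize_image(img, (0.5, 0.5, 0.5), (0.5, 0.5, 0.5)),
        np.full((2, 2, 3), (127.0 / 255.0 - 0.5) / 0.5),
    )
    img = np.zeros((2, 2, 3))
    np.testing.assert_allclose(
        normalize_image(img, (0.3, 0.3, 0.3), (0.2, 0.2, 0.2)),
        np.full((2, 2, 3), -0.3 / 0.2),
    )


def test_normalize_rejects_zero_std():
    with pytest.raises(ValueError):
        normalize_image(np.zeros((2, 2, 3)), (0, 0, 0), (0.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def test_pipeline_output_shape_and_determinism(cfg):
    rng = np.random.default_rng(5)
    raw = (
        rng.integers(0, 255, size=(50, 70, 3)).astype(np.uint8),
        rng.integers(0, 255, size=(80, 40, 3)).astype(np.uint8),
    )
    vp1 = preprocess_pipeline(raw, cfg, pair_id="x")
    vp2 = preprocess_pipeline(raw, cfg)
    assert vp1.front.shape == vp1.back.shape == (32, 32, 3)
    np.testing.assert_array_equal(vp1.front, vp2.front)  # bitwise, augment off
    np.testing.assert_array_equal(vp1.back, vp2.back)
    assert vp1.provenance == "x"


def test_pipeline_crop_contains_flower_extent(cfg):
    img, meta = render_flower("front", FrontCues(6, 2, 1), 64, np.random.default_rng(3))
    mask = detect_edges(img, cfg)
    top, left, side = crop_window(mask)
    r0, r1, c0, c1 = meta.bbox
    # the crop square tightly contains the rendered flower (within Canny's
    # localisation error of a couple of pixels)
    assert top <= r0 + 3 and top + side >= r1 - 3
    assert left <= c0 + 3 and left + side >= c1 - 3


def test_pipeline_augmented_requires_rng():
    cfg = PreprocessConfig(target_size=32, augment=True)
    raw = (np.zeros((40, 40, 3), dtype=np.uint8),) * 2
    with pytest.raises(ValueError):
        preprocess_pipeline(raw, cfg, rng=None)


def test_pipeline_locked_rotation_uses_same_angle():
    cfg = PreprocessConfig(target_size=32, augment=True, lock_rotation=True)
    rng = np.random.default_rng(9)
    img = np.random.default_rng(2).integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
    vp = preprocess_pipeline((img, img.copy()), cfg, rng=rng)
    np.testing.assert_array_equal(vp.front, vp.back)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(canny_low=100, canny_high=50)
    with pytest.raises(ValueError):
        PreprocessConfig(target_size=0)
    with pytest.raises(ValueError):
        PreprocessConfig(max_rotation_deg=-1)
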