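"""Morphological preprocessing against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from ganaug.errors import DegenerateInputError, EmptyForegroundError
from ganaug.phantom import brain_mask, generate_phantom
from ganaug.preprocess import (DISK5, SQUARE3, StructuringElement,
                               contrast_improve, dilate, geodesic_reconstruct,
                               gray_open, largest_connected_component,
                               otsu_threshold, skull_strip)
from tests.test_phantom import spec64

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def otsu_oracle(img):
    """Exhaustive scan of all thresholds for the within-class variance min."""
    a = np.asarray(img).ravel()
    best_t, best_v = None, np.inf
    for t in range(256):
        lo, hi = a[a <= t], a[a > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        v = len(lo) * np.var(lo) + len(hi) * np.var(hi)
        if v < best_v - 1e-9:  # strict improvement keeps the smallest tie
            best_t, best_v = t, v
    return best_t


def dilate_oracle(mask, se):
    """Per-pixel neighbourhood OR."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            for dy, dx in se.offsets():
                sy, sx = y - dy, x - dx
                if 0 <= sy < h and 0 <= sx < w and mask[sy, sx]:
                    out[y, x] = True
                    break
    return out


def gray_open_oracle(img, se):
    """Erosion-then-dilation by explicit min/max over the clipped footprint."""
    a = np.asarray(img, dtype=np.int64)
    h, w = a.shape

    def scan(src, op):
        out = np.empty_like(src)
        for y in range(h):
            for x in range(w):
                vals = [src[y + dy, x + dx] for dy, dx in se.offsets()
                        if 0 <= y + dy < h and 0 <= x + dx < w]
                out[y, x] = op(vals)
        return out

    return scan(scan(a, min), max)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------


def test_otsu_two_value_image():
    t, b = otsu_threshold(np.array([[0, 0], [255, 255]]))
    assert np.array_equal(b, [[False, False], [True, True]])


def test_otsu_constant_image_is_degenerate():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full((2, 2), 5))


def test_otsu_equals_exhaustive_minimizer_on_random_images():
    rng = np.random.default_rng(7)
    for _ in range(100):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        t, b = otsu_threshold(img)
        assert t == otsu_oracle(img)
        assert np.array_equal(b, img > t)


@settings(derandomize=True, max_examples=60)
@given(arrays(np.uint8, (6, 6), elements=st.integers(0, 255)))
def test_otsu_property_matches_oracle_on_arbitrary_images(img):
    if img.min() == img.max():
        return
    t, _ = otsu_threshold(img)
    assert t == otsu_oracle(img)


def test_otsu_bimodal_mixture():
    rng = np.random.default_rng(1)
    img = np.where(rng.random((8, 8)) < 0.6, 10, 200).astype(np.uint8)
    t, _ = otsu_threshold(img)
    assert t == otsu_oracle(img)
    assert 10 <= t < 200


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------


def test_largest_cc_single_pixel():
    m = np.zeros((5, 5), bool)
    m[2, 3] = True
    assert np.array_equal(largest_connected_component(m), m)


def test_largest_cc_keeps_biggest_blob():
    m = np.zeros((8, 8), bool)
    m[0:3, 0:3] = True          # 9 > 7: trim to 7 pixels
    m[0, 0] = m[0, 1] = False
    m[6:8, 5:8] = True          # 6-pixel blob (3x2)
    out = largest_connected_component(m, 8)
    lab, n = ndimage.label(m, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(m, lab, range(1, n + 1))
    assert out.sum() == sizes.max() == 7
    assert not out[6:8, 5:8].any()


def test_largest_cc_tie_breaks_to_first_in_raster_order():
    m = np.zeros((5, 5), bool)
    m[0, 0] = True
    m[4, 4] = True
    out = largest_connected_component(m, 4)
    assert out[0, 0] and not out[4, 4]


def test_largest_cc_empty_mask_errors():
    with pytest.raises(EmptyForegroundError):
        largest_connected_component(np.zeros((3, 3), bool))


@pytest.mark.parametrize("connectivity,joined", [(4, False), (8, True)])
def test_cc_connectivity_distinguishes_diagonals(connectivity, joined):
    m = np.zeros((4, 4), bool)
    m[0, 0] = m[1, 1] = m[2, 2] = True
    m[3, 0] = True
    out = largest_connected_component(m, connectivity)
    assert out.sum() == (3 if joined else 1)


# ---------------------------------------------------------------------------
# dilation and reconstruction
# ---------------------------------------------------------------------------


def test_dilate_empty_and_single_pixel():
    empty = np.zeros((6, 6), bool)
    assert not dilate(empty, SQUARE3).any()
    single = np.zeros((5, 5), bool)
    single[2, 2] = True
    assert np.array_equal(dilate(single, SQUARE3)[1:4, 1:4], np.ones((3, 3), bool))
    assert dilate(single, SQUARE3).sum() == 9


@pytest.mark.parametrize("se", [SQUARE3, StructuringElement("disk", 2)])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dilate_matches_neighbourhood_or_oracle(se, seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((16, 16)) < 0.2
    assert np.array_equal(dilate(mask, se), dilate_oracle(mask, se))


def test_dilate_is_extensive(rng):
    mask = rng.random((20, 20)) < 0.3
    out = dilate(mask, StructuringElement("disk", 2))
    assert (out | mask).sum() == out.sum()


def test_reconstruct_fixpoint_and_empty_marker(rng):
    c = rng.random((10, 10)) < 0.4
    assert np.array_equal(geodesic_reconstruct(c, c), c)
    assert not geodesic_reconstruct(np.zeros_like(c), c).any()


def test_reconstruct_recovers_seeded_component():
    c = np.zeros((10, 10), bool)
    c[1:4, 1:4] = True
    c[6:9, 6:9] = True
    marker = np.zeros_like(c)
    marker[2, 2] = True
    out = geodesic_reconstruct(marker, c)
    assert out[1:4, 1:4].all() and not out[6:9, 6:9].any()


@pytest.mark.parametrize("seed", range(5))
def test_reconstruct_matches_flood_fill_oracle_and_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    c = rng.random((32, 32)) < 0.45
    marker = c & (rng.random((32, 32)) < 0.1)
    out = geodesic_reconstruct(marker, c)
    # oracle: union of labelled components touched by the marker
    lab, n = ndimage.label(c, structure=np.ones((3, 3)))
    touched = set(np.unique(lab[marker])) - {0}
    expect = np.isin(lab, sorted(touched))
    assert np.array_equal(out, expect)
    assert np.array_equal(geodesic_reconstruct(out, c), out)


# ---------------------------------------------------------------------------
# contrast improvement
# ---------------------------------------------------------------------------


def test_contrast_flat_image_unchanged():
    img = np.full((9, 9), 77, np.uint8)
    assert np.array_equal(contrast_improve(img), img)


def test_contrast_plateau_case():
    """3x3 plateau of 150 on background 50, disk radius 4: the opening
    removes the plateau entirely, so the top-hat adds a full 100 there."""
    img = np.full((15, 15), 50, np.uint8)
    img[6:9, 6:9] = 150
    out = contrast_improve(img, StructuringElement("disk", 4))
    assert (out[6:9, 6:9] == 250).all()
    outside = np.ones_like(img, bool)
    outside[6:9, 6:9] = False
    assert (out[outside] == 50).all()


@pytest.mark.parametrize("seed", range(3))
def test_contrast_never_darkens_and_opening_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
    se = StructuringElement("disk", 2)
    out = contrast_improve(img, se)
    assert (out.astype(int) >= img.astype(int)).all()
    assert np.array_equal(gray_open(img, se), gray_open_oracle(img, se))


def test_contrast_equality_iff_open_invariant():
    img = np.full((8, 8), 100, np.uint8)  # opening(img) == img
    assert np.array_equal(contrast_improve(img, DISK5), img)


# ---------------------------------------------------------------------------
# skull stripping
# ---------------------------------------------------------------------------


def test_skull_strip_zeroes_outside_mask_and_matches_phantom_truth():
    spec = spec64(noise_sigma=0.0)
    img, _ = generate_phantom(spec)
    stripped, mask = skull_strip(img)
    assert (stripped[~mask] == 0).all()
    assert np.array_equal(stripped[mask], img[mask])
    truth = brain_mask(spec)
    assert (mask == truth).mean() >= 0.99


def test_skull_strip_mask_is_union_of_otsu_components():
    spec = spec64(noise_sigma=4.0)
    img, _ = generate_phantom(spec)
    _, binary = otsu_threshold(img)
    _, mask = skull_strip(img)
    lab, n = ndimage.label(binary, structure=np.ones((3, 3)))
    kept = set(np.unique(lab[mask])) - {0}
    assert np.array_equal(mask, np.isin(lab, sorted(kept)))
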