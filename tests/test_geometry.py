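"""Geometry: brute-force oracle equivalence and invariances of the CTR lines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctrkit.errors import ContractError, MeasurementFailure
from ctrkit.geometry import clean_mask, iou, measure_ctr
from .conftest import random_blob_mask


def oracle_measure(lung: np.ndarray, heart: np.ndarray) -> dict:
    """Exhaustive per-pixel scan: widest lung row, global heart extent."""
    best = None
    for r in range(lung.shape[0]):
        cols = [c for c in range(lung.shape[1]) if lung[r, c]]
        if not cols:
            continue
        width = cols[-1] - cols[0] + 1
        if best is None or width > best[0]:
            best = (width, r, cols[0], cols[-1])
    h_cols = sorted(c for c in range(heart.shape[1]) if heart[:, c].any())
    return {
        "id_length": best[0],
        "id_row": best[1],
        "id_left_x": best[2],
        "id_right_x": best[3],
        "cardiac_width": h_cols[-1] - h_cols[0] + 1,
        "ctr": (h_cols[-1] - h_cols[0] + 1) / best[0],
    }


def oracle_label_areas(mask: np.ndarray) -> list[int]:
    """4-connected component areas via BFS, independent of scipy labelling."""
    seen = np.zeros_like(mask, dtype=bool)
    areas = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                stack, area = [(sy, sx)], 0
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    area += 1
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                areas.append(area)
    return sorted(areas, reverse=True)


def test_constructed_identity_example():
    lung = np.zeros((40, 240), dtype=bool)
    lung[18, 20:70] = True      # left field, widest row
    lung[18, 170:220] = True    # right field; union spans 20..219 -> ID 200
    lung[10, 30:60] = True
    heart = np.zeros_like(lung)
    heart[25, 70:170] = True    # extent 100
    m = measure_ctr(lung, heart)
    assert m.id_length == 200 and m.cardiac_width == 100
    assert m.ctr == pytest.approx(0.500)
    assert m.midline_x == pytest.approx(119.5)
    assert m.mrd_length == pytest.approx(50) and m.mld_length == pytest.approx(50)


def test_oracle_equivalence_on_random_masks(rng):
    for _ in range(50):
        lung = random_blob_mask(rng)
        heart = random_blob_mask(rng)
        if not lung.any() or not heart.any():
            continue
        m = measure_ctr(lung, heart)
        o = oracle_measure(lung, heart)
        assert m.id_length == o["id_length"]
        assert (m.id_row, m.id_left_x, m.id_right_x) == (o["id_row"], o["id_left_x"], o["id_right_x"])
        assert m.cardiac_width == o["cardiac_width"]
        assert m.ctr == o["ctr"]


def test_mrd_plus_mld_equals_global_extent_regardless_of_midline(rng):
    for _ in range(100):
        lung = random_blob_mask(rng)
        heart = random_blob_mask(rng)
        if not lung.any() or not heart.any():
            continue
        m = measure_ctr(lung, heart)
        assert m.mrd_length + m.mld_length == m.cardiac_width  # exact, algebraic


def test_translation_invariance(rng):
    lung = random_blob_mask(rng, shape=(30, 30))
    heart = random_blob_mask(rng, shape=(30, 30))
    big_l = np.zeros((60, 70), dtype=bool)
    big_h = np.zeros((60, 70), dtype=bool)
    big_l[5:35, 10:40] = lung
    big_h[5:35, 10:40] = heart
    shifted_l = np.roll(np.roll(big_l, 11, axis=0), 13, axis=1)
    shifted_h = np.roll(np.roll(big_h, 11, axis=0), 13, axis=1)
    if big_l.any() and big_h.any():
        m0, m1 = measure_ctr(big_l, big_h), measure_ctr(shifted_l, shifted_h)
        assert m0.id_length == m1.id_length
        assert m0.cardiac_width == m1.cardiac_width
        assert m0.ctr == m1.ctr


def test_horizontal_flip_swaps_mrd_mld(rng):
    for _ in range(20):
        lung = random_blob_mask(rng)
        heart = random_blob_mask(rng)
        if not lung.any() or not heart.any():
            continue
        m = measure_ctr(lung, heart)
        f = measure_ctr(lung[:, ::-1], heart[:, ::-1])
        assert f.ctr == pytest.approx(m.ctr)
        assert f.mrd_length == pytest.approx(m.mld_length)
        assert f.mld_length == pytest.approx(m.mrd_length)


def test_horizontal_dilation_monotonicity(rng):
    from scipy import ndimage
    struct = np.array([[1, 1, 1]], dtype=bool)  # horizontal-only dilation
    for _ in range(20):
        lung = random_blob_mask(rng)
        heart = random_blob_mask(rng)
        if not lung.any() or not heart.any():
            continue
        m = measure_ctr(lung, heart)
        wider_heart = ndimage.binary_dilation(heart, structure=struct)
        assert measure_ctr(lung, wider_heart).ctr >= m.ctr
        wider_lung = ndimage.binary_dilation(lung, structure=struct)
        assert measure_ctr(wider_lung, heart).ctr <= m.ctr


def test_heart_on_one_side_flags_pathology():
    lung = np.zeros((20, 100), dtype=bool)
    lung[10, 5:95] = True
    heart = np.zeros_like(lung)
    heart[12, 70:90] = True  # entirely right of the midline (49.5)
    m = measure_ctr(lung, heart)
    assert m.pathological
    assert m.mrd_length < 0
    assert m.ctr == pytest.approx(20 / 90)  # global-extent identity still holds


def test_empty_masks_raise_measurement_failure():
    empty = np.zeros((10, 10), dtype=bool)
    full = np.ones((10, 10), dtype=bool)
    with pytest.raises(MeasurementFailure):
        measure_ctr(empty, full)
    with pytest.raises(MeasurementFailure):
        measure_ctr(full, empty)
    with pytest.raises(ContractError):
        measure_ctr(np.ones((5, 5)), np.ones((6, 6)))


# -- clean_mask -------------------------------------------------------------

def test_clean_mask_drops_speckles_keeps_giant():
    mask = np.zeros((40, 40), dtype=bool)
    mask[5:25, 5:25] = True    # giant
    mask[35, 35:38] = True     # 3-px speckle
    out = clean_mask(mask, keep_components=1)
    assert out[10, 10] and not out[35, 35]


def test_clean_mask_empty_is_identity():
    empty = np.zeros((16, 16), dtype=bool)
    assert not clean_mask(empty).any()


def test_clean_mask_keeps_top_k_areas_per_bfs_oracle(rng):
    for _ in range(15):
        mask = random_blob_mask(rng, shape=(28, 28), n_blobs=4)
        for k in (1, 2):
            out = clean_mask(mask, min_area_frac=0.0, keep_components=k)
            from scipy import ndimage
            filled = ndimage.binary_fill_holes(mask)
            expected = sum(oracle_label_areas(filled)[:k])
            assert out.sum() == expected


def test_clean_mask_fills_holes():
    mask = np.zeros((20, 20), dtype=bool)
    mask[2:18, 2:18] = True
    mask[8:12, 8:12] = False  # hole
    assert clean_mask(mask, keep_components=1).sum() == 16 * 16


# -- IoU --------------------------------------------------------------------

def test_iou_identical_disjoint_and_empty():
    a = np.zeros((10, 10), dtype=bool)
    a[2:5, 2:5] = True
    b = np.zeros_like(a)
    b[6:9, 6:9] = True
    assert iou(a, a) == 1.0
    assert iou(a, b) == 0.0
    empty = np.zeros_like(a)
    assert iou(empty, empty) == 1.0
    assert iou(a, empty) == 0.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_iou_matches_counting_oracle(seed):
    r = np.random.default_rng(seed)
    a = r.random((12, 15)) < 0.4
    b = r.random((12, 15)) < 0.4
    inter = sum(bool(a[i, j]) and bool(b[i, j]) for i in range(12) for j in range(15))
    union = sum(bool(a[i, j]) or bool(b[i, j]) for i in range(12) for j in range(15))
    expected = 1.0 if union == 0 else inter / union
    assert iou(a, b) == expected
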