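import numpy as np
import pytest

from anthomap.calibrate import (
    calibrate,
    mean_spectrum,
    remove_stalk,
    sample_pixels,
    segment_fruit,
)
from anthomap.types import FruitMask, SpectralCube


def _cube(values, wl=None, role="raw"):
    values = np.asarray(values, dtype=float)
    wl = np.linspace(500, 900, values.shape[2]) if wl is None else np.asarray(wl, float)
    return SpectralCube(wl, values, role)


def _triplet(i, w, d, shape=(2, 2, 3)):
    return (
        _cube(np.full(shape, i)),
        _cube(np.full(shape, w), role="white"),
        _cube(np.full(shape, d), role="dark"),
    )


def test_raw_equals_dark_gives_zero():
    r = calibrate(*_triplet(5.0, 105.0, 5.0))
    np.testing.assert_array_equal(r.values, 0.0)
    assert r.role == "reflectance"


def test_raw_equals_white_gives_one():
    r = calibrate(*_triplet(105.0, 105.0, 5.0))
    np.testing.assert_array_equal(r.values, 1.0)


def test_hand_computed_cell():
    # (55 - 5) / (105 - 5) = 0.5
    r = calibrate(*_triplet(55.0, 105.0, 5.0))
    np.testing.assert_array_equal(r.values, 0.5)


def test_affine_invariance_without_clipping():
    rng = np.random.default_rng(0)
    wl = np.linspace(500, 900, 4)
    i = rng.uniform(40, 60, size=(3, 3, 4))
    w = np.full((3, 3, 4), 100.0)
    d = np.full((3, 3, 4), 10.0)
    base = calibrate(_cube(i, wl), _cube(w, wl, "white"), _cube(d, wl, "dark"))
    a, b = 3.0, 7.0
    scaled = calibrate(
        _cube(a * i + b, wl), _cube(a * w + b, wl, "white"), _cube(a * d + b, wl, "dark")
    )
    np.testing.assert_allclose(scaled.values, base.values, atol=1e-12)


def test_degenerate_white_dark_cells_zeroed_with_warning():
    i, w, d = _triplet(55.0, 105.0, 5.0)
    w.values[0, 0, 0] = 5.0  # W == D at one cell
    with pytest.warns(UserWarning):
        r = calibrate(i, w, d)
    assert r.values[0, 0, 0] == 0.0
    assert r.values[1, 1, 1] == 0.5


def test_shape_mismatch_rejected():
    i, w, d = _triplet(55.0, 105.0, 5.0)
    bad = _cube(np.full((2, 3, 3), 105.0), role="white")
    with pytest.raises(ValueError):
        calibrate(i, bad, d)


def test_segment_threshold_direction():
    wl = np.array([700.0, 800.0, 900.0])
    values = np.zeros((2, 2, 3))
    values[0, 0] = [0.5, 0.6, 0.6]  # bright fruit
    values[1, 1] = [0.05, 0.05, 0.05]  # background
    refl = SpectralCube(wl, values, "reflectance")
    mask = segment_fruit(refl)
    assert mask.grid[0, 0] and not mask.grid[1, 1]


def test_segment_uniform_background_warns_empty():
    refl = SpectralCube(np.array([750.0, 800.0]), np.full((3, 3, 2), 0.05), "reflectance")
    with pytest.warns(UserWarning):
        mask = segment_fruit(refl)
    assert mask.n_fruit_pixels == 0


def test_segment_zero_threshold_marks_all():
    refl = SpectralCube(np.array([750.0, 800.0]), np.full((3, 3, 2), 0.05), "reflectance")
    assert segment_fruit(refl, threshold=0.0).n_fruit_pixels == 9


def test_stalk_rule_evaluation():
    wl = np.array([550.0, 670.0])
    values = np.zeros((1, 3, 2))
    values[0, 0] = [0.30, 0.20]  # diff 0.10 -> stalk, removed
    values[0, 1] = [0.25, 0.25]  # diff 0 -> retained
    values[0, 2] = [0.10, 0.30]  # diff -0.20 -> retained (flesh)
    refl = SpectralCube(wl, values, "reflectance")
    mask = FruitMask(np.ones((1, 3), dtype=bool))
    out = remove_stalk(refl, mask)
    np.testing.assert_array_equal(out.grid, [[False, True, True]])


def test_remove_stalk_subset_of_input_mask(small_scene):
    _, raw, white, dark, _ = small_scene
    refl = calibrate(raw, white, dark)
    seg = segment_fruit(refl)
    roi = remove_stalk(refl, seg)
    assert not np.any(roi.grid & ~seg.grid)


def test_segmentation_matches_truth_on_synthetic_scene(small_scene):
    _, raw, white, dark, truth = small_scene
    refl = calibrate(raw, white, dark)
    seg = segment_fruit(refl)
    union = truth.fruit_mask.grid | truth.stalk_mask
    jaccard = (seg.grid & union).sum() / (seg.grid | union).sum()
    assert jaccard >= 0.95
    roi = remove_stalk(refl, seg)
    stalk_kept = (roi.grid & truth.stalk_mask).sum() / max(truth.stalk_mask.sum(), 1)
    flesh_lost = (truth.fruit_mask.grid & ~roi.grid).sum() / truth.fruit_mask.grid.sum()
    assert stalk_kept <= 0.05
    assert flesh_lost <= 0.05


def test_mean_spectrum_identity_and_two_point_mean():
    wl = np.array([600.0, 700.0])
    values = np.zeros((1, 2, 2))
    values[0, 0] = [0.2, 0.4]
    values[0, 1] = [0.4, 0.8]
    refl = SpectralCube(wl, values, "reflectance")
    one = mean_spectrum(refl, FruitMask(np.array([[True, False]])))
    np.testing.assert_allclose(one.values, [[0.2, 0.4]])
    both = mean_spectrum(refl, FruitMask(np.array([[True, True]])))
    np.testing.assert_allclose(both.values, [[0.3, 0.6]])


def test_mean_spectrum_permutation_invariant(small_scene):
    _, raw, white, dark, truth = small_scene
    refl = calibrate(raw, white, dark)
    m1 = mean_spectrum(refl, truth.fruit_mask)
    flipped = SpectralCube(refl.wavelengths, refl.values[::-1].copy(), "reflectance")
    m2 = mean_spectrum(flipped, FruitMask(truth.fruit_mask.grid[::-1].copy()))
    np.testing.assert_allclose(m1.values, m2.values, rtol=1e-6)


def test_mean_spectrum_empty_mask_raises(small_scene):
    _, raw, white, dark, _ = small_scene
    refl = calibrate(raw, white, dark)
    with pytest.raises(ValueError):
        mean_spectrum(refl, FruitMask(np.zeros(refl.shape[:2], dtype=bool)))


def test_sample_pixels_deterministic_and_distinct(small_scene):
    _, raw, white, dark, truth = small_scene
    refl = calibrate(raw, white, dark)
    a = sample_pixels(refl, truth.fruit_mask, n=50, seed=5)
    b = sample_pixels(refl, truth.fruit_mask, n=50, seed=5)
    c = sample_pixels(refl, truth.fruit_mask, n=50, seed=6)
    np.testing.assert_array_equal(a.values, b.values)
    assert list(a.row_ids) == list(b.row_ids)
    assert list(a.row_ids) != list(c.row_ids)
    assert len(set(a.row_ids)) == 50


def test_sample_pixels_small_mask_returns_all_with_warning():
    wl = np.array([600.0, 700.0])
    refl = SpectralCube(wl, np.random.default_rng(0).random((2, 2, 2)), "reflectance")
    mask = FruitMask(np.array([[True, False], [False, True]]))
    with pytest.warns(UserWarning):
        out = sample_pixels(refl, mask, n=10, seed=0)
    assert out.n == 2


def test_sample_single_pixel():
    wl = np.array([600.0, 700.0])
    values = np.arange(8, dtype=float).reshape(2, 2, 2)
    refl = SpectralCube(wl, values, "reflectance")
    mask = FruitMask(np.array([[False, True], [False, False]]))
    out = sample_pixels(refl, mask, n=1, seed=3)
    np.testing.assert_array_equal(out.values, [[2.0, 3.0]])
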