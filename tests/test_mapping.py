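import numpy as np
import pytest

from anthomap.bundle import AlignmentError, ModelBundle
from anthomap.calibrate import calibrate, remove_stalk, segment_fruit
from anthomap.mapping import map_statistics, predict_map, render_map
from anthomap.models import fit_elm
from anthomap.preprocess import snv_array
from anthomap.synthetic import SceneSpec, generate_scene, reflectance_model
from anthomap.types import FruitMask, GroundTruth, PredictionMap


@pytest.fixture(scope="module")
def linear_bundle():
    """A small ELM bundle trained on model spectra over the full default
    grid; used to exercise the mapping path end to end."""
    from anthomap.synthetic import default_wavelengths

    rng = np.random.default_rng(0)
    wl = default_wavelengths()
    c = rng.uniform(0.1, 4.5, size=300)
    R = reflectance_model(wl, c, 0.4, 0.8) + 0.002 * rng.normal(size=(300, wl.size))
    X = snv_array(R)
    model = fit_elm(X, c, n_hidden=60, seed=1)
    return ModelBundle(wavelengths=wl, model=model, selector_type="none", model_type="elm")


@pytest.fixture(scope="module")
def mapped_scene(linear_bundle):
    spec = SceneSpec(variety="A", stage="S2", shape=(60, 80), seed=21, sample_id="map")
    raw, white, dark, truth = generate_scene(spec)
    refl = calibrate(raw, white, dark)
    roi = remove_stalk(refl, segment_fruit(refl))
    pm = predict_map(refl, roi, linear_bundle)
    return spec, refl, roi, pm, truth


def test_map_finite_on_mask_nan_outside(mapped_scene):
    *_, pm, _ = mapped_scene
    assert np.all(np.isfinite(pm.values[pm.mask.grid]))
    assert np.all(np.isnan(pm.values[~pm.mask.grid]))


def test_map_batch_size_invariance(mapped_scene, linear_bundle):
    _, refl, roi, pm, _ = mapped_scene
    pm2 = predict_map(refl, roi, linear_bundle, batch_size=97)
    # batching changes only BLAS blocking, not results beyond float noise
    np.testing.assert_allclose(pm2.values[roi.grid], pm.values[roi.grid], atol=1e-9)


def test_uniform_fruit_maps_uniformly(linear_bundle):
    """A scene with no within-fruit heterogeneity maps to a nearly
    constant prediction (spread driven only by sensor noise)."""
    spec = SceneSpec(anthocyanin_mean=2.0, anthocyanin_cv=0.0, shape=(60, 80), seed=5)
    raw, white, dark, truth = generate_scene(spec)
    refl = calibrate(raw, white, dark)
    pm = predict_map(refl, truth.fruit_mask, linear_bundle)
    vals = pm.masked_values
    assert vals.std() / vals.mean() < 0.15


def test_map_mean_close_to_roi_mean_prediction(linear_bundle):
    """At low within-fruit heterogeneity, averaging per-pixel predictions
    approximately commutes with predicting on the ROI mean spectrum
    (small Jensen gap for a near-linear model)."""
    spec = SceneSpec(anthocyanin_mean=2.0, anthocyanin_cv=0.05, shape=(60, 80), seed=8)
    raw, white, dark, truth = generate_scene(spec)
    refl = calibrate(raw, white, dark)
    pm = predict_map(refl, truth.fruit_mask, linear_bundle)
    roi_mean = refl.values[truth.fruit_mask.grid].mean(axis=0, dtype=np.float64)
    bundle_pred = float(linear_bundle.predict(roi_mean, refl.wavelengths)[0])
    assert abs(pm.mean_content - bundle_pred) < 0.2


def test_map_tracks_truth(mapped_scene):
    *_, pm, truth = mapped_scene
    stats = map_statistics(pm, truth)
    assert stats["pixelwise_r2"] > 0.5
    assert abs(stats["mean_content_error"]) < 0.2


def test_zero_anthocyanin_scene_maps_low(linear_bundle):
    spec = SceneSpec(anthocyanin_mean=0.0, anthocyanin_cv=0.0, shape=(60, 80), seed=6)
    raw, white, dark, truth = generate_scene(spec)
    refl = calibrate(raw, white, dark)
    pm = predict_map(refl, truth.fruit_mask, linear_bundle)
    from anthomap.synthetic import STAGE_MEANS

    assert pm.mean_content < min(STAGE_MEANS.values())


def test_wavelength_mismatch_raises(linear_bundle):
    bad_wl = linear_bundle.wavelengths + 5.0  # beyond the 2 nm tolerance
    with pytest.raises(AlignmentError):
        linear_bundle.predict(np.zeros(len(bad_wl)), bad_wl)


def test_map_statistics_identities():
    grid = np.zeros((4, 4), dtype=bool)
    grid[1:3, 1:3] = True
    conc = np.zeros((4, 4))
    conc[grid] = [1.0, 2.0, 3.0, 4.0]
    truth = GroundTruth(conc, FruitMask(grid), np.zeros((4, 4), dtype=bool))
    vals = np.where(grid, conc, np.nan)
    pm = PredictionMap(vals, FruitMask(grid))
    stats = map_statistics(pm, truth)
    assert stats["pixelwise_r2"] == pytest.approx(1.0)
    assert stats["pixelwise_rmse"] == 0.0
    off = PredictionMap(np.where(grid, conc + 0.1, np.nan), FruitMask(grid))
    stats2 = map_statistics(off, truth)
    assert stats2["pixelwise_rmse"] == pytest.approx(0.1)
    assert stats2["mean_content_error"] == pytest.approx(0.1)


def test_map_statistics_empty_intersection_raises():
    grid = np.zeros((3, 3), dtype=bool)
    grid[0, 0] = True
    other = np.zeros((3, 3), dtype=bool)
    other[2, 2] = True
    truth = GroundTruth(np.zeros((3, 3)), FruitMask(other), np.zeros((3, 3), dtype=bool))
    pm = PredictionMap(np.where(grid, 1.0, np.nan), FruitMask(grid))
    with pytest.raises(ValueError):
        map_statistics(pm, truth)


def test_render_deterministic_and_pure(mapped_scene, tmp_path):
    *_, pm, _ = mapped_scene
    before = pm.values.copy()
    p1 = render_map(pm, tmp_path / "a.png", scale=(0.0, 4.5))
    p2 = render_map(pm, tmp_path / "b.png", scale=(0.0, 4.5))
    assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()
    np.testing.assert_array_equal(pm.values, before)  # data not mutated


def test_render_rejects_degenerate_scale(mapped_scene, tmp_path):
    *_, pm, _ = mapped_scene
    with pytest.raises(ValueError):
        render_map(pm, tmp_path / "c.png", scale=(2.0, 2.0))


def test_bundle_save_load_round_trip(linear_bundle, tmp_path):
    """A serialized bundle replays the identical transform chain."""
    rng = np.random.default_rng(3)
    spectra = 0.3 + 0.1 * rng.random((4, len(linear_bundle.wavelengths)))
    path = tmp_path / "bundle.h5"
    linear_bundle.save(path)
    back = ModelBundle.load(path)
    np.testing.assert_array_equal(
        back.predict(spectra, linear_bundle.wavelengths),
        linear_bundle.predict(spectra, linear_bundle.wavelengths),
    )
    assert back.selector_type == "none" and back.model_type == "elm"


def test_lssvm_bundle_round_trip(tmp_path):
    from anthomap.models import fit_lssvm
    from anthomap.sae import train_sae
    from anthomap.preprocess import snv_array
    from anthomap.synthetic import default_wavelengths

    rng = np.random.default_rng(5)
    wl = default_wavelengths()
    c = rng.uniform(0.2, 4.0, size=60)
    R = reflectance_model(wl, c, 0.4, 0.8) + 0.005 * rng.normal(size=(60, wl.size))
    X = snv_array(R)
    sae = train_sae(X, h=5, epochs=2, seed=0)
    model = fit_lssvm(sae.encode(X), c, C=10.0, gamma=5.0)
    bundle = ModelBundle(wavelengths=wl, model=model, selector_type="sae",
                         model_type="lssvm", sae_model=sae)
    path = tmp_path / "b.h5"
    bundle.save(path)
    back = ModelBundle.load(path)
    np.testing.assert_allclose(back.predict(R[:5], wl), bundle.predict(R[:5], wl), atol=1e-12)


def test_stage_ordering_under_shared_scale(linear_bundle):
    """Mean predicted content rises S1 -> S2 -> S3 for scenes rendered on
    a shared color scale."""
    means = {}
    for stage, seed in (("S1", 31), ("S2", 32), ("S3", 33)):
        spec = SceneSpec(variety="A", stage=stage, shape=(60, 80), seed=seed)
        raw, white, dark, truth = generate_scene(spec)
        refl = calibrate(raw, white, dark)
        pm = predict_map(refl, truth.fruit_mask, linear_bundle)
        means[stage] = pm.mean_content
    assert means["S1"] < means["S2"] < means["S3"]
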