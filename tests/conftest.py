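import numpy as np
import pytest

from anthomap.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 6-fruit scene at reduced image size."""
    spec = SceneSpec(variety="A", stage="S2", shape=(60, 80), seed=7, sample_id="fix")
    raw, white, dark, truth = generate_scene(spec)
    return spec, raw, white, dark, truth


@pytest.fixture(scope="session")
def spectra_fixture():
    """Spectra-like regression set: 40 reflectance rows over 12 bands with
    anthocyanin content as the response."""
    from anthomap.synthetic import reflectance_model

    rng = np.random.default_rng(11)
    wl = np.linspace(480, 1020, 12)
    c = rng.uniform(0.2, 4.0, size=40)
    X = reflectance_model(wl, c, 0.5, 0.8) + 0.005 * rng.normal(size=(40, 12))
    y = c + 0.05 * rng.normal(size=40)
    return wl, X, y
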