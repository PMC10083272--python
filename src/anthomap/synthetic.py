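"""Synthetic hyperspectral fruit scenes with known anthocyanin truth.

The real imaging study (two mulberry varieties, three maturity stages,
180 six-fruit samples) is not publicly deposited, so this module renders
statistically matched stand-ins: raw/white/dark cube triplets over a
450-1050 nm, 379-band grid in which

* fruit flesh reflectance falls with anthocyanin concentration through a
  broad absorption band centered at 535 nm (spanning roughly 500-700 nm)
  plus a shoulder that depresses the 590-800 nm region,
* immature fruit shows a narrow chlorophyll trough at 680 nm,
* water/sugar absorption dents the spectrum near 840 and 970 nm,
* green stalk tissue has strong positive R(550)-R(670) contrast,
* the background board is uniformly dark (R ~ 0.05),
* the raw image is dark current + source x illumination-gradient x
  reflectance + sensor noise, with the same gradient present in the white
  reference so that flat-field calibration cancels it.

Within-fruit concentration heterogeneity is a smooth lognormal random
field; per-sample wet-chemistry absorbance readings are back-computed
from each scene's true mean content through the inverse of the
pH-differential formula, plus measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import wetchem
from .types import FruitMask, GroundTruth, SpectralCube

VARIETIES = ("A", "B")
STAGES = ("S1", "S2", "S3")

#: Stage-mean anthocyanin content in mg/g; variety A runs higher than B at
#: every stage, and content rises with maturity. Magnitudes are in the
#: range wet chemistry reports for red-to-black mulberry.
STAGE_MEANS = {
    ("A", "S1"): 0.7, ("A", "S2"): 2.0, ("A", "S3"): 3.6,
    ("B", "S1"): 0.4, ("B", "S2"): 1.4, ("B", "S3"): 2.8,
}
#: Within-fruit coefficient of variation by stage: pigment distribution is
#: patchiest at red maturity and the patchiness stays well above the
#: sensor-noise floor at every stage, as the visible within-fruit
#: structure of real distribution maps requires.
STAGE_CV = {"S1": 0.40, "S2": 0.30, "S3": 0.25}
#: Relative chlorophyll level by stage (fades as fruit ripens).
STAGE_CHL = {"S1": 1.0, "S2": 0.4, "S3": 0.15}

#: Between-sample lognormal CV of the sample-mean content around its stage
#: mean.
SAMPLE_CV = 0.18
#: Per-band sensor noise, expressed in reflectance units.
NOISE_SD = 0.005
#: Noise on the white reference, reflectance units.
WHITE_NOISE_SD = 0.002
#: Per-reading absorbance measurement noise (absorbance units).
ABSORBANCE_NOISE_SD = 0.002
#: Sample-mass tolerance, g (balances read 0.5 +/- 0.001 g).
MASS_SD = 0.0005

BACKGROUND_REFLECTANCE = 0.05
STALK_CHL = 4.0
DEFAULT_WATER = 0.8


class GeometryError(ValueError):
    """The requested image is too small to hold the requested fruits."""


class ConfigurationError(ValueError):
    pass


def default_wavelengths(full_range: bool = False) -> np.ndarray:
    """The simulated band grid: 379 evenly spaced bands over 450-1050 nm,
    or the same spacing extended over the camera's full 305-1090 nm."""
    if not full_range:
        return np.linspace(450.0, 1050.0, 379)
    step = 600.0 / 378.0
    n = int(np.floor((1090.0 - 305.0) / step)) + 1
    return 305.0 + step * np.arange(n)


def _sat(c, rate: float = 1.0):
    """Saturating absorber amplitude in [0, 1): 1 - exp(-rate * c)."""
    return 1.0 - np.exp(-rate * np.maximum(np.asarray(c, dtype=float), 0.0))


def _gauss(wl, center, width):
    wl = np.asarray(wl, dtype=float)
    return np.exp(-(((wl - center) / width) ** 2))


def reflectance_model(wavelength, c_anth=0.0, c_chl=0.0, c_water=0.0) -> np.ndarray:
    """Flesh reflectance in [0.01, 0.99] for given absorber levels.

    Broadcasts over ``wavelength`` (nm) and over array-valued ``c_anth``:
    if both are arrays the result has shape ``c_anth.shape + wavelength.shape``.
    Strictly decreasing in ``c_anth`` throughout the visible band
    (including 600 nm, the spec point of the pigment shoulder).
    """
    wl = np.clip(np.asarray(wavelength, dtype=float), 305.0, 1090.0)
    c_anth = np.asarray(c_anth, dtype=float)
    scalar_wl = wl.ndim == 0
    scalar_c = c_anth.ndim == 0
    wl1 = np.atleast_1d(wl)
    c1 = np.atleast_1d(c_anth)[..., None]  # broadcast against bands

    baseline = 0.50 + 0.18 * (wl1 - 450.0) / 600.0
    # pigment absorption saturates slowly (rate 0.35 per mg/g) so the
    # spectrum stays sensitive to concentration across the whole
    # 0.3-4.5 mg/g study range, as the stage-separable spectra of ripe
    # fruit require
    r = (
        baseline
        - 0.50 * _sat(c1, 0.35) * _gauss(wl1, 535.0, 70.0)
        - 0.20 * _sat(c1, 0.35) * _gauss(wl1, 650.0, 90.0)
        - 0.28 * _sat(c_chl, 0.8) * _gauss(wl1, 680.0, 12.0)
        - 0.05 * _sat(c_water) * _gauss(wl1, 840.0, 30.0)
        - 0.10 * _sat(c_water) * _gauss(wl1, 970.0, 35.0)
    )
    r = np.clip(r, 0.01, 0.99)  # shape (*c_anth.shape-or-(1,), n_bands)
    if scalar_wl and scalar_c:
        return float(r[0, 0])
    if scalar_wl:
        return r[..., 0]
    if scalar_c:
        return r[0]
    return r


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic six-fruit sample scene."""

    variety: str = "A"
    stage: str = "S2"
    n_fruits: int = 6
    shape: tuple[int, int] = (120, 120)
    anthocyanin_mean: float | None = None  # mg/g; default: stage mean
    anthocyanin_cv: float | None = None  # within-fruit CV; default: stage CV
    c_chl: float | None = None
    c_water: float = DEFAULT_WATER
    noise_sd: float = NOISE_SD
    illumination_amplitude: float = 0.1
    seed: int = 0
    sample_id: str = "scene"

    def __post_init__(self) -> None:
        if self.variety not in VARIETIES:
            raise ConfigurationError(f"variety must be in {VARIETIES}")
        if self.stage not in STAGES:
            raise ConfigurationError(f"stage must be in {STAGES}")
        if self.anthocyanin_mean is not None and self.anthocyanin_mean < 0:
            raise ConfigurationError("anthocyanin_mean must be >= 0")

    @property
    def mean_content(self) -> float:
        if self.anthocyanin_mean is not None:
            return self.anthocyanin_mean
        return STAGE_MEANS[(self.variety, self.stage)]

    @property
    def cv(self) -> float:
        return self.anthocyanin_cv if self.anthocyanin_cv is not None else STAGE_CV[self.stage]

    @property
    def chl(self) -> float:
        return self.c_chl if self.c_chl is not None else STAGE_CHL[self.stage]


def _place_fruits(spec: SceneSpec, rng: np.random.Generator):
    """Ellipse flesh masks plus thin stalks on a jittered grid layout."""
    rows, cols = spec.shape
    n = spec.n_fruits
    grid_cols = int(np.ceil(np.sqrt(n)))
    grid_rows = int(np.ceil(n / grid_cols))
    cell_h, cell_w = rows / grid_rows, cols / grid_cols
    if cell_h < 24 or cell_w < 24:
        raise GeometryError(
            f"image {rows}x{cols} too small to place {n} fruits (cells {cell_h:.0f}x{cell_w:.0f})"
        )
    rr, cc = np.mgrid[0:rows, 0:cols]
    flesh = np.zeros((rows, cols), dtype=bool)
    stalk = np.zeros((rows, cols), dtype=bool)
    k = 0
    for gi in range(grid_rows):
        for gj in range(grid_cols):
            if k >= n:
                break
            cy = (gi + 0.5) * cell_h + rng.uniform(-2, 2)
            cx = (gj + 0.5) * cell_w + rng.uniform(-2, 2)
            a = rng.uniform(0.28, 0.36) * cell_h  # semi-axis, rows
            b = rng.uniform(0.28, 0.36) * cell_w
            flesh |= ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
            # stalk: a 2-px-wide spur rising from the fruit top
            top = int(cy - a)
            length = int(rng.uniform(5, 9))
            c0 = int(cx + rng.uniform(-1, 1))
            r0 = max(top - length, 0)
            stalk[r0 : max(top + 1, r0 + 1), c0 : c0 + 2] = True
            k += 1
    stalk &= ~flesh
    return flesh, stalk


def _lognormal_field(shape, mean, cv, rng, smooth_sigma=4.0):
    """Smooth lognormal field with expectation ``mean`` and pointwise CV
    ``cv`` (Gaussian-filtered white noise, standardized, exponentiated)."""
    if cv <= 0:
        return np.full(shape, mean)
    z = gaussian_filter(rng.standard_normal(shape), smooth_sigma, mode="reflect")
    z /= z.std()
    sigma = np.sqrt(np.log1p(cv**2))
    return mean * np.exp(sigma * z - 0.5 * sigma**2)


def _illumination(shape, amplitude):
    """Separable quadratic gradient, peak 1.0 at center, 1-amplitude at the
    image edges (split evenly over the two axes)."""
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2) / ((rows - 1) / 2)
    c = (np.arange(cols) - (cols - 1) / 2) / ((cols - 1) / 2)
    g = (1.0 - 0.5 * amplitude * r[:, None] ** 2) * (1.0 - 0.5 * amplitude * c[None, :] ** 2)
    return g


def _source_spectrum(wavelengths):
    """Halogen-like source x sensor response, in counts at full reflectance."""
    return 2500.0 * (0.6 + 0.4 * _gauss(wavelengths, 750.0, 300.0))


def generate_scene(
    spec: SceneSpec, wavelengths: np.ndarray | None = None
) -> tuple[SpectralCube, SpectralCube, SpectralCube, GroundTruth]:
    """Render one scene as a (raw, white, dark) triplet plus ground truth.

    Deterministic given ``spec`` (including its seed): identical calls
    return bit-identical cubes.
    """
    if wavelengths is None:
        wavelengths = default_wavelengths()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    nb = wavelengths.size

    flesh, stalk = _place_fruits(spec, rng)
    conc = np.zeros((rows, cols))
    field_vals = _lognormal_field((rows, cols), spec.mean_content, spec.cv, rng)
    conc[flesh] = field_vals[flesh]

    # true reflectance cube
    r_true = np.full((rows, cols, nb), BACKGROUND_REFLECTANCE, dtype=np.float64)
    r_true[flesh] = reflectance_model(wavelengths, conc[flesh], spec.chl, spec.c_water)
    if stalk.any():
        r_true[stalk] = reflectance_model(wavelengths, 0.0, STALK_CHL, spec.c_water)

    illum = _illumination((rows, cols), spec.illumination_amplitude)[:, :, None]
    source = _source_spectrum(wavelengths)[None, None, :]
    dark_level = 100.0

    dark_vals = dark_level + 2.0 * rng.standard_normal((rows, cols, nb))
    white_vals = (
        dark_level
        + source * illum * (1.0 + WHITE_NOISE_SD * rng.standard_normal((rows, cols, nb)))
    )
    raw_vals = (
        dark_level
        + source * illum * (r_true + spec.noise_sd * rng.standard_normal((rows, cols, nb)))
    )
    meta = {"sample_id": spec.sample_id, "variety": spec.variety, "stage": spec.stage}
    raw = SpectralCube(wavelengths, np.maximum(raw_vals, 0).astype(np.float32), "raw", dict(meta))
    white = SpectralCube(wavelengths, white_vals.astype(np.float32), "white", dict(meta))
    dark = SpectralCube(wavelengths, np.maximum(dark_vals, 0).astype(np.float32), "dark", dict(meta))
    truth = GroundTruth(concentration_map=conc, fruit_mask=FruitMask(flesh), stalk_mask=stalk)
    return raw, white, dark, truth


def _reference_row(
    spec: SceneSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
    absorbance_noise_sd: float = ABSORBANCE_NOISE_SD,
) -> dict:
    """Back-compute noisy wet-chemistry absorbances from true mean content."""
    content = truth.sample_mean_content
    mass = 0.5 + MASS_SD * rng.standard_normal()
    constants = replace(wetchem.DEFAULT_CONSTANTS, M=mass)
    a = wetchem.content_to_absorbance(content, constants)
    a700_ph1 = 0.05 + rng.uniform(0, 0.02)
    a520_ph45 = 0.12 + rng.uniform(0, 0.03)
    a700_ph45 = 0.04 + rng.uniform(0, 0.02)
    a520_ph1 = a + a700_ph1 + (a520_ph45 - a700_ph45)
    noisy = np.maximum(
        np.array([a520_ph1, a700_ph1, a520_ph45, a700_ph45])
        + absorbance_noise_sd * rng.standard_normal(4),
        0.0,
    )
    reading = wetchem.AbsorbanceReading(*noisy)
    measured = wetchem.content_from_reading(reading, constants)
    return {
        "sample_id": spec.sample_id,
        "variety": spec.variety,
        "stage": spec.stage,
        "a520_ph1": noisy[0],
        "a700_ph1": noisy[1],
        "a520_ph45": noisy[2],
        "a700_ph45": noisy[3],
        "mass_g": mass,
        "content_mg_g": measured,
        "true_content_mg_g": content,
    }


@dataclass
class Study:
    """A lazily rendered collection of scenes plus the reference table.

    Scenes are regenerated on demand from their specs (each spec carries
    its own derived seed), so a 180-scene study never holds 180 cubes in
    memory at once.
    """

    specs: list[SceneSpec]
    reference: pd.DataFrame
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)

    def __len__(self) -> int:
        return len(self.specs)

    def scene(self, i: int):
        return generate_scene(self.specs[i], self.wavelengths)

    def __iter__(self) -> Iterator:
        for i in range(len(self)):
            yield self.scene(i)


def generate_study(
    n_per_variety: int = 90,
    seed: int = 0,
    shape: tuple[int, int] = (120, 120),
    noise_sd: float = NOISE_SD,
    absorbance_noise_sd: float = ABSORBANCE_NOISE_SD,
) -> Study:
    """Design-complete synthetic study: ``2 * n_per_variety`` scenes split
    evenly over three maturity stages per variety.

    Sample-mean contents scatter lognormally (CV ~ 0.18) around the stage
    means, which rise with maturity within each variety and run higher in
    variety A than B. The reference table carries the noisy absorbance
    quadruples, sample masses, pH-differential contents computed from
    them, and the true scene means.
    """
    if n_per_variety % 3 != 0:
        raise ConfigurationError("n_per_variety must be divisible by 3 (equal stages)")
    n_per_cell = n_per_variety // 3
    root = np.random.default_rng(seed)
    specs: list[SceneSpec] = []
    rows = []
    for variety in VARIETIES:
        for stage in STAGES:
            for j in range(n_per_cell):
                sid = f"{variety}_{stage}_{j:03d}"
                scene_seed = int(root.integers(0, 2**31 - 1))
                stage_mean = STAGE_MEANS[(variety, stage)]
                sigma = np.sqrt(np.log1p(SAMPLE_CV**2))
                mean = stage_mean * np.exp(sigma * root.standard_normal() - 0.5 * sigma**2)
                spec = SceneSpec(
                    variety=variety,
                    stage=stage,
                    shape=shape,
                    anthocyanin_mean=float(mean),
                    noise_sd=noise_sd,
                    seed=scene_seed,
                    sample_id=sid,
                )
                specs.append(spec)
    # reference readings need each scene's realized truth mean; render the
    # truth cheaply by regenerating the geometry/field only
    for spec in specs:
        truth = generate_truth(spec)
        rows.append(_reference_row(spec, truth, root, absorbance_noise_sd))
    return Study(specs=specs, reference=pd.DataFrame(rows))


def generate_truth(spec: SceneSpec) -> GroundTruth:
    """Ground truth only (geometry + concentration field), skipping the
    cube rendering; draws the same leading random variates as
    :func:`generate_scene` so the truth is identical."""
    rng = np.random.default_rng(spec.seed)
    flesh, stalk = _place_fruits(spec, rng)
    conc = np.zeros(spec.shape)
    field_vals = _lognormal_field(spec.shape, spec.mean_content, spec.cv, rng)
    conc[flesh] = field_vals[flesh]
    return GroundTruth(concentration_map=conc, fruit_mask=FruitMask(flesh), stalk_mask=stalk)
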