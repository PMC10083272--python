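"""Reflectance calibration and rule-based ROI extraction.

Calibration converts raw counts to reflectance using white-panel and
dark-current reference images, R = (I - D) / (W - D) per band, which
cancels both the source's spatial intensity gradient and the sensor's
dark current. Fruit pixels are then separated from the dark background
by thresholding the near-infrared band at 800 nm (fruit tissue is
NIR-bright), and green stalk tissue is removed by the chlorophyll
contrast between 550 and 670 nm.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import FruitMask, SpectralCube, SpectralMatrix

EPS_CAL = 1e-6  # white-minus-dark floor below which a cell is undefined


def calibrate(
    raw: SpectralCube, white: SpectralCube, dark: SpectralCube, clip: tuple[float, float] = (0.0, 1.5)
) -> SpectralCube:
    """Reflectance calibration R = (I - D) / (W - D), elementwise per band.

    Cells where the white and dark references nearly coincide
    (W - D <= 1e-6) carry no radiometric information; they are set to 0
    and counted in a warning. Output is clipped to ``clip`` (specular
    highlights can exceed the white panel slightly).
    """
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise ValueError("raw, white and dark cubes must share shape")
    if not (
        np.array_equal(raw.wavelengths, white.wavelengths)
        and np.array_equal(raw.wavelengths, dark.wavelengths)
    ):
        raise ValueError("raw, white and dark cubes must share wavelengths")
    # computed in the cubes' native float precision (camera exports are
    # float32; float64 inputs stay float64)
    dt = np.result_type(raw.values.dtype, white.values.dtype, np.float32)
    denom = white.values.astype(dt, copy=False) - dark.values.astype(dt, copy=False)
    bad = denom <= EPS_CAL
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} cube cells have degenerate white-dark contrast", stacklevel=2)
    numer = raw.values.astype(dt, copy=False) - dark.values.astype(dt, copy=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(bad, 0.0, numer / np.where(bad, 1.0, denom))
    r = np.clip(r, *clip)
    return SpectralCube(wavelengths=raw.wavelengths.copy(), values=r, role="reflectance",
                        meta=dict(raw.meta))


def segment_fruit(
    refl: SpectralCube, seg_wavelength: float = 800.0, threshold: float = 0.2
) -> FruitMask:
    """Fruit/background segmentation by NIR brightness.

    A pixel is fruit iff its reflectance at the band nearest
    ``seg_wavelength`` is at least ``threshold`` — the threshold is the
    minimum reflectance of fruit tissue, the background board being much
    darker. Green stalks also pass; they are handled by
    :func:`remove_stalk`.
    """
    if refl.role != "reflectance":
        raise ValueError("segment_fruit expects a reflectance cube")
    lo, hi = refl.wavelengths[0], refl.wavelengths[-1]
    if not (lo <= seg_wavelength <= hi):
        raise ValueError(f"segmentation wavelength {seg_wavelength} outside [{lo}, {hi}] nm")
    mask = refl.band(seg_wavelength) >= threshold
    if not mask.any():
        warnings.warn("segmentation produced an empty fruit mask", stacklevel=2)
    return FruitMask(mask)


def remove_stalk(
    refl: SpectralCube,
    mask: FruitMask,
    wl_a: float = 550.0,
    wl_b: float = 670.0,
    max_diff: float = 0.04,
    absolute: bool = False,
) -> FruitMask:
    """Drop stalk pixels from a fruit mask by green-tissue contrast.

    Chlorophyll-rich stalk is bright at 550 nm and dark at 670 nm, so its
    signed difference R(550) - R(670) is large and positive, while
    anthocyanin-rich flesh is at or below zero. A pixel is retained iff
    the difference is <= ``max_diff`` (the maximum difference of retained
    tissue). ``absolute=True`` applies the rule to |R(550) - R(670)|.
    """
    lo, hi = refl.wavelengths[0], refl.wavelengths[-1]
    for wl in (wl_a, wl_b):
        if not (lo <= wl <= hi):
            raise ValueError(f"wavelength {wl} nm outside cube range [{lo}, {hi}]")
    diff = refl.band(wl_a) - refl.band(wl_b)
    if absolute:
        diff = np.abs(diff)
    return FruitMask(mask.grid & (diff <= max_diff))


def mean_spectrum(refl: SpectralCube, mask: FruitMask) -> SpectralMatrix:
    """Arithmetic mean spectrum over masked pixels (1 x p matrix)."""
    if mask.shape != refl.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if mask.n_fruit_pixels == 0:
        raise ValueError("cannot average over an empty mask")
    spectra = refl.values[mask.grid]  # (n_pixels, bands)
    # accumulate in float64 so the mean is independent of pixel order
    return SpectralMatrix(
        wavelengths=refl.wavelengths.copy(),
        values=spectra.mean(axis=0, dtype=np.float64)[None, :],
        row_ids=["roi_mean"],
    )


def sample_pixels(
    refl: SpectralCube,
    mask: FruitMask,
    n: int = 400,
    seed: int | np.random.Generator = 0,
    block: bool = False,
) -> SpectralMatrix:
    """Sample ``n`` distinct ROI pixel spectra, uniformly without
    replacement (deterministic given ``seed``).

    With fewer than ``n`` masked pixels, all of them are returned with a
    warning. ``block=True`` instead samples one contiguous
    sqrt(n) x sqrt(n) window whose masked pixels are returned.
    """
    if mask.shape != refl.shape[:2]:
        raise ValueError("mask shape does not match cube")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = np.nonzero(mask.grid)
    if rows.size == 0:
        raise ValueError("cannot sample from an empty mask")
    if block:
        side = int(np.sqrt(n))
        i = rng.integers(0, rows.size)
        r0 = min(max(rows[i] - side // 2, 0), mask.shape[0] - side)
        c0 = min(max(cols[i] - side // 2, 0), mask.shape[1] - side)
        sub = np.zeros_like(mask.grid)
        sub[r0 : r0 + side, c0 : c0 + side] = True
        sub &= mask.grid
        rows, cols = np.nonzero(sub)
        idx = np.arange(rows.size)
    elif rows.size < n:
        warnings.warn(
            f"mask has {rows.size} pixels < requested {n}; returning all", stacklevel=2
        )
        idx = np.arange(rows.size)
    else:
        idx = rng.choice(rows.size, size=n, replace=False)
        idx.sort()
    spectra = refl.values[rows[idx], cols[idx]]
    ids = [f"px_{r}_{c}" for r, c in zip(rows[idx], cols[idx])]
    return SpectralMatrix(wavelengths=refl.wavelengths.copy(), values=spectra, row_ids=ids)
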