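"""Core domain containers for hyperspectral fruit imaging.

All cubes are held in memory with axis order (row, col, band) regardless of
the on-disk interleave; wavelengths are band centers in nanometres, stored
ascending as float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Valid acquisition roles for a cube.
CUBE_ROLES = ("raw", "white", "dark", "reflectance")


@dataclass
class SpectralCube:
    """A wavelength-indexed 3-D image.

    Parameters
    ----------
    wavelengths : (bands,) float array
        Band centers in nm, strictly ascending.
    values : (rows, cols, bands) float array
        Non-negative intensities (counts for raw/white/dark, unitless
        reflectance for role ``"reflectance"``).
    role : str
        One of :data:`CUBE_ROLES`.
    meta : dict
        Free-form acquisition metadata.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    role: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.values = np.asarray(self.values)
        if self.role not in CUBE_ROLES:
            raise ValueError(f"role must be one of {CUBE_ROLES}, got {self.role!r}")
        if self.values.ndim != 3:
            raise ValueError("cube values must be (rows, cols, bands)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band dimension {self.values.shape[2]}"
            )
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            # re-sort rather than reject: files may store bands descending
            order = np.argsort(self.wavelengths, kind="stable")
            self.wavelengths = self.wavelengths[order]
            self.values = self.values[..., order]
        if self.role == "reflectance" and not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance cube must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, wavelength: float) -> int:
        """Index of the band nearest ``wavelength``; ties resolve to the
        lower wavelength."""
        d = np.abs(self.wavelengths - float(wavelength))
        # argmin returns the first (= lower-wavelength) index on ties
        return int(np.argmin(d))

    def band(self, wavelength: float) -> np.ndarray:
        """The (rows, cols) image plane at the band nearest ``wavelength``."""
        return self.values[..., self.band_index(wavelength)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCube):
            return NotImplemented
        return (
            self.role == other.role
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SpectralMatrix:
    """An n x p matrix of spectra with its wavelength vector.

    Rows are samples (mean ROI spectra) or pixels; columns are bands.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    row_ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectral matrix must not contain missing values")
        if self.row_ids is None:
            self.row_ids = list(range(self.values.shape[0]))
        elif len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def band_index(self, wavelength: float) -> int:
        d = np.abs(self.wavelengths - float(wavelength))
        return int(np.argmin(d))


@dataclass
class FruitMask:
    """Boolean pixel grid marking fruit tissue."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def n_fruit_pixels(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def __and__(self, other: "FruitMask") -> "FruitMask":
        return FruitMask(self.grid & other.grid)


@dataclass
class GroundTruth:
    """Known per-pixel anthocyanin concentration for a synthetic scene."""

    concentration_map: np.ndarray  # mg/g, 0 outside fruit
    fruit_mask: FruitMask
    stalk_mask: np.ndarray  # boolean grid, disjoint from fruit_mask

    def __post_init__(self) -> None:
        self.concentration_map = np.asarray(self.concentration_map, dtype=np.float64)
        self.stalk_mask = np.asarray(self.stalk_mask, dtype=bool)
        if np.any(self.fruit_mask.grid & self.stalk_mask):
            raise ValueError("stalk mask must be disjoint from fruit mask")

    @property
    def sample_mean_content(self) -> float:
        """Mean concentration over fruit pixels, mg/g."""
        return float(self.concentration_map[self.fruit_mask.grid].mean())


@dataclass
class PredictionMap:
    """Per-pixel predicted anthocyanin content aligned to a fruit mask."""

    values: np.ndarray  # mg/g; NaN outside mask
    mask: FruitMask
    scale: tuple[float, float] | None = None  # colormap range, mg/g

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.shape:
            raise ValueError("map shape must equal mask shape")
        on = self.values[self.mask.grid]
        if not np.all(np.isfinite(on)):
            raise ValueError("prediction map must be finite on masked pixels")

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask.grid]

    @property
    def mean_content(self) -> float:
        return float(self.masked_values.mean())
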