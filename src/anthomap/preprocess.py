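"""Spectral pretreatment: analysis-window cropping and SNV.

The raw camera range carries strong noise at both ends; analysis is
restricted to 450-1050 nm before modeling. The standard normal variate
(SNV) transform standardizes each spectrum (row) to zero mean and unit
standard deviation, correcting multiplicative scatter and path-length
effects.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import SpectralMatrix

ANALYSIS_WINDOW = (450.0, 1050.0)  # nm


class WindowError(ValueError):
    """The requested wavelength window retains no bands."""


def crop_window(
    m: SpectralMatrix, low: float = ANALYSIS_WINDOW[0], high: float = ANALYSIS_WINDOW[1]
) -> SpectralMatrix:
    """Retain bands with low <= lambda <= high (closed interval)."""
    keep = (m.wavelengths >= low) & (m.wavelengths <= high)
    if not keep.any():
        raise WindowError(f"window [{low}, {high}] nm retains no bands")
    return SpectralMatrix(
        wavelengths=m.wavelengths[keep], values=m.values[:, keep], row_ids=list(m.row_ids)
    )


def snv(m: SpectralMatrix, ddof: int = 1, sd_floor: float = 1e-12) -> SpectralMatrix:
    """Standard normal variate transform, row-wise.

    Each row is centered by its own mean and scaled by its own standard
    deviation (sample, n-1 denominator by default). Rows with spread below
    ``sd_floor`` carry no shape information and are returned as zeros with
    a warning.
    """
    if m.p < 2:
        raise ValueError("SNV requires at least 2 bands per spectrum")
    x = m.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd < sd_floor).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant spectra set to zero in SNV", stacklevel=2)
    out = np.where(flat[:, None], 0.0, (x - mu) / np.where(flat[:, None], 1.0, sd))
    return SpectralMatrix(wavelengths=m.wavelengths, values=out, row_ids=list(m.row_ids))


def snv_array(x: np.ndarray, ddof: int = 1, sd_floor: float = 1e-12) -> np.ndarray:
    """SNV on a bare (n, p) array; used on pixel batches in the mapping path."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd < sd_floor
    return np.where(flat, 0.0, (x - mu) / np.where(flat, 1.0, sd))
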