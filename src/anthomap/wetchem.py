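"""pH-differential spectrophotometric anthocyanin quantification.

Total monomeric anthocyanin is quantified as cyanidin-3-glucoside
equivalents from absorbance read at 520 and 700 nm in pH 1.0 and pH 4.5
buffers:

    A = (A520 - A700)_pH1.0 - (A520 - A700)_pH4.5
    content [mg/g] = A * MW * DF * V / (eps * l * M)

with MW = 449.2 g/mol (cyanidin-3-glucoside), dilution factor DF = 25,
extract volume V = 10 ml, molar extinction coefficient eps = 26900
l/(mol*cm), path length l = 1 cm and sample mass M in grams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AbsorbanceReading:
    """One sample's four absorbance readings (520/700 nm at pH 1.0/4.5)."""

    a520_ph1: float
    a700_ph1: float
    a520_ph45: float
    a700_ph45: float

    def __post_init__(self) -> None:
        vals = (self.a520_ph1, self.a700_ph1, self.a520_ph45, self.a700_ph45)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("absorbance readings must be finite and >= 0")


@dataclass(frozen=True)
class ChemistryConstants:
    """Assay constants; defaults are the cyanidin-3-glucoside convention."""

    MW: float = 449.2  # g/mol
    DF: float = 25.0  # dilution factor
    V: float = 10.0  # extract volume, ml
    epsilon: float = 26900.0  # molar extinction coefficient, l/(mol*cm)
    path_length: float = 1.0  # cuvette path, cm
    M: float = 0.5  # sample mass, g

    def __post_init__(self) -> None:
        for name in ("MW", "DF", "V", "epsilon", "path_length", "M"):
            if getattr(self, name) <= 0:
                raise ValueError(f"chemistry constant {name} must be > 0")


DEFAULT_CONSTANTS = ChemistryConstants()


def differential_absorbance(r: AbsorbanceReading) -> float:
    """Differential absorbance A of the pH-differential assay.

    May be negative for noisy readings near zero pigment; negative values
    are propagated (with a warning) rather than clamped so that
    measurement-noise statistics survive downstream.
    """
    a = (r.a520_ph1 - r.a700_ph1) - (r.a520_ph45 - r.a700_ph45)
    if a < 0:
        warnings.warn("negative differential absorbance", stacklevel=2)
    return a


def anthocyanin_content(A: float, c: ChemistryConstants = DEFAULT_CONSTANTS) -> float:
    """Total anthocyanin content in mg per g fresh weight.

    Linear in A; with the default constants and M = 0.5 g the multiplier
    is 449.2 * 25 * 10 / (26900 * 0.5) mg/g per absorbance unit.
    """
    if A < 0:
        warnings.warn("negative absorbance yields negative content", stacklevel=2)
    return A * c.MW * c.DF * c.V / (c.epsilon * c.path_length * c.M)


def content_to_absorbance(content: float, c: ChemistryConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse of :func:`anthocyanin_content`: the differential absorbance
    that produces ``content`` mg/g. Used by the synthetic study generator
    to back-compute reference readings."""
    return content * c.epsilon * c.path_length * c.M / (c.MW * c.DF * c.V)


def content_from_reading(
    r: AbsorbanceReading, c: ChemistryConstants = DEFAULT_CONSTANTS
) -> float:
    """Convenience composition: reading -> differential absorbance -> mg/g."""
    return anthocyanin_content(differential_absorbance(r), c)
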