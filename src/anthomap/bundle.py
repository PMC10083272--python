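"""Serializable model bundle: preprocessing chain + selector + regressor.

A bundle freezes everything needed to replay the training-time transform
chain on new spectra — the wavelength window, the SNV convention, the
selected band indices or the trained auto-encoder, and the fitted model —
so per-pixel mapping applies bit-identical preprocessing to what the
model saw in training. Stored as a single HDF5 file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .models import ElmModel, LssvmModel
from .preprocess import snv_array
from .sae import BandScaler, SaeModel

NEAREST_BAND_TOLERANCE = 2.0  # nm


class AlignmentError(ValueError):
    """Cube wavelengths cannot be matched to the bundle's training grid."""


@dataclass
class ModelBundle:
    """A trained selector + regressor with its preprocessing contract."""

    wavelengths: np.ndarray  # cropped training grid, nm
    model: ElmModel | LssvmModel
    selector_type: str = "none"  # none | spa | cars | sae
    model_type: str = "elm"  # elm | lssvm
    indices: np.ndarray | None = None  # for spa/cars
    sae_model: SaeModel | None = None  # for sae
    snv_ddof: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.selector_type in ("spa", "cars") and self.indices is None:
            raise ValueError(f"selector {self.selector_type} requires band indices")
        if self.selector_type == "sae" and self.sae_model is None:
            raise ValueError("selector sae requires a trained SaeModel")

    def align(self, cube_wavelengths: np.ndarray) -> np.ndarray:
        """Column indices in ``cube_wavelengths`` nearest to each training
        band; error if any gap exceeds the +/-2 nm tolerance. Ties in the
        nearest-band lookup resolve toward the lower wavelength."""
        cw = np.asarray(cube_wavelengths, dtype=float)
        pos = np.array([int(np.argmin(np.abs(cw - w))) for w in self.wavelengths])
        gaps = np.abs(cw[pos] - self.wavelengths)
        if gaps.max() > NEAREST_BAND_TOLERANCE:
            raise AlignmentError(
                f"wavelength mismatch: worst gap {gaps.max():.2f} nm exceeds "
                f"{NEAREST_BAND_TOLERANCE} nm"
            )
        return pos

    def features(self, spectra: np.ndarray, cube_wavelengths: np.ndarray) -> np.ndarray:
        """Replay the training chain crop -> SNV -> (subset | encode)."""
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        pos = self.align(cube_wavelengths)
        x = snv_array(spectra[:, pos], ddof=self.snv_ddof)
        if self.selector_type in ("spa", "cars"):
            return x[:, self.indices]
        if self.selector_type == "sae":
            return self.sae_model.encode(x)
        return x

    def predict(self, spectra: np.ndarray, cube_wavelengths: np.ndarray) -> np.ndarray:
        """Predicted anthocyanin content (mg/g) per spectrum row."""
        return self.model.predict(self.features(spectra, cube_wavelengths))

    # ------------------------------------------------------------- storage

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["selector_type"] = self.selector_type
            f.attrs["model_type"] = self.model_type
            f.attrs["snv_ddof"] = self.snv_ddof
            f.attrs["meta"] = json.dumps(self.meta)
            f.create_dataset("wavelengths", data=self.wavelengths)
            if self.indices is not None:
                f.create_dataset("indices", data=np.asarray(self.indices, dtype=int))
            if self.sae_model is not None:
                g = f.create_group("sae")
                for i, (W, b) in enumerate(zip(self.sae_model.weights, self.sae_model.biases)):
                    g.create_dataset(f"W{i}", data=W)
                    g.create_dataset(f"b{i}", data=b)
                g.create_dataset("scaler_mn", data=self.sae_model.scaler.mn)
                g.create_dataset("scaler_mx", data=self.sae_model.scaler.mx)
                g.attrs["scaler_lo"] = self.sae_model.scaler.lo
                g.attrs["scaler_hi"] = self.sae_model.scaler.hi
            m = f.create_group("model")
            if self.model_type == "elm":
                m.create_dataset("input_weights", data=self.model.input_weights)
                m.create_dataset("offsets", data=self.model.offsets)
                m.create_dataset("output_weights", data=self.model.output_weights)
            else:
                m.attrs["C"] = self.model.C
                m.attrs["gamma"] = self.model.gamma
                m.attrs["bias"] = self.model.bias
                m.create_dataset("support_values", data=self.model.support_values)
                m.create_dataset("X_train", data=self.model.X_train)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with h5py.File(path, "r") as f:
            selector_type = str(f.attrs["selector_type"])
            model_type = str(f.attrs["model_type"])
            indices = f["indices"][()] if "indices" in f else None
            sae_model = None
            if "sae" in f:
                g = f["sae"]
                sae_model = SaeModel(
                    weights=[g[f"W{i}"][()] for i in range(6)],
                    biases=[g[f"b{i}"][()] for i in range(6)],
                    scaler=BandScaler(
                        mn=g["scaler_mn"][()], mx=g["scaler_mx"][()],
                        lo=float(g.attrs["scaler_lo"]), hi=float(g.attrs["scaler_hi"]),
                    ),
                )
            m = f["model"]
            if model_type == "elm":
                model = ElmModel(
                    input_weights=m["input_weights"][()],
                    offsets=m["offsets"][()],
                    output_weights=m["output_weights"][()],
                )
            else:
                model = LssvmModel(
                    C=float(m.attrs["C"]), gamma=float(m.attrs["gamma"]),
                    support_values=m["support_values"][()],
                    bias=float(m.attrs["bias"]), X_train=m["X_train"][()],
                )
            return cls(
                wavelengths=f["wavelengths"][()],
                model=model,
                selector_type=selector_type,
                model_type=model_type,
                indices=indices,
                sae_model=sae_model,
                snv_ddof=int(f.attrs["snv_ddof"]),
                meta=json.loads(str(f.attrs["meta"])),
            )
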