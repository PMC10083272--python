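"""Readers and writers for hyperspectral cubes and spectral tables.

Two on-disk layouts are supported:

* **ENVI** header + binary pairs (``.hdr`` / ``.dat``), band-interleaved by
  line (BIL), little-endian float32, with the wavelength list carried in the
  header. This is the most common hyperspectral-camera export dialect.
* **HDF5** with datasets ``/values`` (rows x cols x bands) and
  ``/wavelengths`` (nm) and a root attribute ``role``.

In memory every cube is (row, col, band) with ascending wavelengths; files
stored with descending bands are re-sorted on read.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import CUBE_ROLES, FruitMask, SpectralCube, SpectralMatrix


class FormatError(ValueError):
    """A file is structurally unreadable as a hyperspectral cube."""


# ENVI type code -> numpy dtype (subset: what we write plus common reads)
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict (keys lower-cased)."""
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing magic line)")
    fields: dict[str, str] = {}
    # collapse brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> SpectralCube:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])  # cols
        lines = int(fields["lines"])  # rows
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bil").lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(w) for w in wl_text.split(",") if w.strip()])
    if wavelengths.size != bands:
        raise FormatError("wavelength list length does not match band count")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise FormatError(
            f"ENVI binary holds {raw.size} values, expected {samples * lines * bands}"
        )
    if interleave == "bil":  # (lines, bands, samples)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":  # (bands, lines, samples)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":  # (lines, samples, bands)
        cube = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    role = fields.get("anthomap role", "raw").strip()
    if role not in CUBE_ROLES:
        role = "raw"
    return SpectralCube(wavelengths=wavelengths, values=np.ascontiguousarray(cube), role=role)


def _write_envi(cube: SpectralCube, path: Path) -> Path:
    rows, cols, bands = cube.shape
    values = cube.values
    if values.dtype not in (np.float32, np.float64):
        values = values.astype(np.float32)
    code = _ENVI_CODES[np.dtype(values.dtype)]
    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    band_names = ", ".join(f"band {w:.2f} nm" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {anthomap hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"anthomap role = {cube.role}\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
        f"band names = {{{band_names}}}\n"
    )
    path.with_suffix(".hdr").write_text(header)
    # BIL: (lines, bands, samples)
    values.transpose(0, 2, 1).astype("<" + values.dtype.str[1:]).tofile(path)
    return path


def _read_hdf5(path: Path) -> SpectralCube:
    with h5py.File(path, "r") as f:
        if "wavelengths" not in f:
            raise FormatError("HDF5 cube missing /wavelengths dataset")
        if "values" not in f:
            raise FormatError("HDF5 cube missing /values dataset")
        wavelengths = f["wavelengths"][()]
        values = f["values"][()]
        role = f.attrs.get("role", "raw")
        if isinstance(role, bytes):
            role = role.decode()
    if values.ndim != 3:
        raise FormatError("HDF5 /values is not 3-D")
    return SpectralCube(wavelengths=wavelengths, values=values, role=str(role))


def _write_hdf5(cube: SpectralCube, path: Path) -> Path:
    values = cube.values
    if values.dtype not in (np.float32, np.float64):
        values = values.astype(np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values)
        f.create_dataset("wavelengths", data=cube.wavelengths)
        f.attrs["role"] = cube.role
    return path


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".dat", ".bil", ".img", ".hdr"):
        return "envi"
    raise FormatError(f"cannot infer cube format from suffix {suffix!r}")


def read_cube(path: str | os.PathLike, format: str | None = None) -> SpectralCube:
    """Read a hyperspectral cube from ENVI or HDF5.

    Bands stored in descending wavelength order are re-sorted ascending,
    with image planes permuted consistently.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "envi":
        if path.suffix == ".hdr":
            path = path.with_suffix(".dat")
        return _read_envi(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise FormatError(f"unknown format {fmt!r}")


def write_cube(cube: SpectralCube, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a cube to ENVI (``.dat`` + ``.hdr``) or HDF5; reflectance is
    stored at float32 minimum (float64 inputs are preserved)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "envi":
        return _write_envi(cube, path)
    if fmt == "hdf5":
        return _write_hdf5(cube, path)
    raise FormatError(f"unknown format {fmt!r}")


def write_matrix_csv(m: SpectralMatrix, path: str | os.PathLike) -> Path:
    """Export a spectral matrix as CSV: first column row_id, then one
    column per wavelength (nm)."""
    path = Path(path)
    df = pd.DataFrame(m.values, columns=[f"{w:.6f}" for w in m.wavelengths])
    df.insert(0, "row_id", list(m.row_ids))
    df.to_csv(path, index=False)
    return path


def read_matrix_csv(path: str | os.PathLike) -> SpectralMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "row_id":
        raise FormatError("spectral CSV must start with a row_id column")
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    return SpectralMatrix(
        wavelengths=wavelengths,
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        row_ids=df["row_id"].tolist(),
    )


def write_mask(mask: FruitMask, path: str | os.PathLike) -> Path:
    """Write a fruit mask as an 8-bit PNG (255 = fruit) or as an HDF5
    boolean dataset, by suffix."""
    from PIL import Image

    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("mask", data=mask.grid)
        return path
    img = Image.fromarray((mask.grid * np.uint8(255)))
    img.save(path)
    return path


def read_mask(path: str | os.PathLike) -> FruitMask:
    from PIL import Image

    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return FruitMask(f["mask"][()])
    return FruitMask(np.asarray(Image.open(path)) > 127)
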