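"""ENVI-style cube I/O and dark/white reflectance calibration.

The supported dialect is the plain ASCII ``key = value`` header next to a
little-endian raw binary, with ``samples``, ``lines``, ``bands``,
``interleave`` in {bsq, bil, bip}, ``data type`` (standard ENVI numeric
codes) and a ``wavelength = { ... }`` list. Reflectance calibration follows
the standard black/white correction

    R = (I_raw - I_dark) / (I_white - I_dark)

applied elementwise per band, with a guard for dead bands where the white
and dark references coincide.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np

from .types import ENVI_DTYPES, HyperCube, INTERLEAVES, WavelengthGrid

__all__ = ["read_envi", "write_envi", "calibrate_reflectance"]

_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type")


def _parse_header(text: str) -> dict:
    """Parse the ASCII header into a flat dict; braces gather into lists."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = { multi-line list }  |  key = scalar
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for key, value in pattern.findall(body):
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path) -> HyperCube:
    """Read a cube given its ``.hdr`` path; the binary sits alongside it."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise ValueError(f"header missing required key '{key}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in INTERLEAVES:
        raise ValueError(f"unknown interleave '{interleave}'")
    dtype_code = int(fields["data type"])
    if dtype_code not in ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = ENVI_DTYPES[dtype_code]

    if "wavelength" not in fields:
        raise ValueError("header missing wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(tok) for tok in wl_text.replace("\n", " ").split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but wavelength list has {wavelengths.size} entries"
        )

    bin_path = header_path.with_suffix("")  # strip .hdr
    if not bin_path.exists():
        raise FileNotFoundError(f"companion binary {bin_path} not found")
    expected = samples * lines * bands * dtype.itemsize
    actual = os.path.getsize(bin_path)
    if actual != expected:
        raise ValueError(f"binary size {actual} != expected {expected} bytes")

    flat = np.fromfile(bin_path, dtype=dtype)
    if interleave == "bsq":  # (bands, lines, samples)
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        data = flat.reshape(lines, samples, bands)
    return HyperCube(np.ascontiguousarray(data), WavelengthGrid(wavelengths),
                     interleave=interleave, dtype_code=dtype_code)


def write_envi(cube: HyperCube, path, interleave: str | None = None) -> Path:
    """Write ``path`` (binary) plus ``path + '.hdr'``; returns the header path.

    Values are stored without scaling in the cube's declared data type.
    """
    interleave = (interleave or cube.interleave).lower()
    if interleave not in INTERLEAVES:
        raise ValueError(f"interleave must be one of {INTERLEAVES}")
    if cube.data.size == 0:
        raise ValueError("refusing to write an empty cube")
    dtype = ENVI_DTYPES[cube.dtype_code]
    path = Path(path)

    if interleave == "bsq":
        ordered = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = cube.data.transpose(0, 2, 1)
    else:
        ordered = cube.data
    np.ascontiguousarray(ordered).astype(dtype).tofile(path)

    wl = ", ".join(f"{w:.6f}" for w in cube.grid.values)
    header = (
        "ENVI\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {cube.dtype_code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path = Path(str(path) + ".hdr")
    hdr_path.write_text(header)
    return hdr_path


def calibrate_reflectance(
    raw: HyperCube,
    white: HyperCube,
    dark: HyperCube,
    *,
    clamp: bool = False,
    eps_frac: float = 1e-6,
) -> HyperCube:
    """Black/white correction: ``(raw - dark) / (white - dark)`` per band.

    ``white`` and ``dark`` may be full scans or single-line references; a
    single-line reference broadcasts across the raw cube's lines. Bands where
    ``|white - dark|`` falls below ``eps_frac`` of the white dynamic range
    yield 0 there, and the count of such pixels is recorded on the result as
    ``dead_band_pixels``. Output is not clamped to [0, 1] unless ``clamp``
    (specular pixels legitimately exceed 1).
    """
    if not (raw.bands == white.bands == dark.bands):
        raise ValueError("raw, white and dark cubes must share the band count")

    def _ref(cube: HyperCube) -> np.ndarray:
        arr = np.asarray(cube.data, dtype=float)
        if arr.shape == raw.data.shape:
            return arr
        if arr.shape[0] == 1 and arr.shape[1:] == raw.data.shape[1:]:
            return arr  # broadcasts over lines
        raise ValueError(
            f"reference shape {arr.shape} incompatible with raw shape {raw.data.shape}"
        )

    w = _ref(white)
    d = _ref(dark)
    num = raw.data.astype(float) - d
    den = w - d
    eps = eps_frac * max(float(np.max(np.abs(w))), 1.0)
    dead = np.abs(den) < eps
    out = np.divide(num, den, out=np.zeros_like(num), where=~dead)
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    result = HyperCube(out, raw.grid, interleave=raw.interleave, dtype_code=5)
    result.dead_band_pixels = int(np.broadcast_to(dead, raw.data.shape).sum())
    return result
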