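"""Core data containers shared across the pipeline.

The pipeline's exchange types are deliberately small: a wavelength grid, a
hyperspectral cube (lines x samples x bands), and a flat table of per-seed
reflectance spectra with integer variety labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default VNIR range of the instrument class being emulated: 380-1018 nm
#: sampled in 320 bands (2 nm spacing).
DEFAULT_WL_START = 380.0
DEFAULT_WL_STOP = 1018.0
DEFAULT_N_BANDS = 320


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid must be a 1-D array of >= 2 bands")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Mean band spacing in nm (exact for uniform grids)."""
        return float((self.values[-1] - self.values[0]) / (self.n_bands - 1))

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(np.linspace(DEFAULT_WL_START, DEFAULT_WL_STOP, DEFAULT_N_BANDS))


# ENVI numeric data type codes <-> numpy dtypes (little-endian on disk).
ENVI_DTYPES: dict[int, np.dtype] = {
    1: np.dtype("<u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
    14: np.dtype("<i8"),
}

INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperCube:
    """A 3-D radiance or reflectance cube indexed (line, sample, band)."""

    data: np.ndarray
    grid: WavelengthGrid
    interleave: str = "bil"
    dtype_code: int = 4

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {self.grid.n_bands}"
            )
        if self.interleave not in INTERLEAVES:
            raise ValueError(f"interleave must be one of {INTERLEAVES}")
        if self.dtype_code not in ENVI_DTYPES:
            raise ValueError(f"unsupported ENVI data type code {self.dtype_code}")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class SpectrumSet:
    """N reflectance spectra (rows) on a common wavelength grid with labels.

    This is the pipeline's central exchange type: the synthetic generator
    emits one, ROI extraction produces one from a cube, the smoothers map one
    to another, and the classifiers consume (spectra, labels).
    """

    spectra: np.ndarray
    labels: np.ndarray
    grid: WavelengthGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (N, bands) matrix")
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError("row count must equal label count")
        if self.spectra.shape[1] != self.grid.n_bands:
            raise ValueError("spectrum length must equal grid.n_bands")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx: np.ndarray, provenance: str | None = None) -> "SpectrumSet":
        return SpectrumSet(
            self.spectra[idx],
            self.labels[idx],
            self.grid,
            provenance if provenance is not None else self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """First column ``label``, then one column per band named by wavelength."""
        cols = [f"{w:.1f}" for w in self.grid.values]
        frame = pd.DataFrame(self.spectra, columns=cols)
        frame.insert(0, "label", self.labels)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "SpectrumSet":
        frame = pd.read_csv(path)
        if "label" not in frame.columns:
            raise ValueError("spectrum table must have a 'label' column")
        wavelengths = np.array([float(c) for c in frame.columns if c != "label"])
        return cls(
            frame.drop(columns="label").to_numpy(dtype=float),
            frame["label"].to_numpy(dtype=int),
            WavelengthGrid(wavelengths),
            provenance=provenance or str(path),
        )
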