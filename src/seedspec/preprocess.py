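"""Spectral smoothing and derivative operators.

Four smoothers — Savitzky-Golay polynomial smoothing (SG), Gaussian filter
(GF), median filter (MF) and moving average (MA) — plus SG first and second
derivatives. All operate along the band axis with mirror padding so the
320-band length is preserved, and all are exposed both as plain functions on
1-D/2-D arrays and as a scikit-learn transformer (:class:`SpectralSmoother`)
for use in pipelines.

Defaults (SG window 11 / order 3, GF sigma 2 / window 11, MF window 5,
MA window 5) are conventional for 320-band VNIR reflectance spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter, uniform_filter1d
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .types import SpectrumSet

__all__ = [
    "PreprocessConfig",
    "sg_smooth",
    "gaussian_smooth",
    "median_smooth",
    "moving_average",
    "derivative",
    "apply",
    "SpectralSmoother",
]

METHODS = ("none", "sg", "gaussian", "median", "moving_average", "derivative1", "derivative2")


@dataclass(frozen=True)
class PreprocessConfig:
    """Which smoother/derivative to apply and its window parameters."""

    method: str = "sg"
    window: int = 11
    polyorder: int = 3
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method in ("sg", "median", "moving_average", "derivative1", "derivative2"):
            if self.window < 3 or self.window % 2 == 0:
                raise ValueError("window must be an odd integer >= 3")
        if self.method in ("sg", "derivative1", "derivative2") and self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")
        if self.method == "gaussian" and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _check_window(x: np.ndarray, window: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if x.shape[-1] < window:
        raise ValueError(f"spectrum of length {x.shape[-1]} shorter than window {window}")


def sg_smooth(spectrum: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial fits.

    Exact on polynomials of degree <= ``polyorder`` at interior bands.
    """
    x = np.asarray(spectrum, dtype=float)
    _check_window(x, window)
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    return savgol_filter(x, window, polyorder, axis=-1, mode="mirror")


def gaussian_smooth(spectrum: np.ndarray, sigma: float = 2.0, window: int = 11) -> np.ndarray:
    """Convolution with a truncated, renormalized Gaussian (weights sum to 1)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(spectrum, dtype=float)
    _check_window(x, window)
    return gaussian_filter1d(x, sigma, axis=-1, mode="mirror", radius=window // 2)


def median_smooth(spectrum: np.ndarray, window: int = 5) -> np.ndarray:
    """Sliding-window median along the band axis."""
    x = np.asarray(spectrum, dtype=float)
    _check_window(x, window)
    size = (1,) * (x.ndim - 1) + (window,)
    return median_filter(x, size=size, mode="mirror")


def moving_average(spectrum: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered boxcar mean along the band axis."""
    x = np.asarray(spectrum, dtype=float)
    _check_window(x, window)
    return uniform_filter1d(x, size=window, axis=-1, mode="mirror")


def derivative(
    spectrum: np.ndarray,
    order: int = 1,
    window: int = 11,
    polyorder: int = 3,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay derivative of the given order, scaled by band spacing.

    The derivative of the local fitted polynomial is evaluated at the window
    center; raw finite differencing of noisy reflectance is avoided.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    x = np.asarray(spectrum, dtype=float)
    _check_window(x, window)
    if polyorder >= window or polyorder < order:
        raise ValueError("need order <= polyorder < window")
    return savgol_filter(x, window, polyorder, deriv=order, delta=delta, axis=-1, mode="mirror")


def apply(config: PreprocessConfig, sset: SpectrumSet) -> SpectrumSet:
    """Row-wise application to a spectrum set; labels and grid untouched."""
    x = sset.spectra
    if config.method == "none":
        out = x.copy()
    elif config.method == "sg":
        out = sg_smooth(x, config.window, config.polyorder)
    elif config.method == "gaussian":
        out = gaussian_smooth(x, config.sigma, config.window)
    elif config.method == "median":
        out = median_smooth(x, config.window)
    elif config.method == "moving_average":
        out = moving_average(x, config.window)
    else:
        order = 1 if config.method == "derivative1" else 2
        out = derivative(x, order, config.window, config.polyorder, delta=sset.grid.spacing)
    return SpectrumSet(
        out, sset.labels.copy(), sset.grid,
        provenance=(sset.provenance + f" | {config.method}").strip(" |"),
    )


class SpectralSmoother(BaseEstimator, TransformerMixin):
    """Stateless transformer applying one of the smoothing operators row-wise.

    Parameters mirror :class:`PreprocessConfig`; fit is a no-op, so the
    transformer composes freely with scikit-learn pipelines and grid search.
    """

    def __init__(self, method: str = "sg", window: int = 11, polyorder: int = 3,
                 sigma: float = 2.0, delta: float = 1.0):
        self.method = method
        self.window = window
        self.polyorder = polyorder
        self.sigma = sigma
        self.delta = delta

    def fit(self, X, y=None):
        PreprocessConfig(self.method, self.window, self.polyorder, self.sigma)
        return self

    def transform(self, X):
        config = PreprocessConfig(self.method, self.window, self.polyorder, self.sigma)
        X = np.asarray(X, dtype=float)
        if config.method == "none":
            return X.copy()
        if config.method == "sg":
            return sg_smooth(X, config.window, config.polyorder)
        if config.method == "gaussian":
            return gaussian_smooth(X, config.sigma, config.window)
        if config.method == "median":
            return median_smooth(X, config.window)
        if config.method == "moving_average":
            return moving_average(X, config.window)
        order = 1 if config.method == "derivative1" else 2
        return derivative(X, order, config.window, config.polyorder, delta=self.delta)
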