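"""Synthetic reflectance spectra and tray cubes for seed-variety pipelines.

No public maize accession ships with this package, so every downstream module
is exercised on simulated data with the statistical structure the pipeline
assumes: 30 varieties x 90 seeds, smooth class-specific reflectance curves in
[0, 1] over 380-1018 nm, band-correlated sensor noise, per-spectrum baseline
shifts and tilts, and multiplicative scatter. A tray simulator additionally
emits raw/white/dark cubes (5x6 seed grid on a dark background) so that
reflectance calibration and ROI extraction can be tested end to end.

The class mean curves are built from a smooth monotone-ish baseline
interpolated through a handful of knots, minus a few Gaussian absorption
dips — the shape family of real seed reflectance without any claim of
biochemical realism. Between-class separation is controlled by a single
``class_scale`` knob so that benchmark difficulty is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import uniform_filter1d

from .types import HyperCube, SpectrumSet, WavelengthGrid

__all__ = [
    "VarietyModel",
    "NoiseModel",
    "TrayLayout",
    "make_varieties",
    "mean_spectrum",
    "gen_spectrum_set",
    "gen_tray_cube",
]

#: Shared baseline: a rising VNIR reflectance curve typical of dry seed coats.
_BASE_KNOTS = np.array([0.18, 0.22, 0.30, 0.42, 0.52, 0.60, 0.65, 0.67])

# Default difficulty of the benchmark.  Chosen once so that the weakest
# baseline (KNN on raw spectra) sits well below the neural models while the
# CNN family lands near, not at, ceiling.
DEFAULT_CLASS_SCALE = 0.45
DEFAULT_N_KNOTS = 8


@dataclass(frozen=True)
class VarietyModel:
    """Generative parameters of one variety's mean reflectance curve."""

    class_id: int
    baseline_knots: np.ndarray  # control values in [0, 1]
    feature_centers: np.ndarray  # absorption dip positions, nm
    feature_depths: np.ndarray  # dip magnitudes (reflectance units)
    feature_widths: np.ndarray  # dip Gaussian sigmas, nm

    def __post_init__(self) -> None:
        for name in ("baseline_knots", "feature_centers", "feature_depths", "feature_widths"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum artifact model.

    additive_sd
        Per-band sensor noise scale (reflectance units); drawn independently
        per band then smoothed with a short boxcar to mimic band-correlated
        noise, and rescaled so the marginal standard deviation stays
        ``additive_sd``.
    baseline_shift_sd
        Scale of a per-spectrum constant offset.
    slope_sd
        Scale of a per-spectrum linear tilt across the grid (value at the
        grid edges; zero at the grid center).
    scatter_sd
        Scale of the per-spectrum multiplicative scatter factor ``1 + e``.
    corr_window
        Boxcar width (bands) used to correlate the additive noise; 1 disables.
    """

    additive_sd: float = 0.010
    baseline_shift_sd: float = 0.030
    slope_sd: float = 0.015
    scatter_sd: float = 0.0875
    corr_window: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "baseline_shift_sd", "slope_sd", "scatter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 1, seed)


@dataclass(frozen=True)
class TrayLayout:
    """Rectangular seed tray: ``rows x cols`` equal rectangles on a dark field."""

    rows: int = 5
    cols: int = 6
    seed_extent_px: tuple[int, int] = (8, 8)  # (lines, samples) per seed ROI
    gap_px: int = 4
    margin_px: int = 6
    background_level: float = 0.05

    @property
    def n_seeds(self) -> int:
        return self.rows * self.cols

    def cube_shape(self) -> tuple[int, int]:
        h, w = self.seed_extent_px
        lines = 2 * self.margin_px + self.rows * h + (self.rows - 1) * self.gap_px
        samples = 2 * self.margin_px + self.cols * w + (self.cols - 1) * self.gap_px
        return lines, samples


def make_varieties(
    n_classes: int,
    rng_seed: int,
    *,
    n_knots: int = DEFAULT_N_KNOTS,
    class_scale: float = DEFAULT_CLASS_SCALE,
) -> list[VarietyModel]:
    """Draw ``n_classes`` distinct variety models, reproducibly.

    Each class perturbs the shared baseline knots and receives 2-4 Gaussian
    absorption dips; ``class_scale`` multiplies the perturbation and dip
    scales, so between-class separability is monotone in it.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    base = np.interp(
        np.linspace(0, 1, n_knots), np.linspace(0, 1, _BASE_KNOTS.size), _BASE_KNOTS
    )
    varieties: list[VarietyModel] = []
    for cid in range(1, n_classes + 1):
        knots = base + rng.normal(0.0, 0.030 * class_scale, size=n_knots)
        knots = np.clip(knots, 0.05, 0.95)
        n_dips = int(rng.integers(2, 5))
        centers = rng.uniform(430.0, 960.0, size=n_dips)
        depths = rng.uniform(0.01, 0.05, size=n_dips) * class_scale
        widths = rng.uniform(12.0, 55.0, size=n_dips)
        varieties.append(VarietyModel(cid, knots, centers, depths, widths))
    return varieties


def mean_spectrum(variety: VarietyModel, grid: WavelengthGrid | None = None) -> np.ndarray:
    """The noise-free class mean curve on ``grid``, guaranteed within [0, 1]."""
    grid = grid or WavelengthGrid.default()
    wl = grid.values
    knot_wl = np.linspace(wl[0], wl[-1], variety.baseline_knots.size)
    curve = PchipInterpolator(knot_wl, variety.baseline_knots)(wl)
    for c, d, w in zip(
        variety.feature_centers, variety.feature_depths, variety.feature_widths
    ):
        curve = curve - d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return np.clip(curve, 0.0, 1.0)


def _correlated_noise(rng: np.random.Generator, shape, sd: float, window: int) -> np.ndarray:
    """Band-correlated additive noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(shape)
    raw = rng.normal(0.0, sd, size=shape)
    if window <= 1:
        return raw
    sm = uniform_filter1d(raw, size=window, axis=-1, mode="wrap")
    # boxcar averaging shrinks the variance by ~1/window; restore the scale
    return sm * np.sqrt(window)


def gen_spectrum_set(
    varieties: list[VarietyModel],
    seeds_per_class: int,
    noise: NoiseModel | None = None,
    grid: WavelengthGrid | None = None,
) -> SpectrumSet:
    """Simulate ``len(varieties) * seeds_per_class`` labelled reflectance spectra.

    Each spectrum is ``(1 + e_scatter) * mean + shift + slope * t + noise``
    where ``t`` ramps from -1 to 1 across the grid. With all noise scales zero
    every spectrum equals its class mean exactly.
    """
    if not varieties:
        raise ValueError("variety list is empty")
    if seeds_per_class < 1:
        raise ValueError("seeds_per_class must be >= 1")
    noise = noise or NoiseModel()
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(noise.seed)
    t = np.linspace(-1.0, 1.0, grid.n_bands)

    rows, labels = [], []
    for variety in varieties:
        mu = mean_spectrum(variety, grid)
        scatter = 1.0 + rng.normal(0.0, noise.scatter_sd, size=(seeds_per_class, 1)) \
            if noise.scatter_sd > 0 else np.ones((seeds_per_class, 1))
        shift = rng.normal(0.0, noise.baseline_shift_sd, size=(seeds_per_class, 1)) \
            if noise.baseline_shift_sd > 0 else np.zeros((seeds_per_class, 1))
        slope = rng.normal(0.0, noise.slope_sd, size=(seeds_per_class, 1)) \
            if noise.slope_sd > 0 else np.zeros((seeds_per_class, 1))
        add = _correlated_noise(
            rng, (seeds_per_class, grid.n_bands), noise.additive_sd, noise.corr_window
        )
        rows.append(scatter * mu[None, :] + shift + slope * t[None, :] + add)
        labels.extend([variety.class_id] * seeds_per_class)

    return SpectrumSet(
        np.vstack(rows),
        np.array(labels),
        grid,
        provenance=f"synthetic: {len(varieties)} classes x {seeds_per_class}, {asdict(noise)}",
    )


def default_benchmark(
    rng_seed: int = 7,
    *,
    n_classes: int = 30,
    seeds_per_class: int = 90,
    class_scale: float = DEFAULT_CLASS_SCALE,
    noise: NoiseModel | None = None,
) -> SpectrumSet:
    """The standard 30-variety x 90-seed benchmark set (2,700 x 320)."""
    varieties = make_varieties(n_classes, rng_seed, class_scale=class_scale)
    if noise is None:
        noise = NoiseModel(seed=rng_seed + 1)
    return gen_spectrum_set(varieties, seeds_per_class, noise)


def _default_illumination(grid: WavelengthGrid) -> np.ndarray:
    """A smooth halogen-like source: broad bell peaking in the NIR, in counts."""
    wl = grid.values
    return 3000.0 * np.exp(-0.5 * ((wl - 850.0) / 320.0) ** 2) + 400.0


def gen_tray_cube(
    varieties: list[VarietyModel],
    layout: TrayLayout | None = None,
    noise: NoiseModel | None = None,
    grid: WavelengthGrid | None = None,
    *,
    illumination: np.ndarray | float | None = None,
    dark_current: np.ndarray | float = 100.0,
) -> tuple[HyperCube, HyperCube, HyperCube, pd.DataFrame]:
    """Simulate one tray scan plus its white and dark reference scans.

    Returns ``(raw, white, dark, truth)`` where the raw cube embeds each
    seed's spectrum, scaled by the per-band illumination and offset by the
    dark current, inside its rectangle; the white cube images a unit-
    reflectance reference panel; the dark cube is dark current alone. The
    truth table lists each rectangle's 0-based half-open pixel bounds and
    class label in row-major tray order.
    """
    layout = layout or TrayLayout()
    noise = noise or NoiseModel()
    grid = grid or WavelengthGrid.default()
    if illumination is None:
        illum = _default_illumination(grid)
    else:
        illum = np.broadcast_to(np.asarray(illumination, dtype=float), (grid.n_bands,))
    dark = np.broadcast_to(np.asarray(dark_current, dtype=float), (grid.n_bands,))

    lines, samples = layout.cube_shape()
    h, w = layout.seed_extent_px

    # reflectance scene: dark background + one flat rectangle per seed
    scene = np.full((lines, samples, grid.n_bands), layout.background_level)
    records = []
    seed_spectra = {}
    cells = layout.n_seeds
    spectra_noise = NoiseModel(
        noise.additive_sd, noise.baseline_shift_sd, noise.slope_sd,
        noise.scatter_sd, noise.corr_window, noise.seed,
    )
    draws = gen_spectrum_set(
        [varieties[i % len(varieties)] for i in range(cells)], 1, spectra_noise, grid
    )
    for i in range(cells):
        r, c = divmod(i, layout.cols)
        l0 = layout.margin_px + r * (h + layout.gap_px)
        s0 = layout.margin_px + c * (w + layout.gap_px)
        if l0 + h > lines or s0 + w > samples:
            raise ValueError("seed rectangle overflows cube bounds")
        scene[l0 : l0 + h, s0 : s0 + w, :] = draws.spectra[i]
        seed_spectra[i] = draws.spectra[i]
        records.append(
            dict(
                label=int(draws.labels[i]),
                line_start=l0,
                line_stop=l0 + h,
                sample_start=s0,
                sample_stop=s0 + w,
            )
        )

    raw = HyperCube(scene * illum + dark, grid)
    white = HyperCube(np.broadcast_to(illum * 1.0 + dark, raw.data.shape).copy(), grid)
    dark_cube = HyperCube(np.broadcast_to(dark, raw.data.shape).copy(), grid)
    truth = pd.DataFrame.from_records(records)
    return raw, white, dark_cube, truth
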