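"""Rectangular ROI definitions and mean-spectrum extraction.

Each seed contributes exactly one spectrum: the arithmetic mean over all
pixels of its rectangle, per band. Coordinates are 0-based and half-open
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import TrayLayout
from .types import HyperCube, SpectrumSet

__all__ = ["RoiRect", "extract_spectra", "grid_rois", "read_roi_tsv", "write_roi_tsv"]


@dataclass(frozen=True)
class RoiRect:
    """0-based, half-open pixel rectangle with a class label."""

    line_start: int
    line_stop: int
    sample_start: int
    sample_stop: int
    label: int

    def __post_init__(self) -> None:
        if self.line_stop <= self.line_start or self.sample_stop <= self.sample_start:
            raise ValueError("ROI rectangle is empty")
        if min(self.line_start, self.sample_start) < 0:
            raise ValueError("ROI bounds must be non-negative")

    def validate_against(self, cube: HyperCube) -> None:
        if self.line_stop > cube.lines or self.sample_stop > cube.samples:
            raise ValueError(
                f"ROI {self} exceeds cube bounds ({cube.lines} x {cube.samples})"
            )


def extract_spectra(cube: HyperCube, rois: list[RoiRect]) -> SpectrumSet:
    """One mean reflectance spectrum per ROI, labels carried through."""
    if not rois:
        raise ValueError("no ROIs supplied")
    spectra = np.empty((len(rois), cube.bands))
    labels = np.empty(len(rois), dtype=int)
    for i, roi in enumerate(rois):
        roi.validate_against(cube)
        patch = cube.data[roi.line_start : roi.line_stop, roi.sample_start : roi.sample_stop, :]
        spectra[i] = patch.mean(axis=(0, 1))
        labels[i] = roi.label
    return SpectrumSet(spectra, labels, cube.grid, provenance=f"roi mean x {len(rois)}")


def grid_rois(
    layout: TrayLayout,
    cube_shape: tuple[int, int],
    labels: list[int] | None = None,
) -> list[RoiRect]:
    """Equal-size, non-overlapping rectangles in row-major tray order.

    ``labels`` defaults to 1..n in row-major order (matching the truth table
    the tray simulator emits when each cell holds a distinct variety).
    """
    lines, samples = cube_shape[0], cube_shape[1]
    need_l, need_s = layout.cube_shape()
    if need_l > lines or need_s > samples:
        raise ValueError(f"layout needs {need_l}x{need_s} pixels, cube is {lines}x{samples}")
    if labels is None:
        labels = list(range(1, layout.n_seeds + 1))
    if len(labels) != layout.n_seeds:
        raise ValueError("need one label per tray cell")
    h, w = layout.seed_extent_px
    rois = []
    for i in range(layout.n_seeds):
        r, c = divmod(i, layout.cols)
        l0 = layout.margin_px + r * (h + layout.gap_px)
        s0 = layout.margin_px + c * (w + layout.gap_px)
        rois.append(RoiRect(l0, l0 + h, s0, s0 + w, labels[i]))
    return rois


_ROI_COLUMNS = ["label", "line_start", "line_stop", "sample_start", "sample_stop"]


def write_roi_tsv(rois: list[RoiRect], path) -> None:
    frame = pd.DataFrame(
        [[r.label, r.line_start, r.line_stop, r.sample_start, r.sample_stop] for r in rois],
        columns=_ROI_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_roi_tsv(path) -> list[RoiRect]:
    frame = pd.read_csv(Path(path), sep="\t")
    missing = set(_ROI_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"ROI table missing columns {sorted(missing)}")
    return [
        RoiRect(
            int(row.line_start), int(row.line_stop),
            int(row.sample_start), int(row.sample_stop), int(row.label),
        )
        for row in frame.itertuples()
    ]
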