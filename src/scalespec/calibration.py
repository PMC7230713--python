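"""Reflectance calibration and ground-truth scaling-rate arithmetic.

Raw hyperspectral intensities are normalised against white/dark reference
frames, region-of-interest (ROI) pixel spectra are averaged into one sample
spectrum, the overlapping short-wavelength bands are trimmed away, and the
measured scaling rate is computed from pixel areas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .datasets import ANALYSIS_HIGH_NM, ANALYSIS_LOW_NM, SpectralDataset
from .synthetic import HypercubeScene

__all__ = [
    "ScalingMeasurement",
    "RoiSpec",
    "scaling_rate",
    "correct_reflectance",
    "roi_mean_spectrum",
    "average_replicates",
    "trim_to_analysis_range",
]


@dataclass(frozen=True)
class ScalingMeasurement:
    """Measured scaling rate: scaled pixel area over region pixel area.

    ``p = 100 * p1 / p2`` percent, where ``p1`` is the scaled (skin-exposed)
    pixel area and ``p2`` the whole region's pixel area.
    """

    p1: float
    p2: float
    p: float


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular pixel block, 0-based half-open intervals."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError("ROI must be non-empty")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError("ROI indices must be non-negative")


def scaling_rate(p1: float, p2: float) -> ScalingMeasurement:
    """Ground-truth scaling rate in percent from pixel areas."""
    if p2 <= 0:
        raise ValueError("region pixel area p2 must be positive")
    if not 0 <= p1 <= p2:
        raise ValueError("scaled area p1 must lie in [0, p2]")
    return ScalingMeasurement(p1=float(p1), p2=float(p2), p=100.0 * p1 / p2)


def correct_reflectance(raw: HypercubeScene) -> np.ndarray:
    """White/dark reflectance correction, in percent.

    ``R = 100 * (I_raw - dark) / (white - dark)`` per pixel and band. The
    result is invariant to any common positive gain applied to all three
    frames.
    """
    denom = raw.white_frame - raw.dark_frame
    degenerate = np.flatnonzero(np.any(denom <= 0, axis=(0, 1)))
    if degenerate.size:
        band = int(degenerate[0])
        lam = raw.axis.values[band]
        raise ValueError(
            f"degenerate reference: white equals dark at band {band} "
            f"({lam:.1f} nm)"
        )
    return 100.0 * (raw.cube - raw.dark_frame) / denom


def roi_mean_spectrum(cube: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Per-band arithmetic mean over the ROI pixels of a reflectance cube."""
    if roi.row_end > cube.shape[0] or roi.col_end > cube.shape[1]:
        raise ValueError("ROI exceeds cube bounds")
    block = cube[roi.row_start : roi.row_end, roi.col_start : roi.col_end, :]
    return block.mean(axis=(0, 1))


def average_replicates(spectra: np.ndarray) -> np.ndarray:
    """Arithmetic mean of replicate ROI spectra (e.g. triplicate scans)."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[0] < 1:
        raise ValueError("at least one replicate is required")
    return spectra.mean(axis=0)


def trim_to_analysis_range(
    ds: SpectralDataset,
    low_nm: float = ANALYSIS_LOW_NM,
    high_nm: float = ANALYSIS_HIGH_NM,
) -> SpectralDataset:
    """Keep bands with ``low_nm <= wavelength <= high_nm``.

    On the default synthetic axis the standard [400, 1024.7] nm window keeps
    exactly 352 bands, discarding the overlapping short-wavelength region.
    """
    keep = np.flatnonzero(
        (ds.axis.values >= low_nm) & (ds.axis.values <= high_nm)
    )
    if keep.size == 0:
        raise ValueError(
            f"no bands remain in [{low_nm}, {high_nm}] nm on this axis"
        )
    return ds.select_bands(keep)
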