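"""Core spectral containers.

A :class:`WavelengthAxis` is a shared, uniformly spaced grid of band centres
in nanometres; a :class:`SpectralDataset` holds one reflectance spectrum per
sample on that grid together with the paired scaling-rate response (percent
of region area from which scales have been removed) and a body-region label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

#: Number of bands retained for analysis after trimming the short-wavelength
#: end of the default sensor range (400–1024.7 nm).
N_ANALYSIS_BANDS = 352
ANALYSIS_LOW_NM = 400.0
ANALYSIS_HIGH_NM = 1024.7

#: First retained band centre and band spacing of the default axis.
_FIRST_ANALYSIS_NM = 400.6
_DEFAULT_SPACING_NM = (ANALYSIS_HIGH_NM - _FIRST_ANALYSIS_NM) / (N_ANALYSIS_BANDS - 1)
#: Bands below 400 nm on the default axis (discarded by trimming).
_N_LEADING_BANDS = 8

_UNIFORMITY_TOL_NM = 1e-6


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing, uniformly spaced band centres in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("wavelength axis needs at least one band")
        steps = np.diff(vals)
        if np.any(steps <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if steps.size and np.ptp(steps) > _UNIFORMITY_TOL_NM:
            raise ValueError(
                f"wavelength axis must be uniformly spaced within "
                f"{_UNIFORMITY_TOL_NM} nm (observed spread {np.ptp(steps):.3g} nm)"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Band-to-band step in nm."""
        if self.values.size < 2:
            raise ValueError("spacing undefined for a single-band axis")
        return float(self.values[1] - self.values[0])

    @classmethod
    def default(cls) -> "WavelengthAxis":
        """Default Vis-NIR sensor axis.

        352 analysis bands from 400.6 to 1024.7 nm, extended downward by
        8 bands into the overlapping short-wavelength region (~386 nm) that
        the trimming step removes.
        """
        idx = np.arange(-_N_LEADING_BANDS, N_ANALYSIS_BANDS)
        return cls(_FIRST_ANALYSIS_NM + _DEFAULT_SPACING_NM * idx)

    def subset(self, indices: np.ndarray) -> "WavelengthAxis":
        return WavelengthAxis(self.values[np.asarray(indices)])


@dataclass
class SpectralDataset:
    """Sample spectra on a shared axis with paired scaling-rate responses.

    Parameters
    ----------
    axis
        Shared wavelength grid.
    spectra
        ``(n_samples, n_bands)`` reflectance matrix.
    responses
        Scaling rate of each sample, in percent of region pixel area.
    region
        Body-region label (``back``, ``belly`` or ``tail``).
    reflectance_scale
        Declared scale of ``spectra``: ``"percent"`` (0–100, the output of
        white/dark reflectance correction) or ``"fraction"`` (0–1). Pretreated
        spectra (derivatives, SNV, ...) keep the scale tag of their source.
    """

    axis: WavelengthAxis
    spectra: np.ndarray
    responses: np.ndarray
    region: str = ""
    reflectance_scale: str = "percent"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (samples x bands) matrix")
        if self.spectra.shape[1] != len(self.axis):
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} bands but axis has "
                f"{len(self.axis)}"
            )
        if self.responses.shape != (self.spectra.shape[0],):
            raise ValueError("one response per spectrum is required")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite entries")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def select_bands(self, indices: np.ndarray) -> "SpectralDataset":
        """Dataset restricted to the given band indices."""
        idx = np.asarray(indices, dtype=int)
        return dataclasses.replace(
            self, axis=self.axis.subset(idx), spectra=self.spectra[:, idx]
        )

    def select_samples(self, indices: np.ndarray) -> "SpectralDataset":
        """Dataset restricted to the given sample indices."""
        idx = np.asarray(indices, dtype=int)
        return dataclasses.replace(
            self, spectra=self.spectra[idx], responses=self.responses[idx]
        )

    def with_spectra(self, spectra: np.ndarray) -> "SpectralDataset":
        """Same samples/axis with a replaced spectra matrix (pretreatments)."""
        return dataclasses.replace(self, spectra=np.asarray(spectra, dtype=float))
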