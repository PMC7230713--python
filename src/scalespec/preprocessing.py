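"""Spectral pretreatments: SG smoothing, first derivative, MSC and SNV.

All four operate row-wise per sample spectrum; multiplicative scatter
correction (MSC) is the only dataset-level fit, regressing each spectrum on
the dataset-mean reference spectrum by ordinary least squares and inverting
the fitted affine distortion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datasets import SpectralDataset, WavelengthAxis

__all__ = [
    "MSCFit",
    "sg_smooth",
    "first_derivative",
    "msc_correct",
    "snv_transform",
    "apply_pretreatment",
    "PRETREATMENTS",
]


def sg_smooth(spectrum: np.ndarray, window: int = 7, order: int = 3) -> np.ndarray:
    """Savitzky–Golay local least-squares polynomial smoothing.

    Defaults: window of 7 points, cubic polynomial. Edges are handled by
    fitting the local polynomial to the terminal window and evaluating it at
    the boundary bands, so output length equals input length and spectra
    that are already polynomials of degree <= ``order`` pass through
    unchanged everywhere. Accepts a single spectrum or a (samples x bands)
    matrix.
    """
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if order >= window:
        raise ValueError("SG polynomial order must be smaller than the window")
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the SG window")
    return savgol_filter(x, window_length=window, polyorder=order, mode="interp", axis=-1)


def first_derivative(spectrum: np.ndarray, axis: WavelengthAxis) -> np.ndarray:
    """First derivative of reflectance with respect to wavelength.

    Central difference ``(R(w+1) - R(w-1)) / (lambda(w+1) - lambda(w-1))``
    at interior bands — exact for quadratics on a uniform axis — with
    one-sided differences at the two boundary bands so the band count is
    preserved. Units: reflectance per nm.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("first derivative needs at least 3 bands")
    if x.shape[-1] != len(axis):
        raise ValueError("spectrum band count does not match the axis")
    return np.gradient(x, axis.spacing, axis=-1)


@dataclass
class MSCFit:
    """Fitted MSC parameters: the reference spectrum and per-sample (m, b).

    Each sample is modelled as ``x_i = m_i * reference + b_i``; the corrected
    spectrum is ``(x_i - b_i) / m_i``. Correcting the reference itself is the
    identity (m=1, b=0).
    """

    reference: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray

    def apply(self, spectra: np.ndarray) -> np.ndarray:
        """Correct new spectra against the stored reference."""
        x = np.atleast_2d(np.asarray(spectra, dtype=float))
        m, b = _msc_coefficients(x, self.reference)
        return (x - b[:, None]) / m[:, None]


def _msc_coefficients(x: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref_c = reference - reference.mean()
    var = float(ref_c @ ref_c)
    if var <= 0:
        raise ValueError("degenerate MSC reference: zero variance")
    m = (x - x.mean(axis=1, keepdims=True)) @ ref_c / var
    b = x.mean(axis=1) - m * reference.mean()
    return m, b


def msc_correct(ds: SpectralDataset) -> tuple[SpectralDataset, MSCFit]:
    """Multiplicative scatter correction against the dataset-mean reference.

    Ordinary least squares of each sample spectrum on the mean spectrum gives
    the per-sample gain ``m_i`` and offset ``b_i``; inverting the affine fit
    removes multiplicative scatter and baseline shift.
    """
    if ds.n_samples < 2:
        raise ValueError("MSC needs at least 2 samples")
    reference = ds.spectra.mean(axis=0)
    m, b = _msc_coefficients(ds.spectra, reference)
    corrected = (ds.spectra - b[:, None]) / m[:, None]
    fit = MSCFit(reference=reference, slopes=m, intercepts=b)
    return ds.with_spectra(corrected), fit


def snv_transform(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and unit-SD scale each spectrum.

    Row-oriented: every spectrum ends with mean 0 and sample SD 1 (the
    ``m - 1`` denominator over its bands), which removes per-sample gain and
    offset without using any other sample.
    """
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = x.std(axis=1, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate spectrum: zero within-spectrum variance")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if squeeze else out


#: Canonical pretreatment names in table order.
PRETREATMENTS = ("SG", "FD", "MSC", "SNV")


def apply_pretreatment(ds: SpectralDataset, method: str) -> SpectralDataset:
    """Apply one named pretreatment to a whole dataset.

    ``method`` is one of ``SG``, ``FD``, ``MSC``, ``SNV`` (case-insensitive).
    MSC fits its reference on this dataset; the fit object is discarded here —
    call :func:`msc_correct` directly to keep it.
    """
    key = method.upper()
    if key == "SG":
        return ds.with_spectra(sg_smooth(ds.spectra))
    if key == "FD":
        return ds.with_spectra(first_derivative(ds.spectra, ds.axis))
    if key == "MSC":
        corrected, _ = msc_correct(ds)
        return corrected
    if key == "SNV":
        return ds.with_spectra(snv_transform(ds.spectra))
    raise ValueError(f"unknown pretreatment {method!r}; expected one of {PRETREATMENTS}")
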