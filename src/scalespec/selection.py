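"""Characteristic-wavelength (CW) selection.

Three selectors, all operating on a calibration :class:`SpectralDataset`:

* SPA — successive projections algorithm: forward chains of maximally
  orthogonal bands scored by leave-one-out multiple-linear-regression RMSE;
* RC — the largest-magnitude local extrema of the full-spectrum PLSR
  regression-coefficient vector;
* 2D-COS — auto-peaks on the diagonal of the synchronous two-dimensional
  correlation spectrum, with the scaling rate as the external perturbation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .datasets import SpectralDataset, WavelengthAxis
from .plsr import fit_plsr, select_latent_variables

__all__ = [
    "WavelengthSubset",
    "SyncSpectrum",
    "spa_select",
    "exhaustive_select",
    "rc_select",
    "synchronous_spectrum",
    "autopeak_select",
    "loo_rmse_mlr",
]


@dataclass(frozen=True)
class WavelengthSubset:
    """Ordered characteristic-wavelength indices with provenance."""

    indices: np.ndarray
    wavelengths_nm: np.ndarray
    method: str
    pretreatment: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(
            self, "wavelengths_nm", np.asarray(self.wavelengths_nm, dtype=float)
        )
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be strictly increasing and unique")

    def __len__(self) -> int:
        return self.indices.size


def _subset(axis: WavelengthAxis, indices, method: str, pretreatment: str = "") -> WavelengthSubset:
    idx = np.sort(np.asarray(indices, dtype=int))
    return WavelengthSubset(
        indices=idx,
        wavelengths_nm=axis.values[idx],
        method=method,
        pretreatment=pretreatment,
    )


def loo_rmse_mlr(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out RMSE of multiple linear regression with intercept.

    Computed from the hat matrix: the LOO residual is e_i / (1 - h_ii).
    Returns inf when a leverage reaches 1 (interpolating fit).
    """
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    pinv = np.linalg.pinv(A)
    h = np.einsum("ij,ji->i", A, pinv)
    resid = y - A @ (pinv @ y)
    denom = 1.0 - h
    if np.any(denom < 1e-10):
        return float("inf")
    return float(np.sqrt(np.mean((resid / denom) ** 2)))


def _spa_chain(Xc: np.ndarray, start: int, k_max: int, tol: float) -> list[int]:
    """Forward chain of successively most-orthogonal bands from one start.

    At each step every remaining band's column is projected onto the
    orthogonal complement of the selected bands; the band with the largest
    residual norm joins the chain. Stops early when all projections vanish
    (collinearity exhausted).
    """
    R = Xc.copy()
    chain = [start]
    selected = {start}
    for _ in range(k_max - 1):
        v = R[:, chain[-1]].copy()
        nv = np.linalg.norm(v)
        if nv <= tol:
            break
        v /= nv
        R -= np.outer(v, v @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[list(selected)] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= tol:
            break
        chain.append(nxt)
        selected.add(nxt)
    return chain


def _cv_rmse_plsr(X: np.ndarray, y: np.ndarray, folds: int = 5) -> float:
    """k-fold CV RMSE of a PLSR model at the subset's natural rank cap."""
    from .plsr import _beta_path, _nipals  # local import avoids cycle at load

    n, b = X.shape
    folds = min(folds, n)
    idx = np.arange(n)
    errs = []
    for f in range(folds):
        val = idx[f::folds]
        train = np.setdiff1d(idx, val)
        Xt, yt = X[train], y[train]
        x_mean, y_mean = Xt.mean(axis=0), yt.mean()
        cap = min(b, len(train) - 1)
        W, P, q, achieved = _nipals(Xt - x_mean, yt - y_mean, cap)
        if achieved == 0:
            return float("inf")
        beta = _beta_path(W, P, q)[-1]
        errs.append(y[val] - ((X[val] - x_mean) @ beta + y_mean))
    return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))


def spa_select(
    ds: SpectralDataset,
    k_min: int = 1,
    k_max: int | None = None,
    rmse_rtol: float = 0.01,
    scorer: str = "mlr",
) -> WavelengthSubset:
    """Successive projections algorithm with cross-validated model scoring.

    Chains of length ``k_max`` are grown from every band as a start; every
    chain prefix with ``k_min <= k`` bands is scored by internally validated
    regression RMSE — leave-one-out multiple linear regression by default
    (``scorer="mlr"``, the classical SPA companion), or k-fold CV PLSR
    (``scorer="plsr"``). The result is the best subset of the smallest size
    whose RMSE comes within ``rmse_rtol`` (relative) of the global minimum —
    the smallest wavelength count attaining the minimum RMSE.

    ``k_max`` defaults to ``min(n_samples // 3, 30, n_bands)``: the usual
    at-least-three-samples-per-MLR-variable guideline, so the size search
    covers the RMSE minimum without starving the scoring regression.
    """
    b = ds.n_bands
    if k_max is None:
        k_max = max(1, min(ds.n_samples // 3, 30, b))
    if k_min > k_max:
        raise ValueError("k_min must not exceed k_max")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if k_max > b:
        raise ValueError(f"k_max = {k_max} exceeds the {b} available bands")
    if scorer == "mlr":
        score = loo_rmse_mlr
    elif scorer == "plsr":
        score = _cv_rmse_plsr
    else:
        raise ValueError("scorer must be 'mlr' or 'plsr'")

    Xc = ds.spectra - ds.spectra.mean(axis=0)
    tol = 1e-9 * (np.linalg.norm(Xc) + 1e-30)
    y = ds.responses

    best_by_k: dict[int, tuple[float, tuple[int, ...]]] = {}
    seen: set[tuple[int, ...]] = set()
    for start in range(b):
        chain = _spa_chain(Xc, start, k_max, tol)
        for k in range(k_min, len(chain) + 1):
            key = tuple(sorted(chain[:k]))
            if key in seen:
                continue
            seen.add(key)
            rmse = score(ds.spectra[:, list(key)], y)
            if k not in best_by_k or rmse < best_by_k[k][0]:
                best_by_k[k] = (rmse, key)
    if not best_by_k:
        raise ValueError(
            "degenerate dataset: projections vanish before reaching k_min bands"
        )
    global_min = min(r for r, _ in best_by_k.values())
    if not np.isfinite(global_min):
        raise ValueError("all candidate subsets have infinite LOO-RMSE")
    for k in sorted(best_by_k):
        rmse, key = best_by_k[k]
        if rmse <= global_min * (1.0 + rmse_rtol):
            return _subset(ds.axis, key, method="SPA")
    raise AssertionError("unreachable: global minimum not found among candidates")


def exhaustive_select(
    ds: SpectralDataset,
    k_min: int = 1,
    k_max: int | None = None,
    rmse_rtol: float = 0.01,
) -> WavelengthSubset:
    """Brute-force best subset under the same LOO-RMSE criterion as SPA.

    Enumerates every band subset of size ``k_min..k_max``; only feasible for
    a handful of bands. Serves as the independent reference for SPA.
    """
    b = ds.n_bands
    k_max = b if k_max is None else min(k_max, b)
    y = ds.responses
    best_by_k: dict[int, tuple[float, tuple[int, ...]]] = {}
    for k in range(k_min, k_max + 1):
        for combo in itertools.combinations(range(b), k):
            rmse = loo_rmse_mlr(ds.spectra[:, list(combo)], y)
            if k not in best_by_k or rmse < best_by_k[k][0]:
                best_by_k[k] = (rmse, combo)
    global_min = min(r for r, _ in best_by_k.values())
    for k in sorted(best_by_k):
        rmse, key = best_by_k[k]
        if rmse <= global_min * (1.0 + rmse_rtol):
            return _subset(ds.axis, key, method="exhaustive")
    raise AssertionError("unreachable")


def _local_extrema(curve: np.ndarray) -> np.ndarray:
    """Interior indices where the curve turns (strict sign change of slope)."""
    d = np.diff(curve)
    sign = np.sign(d)
    # carry the last nonzero slope sign through plateaus
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.flatnonzero(sign[:-1] * sign[1:] < 0) + 1
    return turns


def rc_select(
    ds: SpectralDataset,
    n_keep: int = 8,
    n_latent: int | None = None,
) -> WavelengthSubset:
    """Regression-coefficient selection from a full-spectrum PLSR fit.

    Fits PLSR on all bands (component count cross-validated unless given),
    locates the local extrema — peaks and valleys — of the coefficient
    vector beta, and keeps the ``n_keep`` extrema of largest magnitude,
    returned in wavelength order. If fewer extrema exist, all are returned
    with a warning.
    """
    if n_latent is None:
        cap = min(20, ds.n_samples - 1, ds.n_bands)
        n_latent = select_latent_variables(
            ds.spectra, ds.responses, max_lv=cap, folds=min(10, ds.n_samples)
        )
    model = fit_plsr(ds.spectra, ds.responses, n_latent)
    extrema = _local_extrema(model.beta)
    if extrema.size == 0:
        # monotone beta: fall back to its largest-magnitude band
        extrema = np.array([int(np.argmax(np.abs(model.beta)))])
    if extrema.size < n_keep:
        warnings.warn(
            f"only {extrema.size} regression-coefficient extrema available "
            f"(requested {n_keep}); returning all",
            stacklevel=2,
        )
        chosen = extrema
    else:
        order = np.argsort(np.abs(model.beta[extrema]))[::-1]
        chosen = extrema[order[:n_keep]]
    return _subset(ds.axis, chosen, method="RC")


@dataclass(frozen=True)
class SyncSpectrum:
    """Synchronous 2D correlation spectrum under a scaling-rate perturbation.

    ``matrix`` is the (bands x bands) covariance of the dynamic spectra —
    symmetric and positive semidefinite; its diagonal holds the auto-peaks.
    """

    matrix: np.ndarray
    axis: WavelengthAxis
    perturbation: np.ndarray

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


def synchronous_spectrum(ds: SpectralDataset) -> SyncSpectrum:
    """Synchronous 2D-COS map with the scaling rate as perturbation.

    Samples are ordered by increasing scaling rate; dynamic spectra are the
    deviations from the perturbation-mean spectrum; the synchronous matrix is
    ``dynamic' dynamic / (m - 1)``.
    """
    if ds.n_samples < 2:
        raise ValueError("2D-COS needs at least 2 samples")
    if np.ptp(ds.responses) <= 0:
        raise ValueError("all scaling rates identical: no perturbation to correlate")
    order = np.argsort(ds.responses, kind="stable")
    dyn = ds.spectra[order] - ds.spectra[order].mean(axis=0)
    m = ds.n_samples
    matrix = dyn.T @ dyn / (m - 1)
    return SyncSpectrum(matrix=matrix, axis=ds.axis, perturbation=ds.responses[order])


def autopeak_select(
    sync: SyncSpectrum,
    max_peaks: int = 8,
    prominence_frac: float = 0.05,
) -> WavelengthSubset:
    """CWs at the auto-peaks of the synchronous spectrum's diagonal.

    Local maxima of the diagonal with prominence above ``prominence_frac``
    of the diagonal maximum, tallest first, capped at ``max_peaks``; boundary
    bands count as peaks when they dominate their neighbour. A flat diagonal
    yields an empty subset with a warning.
    """
    d = sync.diagonal.copy()
    top = float(d.max(initial=0.0))
    if top <= 0 or np.ptp(d) <= 1e-12 * max(top, 1.0):
        warnings.warn("flat synchronous diagonal: no auto-peaks found", stacklevel=2)
        return _subset(sync.axis, [], method="2D-COS")
    # pad below the minimum so boundary maxima are detectable with a
    # well-defined prominence
    pad = d.min() - 0.1 * np.ptp(d)
    padded = np.concatenate([[pad], d, [pad]])
    peaks, props = find_peaks(padded, prominence=prominence_frac * top)
    peaks = peaks - 1
    if peaks.size == 0:
        warnings.warn("no auto-peak exceeds the prominence threshold", stacklevel=2)
        return _subset(sync.axis, [], method="2D-COS")
    order = np.argsort(d[peaks])[::-1]
    chosen = peaks[order[:max_peaks]]
    return _subset(sync.axis, chosen, method="2D-COS")
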