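"""Partial least squares regression for scaling-rate calibration.

Single-response PLSR fitted by NIPALS on mean-centred data (no unit-variance
scaling of the bands — the pretreatments already condition the spectra).
Includes the rank-ordered calibration/prediction split and cross-validated
latent-variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpectralDataset

__all__ = [
    "SplitSpec",
    "PLSRModel",
    "RankDeficiencyError",
    "split_dataset",
    "fit_plsr",
    "select_latent_variables",
    "predict",
]

_EPS = 1e-12


class RankDeficiencyError(ValueError):
    """Requested more latent variables than the data's effective rank."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"rank deficiency: requested {requested} latent variables but at "
            f"most {achievable} are achievable"
        )


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint calibration/prediction sample indices covering a dataset."""

    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    seed: int
    strategy: str


def split_dataset(
    ds: SpectralDataset,
    n_cal: int = 60,
    n_pred: int = 40,
    strategy: str = "rank",
    seed: int = 0,
) -> SplitSpec:
    """Split samples into calibration and prediction sets (default 60/40).

    ``rank`` (default): sort samples by response and assign systematically
    spaced ranks to the prediction set, so both sets span the full
    scaling-rate range. ``random``: seeded permutation.
    """
    n = ds.n_samples
    if n_cal + n_pred != n:
        raise ValueError(
            f"n_cal + n_pred = {n_cal + n_pred} does not match {n} samples"
        )
    if n_cal < 1 or n_pred < 1:
        raise ValueError("both sets must be non-empty")
    if strategy == "rank":
        order = np.argsort(ds.responses, kind="stable")
        pred_pos = np.floor((np.arange(n_pred) + 0.5) * n / n_pred).astype(int)
        pred = np.sort(order[pred_pos])
        cal = np.sort(np.setdiff1d(np.arange(n), pred))
    elif strategy == "random":
        perm = np.random.default_rng(seed).permutation(n)
        cal = np.sort(perm[:n_cal])
        pred = np.sort(perm[n_cal:])
    else:
        raise ValueError(f"unknown split strategy {strategy!r}")
    return SplitSpec(
        calibration_indices=cal, prediction_indices=pred, seed=seed, strategy=strategy
    )


@dataclass
class PLSRModel:
    """Fitted PLSR: latent decomposition plus the collapsed (beta, intercept).

    ``weights`` (W), ``x_loadings`` (P) are (bands x k); ``y_loadings`` (q)
    has one entry per component. Prediction via the latent scores and via
    ``X @ beta + intercept`` agree to numerical precision.
    """

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    beta: np.ndarray
    intercept: float

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)


def _nipals(X: np.ndarray, y: np.ndarray, n_latent: int):
    """Return (W, P, q, achieved) from NIPALS deflation on centred data."""
    n, b = X.shape
    W = np.zeros((b, n_latent))
    P = np.zeros((b, n_latent))
    q = np.zeros(n_latent)
    Xr = X.copy()
    yr = y.copy()
    x_scale = np.linalg.norm(X) + _EPS
    for a in range(n_latent):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= _EPS * x_scale * (np.linalg.norm(yr) + _EPS):
            return W[:, :a], P[:, :a], q[:a], a
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= (_EPS * x_scale) ** 2:
            return W[:, :a], P[:, :a], q[:a], a
        p = Xr.T @ t / tt
        qa = float(yr @ t) / tt
        Xr -= np.outer(t, p)
        yr = yr - qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
    return W, P, q, n_latent


def _beta_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression-coefficient vectors for every component count 1..k.

    Returns a (k, bands) array; row ``a-1`` is the beta of the ``a``-component
    model. Uses beta_k = W_k (P_k' W_k)^-1 q_k, solved incrementally on the
    upper-triangular P'W.
    """
    k = q.size
    betas = np.zeros((k, W.shape[0]))
    R = P.T @ W  # upper triangular with unit-ish diagonal
    for a in range(1, k + 1):
        c = np.linalg.solve(R[:a, :a], q[:a])
        betas[a - 1] = W[:, :a] @ c
    return betas


def fit_plsr(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSRModel:
    """Fit single-response PLSR with ``n_latent`` components by NIPALS.

    Successive score vectors are mutually orthogonal; at full rank the
    collapsed coefficient vector coincides with the least-squares solution.
    Raises :class:`RankDeficiencyError` when the data cannot support the
    requested number of components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, b = X.shape
    if y.shape != (n,):
        raise ValueError("y must have one entry per row of X")
    if n_latent < 1 or n_latent > min(n - 1, b):
        raise ValueError(
            f"n_latent must lie in [1, min(n_samples-1, n_bands)] = "
            f"[1, {min(n - 1, b)}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, achieved = _nipals(X - x_mean, y - y_mean, n_latent)
    if achieved < n_latent:
        raise RankDeficiencyError(n_latent, achieved)
    beta = _beta_path(W, P, q)[-1]
    intercept = y_mean - float(x_mean @ beta)
    return PLSRModel(
        n_latent=n_latent,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        beta=beta,
        intercept=intercept,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted scaling rates: ``X_new @ beta + intercept``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.beta.size:
        raise ValueError(
            f"band mismatch: model expects {model.beta.size} bands, "
            f"got {X_new.shape[1]}"
        )
    return X_new @ model.beta + model.intercept


def select_latent_variables(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Choose the component count by k-fold cross-validated RMSE.

    Returns the smallest count whose CV-RMSE is within one standard error
    (across folds, at the minimising count) of the minimum — the usual
    parsimony rule, so noise alone never buys extra components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, b = X.shape
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    max_lv = min(max_lv, b)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)

    fold_rmse = np.full((folds, max_lv), np.nan)
    for f, val_idx in enumerate(fold_ids):
        train_idx = np.setdiff1d(perm, val_idx)
        Xt, yt = X[train_idx], y[train_idx]
        cap = min(max_lv, len(train_idx) - 1, b)
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        W, P, q, achieved = _nipals(Xt - x_mean, yt - y_mean, cap)
        betas = _beta_path(W, P, q)
        Xv_c = X[val_idx] - x_mean
        for a in range(max_lv):
            beta = betas[min(a, achieved - 1)] if achieved else np.zeros(b)
            resid = y[val_idx] - (Xv_c @ beta + y_mean)
            fold_rmse[f, a] = np.sqrt(np.mean(resid**2))

    cv_rmse = fold_rmse.mean(axis=0)
    best = int(np.argmin(cv_rmse))
    se = fold_rmse[:, best].std(ddof=1) / np.sqrt(folds)
    within = np.flatnonzero(cv_rmse <= cv_rmse[best] + se)
    return int(within[0]) + 1
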