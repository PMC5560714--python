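"""Regression models and diagnostics: MLR on selected bands, full-spectrum
PLSR (NIPALS, mean-centered) with leave-one-out factor selection, variable
importance in projection (VIP), folded-back B-coefficients, and per-band
correlation curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MlrModel",
    "PlsrModel",
    "CorrelationCurve",
    "fit_mlr",
    "fit_plsr",
    "loo_select_factors",
    "vip_scores",
    "correlation_curve",
]


# ---------------------------------------------------------------------------
# multiple linear regression


@dataclass
class MlrModel:
    """Ordinary least squares on a small set of selected bands."""

    coefficients: np.ndarray
    intercept: float
    band_indices: list[int] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "model": "mlr",
            "coefficients": np.asarray(self.coefficients).tolist(),
            "intercept": float(self.intercept),
            "band_indices": self.band_indices,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MlrModel":
        return cls(
            np.asarray(d["coefficients"], float), float(d["intercept"]),
            d.get("band_indices"),
        )


def fit_mlr(X: np.ndarray, y: np.ndarray, band_indices=None) -> MlrModel:
    """OLS fit of y on X plus intercept.

    Requires more samples than predictors and a full-column-rank design;
    a rank-deficient design (duplicate or constant bands) is an error rather
    than a silently regularised fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x bands)")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match the number of samples")
    if n <= p + 1:
        raise ValueError(f"need more samples ({n}) than bands + 1 ({p + 1})")
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        raise ValueError("rank-deficient design (duplicate or constant bands)")
    return MlrModel(coefficients=coef[1:], intercept=float(coef[0]),
                    band_indices=list(band_indices) if band_indices is not None else None)


# ---------------------------------------------------------------------------
# PLSR (NIPALS, univariate response)


@dataclass
class PlsrModel:
    """Mean-centered NIPALS decomposition for a univariate response.

    weights W (p x A), x_loadings P (p x A), y_loadings q (A,), scores T
    (n x A); ``b_coefficients`` fold the factors back into one coefficient
    per band, so that ``yhat = intercept + X @ b``.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    b_coefficients: np.ndarray
    intercept: float
    rmsecv_curve: dict[int, float] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.b_coefficients

    def to_dict(self) -> dict:
        return {
            "model": "plsr",
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": np.asarray(self.y_loadings).tolist(),
            "b_coefficients": self.b_coefficients.tolist(),
            "intercept": float(self.intercept),
            "rmsecv_curve": (
                None
                if self.rmsecv_curve is None
                else {str(k): float(v) for k, v in self.rmsecv_curve.items()}
            ),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_factors: int, tol: float = 1e-12,
            allow_early_stop: bool = False):
    """One NIPALS pass on centered data; returns W, P, q, T (truncated to
    the achieved number of factors when ``allow_early_stop``).

    For a univariate response each factor has the closed form
    w = X'y / ||X'y||, t = Xw, p = X't / t't, q = y't / t't, followed by
    deflation X <- X - t p', y <- y - t q.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    T = np.zeros((n, n_factors))
    X = Xc.copy()
    y = yc.copy()
    achieved = 0
    for a in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= tol:
            if allow_early_stop:
                break
            raise ValueError(
                f"X carries no further covariance with y at factor {a + 1}; "
                f"reduce n_factors"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= tol:
            if allow_early_stop:
                break
            raise ValueError(f"degenerate score vector at factor {a + 1}")
        p_a = X.T @ t / tt
        q_a = float(y @ t / tt)
        X -= np.outer(t, p_a)
        y -= t * q_a
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        achieved = a + 1
    return W[:, :achieved], P[:, :achieved], q[:achieved], T[:, :achieved]


def fit_plsr(X: np.ndarray, y: np.ndarray, n_factors: int) -> PlsrModel:
    """Fit a PLSR model with ``n_factors`` latent factors (NIPALS)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match the number of samples")
    if not (1 <= n_factors <= min(n - 1, p)):
        raise ValueError(
            f"n_factors must be in [1, min(samples - 1, bands)] = [1, {min(n - 1, p)}]"
        )
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X - x_mean, y - y_mean, n_factors)
    b = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ b)
    return PlsrModel(
        n_factors=n_factors, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, scores=T,
        b_coefficients=b, intercept=intercept,
    )


def _plsr_path_predict(
    X_train: np.ndarray, y_train: np.ndarray, x_new: np.ndarray, max_factors: int
) -> np.ndarray:
    """Predictions for one held-out sample at every factor count 1..A_max.

    Runs NIPALS on the training fold and pushes the new sample through the
    factor sequence (t_a = x'w_a, deflate x by t_a p_a), accumulating
    yhat_A = y_mean + sum_{a<=A} t_a q_a.  If the covariance is exhausted
    before ``max_factors`` (rank-deficient fold), the prediction curve is
    flat beyond the achieved rank: extra factors contribute nothing.
    """
    x_mean = X_train.mean(axis=0)
    y_mean = float(y_train.mean())
    W, P, q, _ = _nipals(X_train - x_mean, y_train - y_mean, max_factors,
                         allow_early_stop=True)
    achieved = q.size
    xc = x_new - x_mean
    preds = np.empty(max_factors)
    acc = y_mean
    for a in range(max_factors):
        if a < achieved:
            t_a = float(xc @ W[:, a])
            acc += t_a * q[a]
            xc = xc - t_a * P[:, a]
        preds[a] = acc
    return preds


def loo_select_factors(
    X: np.ndarray, y: np.ndarray, max_factors: int
) -> tuple[int, dict[int, float]]:
    """Leave-one-out RMSECV over factor counts 1..max_factors.

    Each fold refits the PLSR decomposition without the held-out sample.
    Returns the factor count with the smallest RMSECV (smallest count on
    ties) and the full curve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not (1 <= max_factors <= min(n - 2, p)):
        raise ValueError(
            f"max_factors must be in [1, min(samples - 2, bands)] = [1, {min(n - 2, p)}]"
        )
    errors = np.empty((n, max_factors))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        preds = _plsr_path_predict(X[mask], y[mask], X[i], max_factors)
        errors[i] = y[i] - preds
    rmsecv = np.sqrt(np.mean(errors**2, axis=0))
    chosen = int(np.argmin(rmsecv)) + 1  # argmin returns the first (lowest A) tie
    curve = {a + 1: float(rmsecv[a]) for a in range(max_factors)}
    return chosen, curve


def vip_scores(model: PlsrModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ) with
    SS_a = q_a^2 t_a't_a, the response variance captured by factor a.  The
    mean squared VIP equals 1 by construction; the conventional screening
    threshold is VIP > 0.8.
    """
    W, q, T = model.weights, np.asarray(model.y_loadings), model.scores
    p, A = W.shape
    ss = q**2 * np.einsum("ia,ia->a", T, T)
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    wnorm2 = np.einsum("ja,ja->a", W, W)
    contrib = (W**2 / wnorm2) @ ss
    return np.sqrt(p * contrib / total)


# ---------------------------------------------------------------------------
# correlation analysis


@dataclass
class CorrelationCurve:
    """Per-band Pearson correlation with the response.

    ``r`` holds NaN for degenerate zero-variance bands (also listed in
    ``degenerate_bands``); ``extrema_indices`` are bands where |r| attains a
    local maximum over the configured neighbourhood.
    """

    r: np.ndarray
    wavelengths: np.ndarray | None = None
    degenerate_bands: list[int] = field(default_factory=list)
    extrema_indices: list[int] = field(default_factory=list)

    @property
    def max_abs_r(self) -> float:
        return float(np.nanmax(np.abs(self.r)))

    def to_frame(self) -> pd.DataFrame:
        wl = self.wavelengths if self.wavelengths is not None else np.arange(self.r.size)
        return pd.DataFrame(
            {"wavelength_nm": wl, "r": self.r,
             "is_extremum": np.isin(np.arange(self.r.size), self.extrema_indices)}
        )


def correlation_curve(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray | None = None,
    neighborhood: int = 5,
) -> CorrelationCurve:
    """Pearson product-moment correlation of every band with y.

    Zero-variance bands get r = NaN and are flagged; a zero-variance y is
    an error.  Local extrema of |r| are located over a +/- ``neighborhood``
    band window.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation analysis")
    if y.shape != (n,):
        raise ValueError("y length must match the number of samples")
    yc = y - y.mean()
    sy = np.linalg.norm(yc)
    if sy == 0:
        raise ValueError("y has zero variance")
    Xc = X - X.mean(axis=0)
    sx = np.linalg.norm(Xc, axis=0)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0) * np.sqrt(n)
    degenerate = np.flatnonzero(sx <= 1e-12 * scale)
    sx_safe = np.where(sx == 0, 1.0, sx)
    r = (Xc.T @ yc) / (sx_safe * sy)
    r[degenerate] = np.nan

    extrema = _local_abs_maxima(r, neighborhood)
    return CorrelationCurve(
        r=r,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        degenerate_bands=degenerate.tolist(),
        extrema_indices=extrema,
    )


def _local_abs_maxima(r: np.ndarray, neighborhood: int) -> list[int]:
    a = np.abs(r)
    out = []
    p = a.size
    for j in range(p):
        lo, hi = max(0, j - neighborhood), min(p, j + neighborhood + 1)
        window = a[lo:hi]
        if np.all(np.isnan(window)) or np.isnan(a[j]):
            continue
        if a[j] == np.nanmax(window) and np.nanargmax(window) + lo == j:
            out.append(j)
    return out
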