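"""Successive projections algorithm (SPA) for wavelength selection.

SPA grows a chain of spectral bands by repeatedly choosing the band whose
(mean-centered) column has the largest component orthogonal to the span of
the bands already selected, which yields subsets of minimally collinear
variables.  Candidate subsets (every start band, every chain prefix in a
size range) are then scored by the validation RMSE of a multiple linear
regression fit on the calibration set, and the best (start, size) pair is
returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import fit_mlr

__all__ = ["SpaResult", "spa_chain", "spa_select", "write_band_table"]


class DegenerateBandError(ValueError):
    """A candidate column has (numerically) zero residual norm, i.e. it is
    linearly dependent on the already-selected bands."""


@dataclass
class SpaResult:
    """Outcome of an SPA selection run."""

    selected_indices: list[int]
    selected_wavelengths_nm: np.ndarray | None
    n_selected: int
    rmse_by_size: dict[int, float]
    start_index_chosen: int
    validation_rmse: float

    def __post_init__(self) -> None:
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected band indices must be unique")
        if self.n_selected != len(self.selected_indices):
            raise ValueError("n_selected inconsistent with index list")
        if not self.rmse_by_size:
            raise ValueError("rmse_by_size must not be empty")


def spa_chain(
    X: np.ndarray,
    start_index: int,
    chain_length: int,
    *,
    rtol: float = 1e-10,
) -> list[int]:
    """Grow one projection chain from ``start_index``.

    ``X`` is the (already centered) calibration matrix, samples x bands.
    At each step every remaining column is deflated against the
    last-selected (deflated) column,

        x_j <- x_j - (x_j . x_k / x_k . x_k) x_k,

    and the column with the largest residual Euclidean norm is appended
    (exact ties broken by lowest band index).  Sequential deflation against
    the orthogonalised chain is equivalent to projecting out the span of all
    selected columns.
    """
    X = np.array(X, dtype=float)
    n, p = X.shape
    if not (0 <= start_index < p):
        raise IndexError(f"start_index {start_index} out of range for {p} bands")
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    if chain_length > min(n - 1, p):
        raise ValueError(
            f"chain_length {chain_length} exceeds the rank bound "
            f"min(samples - 1, bands) = {min(n - 1, p)}"
        )
    scale = float(np.max(np.einsum("ij,ij->j", X, X)))
    if scale <= 0:
        raise DegenerateBandError("all columns are zero")
    tol = rtol * scale

    selected = [int(start_index)]
    for _ in range(chain_length - 1):
        xk = X[:, selected[-1]]
        nk2 = float(xk @ xk)
        if nk2 <= tol:
            raise DegenerateBandError(
                f"band {selected[-1]} is linearly dependent on the selected set"
            )
        X = X - np.outer(xk, (X.T @ xk) / nk2)
        norms = np.einsum("ij,ij->j", X, X)
        norms[selected] = -np.inf
        j = int(np.argmax(norms))
        if norms[j] <= tol:
            raise DegenerateBandError(
                "no remaining band has a non-zero component orthogonal to the "
                "selected set (degenerate/duplicate bands)"
            )
        selected.append(j)
    return selected


def _chains_all_starts(Xc: np.ndarray, chain_length: int, starts: np.ndarray):
    for s in starts:
        yield int(s), spa_chain(Xc, int(s), chain_length)


def spa_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    m_min: int,
    m_max: int,
    *,
    wavelengths: np.ndarray | None = None,
    starts: np.ndarray | None = None,
) -> SpaResult:
    """Select the band subset minimising validation RMSE of an MLR model.

    For every start band and every subset size ``m`` in ``[m_min, m_max]``,
    an MLR model is fit on the calibration samples restricted to the first
    ``m`` bands of the start's projection chain and scored by RMSE on the
    validation samples.  Returns the best (start, m) combination; on ties,
    the smaller size, then the smaller start index.  ``rmse_by_size`` holds
    the best validation RMSE attained at each size.

    Columns are mean-centered (calibration means) before the projection
    phase; the MLR itself is fit on the raw reflectance with an intercept.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    n, p = X_cal.shape
    if X_val.shape[1] != p:
        raise ValueError("calibration and validation sets must share the band grid")
    if y_val.size == 0:
        raise ValueError("validation set is empty")
    if not (1 <= m_min <= m_max):
        raise ValueError("require 1 <= m_min <= m_max")
    if m_max > min(n - 1, p):
        raise ValueError("m_max exceeds the rank bound min(samples - 1, bands)")

    Xc = X_cal - X_cal.mean(axis=0)
    if starts is None:
        starts = np.arange(p)

    sizes = range(m_min, m_max + 1)
    rmse_by_size: dict[int, float] = {m: np.inf for m in sizes}
    best = (np.inf, m_max + 1, p, None)  # (rmse, m, start, chain_prefix)

    for s, chain in _chains_all_starts(Xc, m_max, starts):
        for m in sizes:
            idx = chain[:m]
            model = fit_mlr(X_cal[:, idx], y_cal)
            resid = y_val - model.predict(X_val[:, idx])
            rmse = float(np.sqrt(np.mean(resid**2)))
            if rmse < rmse_by_size[m]:
                rmse_by_size[m] = rmse
            key = (rmse, m, s)
            if key < best[:3]:
                best = (rmse, m, s, idx)

    rmse_best, m_best, start_best, idx_best = best
    if idx_best is None:
        raise RuntimeError("no SPA candidate could be scored")
    return SpaResult(
        selected_indices=list(idx_best),
        selected_wavelengths_nm=(
            None if wavelengths is None else np.asarray(wavelengths, float)[idx_best]
        ),
        n_selected=m_best,
        rmse_by_size=dict(rmse_by_size),
        start_index_chosen=start_best,
        validation_rmse=rmse_best,
    )


def write_band_table(results: dict[str, SpaResult], path) -> pd.DataFrame:
    """Write the selected-wavelength table: field_type,rank,band_index,wavelength_nm."""
    rows = []
    for field_type, res in results.items():
        for rank, idx in enumerate(res.selected_indices, start=1):
            wl = (
                float(res.selected_wavelengths_nm[rank - 1])
                if res.selected_wavelengths_nm is not None
                else float("nan")
            )
            rows.append(
                {"field_type": field_type, "rank": rank,
                 "band_index": idx, "wavelength_nm": wl}
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
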