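"""Shared fixtures: wavelength grids, endmember libraries, and small
simulated populations used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from speclai import build_endmembers, make_wavelength_grid


@pytest.fixture(scope="session")
def grid_400_1400():
    return make_wavelength_grid(400, 1400, 1)


@pytest.fixture(scope="session")
def endmembers(grid_400_1400):
    return build_endmembers(grid_400_1400)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def brute_force_spa_chain(X: np.ndarray, start: int, length: int) -> list[int]:
    """Reference SPA chain: at each step, explicitly orthogonalise every
    candidate column against the full selected set with dense least squares
    and pick the largest residual norm (lowest index on ties)."""
    X = np.asarray(X, dtype=float)
    selected = [start]
    for _ in range(length - 1):
        S = X[:, selected]
        best_j, best_norm = None, -1.0
        for j in range(X.shape[1]):
            if j in selected:
                continue
            beta, *_ = np.linalg.lstsq(S, X[:, j], rcond=None)
            resid = X[:, j] - S @ beta
            norm = float(resid @ resid)
            if norm > best_norm + 0.0:
                best_j, best_norm = j, norm
        selected.append(best_j)
    return selected
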