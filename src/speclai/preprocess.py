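"""Spectral preprocessing: replicate averaging, Savitzky-Golay smoothing,
band-range subsetting, and optional regridding of variable-interval exports.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .spectra import ReplicateSpectra, SpectraSet

__all__ = [
    "average_replicates",
    "savgol_smooth",
    "subset_band_range",
    "regrid_linear",
]

#: default smoothing window (points).  Field protocols often quote an
#: "8-point" smooth; a Savitzky-Golay window must be odd, so the nearest odd
#: width, 9, is used.
DEFAULT_WINDOW = 9
DEFAULT_POLYORDER = 2


def average_replicates(replicates: ReplicateSpectra) -> SpectraSet:
    """Per-band arithmetic mean over replicate scans, one row per sample."""
    mean = replicates.reflectance.mean(axis=1)
    return SpectraSet(replicates.wavelengths.copy(), mean, replicates.metadata.copy())


def savgol_smooth(
    spectra: SpectraSet,
    window_points: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> SpectraSet:
    """Savitzky-Golay least-squares polynomial smoothing along wavelength.

    Interior points are the central value of a local degree-``polyorder``
    least-squares fit over ``window_points`` neighbours; edges are handled by
    fitting the polynomial to the one-sided window of the first/last
    ``window_points`` samples (no values are invented beyond the signal).
    The filter is linear and reproduces polynomials of degree
    <= ``polyorder`` exactly.
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if polyorder >= window_points:
        raise ValueError("polyorder must be smaller than window_points")
    if window_points > spectra.n_bands:
        raise ValueError("window_points exceeds the number of bands")
    smoothed = savgol_filter(
        spectra.reflectance, window_points, polyorder, axis=1, mode="interp"
    )
    # smoothing can produce tiny negative overshoots on near-zero signal
    smoothed = np.clip(smoothed, 0.0, None)
    return SpectraSet(spectra.wavelengths.copy(), smoothed, spectra.metadata.copy())


def subset_band_range(spectra: SpectraSet, low_nm: float, high_nm: float) -> SpectraSet:
    """Retain bands with ``low_nm <= lambda <= high_nm`` (closed interval)."""
    if low_nm >= high_nm:
        raise ValueError(f"invalid band range [{low_nm}, {high_nm}]: low must be < high")
    mask = (spectra.wavelengths >= low_nm) & (spectra.wavelengths <= high_nm)
    if not mask.any():
        raise ValueError(
            f"band range [{low_nm}, {high_nm}] does not overlap the grid "
            f"({spectra.wavelengths[0]:g}-{spectra.wavelengths[-1]:g} nm)"
        )
    return SpectraSet(
        spectra.wavelengths[mask].copy(),
        spectra.reflectance[:, mask].copy(),
        spectra.metadata.copy(),
    )


def regrid_linear(spectra: SpectraSet, new_wavelengths: np.ndarray) -> SpectraSet:
    """Linear interpolation onto a new grid (for instrument exports whose
    sampling interval changes along the spectrum).  Extrapolation is refused.
    """
    new_wl = np.asarray(new_wavelengths, dtype=float)
    if new_wl[0] < spectra.wavelengths[0] or new_wl[-1] > spectra.wavelengths[-1]:
        raise ValueError("new grid must lie within the measured range")
    refl = np.vstack(
        [np.interp(new_wl, spectra.wavelengths, row) for row in spectra.reflectance]
    )
    return SpectraSet(new_wl, refl, spectra.metadata.copy())
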