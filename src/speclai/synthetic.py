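"""Synthetic winter-wheat canopy spectra with known LAI ground truth.

The generator emulates the data structure of a two-field-type (irrigated vs
rainfed) hyperspectral LAI campaign: per-sample LAI drawn from a truncated
normal, canopy reflectance formed as a gap-fraction mixture of a bare-soil
and a dense-leaf endmember, three replicate scans with instrument noise, and
the spectral saturation of reflectance above LAI ~ 3.

Optical model
-------------
For a sample with leaf area index ``L`` the canopy gap fraction follows
Beer-Lambert, ``T(lambda, L) = exp(-k(lambda) * L)``, and the noiseless
canopy reflectance is the two-endmember mixture

    R(lambda) = R_soil(lambda) * T + R_leaf(lambda) * (1 - T).

The extinction coefficient is wavelength dependent: ``k(lambda) =
extinction_k * m(lambda)`` where the modulation ``m`` is exactly 1 away
from a fixed set of physiological feature centers (chlorophyll absorption,
red edge, NIR structure, leaf water) and deviates inside a compact +/-10 nm
window around each.  Strongly absorbed bands (chlorophyll) saturate faster
than weakly absorbed ones (red edge, NIR), the documented behaviour of real
canopies.  Away from the centers every band is an affine function of the
same gap fraction, so only the feature windows carry independent
information about LAI: these centers are the planted ground truth that
wavelength-selection methods are expected to recover.

Per-sample heterogeneity, all canopy-structural rather than instrumental:

* ``feature_cv`` — the absorber concentration behind each feature
  (chlorophyll, leaf water, structural dry matter) varies between samples
  at a given LAI, jittering that feature's extinction independently.  This
  is what gives each planted band its own variance direction; without it a
  single latent (LAI) can feed only a handful of distinguishable bands.
* ``extinction_cv`` — plot-to-plot canopy architecture (leaf angle,
  variety) jitters the global extinction coefficient coherently across the
  spectrum; this is the dominant, irreducible part of the LAI error budget.
* ``soil_brightness_cv`` — background soil moisture/roughness scales the
  soil endmember per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import FIELD_TYPES, ReplicateSpectra

__all__ = [
    "FEATURE_CENTERS_NM",
    "SimulationConfig",
    "EndmemberLibrary",
    "make_wavelength_grid",
    "build_endmembers",
    "draw_lai",
    "truncated_normal_mean",
    "canopy_reflectance",
    "simulate_canopy",
    "irrigated_defaults",
    "rainfed_defaults",
]

#: Planted informative band centers (nm): blue/violet chlorophyll absorption,
#: chlorophyll-b, green reflectance peak, red chlorophyll-a absorption, two
#: red-edge points, NIR structural band, and three leaf-water features.
FEATURE_CENTERS_NM: tuple[float, ...] = (
    410.0, 450.0, 540.0, 677.0, 715.0, 735.0, 816.0, 970.0, 1120.0, 1290.0,
)

# Relative deviation of the extinction coefficient at each feature center.
# Positive => faster saturation (strong absorption), negative => slower.
_FEATURE_K_AMPLITUDE: tuple[float, ...] = (
    0.80, 1.10, 0.50, 1.40, -0.30, -0.45, -0.62, -0.38, -0.52, -0.68,
)
#: half-width of the compactly supported feature windows (information is
#: planted strictly within +/- this distance of each center)
FEATURE_HALFWIDTH_NM = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one field-type population.

    LAI distribution parameters default to the descriptive statistics of the
    two calibration populations (see :func:`irrigated_defaults` and
    :func:`rainfed_defaults`); replicate count defaults to the three scans
    per sample of a field spectroradiometer protocol.
    """

    field_type: str
    n_samples: int
    lai_mean: float
    lai_sd: float
    lai_min: float
    lai_max: float
    extinction_k: float = 0.5
    noise_additive_sd: float = 0.005
    noise_multiplicative_sd: float = 0.01
    n_replicates: int = 3
    seed: int = 0
    wavelength_start_nm: float = 400.0
    wavelength_stop_nm: float = 1400.0
    wavelength_step_nm: float = 1.0
    #: per-sample CV of the extinction coefficient (canopy architecture,
    #: variety and stage heterogeneity acting coherently across the spectrum)
    extinction_cv: float = 0.32
    #: per-sample SD of the multiplicative soil-brightness factor
    soil_brightness_cv: float = 0.10
    #: per-sample, per-feature CV of absorber concentration (chlorophyll,
    #: water, dry matter) modulating each feature's extinction independently
    feature_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.field_type not in FIELD_TYPES:
            raise ValueError(f"field_type must be one of {FIELD_TYPES}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.lai_sd < 0:
            raise ValueError("lai_sd must be non-negative")
        if not (self.lai_min < self.lai_mean < self.lai_max):
            raise ValueError("require lai_min < lai_mean < lai_max")
        if self.extinction_k <= 0:
            raise ValueError("extinction_k must be > 0")
        if self.noise_additive_sd < 0 or self.noise_multiplicative_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if min(self.extinction_cv, self.soil_brightness_cv, self.feature_cv) < 0:
            raise ValueError("heterogeneity parameters must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.wavelength_start_nm >= self.wavelength_stop_nm:
            raise ValueError("wavelength_start must be < wavelength_stop")
        if self.wavelength_step_nm <= 0:
            raise ValueError("wavelength_step must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def low_noise(self) -> "SimulationConfig":
        """Idealised variant: negligible instrument noise, homogeneous canopy
        architecture and soil.  Absorber-concentration variability
        (``feature_cv``) is biological, not instrumental, and stays on."""
        return self.with_(
            noise_additive_sd=1e-4,
            noise_multiplicative_sd=1e-3,
            extinction_cv=0.0,
            soil_brightness_cv=0.0,
        )


def irrigated_defaults(seed: int = 0, n_samples: int = 93) -> SimulationConfig:
    """Irrigated population: high LAI (mean 5.100, SD 2.283, range 1.31-11.91)."""
    return SimulationConfig(
        field_type="irrigated", n_samples=n_samples,
        lai_mean=5.100, lai_sd=2.283, lai_min=1.31, lai_max=11.91, seed=seed,
    )


def rainfed_defaults(seed: int = 0, n_samples: int = 84) -> SimulationConfig:
    """Rainfed population: low LAI (mean 2.951, SD 2.002, range 0.31-9.27)."""
    return SimulationConfig(
        field_type="rainfed", n_samples=n_samples,
        lai_mean=2.951, lai_sd=2.002, lai_min=0.31, lai_max=9.27, seed=seed,
    )


# ---------------------------------------------------------------------------
# wavelength grid and endmembers


def make_wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> np.ndarray:
    """Strictly increasing grid from ``start_nm`` in steps of ``step_nm``.

    Inclusive of the start; the last point is the largest grid point
    ``<= stop_nm``.
    """
    if step_nm <= 0:
        raise ValueError("step must be positive")
    if start_nm >= stop_nm:
        raise ValueError("start must be < stop")
    n = int(np.floor((stop_nm - start_nm) / step_nm + 1e-9)) + 1
    return start_nm + step_nm * np.arange(n, dtype=float)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _bump(wl: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Smooth bump with compact support: exactly zero beyond +/- halfwidth."""
    u = (wl - center) / halfwidth
    out = np.zeros_like(wl)
    inside = np.abs(u) < 1.0
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - u[inside] ** 2))
    return out


@dataclass(frozen=True)
class EndmemberLibrary:
    """Pure-component spectra mixed to synthesise canopy reflectance.

    ``extinction_modulation`` is the dimensionless per-band factor m(lambda)
    multiplying the canopy extinction coefficient (1 away from features).
    ``feature_profiles`` is the (n_features, n_bands) matrix of the
    compactly supported feature windows; row f is the spectral footprint of
    feature f's absorber, used to apply per-sample concentration jitter.
    """

    wavelengths: np.ndarray
    soil_reflectance: np.ndarray
    leaf_reflectance: np.ndarray
    feature_centers: tuple[float, ...]
    extinction_modulation: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_profiles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("soil_reflectance", "leaf_reflectance"):
            v = getattr(self, name)
            if v.shape != self.wavelengths.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.extinction_modulation is None:
            object.__setattr__(
                self, "extinction_modulation", np.ones_like(self.wavelengths)
            )
        if np.any(self.extinction_modulation <= 0):
            raise ValueError("extinction modulation must be positive")
        if self.feature_profiles is None:
            object.__setattr__(
                self,
                "feature_profiles",
                np.zeros((len(self.feature_centers), self.wavelengths.size)),
            )


def build_endmembers(wavelengths: np.ndarray) -> EndmemberLibrary:
    """Deterministic soil and leaf endmembers on the given grid.

    The leaf endmember is a smooth parametric curve with chlorophyll
    absorption minima near 450 and 677 nm, the green peak near 560 nm, a
    steep red-edge rise between ~690 and 760 nm onto a NIR plateau, and
    leaf-water features near 970, 1120 and 1290 nm.  The soil endmember is a
    smooth, monotonically increasing dry-soil curve (brighter than leaf in
    the visible, darker on the NIR plateau).
    """
    wl = _validate_endmember_grid(wavelengths)

    # calcareous soil: saturating rise from ~0.10 (blue) through the VIS/NIR,
    # then a moist-soil water absorption decline in the SWIR (beyond 1100 nm)
    soil = 0.10 + 0.28 * (1.0 - np.exp(-(wl - 340.0) / 900.0))
    soil = soil - 0.16 * _sigmoid((wl - 1160.0) / 35.0)
    soil = np.clip(soil, 0.02, 0.98)

    # green leaf: VIS floor + red-edge sigmoid to the NIR plateau
    leaf = 0.055 + 0.40 * _sigmoid((wl - 715.0) / 12.0)
    leaf = leaf + 0.055 * _gauss(wl, 560.0, 22.0)       # green peak
    leaf = leaf - 0.020 * _gauss(wl, 410.0, 12.0)       # violet chl absorption
    leaf = leaf - 0.025 * _gauss(wl, 450.0, 14.0)       # chl-b absorption
    leaf = leaf - 0.030 * _gauss(wl, 677.0, 15.0)       # chl-a red absorption
    leaf = leaf - 0.030 * _gauss(wl, 970.0, 28.0)       # water
    leaf = leaf - 0.070 * _gauss(wl, 1120.0, 40.0)      # water
    leaf = leaf - 0.060 * _gauss(wl, 1290.0, 45.0)      # water shoulder
    leaf = np.clip(leaf, 0.02, 0.98)

    profiles = np.vstack(
        [_bump(wl, c, FEATURE_HALFWIDTH_NM) for c in FEATURE_CENTERS_NM]
    )
    modulation = 1.0 + np.asarray(_FEATURE_K_AMPLITUDE) @ profiles

    return EndmemberLibrary(
        wavelengths=wl,
        soil_reflectance=soil,
        leaf_reflectance=leaf,
        feature_centers=FEATURE_CENTERS_NM,
        extinction_modulation=modulation,
        feature_profiles=profiles,
    )


def _validate_endmember_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be 1-D strictly increasing")
    if wl[0] < 350.0 or wl[-1] > 2500.0:
        raise ValueError("endmembers are defined on 350-2500 nm only")
    return wl


# ---------------------------------------------------------------------------
# LAI sampling


def _seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent RNG streams derived from one seed.

    Keeping per-stage streams means e.g. the LAI draw is identical whether
    or not spectra are simulated afterwards.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("lai", "structure", "noise")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def draw_lai(config: SimulationConfig) -> np.ndarray:
    """Truncated-normal LAI draws for one population.

    N(lai_mean, lai_sd^2) truncated to [lai_min, lai_max]; the degenerate
    ``lai_sd == 0`` limit returns the mean for every sample.
    """
    if config.lai_max <= config.lai_min:
        raise ValueError("infeasible truncation: lai_max <= lai_min")
    rng = _seed_streams(config.seed)["lai"]
    if config.lai_sd == 0:
        return np.full(config.n_samples, config.lai_mean)
    a = (config.lai_min - config.lai_mean) / config.lai_sd
    b = (config.lai_max - config.lai_mean) / config.lai_sd
    return stats.truncnorm.rvs(
        a, b, loc=config.lai_mean, scale=config.lai_sd,
        size=config.n_samples, random_state=rng,
    )


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of a truncated normal by numerical quadrature (oracle utility)."""
    from scipy.integrate import quad

    norm = stats.norm(mean, sd)
    z = norm.cdf(hi) - norm.cdf(lo)
    num, _ = quad(lambda x: x * norm.pdf(x), lo, hi)
    return num / z


# ---------------------------------------------------------------------------
# reflectance simulation


def canopy_reflectance(
    lai,
    endmembers: EndmemberLibrary,
    extinction_k: float = 0.5,
    soil_brightness: float | np.ndarray = 1.0,
    feature_jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless gap-fraction mixture reflectance.

    ``lai`` may be a scalar (returns one spectrum) or an (n,) vector
    (returns an (n, p) matrix).  ``extinction_k`` may likewise be scalar or
    per-sample; ``soil_brightness`` scales the soil endmember per sample.
    ``feature_jitter``, if given, is an (n, n_features) matrix of relative
    absorber-concentration deviations: sample i's extinction modulation at
    feature f is scaled by ``(1 + feature_jitter[i, f])`` inside that
    feature's spectral window.
    """
    lai_arr = np.atleast_1d(np.asarray(lai, dtype=float))
    if np.any(lai_arr < 0):
        raise ValueError("LAI must be non-negative")
    k = np.atleast_1d(np.asarray(extinction_k, dtype=float))
    if np.any(k <= 0):
        raise ValueError("extinction coefficient must be positive")
    bright = np.atleast_1d(np.asarray(soil_brightness, dtype=float))

    # (n, p) extinction with wavelength-dependent (and optionally
    # per-sample feature-jittered) modulation
    modulation = endmembers.extinction_modulation[None, :]
    if feature_jitter is not None:
        jitter = np.asarray(feature_jitter, dtype=float)
        if jitter.shape != (lai_arr.size, len(endmembers.feature_centers)):
            raise ValueError("feature_jitter must be (n_samples, n_features)")
        modulation = modulation * (1.0 + jitter @ endmembers.feature_profiles)
    k_lambda = k[:, None] * np.clip(modulation, 0.05, None)
    gap = np.exp(-k_lambda * lai_arr[:, None])
    soil = bright[:, None] * endmembers.soil_reflectance[None, :]
    refl = soil * gap + endmembers.leaf_reflectance[None, :] * (1.0 - gap)
    refl = np.clip(refl, 0.0, 1.0)
    if np.isscalar(lai) or np.asarray(lai).ndim == 0:
        return refl[0]
    return refl


def simulate_canopy(
    config: SimulationConfig,
    endmembers: EndmemberLibrary | None = None,
) -> ReplicateSpectra:
    """Simulate replicate canopy scans for one field-type population.

    Each replicate scan is ``R * (1 + eps_m) + eps_a`` with independent
    zero-mean Gaussian multiplicative and additive noise, clipped to [0, 1].
    Growth-stage labels are assigned by LAI tercile (jointing < booting <
    filling), mirroring the coarse stage structure of a season-long campaign.
    """
    grid = make_wavelength_grid(
        config.wavelength_start_nm, config.wavelength_stop_nm, config.wavelength_step_nm
    )
    if endmembers is None:
        endmembers = build_endmembers(grid)
    elif endmembers.wavelengths.shape != grid.shape or not np.allclose(
        endmembers.wavelengths, grid
    ):
        raise ValueError("endmember library grid does not match the config grid")

    streams = _seed_streams(config.seed)
    lai = draw_lai(config)

    rng_struct = streams["structure"]
    k_sample = config.extinction_k * (
        1.0 + config.extinction_cv * rng_struct.standard_normal(config.n_samples)
    )
    k_sample = np.clip(k_sample, 0.05 * config.extinction_k, None)
    brightness = 1.0 + config.soil_brightness_cv * rng_struct.standard_normal(
        config.n_samples
    )
    brightness = np.clip(brightness, 0.2, None)
    jitter = config.feature_cv * rng_struct.standard_normal(
        (config.n_samples, len(endmembers.feature_centers))
    )

    clean = canopy_reflectance(lai, endmembers, k_sample, brightness, jitter)

    rng_noise = streams["noise"]
    n, p = clean.shape
    r = config.n_replicates
    eps_m = config.noise_multiplicative_sd * rng_noise.standard_normal((n, r, p))
    eps_a = config.noise_additive_sd * rng_noise.standard_normal((n, r, p))
    scans = clean[:, None, :] * (1.0 + eps_m) + eps_a
    scans = np.clip(scans, 0.0, 1.0)

    stage = _stage_by_tercile(lai)
    meta = pd.DataFrame(
        {
            "sample_id": [f"{config.field_type[:3]}_{i:04d}" for i in range(n)],
            "field_type": config.field_type,
            "stage": stage,
            "lai": lai,
        }
    )
    return ReplicateSpectra(grid, scans, meta)


def _stage_by_tercile(lai: np.ndarray) -> list[str]:
    labels = ("jointing", "booting", "filling")
    if lai.size < 3:
        return [labels[0]] * lai.size
    q1, q2 = np.quantile(lai, [1 / 3, 2 / 3])
    return [labels[0] if v <= q1 else labels[1] if v <= q2 else labels[2] for v in lai]
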