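"""Synthetic canopy generator: wavelength grids, endmember optics, LAI
sampling, and the gap-fraction mixing model."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm, pearsonr

from speclai import (
    build_endmembers,
    canopy_reflectance,
    draw_lai,
    irrigated_defaults,
    make_wavelength_grid,
    rainfed_defaults,
    simulate_canopy,
)
from speclai.preprocess import average_replicates
from speclai.synthetic import SimulationConfig


# ---------------------------------------------------------------------------
# wavelength grid


@pytest.mark.parametrize(
    "start,stop,step,n,first,last",
    [
        (400, 1400, 1, 1001, 400, 1400),
        (400, 402, 1, 3, 400, 402),
        (350, 2500, 1, 2151, 350, 2500),  # full spectroradiometer span
        (400, 1400, 5, 201, 400, 1400),
    ],
)
def test_wavelength_grid(start, stop, step, n, first, last):
    wl = make_wavelength_grid(start, stop, step)
    assert wl.size == n
    assert wl[0] == first and wl[-1] == last
    assert np.all(np.diff(wl) > 0)


@pytest.mark.parametrize("args", [(400, 1400, 0), (400, 1400, -1), (1400, 400, 1), (400, 400, 1)])
def test_wavelength_grid_rejects_bad_args(args):
    with pytest.raises(ValueError):
        make_wavelength_grid(*args)


# ---------------------------------------------------------------------------
# endmembers


class TestEndmembers:
    def band(self, em, nm):
        return int(np.argmin(np.abs(em.wavelengths - nm)))

    def test_vegetation_features(self, endmembers):
        em = endmembers
        leaf = em.leaf_reflectance
        # red absorption below the green peak; NIR plateau above both
        assert leaf[self.band(em, 677)] < leaf[self.band(em, 560)]
        assert leaf[self.band(em, 800)] > 0.3
        assert leaf[self.band(em, 800)] > leaf[self.band(em, 677)]
        # chlorophyll absorption: local minima of the leaf curve near 450/677
        for nm in (450, 677):
            j = self.band(em, nm)
            lo = j - 25
            j_min = lo + int(np.argmin(leaf[lo : j + 26]))
            assert abs(em.wavelengths[j_min] - nm) <= 10
            # a genuine interior minimum, not a window-edge artefact
            assert leaf[j_min] < leaf[j_min - 20] and leaf[j_min] < leaf[j_min + 20]
        # steep red edge between ~690 and 760 nm
        assert leaf[self.band(em, 760)] - leaf[self.band(em, 690)] > 0.2
        # leaf-water feature near 1120 nm (dip relative to the NIR plateau)
        assert leaf[self.band(em, 1120)] < leaf[self.band(em, 1040)]

    def test_soil_monotone_in_vis_nir(self, endmembers):
        em = endmembers
        upto = self.band(em, 1000)
        assert np.all(np.diff(em.soil_reflectance[: upto + 1]) >= -1e-9)

    def test_reflectances_bounded(self, endmembers):
        for v in (endmembers.soil_reflectance, endmembers.leaf_reflectance):
            assert np.all(v > 0) and np.all(v < 1)

    def test_deterministic(self, grid_400_1400):
        a = build_endmembers(grid_400_1400)
        b = build_endmembers(grid_400_1400)
        assert np.array_equal(a.leaf_reflectance, b.leaf_reflectance)
        assert np.array_equal(a.soil_reflectance, b.soil_reflectance)
        assert np.array_equal(a.extinction_modulation, b.extinction_modulation)

    def test_rejects_out_of_range_grid(self):
        with pytest.raises(ValueError):
            build_endmembers(make_wavelength_grid(300, 800, 1))


# ---------------------------------------------------------------------------
# LAI sampling


def _truncnorm_moments(mean, sd, lo, hi):
    """Quadrature oracle for the truncated normal mean and SD."""
    d = norm(mean, sd)
    z = d.cdf(hi) - d.cdf(lo)
    m1 = quad(lambda x: x * d.pdf(x), lo, hi)[0] / z
    m2 = quad(lambda x: x * x * d.pdf(x), lo, hi)[0] / z
    return m1, np.sqrt(m2 - m1**2)


@pytest.mark.parametrize("make_cfg", [irrigated_defaults, rainfed_defaults])
def test_draw_lai_matches_truncated_normal_oracle(make_cfg):
    cfg = make_cfg(seed=11).with_(n_samples=10000)
    lai = draw_lai(cfg)
    assert lai.size == 10000
    assert lai.min() >= cfg.lai_min and lai.max() <= cfg.lai_max
    mean_o, sd_o = _truncnorm_moments(cfg.lai_mean, cfg.lai_sd, cfg.lai_min, cfg.lai_max)
    se = sd_o / np.sqrt(lai.size)
    assert abs(lai.mean() - mean_o) < 3 * se
    assert abs(np.std(lai, ddof=1) - sd_o) < 3 * sd_o / np.sqrt(2 * lai.size)


def test_draw_lai_zero_sd_limit():
    cfg = rainfed_defaults(seed=0).with_(lai_sd=0.0, n_samples=50)
    assert np.all(draw_lai(cfg) == cfg.lai_mean)


def test_draw_lai_deterministic():
    cfg = irrigated_defaults(seed=5)
    assert np.array_equal(draw_lai(cfg), draw_lai(cfg))


def test_infeasible_truncation_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(
            field_type="rainfed", n_samples=5, lai_mean=2.0, lai_sd=1.0,
            lai_min=3.0, lai_max=1.0,
        )


# ---------------------------------------------------------------------------
# reflectance simulation


class TestCanopyReflectance:
    def test_bare_soil_limit(self, endmembers):
        r = canopy_reflectance(0.0, endmembers)
        assert np.allclose(r, endmembers.soil_reflectance, atol=1e-12)

    def test_dense_canopy_limit_and_saturation(self, endmembers):
        r_dense = canopy_reflectance(40.0, endmembers)
        assert np.allclose(r_dense, endmembers.leaf_reflectance, atol=1e-3)
        # sensitivity |dR/dL| at the red absorption band collapses at high LAI
        j = int(np.argmin(np.abs(endmembers.wavelengths - 677)))
        eps = 1e-4

        def slope(L):
            lo = canopy_reflectance(L - eps, endmembers)[j]
            hi = canopy_reflectance(L + eps, endmembers)[j]
            return abs(hi - lo) / (2 * eps)

        assert slope(6.0) < 0.1 * slope(0.5)

    def test_per_band_scalar_oracle(self, endmembers):
        """Mixture matches an explicit scalar per-band evaluation (L=3, k=0.5)."""
        L, k = 3.0, 0.5
        r = canopy_reflectance(L, endmembers, extinction_k=k)
        for j in range(0, endmembers.wavelengths.size, 37):
            t = np.exp(-k * endmembers.extinction_modulation[j] * L)
            expect = endmembers.soil_reflectance[j] * t + endmembers.leaf_reflectance[j] * (1 - t)
            assert r[j] == pytest.approx(expect, abs=1e-12)

    def test_monotone_darkening_in_red(self, endmembers):
        j = int(np.argmin(np.abs(endmembers.wavelengths - 677)))
        lai = np.linspace(0.0, 9.0, 40)
        r677 = canopy_reflectance(lai, endmembers)[:, j]
        assert np.all(np.diff(r677) < 0)

    def test_saturation_weakens_correlation(self, endmembers):
        j = int(np.argmin(np.abs(endmembers.wavelengths - 677)))
        low = np.linspace(0.3, 3.0, 200)
        high = np.linspace(3.0, 9.0, 200)
        r_low = pearsonr(canopy_reflectance(low, endmembers)[:, j], low)[0]
        r_high = pearsonr(canopy_reflectance(high, endmembers)[:, j], high)[0]
        assert abs(r_high) < abs(r_low)


class TestSimulateCanopy:
    def test_shapes_bounds_and_metadata(self):
        cfg = rainfed_defaults(seed=3).with_(n_samples=12, wavelength_step_nm=5)
        reps = simulate_canopy(cfg)
        assert reps.reflectance.shape == (12, 3, 201)
        assert reps.reflectance.min() >= 0 and reps.reflectance.max() <= 1
        assert set(reps.metadata["stage"]) <= {"jointing", "booting", "filling"}
        assert reps.metadata["field_type"].eq("rainfed").all()

    def test_bit_identical_under_fixed_seed(self):
        cfg = irrigated_defaults(seed=9).with_(n_samples=8, wavelength_step_nm=10)
        a, b = simulate_canopy(cfg), simulate_canopy(cfg)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert a.metadata.equals(b.metadata)

    def test_zero_noise_replicates_identical(self):
        cfg = rainfed_defaults(seed=2).with_(
            n_samples=6, wavelength_step_nm=10, noise_additive_sd=0.0,
            noise_multiplicative_sd=0.0,
        )
        reps = simulate_canopy(cfg)
        assert np.allclose(reps.reflectance[:, 0], reps.reflectance[:, 1])
        assert np.allclose(reps.reflectance[:, 0], reps.reflectance[:, 2])

    def test_mismatched_endmember_grid_rejected(self, endmembers):
        cfg = rainfed_defaults(seed=0).with_(wavelength_step_nm=5)
        with pytest.raises(ValueError, match="grid"):
            simulate_canopy(cfg, endmembers)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            rainfed_defaults().with_(noise_additive_sd=-0.1)

    def test_generated_lai_matches_labels(self):
        cfg = rainfed_defaults(seed=4).with_(n_samples=20, wavelength_step_nm=10)
        reps = simulate_canopy(cfg)
        assert np.array_equal(reps.metadata["lai"].to_numpy(), draw_lai(cfg))

    def test_replicate_average_tracks_clean_signal(self):
        """With noise off, the replicate average equals the deterministic
        mixture when heterogeneity is also off."""
        cfg = rainfed_defaults(seed=6).with_(
            n_samples=5, wavelength_step_nm=10, noise_additive_sd=0.0,
            noise_multiplicative_sd=0.0, extinction_cv=0.0,
            soil_brightness_cv=0.0, feature_cv=0.0,
        )
        reps = simulate_canopy(cfg)
        em = build_endmembers(reps.wavelengths)
        clean = canopy_reflectance(draw_lai(cfg), em, cfg.extinction_k)
        assert np.allclose(average_replicates(reps).reflectance, clean, atol=1e-12)
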