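"""Cone mosaics: geometry, spectral sensitivity, and Poisson absorptions."""

import numpy as np
import pytest

from coneobserver import (
    GaborSpec,
    OpticsModel,
    apply_optics,
    build_mosaic,
    compute_isomerizations,
    cone_quantal_sensitivity,
    coverage_at_eccentricity,
    density_to_eccentricity,
    eccentricity_to_density,
    make_gabor_scene,
)
from coneobserver.mosaic import CONE_TYPES, mean_absorption_maps, sample_mean_at_shift
from coneobserver.runner import trial_mean_maps


class TestGeometry:
    def test_reference_grid_is_79(self):
        m = build_mosaic(1560.0, 2.0, (0.6, 0.3, 0.1), 0.49, seed=0)
        assert m.grid.shape == (79, 79)

    def test_low_density_grid_is_43(self):
        m = build_mosaic(466.0, 2.0, seed=0)
        assert m.grid.shape == (43, 43)

    def test_pure_l_mosaic(self):
        m = build_mosaic(1560.0, 2.0, (1.0, 0.0, 0.0), 0.49, seed=3)
        assert np.all(m.grid == 0)

    def test_type_fractions_near_ratio(self):
        m = build_mosaic(1560.0, 2.0, (0.6, 0.3, 0.1), 0.49, seed=5)
        n2 = m.n**2
        for i, p in enumerate((0.6, 0.3, 0.1)):
            se = np.sqrt(p * (1 - p) / n2)
            assert abs(np.mean(m.grid == i) - p) < 3 * se

    def test_same_seed_bit_identical(self):
        a = build_mosaic(seed=42)
        b = build_mosaic(seed=42)
        assert np.array_equal(a.grid, b.grid)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            build_mosaic(lms_ratio=(0.5, 0.3, 0.1))


class TestDensityEccentricity:
    def test_printed_anchors(self):
        assert density_to_eccentricity(22500.0) == pytest.approx(0.0, abs=1e-6)
        assert density_to_eccentricity(466.0) == pytest.approx(40.0, abs=1e-6)
        assert density_to_eccentricity(1560.0) == pytest.approx(4.5, abs=0.05)

    @pytest.mark.parametrize("d", [500.0, 1560.0, 4000.0, 20000.0])
    def test_roundtrip(self, d):
        assert eccentricity_to_density(density_to_eccentricity(d)) == pytest.approx(d, rel=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            density_to_eccentricity(100.0)

    def test_coverage_anchors(self):
        assert coverage_at_eccentricity(0.0) == pytest.approx(1.0, abs=1e-9)
        assert coverage_at_eccentricity(4.5) == pytest.approx(0.49, abs=1e-3)
        assert coverage_at_eccentricity(40.0) == pytest.approx(0.25, abs=1e-3)

    def test_coverage_monotone(self):
        e = np.linspace(0, 40, 100)
        k = np.array([coverage_at_eccentricity(x) for x in e])
        assert np.all(np.diff(k) < 0)


class TestSpectralSensitivity:
    def test_unit_peak_by_normalization(self):
        for t in CONE_TYPES:
            assert cone_quantal_sensitivity(t).max() == pytest.approx(1.0)

    def test_s_cone_is_short_wavelength(self):
        s = cone_quantal_sensitivity("S", np.array([440.0, 560.0]))
        assert s[0] > s[1]

    def test_peak_ordering_s_m_l(self):
        wl = np.arange(400, 701, 10.0)
        peaks = {t: wl[np.argmax(cone_quantal_sensitivity(t, wl))] for t in CONE_TYPES}
        assert peaks["S"] < peaks["M"] < peaks["L"]

    def test_l_m_curves_cross_once(self):
        wl = np.arange(400, 701, 10.0)
        diff = cone_quantal_sensitivity("L", wl) - cone_quantal_sensitivity("M", wl)
        crossings = np.sum(np.diff(np.sign(diff[np.abs(diff) > 1e-12])) != 0)
        assert crossings == 1

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            cone_quantal_sensitivity("X")


@pytest.fixture(scope="module")
def background_irradiance():
    sc = make_gabor_scene(GaborSpec(michelson_contrast=0.0))
    return apply_optics(sc, OpticsModel())


class TestIsomerizations:
    def test_zero_irradiance_zero_counts(self, background_irradiance, mosaic_default):
        irr = background_irradiance
        dark = type(irr)(
            irradiance=np.zeros_like(irr.irradiance),
            wavelengths=irr.wavelengths,
            samples_per_deg=irr.samples_per_deg,
            pad_deg=irr.pad_deg,
            fov_deg=irr.fov_deg,
        )
        mov = compute_isomerizations(dark, mosaic_default, seed=0)
        assert np.all(mov.counts == 0)

    def test_baseline_rates_match_printed_values(self, background_irradiance, mosaic_default):
        """Background absorption rates land near ~110/75/12 photons/ms (L/M/S)."""
        mov = compute_isomerizations(background_irradiance, mosaic_default, seed=1)
        expected = {"L": 110.0, "M": 75.0, "S": 12.0}
        rates = {t: mov.rate_per_ms(t) for t in CONE_TYPES}
        assert rates["L"] > rates["M"] > rates["S"]
        for t, ref in expected.items():
            assert abs(rates[t] - ref) / ref < 0.20, f"{t}: {rates[t]:.1f} vs {ref}"

    def test_poisson_dispersion(self, background_irradiance):
        """Across repeated draws, count variance/mean stays near 1."""
        m = build_mosaic(466.0, 2.0, seed=9)
        mov0 = compute_isomerizations(background_irradiance, m, seed=0)
        draws = np.stack(
            [
                compute_isomerizations(background_irradiance, m, seed=s).counts[21, 21, :]
                for s in range(40)
            ]
        ).ravel()  # 40 seeds x 28 bins of one cone
        ratio = draws.var(ddof=1) / draws.mean()
        assert 0.9 < ratio < 1.1
        assert np.issubdtype(mov0.counts.dtype, np.integer)
        assert mov0.counts.min() >= 0

    def test_counts_deterministic_given_seed(self, background_irradiance, mosaic_default):
        a = compute_isomerizations(background_irradiance, mosaic_default, seed=7)
        b = compute_isomerizations(background_irradiance, mosaic_default, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_halving_coverage_halves_means(self, background_irradiance):
        hi = build_mosaic(1560.0, 2.0, coverage=0.49, seed=4)
        lo = build_mosaic(1560.0, 2.0, coverage=0.245, seed=4)
        mhi = mean_absorption_maps(background_irradiance, hi, 2.0)
        mlo = mean_absorption_maps(background_irradiance, lo, 2.0)
        assert np.allclose(mlo, 0.5 * mhi)

    def test_high_contrast_increments_near_printed_values(
        self, background_irradiance, mosaic_default, maps_default
    ):
        """100%-contrast increments over baseline ~50/30/4 photons/ms (L/M/S)."""
        m = mosaic_default
        bg = sample_mean_at_shift(
            trial_mean_maps(maps_default, 0.0, 15.0, 90.0, m), maps_default.irr_grid, m
        )
        hi = sample_mean_at_shift(
            trial_mean_maps(maps_default, 1.0, 15.0, 90.0, m), maps_default.irr_grid, m
        )
        incr = np.abs(hi - bg) / 2.0  # photons/ms (2-ms bins)
        # average over cones within the central degree (the +/-1 sd extent)
        pos = m.positions_deg()
        inside = (np.abs(pos)[:, None] <= 0.5) & (np.abs(pos)[None, :] <= 0.5)
        expected = {"L": 50.0, "M": 30.0, "S": 4.0}
        for i, t in enumerate(CONE_TYPES):
            sel = inside & (m.grid == i)
            val = incr[sel].mean()
            assert abs(val - expected[t]) / expected[t] < 0.30, f"{t}: {val:.1f}"

    def test_shift_beyond_padding_rejected(self, background_irradiance, mosaic_default):
        maps = mean_absorption_maps(background_irradiance, mosaic_default, 2.0)
        with pytest.raises(ValueError, match="padding"):
            sample_mean_at_shift(maps, background_irradiance, mosaic_default, (30, 0))
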