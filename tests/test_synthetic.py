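"""Fingerprint rendering, stick broadening, mixture simulation, fixture."""

import itertools

import numpy as np
import pytest

import glycounmix as g


class TestRenderFingerprint:
    def test_single_band_peaks_at_nearest_grid_point(self, analysis_grid):
        model = g.IsomerModel("x", (g.PeakBand(1065, 1.0, 8),))
        s = g.render_fingerprint(model, analysis_grid)
        peak = s.wavenumbers[np.argmax(s.intensities)]
        assert peak in (1064.0, 1066.0)
        # symmetric decay around the band center
        left = s.intensities[s.wavenumbers == 1060][0]
        right = s.intensities[s.wavenumbers == 1070][0]
        assert left == pytest.approx(right, rel=1e-12)

    def test_zero_intensity_bands_render_zero(self, analysis_grid):
        model = g.IsomerModel("x", (g.PeakBand(1065, 0.0, 8),))
        s = g.render_fingerprint(model, analysis_grid)
        assert np.all(s.intensities == 0)

    def test_superposition_linearity(self, analysis_grid):
        halves = g.IsomerModel(
            "x", (g.PeakBand(1065, 0.5, 8), g.PeakBand(1065, 0.5, 8))
        )
        whole = g.IsomerModel("x", (g.PeakBand(1065, 1.0, 8),))
        np.testing.assert_allclose(
            g.render_fingerprint(halves, analysis_grid).intensities,
            g.render_fingerprint(whole, analysis_grid).intensities,
            atol=1e-15,
        )

    def test_empty_model_rejected(self, analysis_grid):
        with pytest.raises(ValueError, match="empty model"):
            g.render_fingerprint(g.IsomerModel("x", ()), analysis_grid)


class TestBroadenSticks:
    def test_harmonic_scale_factor(self):
        grid = g.WavenumberGrid(900, 1100, 1)
        sticks = g.StickSpectrum([1000.0], [1.0], scale_factor=0.965)
        s = g.broaden_sticks(sticks, grid, fwhm=8)
        assert s.wavenumbers[np.argmax(s.intensities)] == pytest.approx(965.0)

    def test_anharmonic_constant_shift(self):
        grid = g.WavenumberGrid(1000, 1150, 1)
        sticks = g.StickSpectrum([1100.0], [1.0], scale_factor=1.0, shift=20.0)
        s = g.broaden_sticks(sticks, grid, fwhm=8)
        assert s.wavenumbers[np.argmax(s.intensities)] == pytest.approx(1120.0)

    def test_identity_matches_band_rendering(self, analysis_grid):
        sticks = g.StickSpectrum([1040.0, 1110.0], [1.0, 0.5])
        via_sticks = g.broaden_sticks(sticks, analysis_grid, fwhm=8)
        model = g.IsomerModel(
            "x", (g.PeakBand(1040, 1.0, 8), g.PeakBand(1110, 0.5, 8))
        )
        via_bands = g.render_fingerprint(model, analysis_grid)
        np.testing.assert_allclose(
            via_sticks.intensities, via_bands.intensities, atol=1e-15
        )

    def test_out_of_grid_sticks_contribute_tails_only(self):
        grid = g.WavenumberGrid(1000, 1020, 2)
        s = g.broaden_sticks(g.StickSpectrum([990.0], [1.0]), grid, fwhm=8)
        assert s.intensities[0] > s.intensities[-1]
        assert np.all(s.intensities >= 0)


class TestSimulateMixture:
    def test_pure_component_limit(self, library, raw_grid):
        name = library.names[0]
        clean = g.simulate_mixture_spectrum(library, {name: 1.0}, raw_grid)
        np.testing.assert_array_equal(
            clean.intensities,
            g.render_fingerprint(library[name], raw_grid).intensities,
        )

    def test_linear_mixing_superposition(self, library, raw_grid):
        a, b = library.names[:2]
        mix = g.simulate_mixture_spectrum(library, {a: 0.5, b: 0.5}, raw_grid)
        mean = 0.5 * (
            g.render_fingerprint(library[a], raw_grid).intensities
            + g.render_fingerprint(library[b], raw_grid).intensities
        )
        np.testing.assert_allclose(mix.intensities, mean, atol=1e-12)

    def test_seed_determinism_bitwise(self, library, raw_grid):
        a, b = library.names[:2]
        noise = g.NoiseModel(snr=20, seed=99)
        one = g.simulate_mixture_spectrum(library, {a: 0.3, b: 0.7}, raw_grid, noise)
        two = g.simulate_mixture_spectrum(library, {a: 0.3, b: 0.7}, raw_grid, noise)
        assert np.array_equal(one.intensities, two.intensities)

    def test_noise_sd_calibration(self, library):
        # >= 1000 grid points: empirical sd within 10% of max(clean)/snr
        grid = g.WavenumberGrid(1000, 1150, 0.1)
        name = library.names[0]
        clean = g.render_fingerprint(library[name], grid).intensities
        noisy = g.simulate_mixture_spectrum(
            library, {name: 1.0}, grid, g.NoiseModel(snr=50, seed=3)
        ).intensities
        expected_sd = clean.max() / 50
        assert np.std(noisy - clean) == pytest.approx(expected_sd, rel=0.10)

    def test_fraction_validation(self, library, raw_grid):
        a, b = library.names[:2]
        with pytest.raises(ValueError, match="sum to 1"):
            g.simulate_mixture_spectrum(library, {a: 0.6, b: 0.6}, raw_grid)
        with pytest.raises(ValueError, match="unknown isomer"):
            g.simulate_mixture_spectrum(library, {"nope": 1.0}, raw_grid)
        with pytest.raises(ValueError, match="non-negative"):
            g.simulate_mixture_spectrum(library, {a: 1.5, b: -0.5}, raw_grid)


class TestDefaultLibrary:
    def test_four_isomers(self, library):
        assert len(library) == 4

    def test_unique_1065_band(self, library):
        holders = [
            m.name
            for m in library.models
            if any(b.center == 1065.0 and b.intensity > 0 for b in m.bands)
        ]
        assert holders == ["alpha-Gal-phytosphingosine"]

    def test_each_model_has_separated_diagnostic_band(self, library):
        for m in library.models:
            others = [
                b.center
                for o in library.models
                if o.name != m.name
                for b in o.bands
            ]
            assert any(
                min(abs(b.center - c) for c in others) >= 6.0 for b in m.bands
            ), m.name

    def test_pairwise_spectra_distinguishable(self, library, analysis_grid):
        rendered = {
            m.name: g.normalize_area(
                g.render_fingerprint(m, analysis_grid), library.window
            ).intensities
            for m in library.models
        }
        for a, b in itertools.combinations(rendered, 2):
            x, y = rendered[a], rendered[b]
            cosine = x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
            assert cosine < 0.99

    def test_equal_integrated_response(self, library, raw_grid):
        areas = [
            np.trapezoid(
                g.render_fingerprint(m, raw_grid).intensities, raw_grid.centers
            )
            for m in library.models
        ]
        np.testing.assert_allclose(areas, areas[0], rtol=1e-3)
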