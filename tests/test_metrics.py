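"""Rendering, FRC resolution, particle profiles, spectral averages."""

import numpy as np
import pytest

from splitkit import (
    LocalizationTable,
    Rectangle,
    Spectrum,
    average_wavelength,
    fit_sideview_profile,
    frc_resolution,
    radial_distribution,
    render_histogram,
)
from splitkit.metrics import frc_curve


def table_from(frame, x, y, photons=None, **kw):
    if photons is None:
        photons = np.full(len(x), 1000.0)
    return LocalizationTable.from_arrays(frame, x, y, photons, **kw)


class TestRenderHistogram:
    def test_floor_binning(self):
        t = table_from([1], [12.4], [3.0], bounds=Rectangle(0, 20, 0, 20))
        img = render_histogram(t, pixel_size=5.0)
        assert img.pixels[0, 2] == 1  # (row=y//5=0, col=x//5=2)
        assert img.pixels.sum() == 1

    def test_sum_conserves_count(self, rng):
        n = 1000
        t = table_from(np.ones(n, int), rng.uniform(0, 500, n), rng.uniform(0, 500, n),
                       bounds=Rectangle(0, 500, 0, 500))
        assert render_histogram(t, 5.0).pixels.sum() == n

    def test_boundary_point_enters_upper_pixel(self):
        t = table_from([1], [5.0], [0.0], bounds=Rectangle(0, 20, 0, 20))
        img = render_histogram(t, pixel_size=5.0)
        assert img.pixels[0, 1] == 1
        assert img.pixels[0, 0] == 0


class TestFRC:
    def _grid_table(self, loc_sd, n_emitters=200, n_per=40, seed=0):
        """Scattered emitters, each localized n_per times with isotropic
        Gaussian error loc_sd: a structure whose FRC tracks the blur."""
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0, 1000, size=(n_emitters, 2))
        pts = np.repeat(centers, n_per, axis=0) + rng.normal(0, loc_sd, (n_emitters * n_per, 2))
        return table_from(np.arange(1, len(pts) + 1), pts[:, 0], pts[:, 1],
                          bounds=Rectangle(0, 1000, 0, 1000))

    def test_image_against_itself_has_unit_curve(self):
        t = self._grid_table(5.0)
        img = render_histogram(t, 5.0).pixels
        _, frc = frc_curve(img, img, 5.0)
        occupied = np.abs(frc) > 0
        np.testing.assert_allclose(frc[occupied], 1.0, atol=1e-9)

    def test_independent_point_sets_decorrelate(self, rng):
        n = 3000
        t = table_from(np.arange(1, 2 * n + 1),
                       rng.uniform(0, 1000, 2 * n), rng.uniform(0, 1000, 2 * n),
                       bounds=Rectangle(0, 1000, 0, 1000))
        res = frc_resolution(t, pixel_size=5.0, n_repeats=3, seed=1)
        # uniform noise: correlation collapses beyond the lowest bins
        assert np.all(np.abs(res.mean_curve[10:]) < 0.25)

    def test_resolution_improves_with_sharper_localizations(self):
        sharp = self._grid_table(5.0, seed=2)
        blurred = self._grid_table(20.0, seed=2)
        r_sharp = frc_resolution(sharp, 5.0, n_repeats=5, seed=3).resolution_mean
        r_blur = frc_resolution(blurred, 5.0, n_repeats=5, seed=3).resolution_mean
        assert r_sharp < r_blur

    def test_frc_invariant_under_common_translation(self):
        t = self._grid_table(8.0, seed=4)
        shifted = t.with_df(t.df.assign(x=t.df["x"] + 40.0, y=t.df["y"] + 15.0),
                            bounds=Rectangle(40, 1040, 15, 1015))
        r1 = frc_resolution(t, 5.0, n_repeats=4, seed=5).resolution_mean
        r2 = frc_resolution(shifted, 5.0, n_repeats=4, seed=5).resolution_mean
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_too_few_localizations_rejected(self):
        t = table_from(np.ones(10, int), np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            frc_resolution(t)


class TestRadialDistribution:
    def test_uniform_disc_gives_flat_profile(self, rng):
        """Points uniform on a disc of radius R have constant density, so the
        annulus-normalized profile is flat up to R (uniform-disc oracle)."""
        R, n = 100.0, 60_000
        radius = R * np.sqrt(rng.random(n))
        theta = rng.uniform(0, 2 * np.pi, n)
        xy = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        prof = radial_distribution([(xy, (0.0, 0.0))], bin_width=10.0, r_max=100.0)
        expected = n / (np.pi * R**2)
        np.testing.assert_allclose(prof.density, expected, rtol=0.1)

    def test_single_radius_fills_one_bin(self):
        xy = np.array([[75.0, 0.0], [0.0, 75.0], [-75.0, 0.0]])
        prof = radial_distribution([(xy, (0.0, 0.0))], bin_width=10.0, r_max=130.0)
        assert prof.counts[7] == 3  # bin [70, 80)
        assert prof.counts.sum() == 3

    def test_empty_input_gives_zero_profile(self):
        prof = radial_distribution([], bin_width=5.0, r_max=130.0)
        assert np.all(prof.density == 0)

    def test_density_times_area_integrates_back_to_count(self, rng):
        n = 5000
        xy = rng.normal(0, 40.0, size=(n, 2))
        prof = radial_distribution([(xy, (0.0, 0.0))], bin_width=5.0, r_max=400.0)
        areas = np.pi * (prof.bin_edges[1:] ** 2 - prof.bin_edges[:-1] ** 2)
        assert (prof.density * areas).sum() == pytest.approx(
            np.sum(np.linalg.norm(xy, axis=1) < 400.0)
        )


class TestSideviewProfile:
    def _profile(self, mu1, mu2, s=10.0, noise=0.0, seed=0):
        x = np.linspace(-80, 80, 81)
        y = np.exp(-0.5 * ((x - mu1) / s) ** 2) + np.exp(-0.5 * ((x - mu2) / s) ** 2)
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, len(x))
        return x, np.clip(y, 0, None)

    def test_peak_separation_recovered(self):
        x, y = self._profile(-25.0, 25.0, noise=0.01)
        fit = fit_sideview_profile(x, y)
        assert fit.separation == pytest.approx(50.0, rel=0.05)
        assert not fit.degenerate

    def test_symmetric_profile_centers_at_midpoint(self):
        x, y = self._profile(-30.0, 30.0)
        fit = fit_sideview_profile(x, y)
        assert fit.center == pytest.approx(0.0, abs=0.5)
        assert fit.alignment_shift == pytest.approx(0.0, abs=0.5)

    def test_single_peak_flagged_degenerate(self):
        x = np.linspace(-80, 80, 81)
        y = np.exp(-0.5 * (x / 12.0) ** 2)
        fit = fit_sideview_profile(x, y)
        assert fit.degenerate

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_sideview_profile(np.arange(5.0), np.ones(5))


class TestAverageWavelength:
    def test_flat_box_centroid(self):
        wl = np.arange(690.0, 731.0)
        em = Spectrum(wl, np.where((wl >= 700) & (wl <= 720), 1.0, 0.0))
        assert average_wavelength(em) == pytest.approx(710.0, abs=0.5)

    def test_narrow_peak_converges_to_its_position(self):
        for width in (8.0, 2.0, 0.6):
            wl = np.arange(600.0, 800.0, 0.1)
            em = Spectrum(wl, np.exp(-0.5 * ((wl - 680.0) / width) ** 2))
            assert average_wavelength(em) == pytest.approx(680.0, abs=0.2)

    def test_step_transmission_truncates_the_box(self):
        wl = np.arange(600.0, 820.0)
        em = Spectrum(wl, np.ones_like(wl))
        step = Spectrum(wl, np.where(wl <= 690.0, 1.0, 0.0))
        lam0 = average_wavelength(em, [step])
        assert lam0 == pytest.approx(660.0, abs=0.5)

    def test_scale_invariance(self):
        wl = np.arange(630.0, 801.0)
        em = Spectrum(wl, np.exp(-0.5 * ((wl - 700) / 30.0) ** 2))
        t = Spectrum(wl, np.clip((wl - 630) / 170.0, 0, 1))
        a = average_wavelength(em, [t])
        b = average_wavelength(
            Spectrum(wl, em.value * 37.0), [Spectrum(wl, t.value * 0.01)]
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_intensity_on_range_rejected(self):
        wl = np.arange(400.0, 500.0)
        em = Spectrum(wl, np.ones_like(wl))
        with pytest.raises(ValueError):
            average_wavelength(em)  # emission entirely outside 630-800 nm
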