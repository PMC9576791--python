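"""Species assignment, output-coordinate methods, chromatic fit, cross-talk."""

import numpy as np
import pandas as pd
import pytest

from splitkit import (
    SectorRegion,
    assign_species,
    bivariate_histogram,
    demix_coordinates,
    estimate_crosstalk,
    fit_chromatic_model,
    photon_ratio,
)
from splitkit.demix import REJECTED_LABEL, SectorConfigError

from conftest import make_pairs


class TestPhotonRatio:
    @pytest.mark.parametrize(
        "i_s,i_l,expected", [(1000, 600, 0.6), (1000, 1000, 1.0), (1000, 3500, 3.5)]
    )
    def test_ratio_values(self, i_s, i_l, expected):
        assert photon_ratio(i_s, i_l) == pytest.approx(expected)

    def test_zero_i_s_rejected(self):
        with pytest.raises(ValueError):
            photon_ratio(0, 100)


class TestBivariateHistogram:
    def test_identical_pairs_fill_one_bin(self):
        pairs = make_pairs(np.full(100, 1000.0), np.full(100, 1000.0))
        h = bivariate_histogram(pairs, bins_per_axis=16)
        assert h.counts.sum() == 100
        assert (h.counts > 0).sum() == 1

    def test_empty_input_gives_zero_histogram(self):
        pairs = make_pairs([], [])
        h = bivariate_histogram(pairs, bins_per_axis=8)
        assert h.counts.sum() == 0

    def test_log_scale_species_form_slope_one_ridges(self, rng):
        """In log-log coordinates each fixed-r species lies on a slope-1 line
        with intercept log10(r); recover both intercepts by least squares."""
        n = 2000
        recovered = []
        for r in (0.6, 3.5):
            totals = rng.integers(1000, 4000, n)
            i_l = rng.binomial(totals, r / (1 + r))
            keep = (i_l > 0) & (totals - i_l > 0)
            i_l = i_l[keep]
            i_s = totals[keep] - i_l
            # least-squares intercept of log10(I_L) - log10(I_S)
            recovered.append(10 ** np.mean(np.log10(i_l) - np.log10(i_s)))
        assert recovered[0] == pytest.approx(0.6, rel=0.05)
        assert recovered[1] == pytest.approx(3.5, rel=0.05)


class TestAssignSpecies:
    sectors = [
        SectorRegion("A", 0.3, 1.0, i_total_min=500),
        SectorRegion("B", 1.0, 5.0, i_total_min=500),
    ]

    def test_in_sector_pair_assigned(self):
        pairs = make_pairs([1250.0], [750.0])  # r = 0.6, total 2000
        labels, rejection = assign_species(pairs, self.sectors)
        assert labels[0] == "A" and rejection == 0.0

    def test_low_intensity_pair_rejected(self):
        pairs = make_pairs([187.5], [112.5])  # r = 0.6, total 300 < 500
        labels, rejection = assign_species(pairs, self.sectors)
        assert labels[0] == REJECTED_LABEL and rejection == 1.0

    def test_r_exactly_at_r_max_falls_in_next_sector(self):
        pairs = make_pairs([1000.0], [1000.0])  # r = 1.0 == A.r_max == B.r_min
        labels, _ = assign_species(pairs, self.sectors)
        assert labels[0] == "B"

    def test_overlapping_sectors_raise_before_assignment(self):
        bad = [SectorRegion("A", 0.3, 1.2), SectorRegion("B", 1.0, 5.0)]
        with pytest.raises(SectorConfigError):
            assign_species(make_pairs([1000.0], [600.0]), bad)

    def test_matches_brute_force_loop(self, rng):
        """Vectorized assignment equals an explicit per-pair loop."""
        n = 10_000
        i_s = rng.uniform(1, 3000, n)
        i_l = rng.uniform(1, 3000, n)
        pairs = make_pairs(i_s, i_l)
        labels, _ = assign_species(pairs, self.sectors)
        for k in rng.integers(0, n, 500):  # spot-check a random subset
            r = i_l[k] / i_s[k]
            tot = i_s[k] + i_l[k]
            expected = REJECTED_LABEL
            for s in self.sectors:
                if s.r_min <= r < s.r_max and tot >= s.i_total_min:
                    expected = s.species_name
            assert labels[k] == expected


class TestDemixCoordinates:
    def test_equal_intensities_make_wmean_equal_mean(self):
        pairs = make_pairs([1000.0], [1000.0], x_l=[24.0], y_l=[8.0])
        labels = np.array(["A"], dtype=object)
        wm = demix_coordinates(pairs, labels, "wmean").tables["A"].xy[0]
        m = demix_coordinates(pairs, labels, "mean").tables["A"].xy[0]
        np.testing.assert_allclose(wm, [12.0, 4.0])
        np.testing.assert_allclose(wm, m)

    def test_weighted_mean_arithmetic(self):
        pairs = make_pairs([500.0], [1500.0], x_l=[24.0], y_l=[8.0])
        labels = np.array(["A"], dtype=object)
        out = demix_coordinates(pairs, labels, "wmean").tables["A"].xy[0]
        np.testing.assert_allclose(out, [18.0, 6.0])  # w_L = 0.75

    def test_brightest_picks_larger_channel_with_tie_to_s(self):
        pairs = make_pairs([500.0, 1000.0], [1500.0, 1000.0],
                           x_s=[0.0, 0.0], x_l=[24.0, 24.0], y_l=[8.0, 8.0])
        labels = np.array(["A", "A"], dtype=object)
        out = demix_coordinates(pairs, labels, "brightest").tables["A"].xy
        np.testing.assert_allclose(out[0], [24.0, 8.0])  # L brighter
        np.testing.assert_allclose(out[1], [0.0, 0.0])  # tie -> S

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            demix_coordinates(make_pairs([1.0], [1.0]), np.array(["A"]), "median")

    def test_output_photons_conserve_i_s_plus_i_l(self, rng):
        n = 200
        pairs = make_pairs(rng.uniform(1, 2000, n), rng.uniform(1, 2000, n),
                           x_s=rng.normal(size=n), x_l=rng.normal(size=n))
        labels = np.where(pairs["r"] < 1.0, "A", "B").astype(object)
        for method in ("brightest", "lambdaS", "lambdaL", "mean", "wmean"):
            res = demix_coordinates(pairs, labels, method)
            got = np.sort(np.concatenate([t.photons for t in res.tables.values()]))
            np.testing.assert_allclose(
                got, np.sort((pairs["i_s"] + pairs["i_l"]).to_numpy())
            )
            assert res.n_assigned + len(res.rejected) == n


class TestChromaticFit:
    def _positions(self, rng, n, span=50_000.0):
        return rng.uniform(0, span, size=(n, 2))

    def test_constant_field_recovered(self, rng):
        n = 10_000
        pos = self._positions(rng, n)
        delta = np.array([3.0, -1.0]) + rng.normal(0, 15.0, size=(n, 2))
        model = fit_chromatic_model(pos + delta, pos, degree=0)
        offsets = model.evaluate(pos[:5])
        np.testing.assert_allclose(offsets[:, 0], 3.0, atol=0.5)
        np.testing.assert_allclose(offsets[:, 1], -1.0, atol=0.5)

    def test_zero_field_gives_null_coefficients(self, rng):
        n = 10_000
        pos = self._positions(rng, n)
        delta = rng.normal(0, 15.0, size=(n, 2))
        model = fit_chromatic_model(pos + delta, pos, degree=0)
        se = 15.0 / np.sqrt(n)
        assert abs(model.coeffs_x[0]) < 3 * se
        assert abs(model.coeffs_y[0]) < 3 * se

    def test_linear_field_slope_recovered(self, rng):
        n = 10_000
        pos = self._positions(rng, n)
        field = np.column_stack([1e-4 * pos[:, 0], np.zeros(n)])
        delta = field + rng.normal(0, 5.0, size=(n, 2))
        model = fit_chromatic_model(pos + delta, pos, degree=1)
        probe = np.array([[10_000.0, 25_000.0], [40_000.0, 25_000.0]])
        dx = model.evaluate(probe)[:, 0]
        slope = (dx[1] - dx[0]) / 30_000.0
        assert slope == pytest.approx(1e-4, rel=0.10)

    def test_collinear_points_raise_rank_error(self, rng):
        n = 500
        x = rng.uniform(0, 1000, n)
        pos = np.column_stack([x, np.zeros(n)])  # all on the y = 0 line
        with pytest.raises(np.linalg.LinAlgError, match="lower"):
            fit_chromatic_model(pos + 1.0, pos, degree=1)

    def test_too_few_pairs_rejected(self, rng):
        pos = self._positions(rng, 20)
        with pytest.raises(ValueError, match="need >="):
            fit_chromatic_model(pos, pos, degree=1)


class TestCrosstalk:
    sectors = [
        SectorRegion("red", 0.0, np.sqrt(0.6 * 3.5)),
        SectorRegion("blue", np.sqrt(0.6 * 3.5), 1e6),
    ]

    def test_pure_sample_has_unit_diagonal(self):
        pairs = make_pairs(np.full(50, 1000.0), np.full(50, 600.0))
        res = estimate_crosstalk(pairs, self.sectors, "red")
        assert res.matrix.loc["red", "red"] == 1.0
        assert res.matrix.loc["red", "blue"] == 0.0

    def test_rows_sum_to_one(self, rng):
        pairs = make_pairs(rng.uniform(1, 2000, 400), rng.uniform(1, 2000, 400))
        res = estimate_crosstalk(pairs, self.sectors, "red")
        assert res.matrix.loc["red"].sum() == pytest.approx(1.0)

    def test_binomial_split_simulation_below_two_percent(self, rng):
        """Two-species binomial splitting at r=0.6 / 3.5 with the boundary at
        their geometric mean misassigns far fewer than 2% either way."""
        n, total = 2000, 2000
        for r, own in ((0.6, "red"), (3.5, "blue")):
            i_l = rng.binomial(total, r / (1 + r), n).astype(float)
            i_l = np.clip(i_l, 1, total - 1)
            pairs = make_pairs(total - i_l, i_l)
            res = estimate_crosstalk(pairs, self.sectors, own)
            other = "blue" if own == "red" else "red"
            assert res.matrix.loc[own, other] < 0.02

    def test_matches_brute_force_counting(self, rng):
        n = 10_000
        pairs = make_pairs(rng.uniform(1, 3000, n), rng.uniform(1, 3000, n))
        res = estimate_crosstalk(pairs, self.sectors, "red")
        # oracle: direct loop over the pair list
        n_red = n_blue = 0
        for i_s, i_l in zip(pairs["i_s"], pairs["i_l"]):
            r = i_l / i_s
            if 0.0 <= r < np.sqrt(0.6 * 3.5):
                n_red += 1
            elif r < 1e6:
                n_blue += 1
        assert res.matrix.loc["red", "red"] == pytest.approx(n_red / (n_red + n_blue))
        assert res.matrix.loc["red", "blue"] == pytest.approx(n_blue / (n_red + n_blue))

    def test_no_assigned_pairs_is_an_error(self):
        pairs = make_pairs([1e7], [1.0])  # r ~ 1e-7 but huge total: still red
        tight = [
            SectorRegion("red", 0.5, 0.7, i_total_min=1e9),
            SectorRegion("blue", 1.0, 2.0, i_total_min=1e9),
        ]
        with pytest.raises(ZeroDivisionError):
            estimate_crosstalk(pairs, tight, "red")
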