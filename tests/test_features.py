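"""Feature bank: band statistics, bispectral line statistics, matrix
assembly and [0, 1] scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from awakeosa.catalog import full_catalog, published_definitions
from awakeosa.features import (
    FeatureTable,
    SubjectSignalSummary,
    band_mean_difference,
    bispectrum_line_statistic,
    build_feature_matrix,
    psd_band_statistic,
    scale_unit_interval,
)
from awakeosa.spectral import BispectrumEstimate, SpectrumEstimate

FREQS = np.arange(0.0, 5121.0, 10.0)


def spectrum(power):
    return SpectrumEstimate(FREQS, np.asarray(power, dtype=float))


def bispec(mag):
    grid = np.arange(0.0, 2001.0, 20.0)
    return BispectrumEstimate(grid, np.asarray(mag, dtype=complex))


class TestPsdStatistics:
    def test_constant_psd_statistics(self):
        c = 4.0
        est = spectrum(np.full(FREQS.size, c))
        band = (100.0, 300.0)
        assert psd_band_statistic(est, band, "band_mean", scale="linear") == pytest.approx(c)
        assert psd_band_statistic(est, band, "geometric_mean") == pytest.approx(c)
        assert psd_band_statistic(est, band, "slope_mean") == 0.0
        assert psd_band_statistic(est, band, "centroid") == pytest.approx(200.0)

    def test_first_peak_below_cutoff(self):
        p = np.full(FREQS.size, 1.0)
        for f0, h in ((180, 10.0), (400, 100.0)):
            p += h * np.exp(-0.5 * ((FREQS - f0) / 12.0) ** 2)
        assert psd_band_statistic(spectrum(p), (0, 550), "first_peak_freq") == pytest.approx(180)
        assert psd_band_statistic(spectrum(p), (0, 550), "mean_max_peak_freq") == pytest.approx(290)

    def test_no_peak_returns_missing(self):
        flat = spectrum(np.ones(FREQS.size))
        assert np.isnan(psd_band_statistic(flat, (0, 550), "first_peak_freq"))

    def test_centroid_matches_brute_force_on_linear_ramp(self):
        p = np.linspace(1.0, 5.0, FREQS.size)
        est = spectrum(p)
        idx = (FREQS >= 100) & (FREQS <= 300)
        f, w = FREQS[idx], p[idx]
        c_ref = np.sum(f * w) / np.sum(w)
        bw_ref = np.sqrt(np.sum((f - c_ref) ** 2 * w) / np.sum(w))
        assert psd_band_statistic(est, (100, 300), "centroid") == pytest.approx(c_ref, rel=1e-12)
        assert psd_band_statistic(est, (100, 300), "centroid_bandwidth") == pytest.approx(bw_ref, rel=1e-12)

    def test_band_mean_difference_composition(self, rng):
        est = spectrum(rng.uniform(0.5, 5.0, FREQS.size))
        a, b = (130.0, 235.0), (1260.0, 1410.0)
        diff = band_mean_difference(est, a, b)
        assert diff == pytest.approx(
            psd_band_statistic(est, a, "band_mean") - psd_band_statistic(est, b, "band_mean")
        )

    def test_equal_bands_difference_is_zero(self):
        est = spectrum(np.ones(FREQS.size))
        assert band_mean_difference(est, (100, 200), (300, 400)) == 0.0

    def test_empty_band_is_error(self):
        with pytest.raises(ValueError):
            psd_band_statistic(spectrum(np.ones(FREQS.size)), (5200, 5300), "band_mean")

    def test_band_statistics_stable_under_grid_refinement(self):
        # same smooth spectrum on a 2x finer grid: statistics within 2%
        shape = lambda f: 1.0 + np.exp(-0.5 * ((f - 300) / 150.0) ** 2)
        coarse = SpectrumEstimate(FREQS, shape(FREQS))
        fine_f = np.arange(0.0, 5121.0, 5.0)
        fine = SpectrumEstimate(fine_f, shape(fine_f))
        for op in ("band_mean", "geometric_mean", "centroid", "centroid_bandwidth"):
            a = psd_band_statistic(coarse, (100, 600), op)
            b = psd_band_statistic(fine, (100, 600), op)
            assert a == pytest.approx(b, rel=0.02)


class TestBispectralLines:
    def test_constant_diagonal_weight_center_is_band_midpoint(self):
        grid_n = 101
        est = bispec(np.ones((grid_n, grid_n)))
        wc = bispectrum_line_statistic(est, "main_diagonal", (400, 800), "bis_weight_center")
        assert wc == pytest.approx(600.0)

    def test_point_mass_weight_center_at_the_point(self):
        mag = np.zeros((101, 101))
        mag[30, 30] = 5.0  # f0 = 600 Hz
        est = bispec(mag)
        wc = bispectrum_line_statistic(est, "main_diagonal", (0, 2000), "bis_weight_center")
        assert wc == pytest.approx(600.0)

    @pytest.mark.parametrize("line", ["main_diagonal", "negative_diagonal", "half_f_line", "two_f_line"])
    def test_moments_match_summation_oracle(self, rng, line):
        est = bispec(rng.uniform(0, 2, (101, 101)))
        from awakeosa.features import _line_samples

        f, m = _line_samples(est, line, (200, 900))
        m1 = bispectrum_line_statistic(est, line, (200, 900), "bis_moment1")
        m2 = bispectrum_line_statistic(est, line, (200, 900), "bis_moment2")
        assert m1 == pytest.approx(np.sum(f * m) / f.size, rel=1e-12)
        assert m2 == pytest.approx(np.sum(f**2 * m) / f.size, rel=1e-12)

    def test_empty_intersection_is_error(self):
        est = bispec(np.ones((101, 101)))
        with pytest.raises(ValueError):
            bispectrum_line_statistic(est, "main_diagonal", (3000, 4000), "bis_mean")


def _summary(sid, seed=0):
    rng = np.random.default_rng(seed)
    s = SubjectSignalSummary(sid)
    for man in ("mouth", "nose"):
        for ph in ("inspiration", "expiration"):
            # smooth PSD with a clear peak so peak operators find one
            p = 1.0 + 50 * np.exp(-0.5 * ((FREQS - rng.uniform(200, 400)) / 60) ** 2)
            s.spectra[(man, ph)] = SpectrumEstimate(FREQS, p * rng.uniform(0.5, 2))
            grid = np.arange(0.0, 5121.0, 20.0)
            s.bispectra[(man, ph)] = BispectrumEstimate(
                grid, rng.uniform(0.1, 1, (grid.size, grid.size)).astype(complex)
            )
            s.fractal[(man, ph)] = {"katz": 1.2, "higuchi": 1.8, "hurst": 0.4}
    return s


class TestMatrixAssembly:
    def test_small_matrix_shape_and_completeness(self):
        defs = published_definitions()[:12]
        summaries = {f"s{i}": _summary(f"s{i}", i) for i in range(10)}
        table = build_feature_matrix(summaries, defs)
        assert table.data.shape == (10, 12)
        assert not table.data.isna().any().any()

    def test_default_catalog_size_in_expected_range(self):
        n = len(full_catalog())
        assert 200 <= n <= 300

    def test_missing_maneuver_leaves_row_with_missing_entries(self):
        defs = [d for d in published_definitions() if d.operator != "first_peak_freq"]
        s = _summary("s0")
        for key in list(s.spectra):
            if key[0] == "mouth":
                del s.spectra[key]
                del s.bispectra[key]
                del s.fractal[key]
        with pytest.warns(UserWarning, match="missing"):
            table = build_feature_matrix({"s0": s}, defs)
        mouth_cols = [d.feature_id for d in defs if d.maneuver == "mouth"]
        nose_cols = [d.feature_id for d in defs if d.maneuver == "nose"]
        assert table.data.loc["s0", mouth_cols].isna().all()
        assert table.data.loc["s0", nose_cols].notna().all()

    def test_deterministic_given_inputs(self):
        defs = published_definitions()[:8]
        summaries = {f"s{i}": _summary(f"s{i}", i) for i in range(4)}
        a = build_feature_matrix(summaries, defs)
        b = build_feature_matrix(summaries, defs)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestScaling:
    def test_minmax_example(self):
        table = FeatureTable(pd.DataFrame({"f": [2.0, 4.0, 6.0]}, index=list("abc")))
        scaled = scale_unit_interval(table, ["a", "b", "c"])
        assert list(scaled.data["f"]) == [0.0, 0.5, 1.0]

    def test_test_rows_clipped(self):
        table = FeatureTable(
            pd.DataFrame({"f": [2.0, 4.0, 6.0, 8.0]}, index=list("abcd"))
        )
        scaled = scale_unit_interval(table, ["a", "b", "c"])
        assert scaled.data.loc["d", "f"] == 1.0

    def test_rescaling_with_own_parameters_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("vwxyz"))
        once = scale_unit_interval(FeatureTable(df), df.index)
        twice = scale_unit_interval(once, df.index)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_constant_feature_dropped_with_warning(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            scaled = scale_unit_interval(FeatureTable(df), df.index)
        assert list(scaled.data.columns) == ["ok"]

    @given(st.integers(0, 10_000))
    def test_training_values_always_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        df = pd.DataFrame(r.normal(0, r.uniform(0.5, 50), size=(12, 3)))
        scaled = scale_unit_interval(FeatureTable(df), df.index)
        assert ((scaled.data >= 0) & (scaled.data <= 1)).all().all()
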