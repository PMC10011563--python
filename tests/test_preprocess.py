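import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chertspec as cs
from chertspec.preprocess import (
    PreprocessConfig,
    SegmentedSpectrum,
    lower_convex_hull,
    preprocess_spectrum,
    resample_segments,
)

from conftest import single_band_spectrum


def unit_grid_spectrum():
    w = np.arange(650.0, 4001.0)
    rng = np.random.default_rng(0)
    return cs.Spectrum("unit", w, rng.uniform(0.1, 1.0, w.size))


def chord_oracle_baseline(w, y):
    """O(n^3) rubberband oracle: at each point the baseline is the highest
    chord (line through two data points) that stays at or below the data
    everywhere."""
    n = len(w)
    base = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (w[j] - w[i])
            line = y[i] + slope * (w - w[i])
            if np.all(line <= y + 1e-12):
                base = np.maximum(base, line)
    return base


class TestTruncateAndCut:
    def test_default_windows_point_counts(self):
        """Unit grid 4000..650: closed windows [2700,3000] and [1400,1760]
        contain 301 and 361 points."""
        seg = cs.truncate_and_cut(unit_grid_spectrum())
        assert [s[0] for s in seg.segments] == [(1400.0, 1760.0), (2700.0, 3000.0)]
        assert [len(s[1]) for s in seg.segments] == [361, 301]

    def test_no_cut_single_segment(self):
        cfg = PreprocessConfig(cut_ranges=())
        seg = cs.truncate_and_cut(unit_grid_spectrum(), cfg)
        assert len(seg.segments) == 1
        assert seg.segments[0][0] == (1400.0, 3000.0)

    def test_spectrum_outside_keep_range_errors(self):
        w = np.arange(650.0, 901.0)
        s = cs.Spectrum("low", w, np.ones_like(w) * 0.5)
        with pytest.raises(ValueError, match="outside keep_range"):
            cs.truncate_and_cut(s)

    def test_cut_outside_keep_range_rejected(self):
        with pytest.raises(ValueError, match="not inside keep_range"):
            PreprocessConfig(cut_ranges=((3500.0, 3200.0),))


class TestRubberband:
    def _segmented(self, w, y):
        return SegmentedSpectrum("t", [((float(w[0]), float(w[-1])),
                                        np.asarray(w, float), np.asarray(y, float))])

    def test_line_corrects_to_zero(self):
        w = np.arange(10.0)
        seg = cs.rubberband_baseline(self._segmented(w, 0.3 * w + 2.0))
        np.testing.assert_allclose(seg.segments[0][2], 0.0, atol=1e-12)

    def test_five_point_chord_oracle(self):
        w = np.arange(5.0)
        y = np.array([1.0, 0.2, 0.9, 0.1, 1.0])
        seg = cs.rubberband_baseline(self._segmented(w, y))
        np.testing.assert_allclose(seg.segments[0][2], y - chord_oracle_baseline(w, y),
                                   atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 25))
    def test_matches_chord_oracle_and_affine_invariant(self, seed, n):
        """Hull baseline equals the brute-force chord envelope, and adding
        any affine function of wavenumber leaves the correction unchanged."""
        rng = np.random.default_rng(seed)
        w = np.sort(rng.uniform(0, 100, n))
        w += np.arange(n) * 1e-6  # strict monotonicity
        y = rng.uniform(0, 1, n)
        seg = cs.rubberband_baseline(self._segmented(w, y))
        np.testing.assert_allclose(seg.segments[0][2], y - chord_oracle_baseline(w, y),
                                   atol=1e-9)
        a, b = rng.uniform(-5, 5, 2)
        seg2 = cs.rubberband_baseline(self._segmented(w, y + a * w + b))
        np.testing.assert_allclose(seg2.segments[0][2], seg.segments[0][2], atol=1e-8)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        w = np.arange(30.0)
        seg = cs.rubberband_baseline(self._segmented(w, rng.uniform(0, 1, 30)))
        twice = cs.rubberband_baseline(seg)
        np.testing.assert_allclose(twice.segments[0][2], seg.segments[0][2], atol=1e-12)

    def test_short_segment_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            cs.rubberband_baseline(self._segmented([0.0, 1.0], [0.0, 1.0]))


class TestMinMax:
    def test_linear_map(self):
        seg = SegmentedSpectrum("t", [((0.0, 2.0), np.array([0.0, 1.0, 2.0]),
                                       np.array([0.2, 0.6, 1.0]))])
        out, rep = cs.minmax_normalize(seg)
        np.testing.assert_allclose(out.segments[0][2], [0.0, 0.5, 1.0])

    def test_constant_spectrum_errors(self):
        seg = SegmentedSpectrum("t", [((0.0, 2.0), np.array([0.0, 1.0, 2.0]),
                                       np.full(3, 0.7))])
        with pytest.raises(ValueError, match="constant"):
            cs.minmax_normalize(seg)

    def test_synthetic_anchor_at_silica_band(self):
        """The dominant ~1615 silica overtone is the global maximum of every
        preprocessed synthetic spectrum."""
        cfg = cs.AssemblageConfig(seed=5)
        prof = cs.default_profiles()["eukaryote"]
        sp, _ = cs.generate_spectrum(prof, cfg, seed=5)
        _, report = preprocess_spectrum(sp)
        assert report["max_at_anchor"]
        assert abs(report["max_wavenumber"] - 1615.0) <= 15.0


class TestSavgol:
    def test_quadratic_second_derivative(self):
        w = np.arange(0.0, 50.0)
        a = 0.37
        s = cs.Spectrum("q", w, a * w**2)
        d = cs.savgol_derivative(s, 9, 2, deriv=2)
        np.testing.assert_allclose(d.intensities[5:-5], 2 * a, atol=1e-8)

    def test_gaussian_minimum_at_band_center(self):
        s = single_band_spectrum(center=2000.0, fwhm=40.0, step=1.0)
        d = cs.savgol_derivative(s, 9, 2, deriv=2)
        assert abs(s.wavenumbers[np.argmin(d.intensities)] - 2000.0) <= 1.0

    def test_even_window_rejected(self):
        s = single_band_spectrum()
        with pytest.raises(ValueError, match="odd"):
            cs.savgol_derivative(s, window=4)

    def test_non_uniform_grid_instructs_resampling(self):
        w = np.array([0.0, 1.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        s = cs.Spectrum("nu", w, np.sin(w))
        with pytest.raises(ValueError, match="resample"):
            cs.savgol_derivative(s)


class TestResample:
    def test_identity_on_grid(self):
        s = unit_grid_spectrum()
        sset = cs.SpectrumSet([s])
        out = cs.resample_common_grid(sset, step=1.0)
        np.testing.assert_allclose(out[0].intensities, s.intensities, atol=1e-12)

    def test_two_point_midpoint(self):
        s = cs.Spectrum("mid", [0.0, 2.0], [0.0, 2.0])
        out = cs.resample_common_grid(cs.SpectrumSet([s]), step=1.0)
        assert np.interp(1.0, out[0].wavenumbers, out[0].intensities) == 1.0

    def test_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(8)
        w = np.sort(rng.uniform(1000, 2000, 60))
        y = rng.uniform(0, 1, 60)
        seg = SegmentedSpectrum("r", [((1100.0, 1900.0),
                                       w[(w >= 1100) & (w <= 1900)],
                                       y[(w >= 1100) & (w <= 1900)])])
        out = resample_segments(seg, 5.0)
        gw, gy = out.segments[0][1], out.segments[0][2]
        # independent oracle: manual piecewise-linear evaluation per point
        src_w, src_y = seg.segments[0][1], seg.segments[0][2]
        for xi, yi in zip(gw, gy):
            j = np.searchsorted(src_w, xi)
            if j == 0:
                expected = src_y[0]
            else:
                x0, x1 = src_w[j - 1], src_w[j]
                expected = src_y[j - 1] + (src_y[j] - src_y[j - 1]) * (xi - x0) / (x1 - x0)
            assert abs(yi - expected) < 1e-12


class TestPipeline:
    def test_identical_inputs_identical_rows(self):
        s = unit_grid_spectrum()
        clones = cs.SpectrumSet([
            cs.Spectrum(f"c{i}", s.wavenumbers, s.intensities) for i in range(3)
        ])
        matrix, _, _ = cs.preprocess_pipeline(clones)
        assert (matrix.nunique(axis=0) == 1).all()

    def test_log_lists_four_steps(self):
        sp, _ = cs.generate_spectrum(cs.default_profiles()["eukaryote"],
                                     cs.AssemblageConfig(seed=1), seed=1)
        seg, _ = preprocess_spectrum(sp)
        steps = [e["step"] for e in seg.preprocessing_log]
        assert steps == ["truncate_and_cut", "resample", "rubberband_baseline",
                         "minmax_normalize"]

    def test_matrix_shape_matches_retained_grid(self):
        cfg = cs.AssemblageConfig(
            n_per_group={"eukaryote": 12, "prokaryote": 8, "unknown": 0}, seed=2
        )
        sset, _ = cs.generate_assemblage(cfg)
        matrix, _, _ = cs.preprocess_pipeline(sset)
        # [1400,1760] and [2700,3000] at 2 cm^-1: 181 + 151 points
        assert matrix.shape == (20, 332)

    def test_deterministic_and_scale_invariant(self):
        """Re-running is bit-identical, and scaling intensities by c > 0
        changes nothing (rubberband is linear, min-max removes scale)."""
        sp, _ = cs.generate_spectrum(cs.default_profiles()["prokaryote"],
                                     cs.AssemblageConfig(seed=4), seed=4)
        m1, _, _ = cs.preprocess_pipeline(cs.SpectrumSet([sp]))
        m2, _, _ = cs.preprocess_pipeline(cs.SpectrumSet([sp]))
        assert m1.equals(m2)
        scaled = cs.Spectrum(sp.specimen_id, sp.wavenumbers, 3.7 * sp.intensities)
        m3, _, _ = cs.preprocess_pipeline(cs.SpectrumSet([scaled]))
        np.testing.assert_allclose(m3.to_numpy(), m1.to_numpy(), atol=1e-12)
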