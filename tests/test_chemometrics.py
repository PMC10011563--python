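import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import chertspec as cs
from chertspec.chemometrics import _exact_u_pmf
from chertspec.preprocess import preprocess_spectrum


def two_band_ch_spectrum(a_ch3, a_ch2, fwhm=20.0):
    """CH3 (2960) + CH2 (2922) bands on an otherwise chert-like spectrum."""
    prof = cs.BandProfile("toy", {
        "CH3_asym": cs.BandSpec(2960.0, a_ch3, fwhm, sigma_log=0.0),
        "CH2_asym": cs.BandSpec(2922.0, a_ch2, fwhm, sigma_log=0.0),
        "amide_CO": cs.BandSpec(1650.0, 0.1, 25.0, sigma_log=0.0),
        "N_moiety_1560": cs.BandSpec(1560.0, 0.05, 25.0, sigma_log=0.0),
        "ester_CO": cs.BandSpec(1735.0, 0.05, 25.0, sigma_log=0.0),
    })
    cfg = cs.AssemblageConfig(seed=0, noise_sd=0.0, sigma_abundance=0.0,
                              silica_sigma_log=0.0,
                              baseline_offset_range=(0.0, 0.0),
                              baseline_coeff_range=(0.0, 0.0))
    sp = cs.noiseless_spectrum(prof, cfg)
    seg, _ = preprocess_spectrum(sp)
    return seg


class TestR32:
    def test_equal_amplitudes_give_unity(self):
        assert cs.r32(two_band_ch_spectrum(0.3, 0.3)) == pytest.approx(1.0, rel=0.02)

    def test_half_amplitude_gives_half(self):
        assert cs.r32(two_band_ch_spectrum(0.3, 0.6)) == pytest.approx(0.5, rel=0.02)

    def test_no_aliphatic_signal_errors(self):
        w = np.arange(650.0, 4001.0)
        y = np.exp(-4 * np.log(2) * ((w - 1615.0) / 60.0) ** 2)  # silica only
        seg, _ = preprocess_spectrum(cs.Spectrum("sil", w, y))
        with pytest.raises(ValueError, match="no aliphatic signal"):
            cs.r32(seg)


class TestMoietyRatios:
    def test_zero_ester_band_gives_zero_ratio(self):
        prof = cs.BandProfile("noester", {
            "CH3_asym": cs.BandSpec(2960.0, 0.1, sigma_log=0.0),
            "CH2_asym": cs.BandSpec(2922.0, 0.2, sigma_log=0.0),
        })
        cfg = cs.AssemblageConfig(seed=0)
        seg, _ = preprocess_spectrum(cs.noiseless_spectrum(prof, cfg))
        r = cs.moiety_ratios(seg)
        # only silica shoulders remain near 1735; after the rubberband they
        # leave a small residual, far below any real ester band
        assert r["ester_CH2"] < 0.5

    def test_group_ordering_matches_profiles(self, ratios):
        g = ratios.groupby("group")[["CO_CH2", "N_CH2", "ester_CH2"]].mean()
        assert g.loc["eukaryote", "CO_CH2"] > g.loc["prokaryote", "CO_CH2"]
        assert g.loc["eukaryote", "N_CH2"] > g.loc["prokaryote", "N_CH2"]
        assert g.loc["eukaryote", "ester_CH2"] > g.loc["prokaryote", "ester_CH2"]

    def test_ch2_silica_equals_ch2_when_anchor_is_max(self, preprocessed):
        """After min-max normalization the 1615 band reads 1.0, so the
        CH2/silica ratio equals the CH2 intensity itself."""
        _, segs, reports = preprocessed
        seg, rep = segs[0], reports[0]
        assert rep["max_at_anchor"]
        r = cs.moiety_ratios(seg)
        from chertspec.bands import catalogue_by_label
        ch2 = cs.band_intensity(seg, catalogue_by_label()["CH2_asym"])
        assert r["CH2_silica"] == pytest.approx(ch2, rel=1e-6)

    def test_ratios_invariant_under_intensity_scaling(self):
        cfg = cs.AssemblageConfig(seed=6)
        sp, _ = cs.generate_spectrum(cs.default_profiles()["eukaryote"], cfg, seed=6)
        seg1, _ = preprocess_spectrum(sp)
        scaled = cs.Spectrum(sp.specimen_id, sp.wavenumbers, 11.0 * sp.intensities)
        seg2, _ = preprocess_spectrum(scaled)
        r1, r2 = cs.moiety_ratios(seg1), cs.moiety_ratios(seg2)
        for k in r1:
            assert r1[k] == pytest.approx(r2[k], rel=1e-9)


def brute_force_two_sided_p(x, y):
    """Enumerate every rank split of the pooled sample; two-sided p is the
    fraction of splits at least as extreme (|U - n1 n2 / 2|) as observed."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * len(y) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - center) >= abs(u_obs - center) - 1e-9
        total += 1
    return count / total


class TestMannWhitney:
    def test_perfect_mixing(self):
        u, p = cs.mann_whitney_u([1, 4], [2, 3], method="exact")
        assert u == 2.0 and p == 1.0

    def test_complete_separation(self):
        u, p = cs.mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert u == 0.0
        assert p == pytest.approx(2 / 20)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10**6))
    def test_u_sum_property_and_enumeration(self, n1, n2, seed):
        """U(x,y) + U(y,x) = n1*n2, and the exact p equals full enumeration
        over all rank splits for n1 + n2 <= 10."""
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = vals[:n1], vals[n1:]
        u_xy, p = cs.mann_whitney_u(x, y, method="exact")
        u_yx, _ = cs.mann_whitney_u(y, x, method="exact")
        assert u_xy + u_yx == pytest.approx(n1 * n2)
        assert p == pytest.approx(brute_force_two_sided_p(x, y))

    def test_matches_scipy_exact(self):
        """Independent cross-check against scipy's exact implementation."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.permutation(np.arange(30.0))[:8]
            rest = np.setdiff1d(np.arange(30.0), x)
            y = rng.choice(rest, 12, replace=False)
            u, p = cs.mann_whitney_u(x, y, method="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            # scipy's U counts pairs x > y as well (with their convention U1)
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            n1, n2 = rng.integers(4, 12, 2)
            vals = rng.normal(size=n1 + n2) + np.linspace(0, 1e-9, n1 + n2)
            x, y = vals[:n1], vals[n1:]
            _, pe = cs.mann_whitney_u(x, y, method="exact")
            _, pn = cs.mann_whitney_u(x, y, method="normal_approx")
            worst = max(worst, abs(pe - pn))
        assert worst <= 0.05

    def test_exact_refuses_ties(self):
        with pytest.raises(ValueError, match="ties"):
            cs.mann_whitney_u([1, 2, 2], [2, 3], method="exact")

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            cs.mann_whitney_u([], [1.0])

    def test_pmf_is_a_symmetric_distribution(self):
        pmf = _exact_u_pmf(5, 7)
        assert pmf.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-15)


class TestShapiroGate:
    def test_normal_samples_flagged_normal(self):
        hits = sum(
            cs.shapiro_wilk_flag(np.random.default_rng(s).normal(size=200))[2]
            for s in range(20)
        )
        assert hits >= 18

    def test_exponential_samples_flagged_non_normal(self):
        hits = sum(
            not cs.shapiro_wilk_flag(np.random.default_rng(s).exponential(size=50))[2]
            for s in range(20)
        )
        assert hits >= 18

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            cs.shapiro_wilk_flag([0.1, 0.2])


class TestCompareGroups:
    def test_group_summary_fields(self, ratios):
        cmp = cs.compare_groups(ratios, "R32")
        assert cmp.n1 == 9 and cmp.n2 == 40
        assert 0 <= cmp.U <= cmp.n1 * cmp.n2
        assert 0 < cmp.p_value <= 1
        prok = ratios.loc[ratios["group"] == "prokaryote", "R32"]
        assert cmp.mean1 == pytest.approx(prok.mean())
        assert cmp.sem1 == pytest.approx(prok.std(ddof=1) / np.sqrt(9))

    def test_shifted_groups_detected(self, ratios):
        cmp = cs.compare_groups(ratios, "CO_CH2")
        assert cmp.p_value < 0.01

    def test_missing_group_errors(self, ratios):
        euk_only = ratios[ratios["group"] == "eukaryote"]
        with pytest.raises(ValueError, match="group missing"):
            cs.compare_groups(euk_only, "R32")
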