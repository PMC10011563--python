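"""Synthetic chert-fossil ATR-FTIR spectra with known ground truth.

A generated spectrum is the sum of

* seven quartz overtone bands (~1995, 1870, 1793, 1684, 1615, 1525,
  1492 cm^-1) present in every specimen, the ~1615 cm^-1 band strictly
  dominant so min-max normalization anchors there;
* a broad OH absorption hump centred near 3400 cm^-1 (discarded by
  truncation, but present so truncation is genuinely exercised);
* group-specific organic bands in the 3000-2800 and 1760-1400 cm^-1
  intervals — the prokaryote profile has ~1.5x stronger aliphatic CH
  stretches and a stronger absolute ester C=O band, the eukaryote profile
  stronger carbonyl / carboxyl / N-moiety bands;
* a weak polynomial baseline drift and iid Gaussian noise.

Amplitude variation is split into a shared per-specimen organic-abundance
factor (log-normal, sigma_log = 0.08) and independent per-band jitter
(sigma_log = 0.08).  The modest abundance dispersion emulates the regime
the chemotaxonomic method presumes and real chert assemblages exhibit:
between-specimen differences are chiefly compositional, so unsupervised
axes sort by chemistry rather than by the amount of organic matter (the
`abundance_only_config` control inverts this).  Every draw is recorded in
a truth table so each pipeline stage can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Spectrum, SpectrumSet
from .preprocess import PreprocessConfig, preprocess_spectrum

SILICA_BANDS = {
    1995.0: 0.12, 1870.0: 0.15, 1793.0: 0.20, 1684.0: 0.25,
    1615.0: 1.00, 1525.0: 0.18, 1492.0: 0.15,
}

ORGANIC_CENTERS = {
    "CH3_asym": 2960.0, "CH2_asym": 2922.0, "CH2_sym": 2851.0,
    "ester_CO": 1735.0, "carboxyl_CO": 1715.0, "amide_CO": 1650.0,
    "N_moiety_1560": 1560.0, "N_moiety_1540": 1540.0, "CH_bend": 1460.0,
}


@dataclass(frozen=True)
class BandSpec:
    center: float
    median_amplitude: float
    fwhm: float = 25.0
    shape: str = "gaussian"
    sigma_log: float = 0.08      # per-band log-normal jitter

    def __post_init__(self):
        if self.median_amplitude < 0 or self.fwhm <= 0:
            raise ValueError("amplitude must be >= 0 and fwhm > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class BandProfile:
    """Organic band amplitude profile of one group (label -> BandSpec)."""

    name: str
    bands: Mapping[str, BandSpec]

    def scaled(self, factor: float) -> "BandProfile":
        return BandProfile(self.name, {
            k: replace(b, median_amplitude=b.median_amplitude * factor)
            for k, b in self.bands.items()
        })


def _profile(name: str, amplitudes: Mapping[str, float]) -> BandProfile:
    return BandProfile(name, {
        label: BandSpec(ORGANIC_CENTERS[label], amp) for label, amp in amplitudes.items()
    })


def default_profiles() -> dict[str, BandProfile]:
    """Group band-amplitude profiles.

    The prokaryote profile has lipid CH medians ~1.5x the eukaryote's and a
    slightly stronger absolute ester band; the eukaryote profile has
    carbonyl/carboxyl/N-moiety medians high enough that its expected
    C=O/CH2 and N/CH2 ratios exceed the prokaryote's by well over 1.5x.
    Both profiles keep the methyl/methylene ratio near the 0.25-0.63
    range observed for fossil and living aliphatic biomass.
    """
    euk = _profile("eukaryote", {
        "CH3_asym": 0.15, "CH2_asym": 0.36, "CH2_sym": 0.24,
        "ester_CO": 0.10, "carboxyl_CO": 0.16, "amide_CO": 0.32,
        "N_moiety_1560": 0.20, "N_moiety_1540": 0.16, "CH_bend": 0.12,
    })
    prok = _profile("prokaryote", {
        "CH3_asym": 0.234, "CH2_asym": 0.54, "CH2_sym": 0.36,
        "ester_CO": 0.12, "carboxyl_CO": 0.07, "amide_CO": 0.13,
        "N_moiety_1560": 0.08, "N_moiety_1540": 0.07, "CH_bend": 0.18,
    })
    return {"eukaryote": euk, "prokaryote": prok}


@dataclass
class AssemblageConfig:
    """Stated world of the synthetic assemblage.

    Defaults mirror the studied assemblage: 40 eukaryotes, 9 prokaryotes
    (and optionally unknowns generated from a chosen profile); spectra on a
    4000-650 cm^-1 grid at 2 cm^-1 spacing; the 1615 cm^-1 silica band
    dominant in every spectrum.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"eukaryote": 40, "prokaryote": 9, "unknown": 0}
    )
    profiles: dict = field(default_factory=default_profiles)
    unknown_source_profile: str = "eukaryote"
    silica_amplitudes: dict = field(default_factory=lambda: dict(SILICA_BANDS))
    silica_fwhm: float = 60.0
    silica_sigma_log: float = 0.05
    oh_center: float = 3400.0
    oh_fwhm: float = 350.0
    oh_amplitude: float = 0.35
    baseline_offset_range: tuple[float, float] = (0.0, 0.03)
    baseline_coeff_range: tuple[float, float] = (-0.02, 0.02)
    noise_sd: float = 0.002
    grid: tuple[float, float, float] = (650.0, 4000.0, 2.0)
    sigma_abundance: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        amps = self.silica_amplitudes
        if 1615.0 not in amps or amps[1615.0] <= max(
            v for c, v in amps.items() if c != 1615.0
        ):
            raise ValueError("silica 1615 amplitude must dominate the other bands")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + step / 2, step)


def band_shape(w: np.ndarray, center: float, fwhm: float, shape: str) -> np.ndarray:
    """Unit-amplitude band profile evaluated on grid `w`."""
    if shape == "gaussian":
        return np.exp(-4.0 * np.log(2.0) * ((w - center) / fwhm) ** 2)
    if shape == "lorentzian":
        return 1.0 / (1.0 + (2.0 * (w - center) / fwhm) ** 2)
    raise ValueError(f"unknown shape {shape!r}")


def _mineral_signal(w: np.ndarray, cfg: AssemblageConfig,
                    silica_factors: Mapping[float, float] | None = None,
                    oh_factor: float = 1.0) -> np.ndarray:
    y = np.zeros_like(w)
    for center, amp in cfg.silica_amplitudes.items():
        f = 1.0 if silica_factors is None else silica_factors[center]
        y += amp * f * band_shape(w, center, cfg.silica_fwhm, "gaussian")
    y += cfg.oh_amplitude * oh_factor * band_shape(w, cfg.oh_center, cfg.oh_fwhm, "gaussian")
    return y


def noiseless_spectrum(
    profile: BandProfile,
    cfg: AssemblageConfig | None = None,
    use_mean_amplitudes: bool = False,
) -> Spectrum:
    """The deterministic noiseless spectrum of a profile (no drift, unit
    abundance).  With ``use_mean_amplitudes`` each band enters at its
    log-normal mean, median * exp(sigma_log^2 / 2), rather than its median;
    that variant is the first-order expectation of a generated spectrum and
    is the analytic oracle used by :func:`expected_ratio`."""
    cfg = cfg or AssemblageConfig()
    w = cfg.wavenumbers()
    if use_mean_amplitudes:
        mf = float(np.exp(cfg.silica_sigma_log**2 / 2.0))
        y = _mineral_signal(w, cfg, {c: mf for c in cfg.silica_amplitudes}, mf)
    else:
        y = _mineral_signal(w, cfg)
    for b in profile.bands.values():
        amp = b.median_amplitude
        if use_mean_amplitudes:
            amp *= float(np.exp((cfg.sigma_abundance**2 + b.sigma_log**2) / 2.0))
        y += amp * band_shape(w, b.center, b.fwhm, b.shape)
    return Spectrum(f"noiseless_{profile.name}", w, y,
                    metadata={"group": profile.name if profile.name in
                              ("eukaryote", "prokaryote") else "unknown"})


def generate_spectrum(
    profile: BandProfile,
    cfg: AssemblageConfig,
    seed: int | np.random.Generator,
    specimen_id: str = "synthetic",
    group_label: str | None = None,
) -> tuple[Spectrum, dict]:
    """Draw one spectrum from a profile; returns (spectrum, truth record).

    The truth record stores the abundance factor, every drawn band
    amplitude and the baseline coefficients, so recovery tests can compare
    measured intensities against what was generated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = cfg.wavenumbers()
    abundance = float(np.exp(rng.normal(0.0, cfg.sigma_abundance)))
    amps = {
        label: b.median_amplitude * abundance * float(np.exp(rng.normal(0.0, b.sigma_log)))
        for label, b in profile.bands.items()
    }
    silica_factors = {
        c: float(np.exp(rng.normal(0.0, cfg.silica_sigma_log)))
        for c in cfg.silica_amplitudes
    }
    oh_factor = float(np.exp(rng.normal(0.0, cfg.silica_sigma_log)))
    y = _mineral_signal(w, cfg, silica_factors, oh_factor)
    for label, b in profile.bands.items():
        y += amps[label] * band_shape(w, b.center, b.fwhm, b.shape)
    off = rng.uniform(*cfg.baseline_offset_range)
    c1, c2 = rng.uniform(*cfg.baseline_coeff_range, size=2)
    t = (w - w[0]) / (w[-1] - w[0])
    y += off + c1 * t + c2 * t**2
    if cfg.noise_sd > 0:
        y += rng.normal(0.0, cfg.noise_sd, size=w.size)
    if group_label is not None:
        group = group_label
    elif profile.name in ("eukaryote", "prokaryote", "unknown"):
        group = profile.name
    else:
        group = "unknown"
    spec = Spectrum(specimen_id, w, y, metadata={"group": group,
                                                 "taxon": f"synthetic_{profile.name}"})
    truth = {
        "specimen_id": specimen_id, "group": group,
        "source_profile": profile.name, "abundance": abundance,
        "baseline": (off, c1, c2),
        **{f"amp_{k}": v for k, v in amps.items()},
    }
    return spec, truth


def generate_assemblage(cfg: AssemblageConfig | None = None) -> tuple[SpectrumSet, pd.DataFrame]:
    """Generate the full synthetic assemblage with its truth table.

    Specimens are labelled by group except "unknown" specimens, whose
    generating profile is recorded only in the truth table.
    """
    cfg = cfg or AssemblageConfig()
    if sum(cfg.n_per_group.values()) == 0:
        raise ValueError("assemblage must contain at least one specimen")
    rng = np.random.default_rng(cfg.seed)
    spectra = []
    truths = []
    idx = 1
    for group, n in cfg.n_per_group.items():
        profile = cfg.profiles[
            cfg.unknown_source_profile if group == "unknown" else group
        ]
        for _ in range(n):
            sid = f"S{idx:03d}"
            spec, truth = generate_spectrum(
                profile, cfg, rng, specimen_id=sid, group_label=group
            )
            spectra.append(spec)
            truths.append(truth)
            idx += 1
    truth_df = pd.DataFrame(truths).set_index("specimen_id")
    sset = SpectrumSet(spectra, provenance={"generator": "chertspec.synthetic",
                                            "seed": cfg.seed})
    return sset, truth_df


def abundance_only_config(seed: int = 0, n: int = 30) -> AssemblageConfig:
    """One composition, per-specimen amplitudes globally scaled: the control
    assemblage whose PCA structure is pure organic abundance."""
    profiles = default_profiles()
    base = profiles["eukaryote"]
    no_jitter = BandProfile(base.name, {
        k: replace(b, sigma_log=0.0) for k, b in base.bands.items()
    })
    return AssemblageConfig(
        n_per_group={"eukaryote": n, "prokaryote": 0, "unknown": 0},
        profiles={"eukaryote": no_jitter, "prokaryote": profiles["prokaryote"]},
        sigma_abundance=0.5,
        seed=seed,
    )


def expected_ratio(
    profile: BandProfile,
    ratio: str,
    cfg: AssemblageConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    mode: str = "peak_max",
) -> float:
    """Analytic expectation of a chemometric ratio for a profile.

    The oracle is the expectation of the noiseless read-off over the
    shared log-normal abundance factor, computed by Gauss-Hermite
    quadrature: for each node the noiseless band sum (organic amplitudes at
    their per-band log-normal means, scaled by the node's abundance value)
    is evaluated on the grid and passed through the same read-off as the
    measurement path, so band overlap, silica shoulders and baseline
    handling are all accounted for.  The quadrature matters because the
    numerators mix abundance-scaled organic bands with unscaled silica
    shoulders, making the ratio nonlinear in the abundance factor; a single
    evaluation would be biased for shoulder-dominated bands.
    """
    from .chemometrics import moiety_ratios

    cfg = cfg or AssemblageConfig()
    nodes, weights = np.polynomial.hermite_e.hermegauss(9)
    mineral_mean = float(np.exp(cfg.silica_sigma_log**2 / 2.0))
    w = cfg.wavenumbers()
    values = []
    for x in nodes:
        abundance = float(np.exp(cfg.sigma_abundance * x))
        y = _mineral_signal(w, cfg, {c: mineral_mean for c in cfg.silica_amplitudes},
                            mineral_mean)
        for b in profile.bands.values():
            amp = b.median_amplitude * abundance * float(np.exp(b.sigma_log**2 / 2.0))
            y += amp * band_shape(w, b.center, b.fwhm, b.shape)
        spec = Spectrum(f"oracle_{profile.name}", w, y)
        seg, _ = preprocess_spectrum(spec, preprocess_cfg)
        ratios = moiety_ratios(seg, mode=mode)
        if ratio not in ratios:
            raise ValueError(f"unknown ratio {ratio!r}")
        values.append(ratios[ratio])
    weights = weights / weights.sum()
    return float(np.dot(weights, values))
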