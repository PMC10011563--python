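# Methods

This note documents the models, parameter choices and numerical decisions
behind `chertspec`, and states what the synthetic validation does and does
not establish.

## The measurement problem

An ATR-FTIR spectrum of a chert-hosted fossil is a mixture: quartz
contributes seven overtone/combination bands between ~1995 and ~1492 cm⁻¹
(the ~1615 cm⁻¹ band dominant), hydrous silica a broad OH absorption over
3800–3000 cm⁻¹, and the kerogenized organism a comparatively weak organic
signal — aliphatic CH stretches at ~2960/2922/2851 cm⁻¹ and
carbonyl/carboxyl/amide/N-moiety bands between ~1760 and ~1400 cm⁻¹.
Absolute intensities additionally depend on specimen thickness and
organic-matter content. Chemotaxonomic inference therefore needs (i) a
baseline and normalization scheme that makes spectra comparable, and
(ii) statistics that are robust to the residual nuisance variation.

## Preprocessing chain

Order of operations: **truncate/cut → resample → rubberband → min–max**.

* **Windows.** Closed intervals; defaults keep 3000–1400 cm⁻¹ and cut
  2700–1760 cm⁻¹, leaving segments [2700, 3000] and [1400, 1760]. A grid
  point equal to a boundary belongs to the retained window.
* **Resampling.** Linear interpolation onto a window-aligned grid,
  default step 2 cm⁻¹ (half the typical 4 cm⁻¹ instrument resolution, so
  band maxima are not aliased). Resampling precedes the baseline so the
  hull is computed on a grid common to all specimens.
* **Rubberband.** Per contiguous segment (the cut interval breaks the
  hull), the baseline is the lower convex hull of the (ν, I) points,
  linearly interpolated between vertices (Andrew monotone chain, O(n)).
  The correction is exactly zero at hull vertices, non-negative
  everywhere, idempotent, and invariant to adding any affine function of
  wavenumber. It is verified against an O(n³) brute-force chord oracle.
* **Min–max.** Jointly over the union of segments, so inter-region
  intensity relations (organic vs silica) are preserved. The
  normalization is *not* forced to the 1615 cm⁻¹ band; instead an anchor
  report states where the global maximum lies and whether it is within
  ±15 cm⁻¹ of 1615 (the band is variously cited at 1610–1615). Because
  the rubberband forces the corrected minimum to zero, min–max reduces to
  a pure rescaling, which is why organic/silica ratios are identical
  before and after normalization.
* **Savitzky–Golay.** Second-derivative spectra (band-assignment aid) use
  polynomial order 2, window 9 *points* (the convention of the common
  preprocessing GUIs; the alternative reading "9 cm⁻¹" is not used).
  Edges are handled by the polynomial fit on the one-sided window — no
  data are invented beyond segment ends. A non-uniform grid is an error
  instructing resampling first.

The whole chain is deterministic and scale-invariant (scaling a spectrum
by c > 0 changes nothing), and every step appends its parameters to a log
from which a run can be replayed.

## Band extraction and ratios

Band intensities default to the local maximum within ±10 cm⁻¹ of the
nominal center (`peak_max`), because ATR band maxima shift a few cm⁻¹
between specimens; interpolation at the nominal center (`at_center`) is
available, and `peak_max ≥ at_center` always. The CH₂ asymmetric stretch
is catalogued at 2922 cm⁻¹ with ±10 tolerance so it captures maxima
reported anywhere in 2920–2925 cm⁻¹. *R*₃/₂ alone uses a dedicated
two-point linear baseline across 3000–2800 cm⁻¹ before read-off; all
other ratios read the rubberband-corrected, normalized spectrum.

A caveat the synthetic tests make explicit: in the 1760–1400 cm⁻¹ window
the organic bands ride on silica-overtone shoulders that survive the
rubberband, so measured "1650 cm⁻¹ intensity" includes a mineral
contribution shared by all specimens. Group *contrasts* in the ratios are
attenuated but not created by this; the analytic ratio oracle (below)
accounts for it exactly.

## Group statistics

Ratios are compared between domains with a two-sided Mann–Whitney *U*
test. U counts pairs (x, y) with x > y (ties ½), so U(x,y) + U(y,x) =
n₁n₂. With n₁·n₂ ≤ 400 and no ties the exact null distribution is used,
computed by dynamic programming over rank subsets (equivalently, full
enumeration — the two are tested equal for all n₁+n₂ ≤ 10); otherwise a
tie-corrected normal approximation with continuity correction. Two-sided
p = 2·P(U ≤ min(U, n₁n₂−U)), capped at 1. Per-group Shapiro–Wilk flags
(α = 0.05) report the gate that justifies the nonparametric choice. No
multiple-testing correction is applied: the four ratio tests are reported
raw, as is conventional for this small family of pre-registered
contrasts; users combining many bands should correct downstream.
Group means are reported with σx̄ = sd/√n (n−1 denominator).

## Unsupervised analysis

PCA is computed on mean-centered, *unscaled* features: spectra are
already min–max normalized, and per-wavenumber variance scaling would
inflate noise in low-signal regions. Loadings follow a deterministic sign
convention (largest-magnitude element positive). K-means uses Lloyd's
algorithm with random data-row initialization, ≤ 300 iterations, best of
10 seeded restarts; since no selection rule fixes k, a silhouette scan
over k = 2…6 is reported. Clustering accuracy against known labels is
maximized over cluster-label permutations (Hungarian assignment), which
also yields the misassigned specimen ids.

**Compositional sanity check.** For each leading component the Spearman
correlation of scores with CH₂/silica and C=O/silica is computed. An axis
along which *both* ratios rise together (same sign, both |ρ| ≥ 0.7) is
flagged as abundance-driven; if no such axis exists among the components
examined, the sorting is compositional. The 0.7 threshold (at least half
the variance shared) was chosen because in the abundance-only control
both correlations reach ~0.99 while in compositional assemblages a single
ratio can incidentally co-vary with a mixed axis at ρ ≈ 0.5; 0.7
separates the regimes robustly.

## Discriminant ordination

Canonical variates analysis on the specimens × bands matrix: eigenvectors
of W⁻¹B, with W the pooled within-group covariance and B the
between-group covariance, fitted on active specimens only. Axis count =
min(groups − 1, bands). A singular W is ridge-regularized with
λ = 10⁻⁶·trace(W) and a warning. Passive specimens are centered with the
active grand mean and projected; a passive specimen equal to a group
centroid lands exactly on that centroid's score. Axis 1 is oriented so
the alphabetically last group's centroid scores higher; higher axes take
their largest-magnitude coefficient positive. In this literature the same
ordination is sometimes labelled "canonical correspondence analysis",
but a group-supervised analysis of a band-intensity matrix is canonical
variates / multi-class LDA, which is what is implemented; the band matrix
is exportable for users who want to re-run alternatives.

## Supervised protocol

Unknown-affinity specimens are excluded; the labelled remainder is split
with training count = ⌈n·0.6⌉ (47 labelled specimens give 29/18),
stratified by proportional allocation with largest-remainder rounding —
with 9 prokaryotes among 47 an unstratified draw risks a class-absent
side; a degenerate draw is redrawn (≤ 100 attempts). Learners: logistic
regression (L2, C = 1), kNN (Euclidean, k = 5; AUC scores are
neighbour-vote fractions, so the ROC is step-like with 6 levels; vote
ties break toward the nearest single neighbour via sklearn's weighting of
equidistant points), random forest (50 trees, unlimited depth, √p
features per split, seeded — only the tree count is prescribed; the rest
are common defaults). Leave-one-out CV reports held-out accuracy and
ROC-AUC; a fold whose training block degenerates to one class predicts
that class. The whole protocol is reproducible bit-for-bit from (matrix,
master seed), and no preprocessing statistic crosses the train/test
boundary: baseline and normalization are strictly per-spectrum
operations.

## Synthetic assemblage: the stated world

The generator emulates a 49-specimen assemblage (40 eukaryotes, 9
prokaryotes; unknowns optional) on a 4000–650 cm⁻¹ grid at 2 cm⁻¹:

* **Mineral signal.** The seven silica overtones (1615 band amplitude 1,
  strictly dominant; fwhm 60 cm⁻¹) and an OH hump (3400 cm⁻¹, fwhm 350,
  amplitude 0.35) appear in every spectrum with small log-normal jitter
  (σ = 0.05).
* **Organic signal.** Gaussian bands (fwhm 25 cm⁻¹; Lorentzian
  available). The prokaryote profile has ~1.5× the eukaryote's aliphatic
  CH amplitudes and a stronger absolute ester C=O band; the eukaryote
  profile has carbonyl/carboxyl/N-moiety amplitudes high enough that its
  expected C=O/CH₂ and N/CH₂ ratios exceed the prokaryote's ~1.8–2.1×,
  while expected ester/CH₂ is still higher for eukaryotes (their smaller
  CH₂ denominator wins). Both profiles keep expected *R*₃/₂ within the
  0.25–0.63 range of fossil and living aliphatic biomass. Organic peak
  amplitudes reach ~0.07–0.54 of the silica anchor.
* **Dispersion.** Per specimen, a shared organic-abundance factor
  (log-normal, σ = 0.08) scales all organic bands; each band additionally
  jitters independently (log-normal, σ = 0.08). This encodes the regime
  the method presumes and the motivating assemblage exhibits —
  between-specimen variation chiefly compositional — and was calibrated,
  together with the amplitude scale and noise floor, against the
  generator's own design constraints (ratio recovery within 5%, k-means
  group recovery, all learners' LOO accuracy ≥ 0.9), once, before the
  acceptance tests were frozen. An `abundance_only_config` control (one
  composition, σ_abundance = 0.5, zero jitter) inverts the regime and
  must trip the sanity check.
* **Nuisance.** A quadratic baseline drift (coefficients uniform in
  ±0.02, offset 0–0.03) and iid Gaussian noise (σ = 0.002 absorbance;
  SNR ≈ 500 on the silica anchor, typical of high-accumulation ATR).

Every draw (abundance factor, band amplitudes, drift coefficients) is
recorded in a truth table.

**Analytic ratio oracle.** `expected_ratio` computes the expectation of a
measured ratio without Monte Carlo: the noiseless band sum (per-band
log-normal means) is evaluated on the grid and passed through the same
read-off as the measurement path, averaged over the shared abundance
factor by 9-node Gauss–Hermite quadrature. The quadrature matters because
numerators mix abundance-scaled organic bands with unscaled silica
shoulders, making ratios nonlinear in the abundance factor. Residual
discrepancy between the oracle and the mean of measured ratios comes from
the positive bias of `peak_max` on noisy data (~1–2% at the default noise
floor) and second-order jitter terms (~1%).

**What a green synthetic test does not establish.** The generator uses
symmetric Gaussian bands, additive noise and a smooth polynomial drift;
real ATR spectra have asymmetric band shapes, anomalous-dispersion
distortion near strong mineral bands, scattering artifacts and
band-position shifts with thermal maturity, none of which are modelled.
Synthetic recovery therefore validates the *pipeline's* correctness and
calibration, not the taxonomic separability of any real assemblage.

## Degenerate inputs and tolerances

Constant spectra cannot be normalized (error); segments need ≥ 3 points
for a hull; exact Mann–Whitney refuses ties; Shapiro–Wilk needs
3 ≤ n ≤ 5000; PCA on identical rows reports zero total variance; k-means
requires k ≤ n; CVA needs ≥ 2 groups with ≥ 2 active members.
Rubberband idempotence and the hull-oracle equivalence are asserted at
10⁻¹²/10⁻⁹; PCA reconstruction at 10⁻⁸; resampling against a direct
piecewise-linear oracle at 10⁻¹²; read/write round trips at 10⁻⁹.

## Known limitations

* Band intensities, not integrated areas; no deconvolution of overlapping
  peaks — shoulder contamination in the carbonyl window is documented,
  not removed.
* JCAMP-DX support covers the plain AFFN ##XYDATA=(X++(Y..Y)) and
  ##XYPOINTS dialects only (no SQZ/DIF compression, no vendor binaries).
* The published headline classification accuracies depend on an unstated
  split seed, so they are reproduced as properties (thresholds on the
  synthetic assemblage), not as point targets; the deposited-data
  benchmark helper exists for users who download the raw archive.
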