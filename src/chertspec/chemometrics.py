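"""Chemometric band ratios and nonparametric group comparison.

Per specimen the pipeline reports six dimensionless ratios:

* ``R32`` — CH3 asymmetric (~2960 cm^-1) over CH2 asymmetric (~2922 cm^-1)
  stretch intensity, read after a dedicated two-point linear baseline over
  3000-2800 cm^-1; a proxy for aliphatic chain branching/length and a
  proposed domain indicator.
* ``ester_CH2``, ``CO_CH2``, ``N_CH2`` — ester C=O (1735), carbonyl C=O
  (1650) and N-moiety (1560) intensities over the CH2 asymmetric stretch;
  they track sugar/protein fossilization products relative to lipids.
* ``CH2_silica``, ``CO_silica`` — organic bands over the ~1615 cm^-1 silica
  overtone; sanity ratios separating compositional variation from mere
  organic-abundance variation.

Group differences are tested with a two-sided Mann-Whitney U test (exact
null enumeration for small samples without ties, tie-corrected normal
approximation otherwise), gated by a per-group Shapiro-Wilk normality
report.  No multiple-testing correction is applied; the four ratio tests
are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import (
    band_intensity,
    catalogue_by_label,
    local_linear_baseline,
)
from .preprocess import SegmentedSpectrum

RATIO_NAMES = ("R32", "ester_CH2", "CO_CH2", "N_CH2", "CH2_silica", "CO_silica")

_EPS = 1e-12


def _intensity(seg: SegmentedSpectrum, label: str, mode: str = "peak_max") -> float:
    return band_intensity(seg, catalogue_by_label()[label], mode)


def r32(seg: SegmentedSpectrum, mode: str = "peak_max") -> float:
    """Methyl/methylene ratio I(CH3 asym)/I(CH2 asym).

    The CH stretching window 3000-2800 cm^-1 gets its own two-point linear
    baseline before the read-off.  Raises if the CH2 intensity is at noise
    floor ("no aliphatic signal").
    """
    based = local_linear_baseline(seg, (3000.0, 2800.0))
    ch3 = _intensity(based, "CH3_asym", mode)
    ch2 = _intensity(based, "CH2_asym", mode)
    if ch2 <= _EPS:
        raise ValueError(f"{seg.specimen_id}: no aliphatic signal (CH2 ~ 0)")
    return ch3 / ch2


def moiety_ratios(seg: SegmentedSpectrum, mode: str = "peak_max") -> dict[str, float]:
    """All six ratios for one preprocessed (rubberband + min-max) spectrum.

    The silica denominator uses the 1615 cm^-1 band of the same corrected
    spectrum; because the rubberband forces the corrected minimum to zero,
    min-max normalization is a pure rescaling and the organic/silica ratios
    are identical before and after normalization.
    """
    ch2 = _intensity(seg, "CH2_asym", mode)
    if ch2 <= _EPS:
        raise ValueError(f"{seg.specimen_id}: no aliphatic signal (CH2 ~ 0)")
    silica = _intensity(seg, "silica_1615", mode)
    if silica <= _EPS:
        raise ValueError(f"{seg.specimen_id}: no silica anchor band")
    co = _intensity(seg, "amide_CO", mode)
    return {
        "R32": r32(seg, mode),
        "ester_CH2": _intensity(seg, "ester_CO", mode) / ch2,
        "CO_CH2": co / ch2,
        "N_CH2": _intensity(seg, "N_moiety_1560", mode) / ch2,
        "CH2_silica": ch2 / silica,
        "CO_silica": co / silica,
    }


def ratio_table(
    segs: Sequence[SegmentedSpectrum], mode: str = "peak_max"
) -> pd.DataFrame:
    """Per-specimen ratio table with group labels (columns: group + ratios)."""
    rows = []
    for seg in segs:
        row = {"specimen_id": seg.specimen_id, "group": seg.group}
        row.update(moiety_ratios(seg, mode))
        rows.append(row)
    return pd.DataFrame(rows).set_index("specimen_id")


@lru_cache(maxsize=128)
def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic by exact enumeration.

    Counts, for every u, the rank subsets of size n1 from {1..n1+n2} whose
    rank sum yields U = u; dynamic programming over ranks, normalised by
    C(n1+n2, n1).
    """
    n = n1 + n2
    umax = n1 * n2
    # ways[k][s]: subsets of size k with "excess" sum s (= U contribution)
    ways = np.zeros((n1 + 1, umax + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            # choosing rank r as the k-th smallest adds excess r - k
            shift = r - k
            if shift > umax:
                continue
            ways[k, shift:] += ways[k - 1, : umax + 1 - shift]
    pmf = ways[n1]
    return pmf / pmf.sum()


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    U counts pairs (xi, yj) with xi > yj (ties 1/2), so
    U(x, y) + U(y, x) = n1*n2.  method="exact" enumerates the null
    distribution (valid without ties); "normal_approx" uses the
    tie-corrected normal approximation with continuity correction; "auto"
    picks exact when n1*n2 <= 400 and the pooled sample has no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    if method not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    if method == "auto":
        method = "exact" if (n1 * n2 <= 400 and not has_ties) else "normal_approx"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method is only valid without ties")
        pmf = _exact_u_pmf(n1, n2)
        u_lo = int(round(min(u1, n1 * n2 - u1)))
        p = min(1.0, 2.0 * pmf[: u_lo + 1].sum())
        return float(u1), float(p)
    # tie-corrected normal approximation, continuity-corrected toward center
    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return float(u1), float(min(1.0, p))


def shapiro_wilk_flag(values: Sequence[float], alpha: float = 0.05):
    """Shapiro-Wilk normality check: returns (W, p, normal at alpha).

    Used only to report the gate that justifies nonparametric group tests.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if len(values) > 5000:
        raise ValueError("Shapiro-Wilk supported for n <= 5000")
    w, p = stats.shapiro(values)
    return float(w), float(p), bool(p > alpha)


@dataclass
class GroupComparison:
    """Two-group nonparametric comparison of one chemometric ratio."""

    ratio: str
    group1: str
    group2: str
    n1: int
    n2: int
    U: float
    p_value: float
    mean1: float
    mean2: float
    sem1: float
    sem2: float
    normal1: bool | None
    normal2: bool | None

    def as_dict(self) -> dict:
        return vars(self).copy()


def compare_groups(
    table: pd.DataFrame,
    ratio: str,
    groups: tuple[str, str] = ("prokaryote", "eukaryote"),
    method: str = "auto",
) -> GroupComparison:
    """Mann-Whitney comparison of one ratio between two labelled groups.

    Specimens with other labels (e.g. "unknown") are excluded.  Reports
    group means with standard errors (sd/sqrt(n), n-1 denominator) and the
    per-group Shapiro-Wilk normality flags (None when n < 3).
    """
    if ratio not in table.columns:
        raise ValueError(f"ratio {ratio!r} not in table")
    g1, g2 = groups
    x = table.loc[table["group"] == g1, ratio].to_numpy(dtype=float)
    y = table.loc[table["group"] == g2, ratio].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"group missing: n({g1})={len(x)}, n({g2})={len(y)}")
    u, p = mann_whitney_u(x, y, method=method)

    def _sem(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    def _flag(v):
        return shapiro_wilk_flag(v)[2] if len(v) >= 3 else None

    return GroupComparison(
        ratio=ratio, group1=g1, group2=g2, n1=len(x), n2=len(y),
        U=u, p_value=p,
        mean1=float(np.mean(x)), mean2=float(np.mean(y)),
        sem1=_sem(x), sem2=_sem(y),
        normal1=_flag(x), normal2=_flag(y),
    )


def compare_all_ratios(
    table: pd.DataFrame,
    ratios: Sequence[str] = ("R32", "ester_CH2", "CO_CH2", "N_CH2"),
    groups: tuple[str, str] = ("prokaryote", "eukaryote"),
) -> pd.DataFrame:
    """Run compare_groups for several ratios; one row per ratio."""
    return pd.DataFrame([compare_groups(table, r, groups).as_dict() for r in ratios])
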