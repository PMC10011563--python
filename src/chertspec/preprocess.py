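"""Spectral preprocessing chain for chert-hosted FTIR spectra.

The analysis keeps two windows of the mid-IR trace: 3000-2700 cm^-1
(aliphatic CH stretches) and 1760-1400 cm^-1 (carbonyl / amide /
carboxyl / N-moiety bands plus silica overtones).  The broad OH hump above
3000 cm^-1, the atmospheric-CO2 / diamond-ATR interval 2700-1760 cm^-1 and
the saturated Si-O fundamental below 1400 cm^-1 are discarded.  Within the
retained windows each spectrum is resampled onto a common grid, baseline
corrected with a rubberband (lower convex hull) per contiguous segment, and
min-max normalized over the union of segments so that the dominant ~1615
cm^-1 silica overtone maps to 1.

Pipeline order: truncate/cut -> resample -> rubberband -> min-max.
Every step appends a descriptor to the preprocessing log, so a run is
auditable and replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .io import Spectrum, SpectrumSet


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``keep_range`` and ``cut_ranges`` are in cm^-1, given high-to-low as
    spectroscopists write them; ``sg_window`` is in points (odd, greater
    than ``sg_polyorder``); ``resample_step`` in cm^-1 (default 2: half the
    4 cm^-1 instrument resolution, so band maxima are not aliased).
    """

    keep_range: tuple[float, float] = (3000.0, 1400.0)
    cut_ranges: tuple[tuple[float, float], ...] = ((2700.0, 1760.0),)
    normalize_anchor: float = 1615.0
    anchor_tolerance: float = 15.0
    sg_window: int = 9
    sg_polyorder: int = 2
    resample_step: float = 2.0

    def __post_init__(self) -> None:
        self.keep_range = (max(self.keep_range), min(self.keep_range))
        self.cut_ranges = tuple(
            (max(c), min(c)) for c in self.cut_ranges
        )
        hi, lo = self.keep_range
        for chi, clo in self.cut_ranges:
            if not (lo <= clo and chi <= hi):
                raise ValueError(f"cut range {(chi, clo)} not inside keep_range")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.resample_step <= 0:
            raise ValueError("resample_step must be positive")

    def windows(self) -> list[tuple[float, float]]:
        """Retained windows as ascending (lo, hi) pairs, low wavenumber first."""
        hi, lo = self.keep_range
        edges = sorted({lo, hi})
        cuts = sorted((min(c), max(c)) for c in self.cut_ranges)
        wins = []
        start = lo
        for clo, chi in cuts:
            if clo > start:
                wins.append((start, clo))
            start = max(start, chi)
        if start < hi:
            wins.append((start, hi))
        return wins

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentedSpectrum:
    """A spectrum restricted to the retained analysis windows.

    `segments` is a list of (window, wavenumbers, intensities) with windows
    as ascending (lo, hi); segments are mutually disjoint and each grid is
    ascending.  `preprocessing_log` records each applied step.
    """

    specimen_id: str
    segments: list[tuple[tuple[float, float], np.ndarray, np.ndarray]]
    metadata: dict = field(default_factory=dict)
    preprocessing_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for (lo, hi), w, y in sorted(self.segments, key=lambda s: s[0][0]):
            if lo >= hi or lo < prev_hi:
                raise ValueError(f"{self.specimen_id}: overlapping or empty segments")
            if len(w) != len(y) or np.any(np.diff(w) <= 0):
                raise ValueError(f"{self.specimen_id}: segment grid not ascending")
            prev_hi = hi
        self.segments = sorted(self.segments, key=lambda s: s[0][0])

    @property
    def group(self) -> str | None:
        return self.metadata.get("group")

    def segment_containing(self, wavenumber: float):
        for (lo, hi), w, y in self.segments:
            if lo <= wavenumber <= hi:
                return (lo, hi), w, y
        return None

    def concatenated(self) -> tuple[np.ndarray, np.ndarray]:
        """All retained points, ascending across segments."""
        w = np.concatenate([s[1] for s in self.segments])
        y = np.concatenate([s[2] for s in self.segments])
        return w, y

    def with_segments(self, segments, step: dict) -> "SegmentedSpectrum":
        return SegmentedSpectrum(
            self.specimen_id,
            segments,
            metadata=dict(self.metadata),
            preprocessing_log=self.preprocessing_log + [step],
        )


def truncate_and_cut(s: Spectrum, cfg: PreprocessConfig | None = None) -> SegmentedSpectrum:
    """Restrict a spectrum to the retained windows (closed intervals).

    With the default config this yields exactly two segments,
    [2700, 3000] and [1400, 1760] cm^-1.  A spectrum entirely outside the
    keep range is an error.
    """
    cfg = cfg or PreprocessConfig()
    segments = []
    for lo, hi in cfg.windows():
        mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
        if mask.sum() >= 2:
            segments.append(((lo, hi), s.wavenumbers[mask], s.intensities[mask]))
    if not segments:
        raise ValueError(
            f"{s.specimen_id}: spectrum ({s.wavenumbers[0]:.0f}-"
            f"{s.wavenumbers[-1]:.0f} cm^-1) lies outside keep_range {cfg.keep_range}"
        )
    return SegmentedSpectrum(
        s.specimen_id,
        segments,
        metadata=dict(s.metadata),
        preprocessing_log=[
            {
                "step": "truncate_and_cut",
                "keep_range": cfg.keep_range,
                "cut_ranges": cfg.cut_ranges,
            }
        ],
    )


def lower_convex_hull(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices of points (w, y), w ascending.

    Andrew monotone chain, lower envelope only.  First and last points are
    always vertices.
    """
    n = len(w)
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep turn strictly convex (cross product > 0 removes i2)
            cross = (w[i2] - w[i1]) * (y[i] - y[i1]) - (w[i] - w[i1]) * (y[i2] - y[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.array(hull, dtype=int)


def rubberband_baseline(seg: SegmentedSpectrum) -> SegmentedSpectrum:
    """Subtract the rubberband baseline per contiguous segment.

    The baseline is the lower convex-hull envelope of the segment's points,
    linearly interpolated between hull vertices; corrected intensities are
    non-negative and vanish exactly at hull vertices (in particular at both
    segment endpoints).  Idempotent, and invariant to adding any affine
    function of wavenumber.
    """
    new_segments = []
    for win, w, y in seg.segments:
        if len(w) < 3:
            raise ValueError(
                f"{seg.specimen_id}: segment {win} has {len(w)} points; need >= 3"
            )
        hull = lower_convex_hull(w, y)
        baseline = np.interp(w, w[hull], y[hull])
        corrected = y - baseline
        corrected[hull] = 0.0  # exact zeros at vertices despite float round-off
        corrected = np.maximum(corrected, 0.0)
        new_segments.append((win, w, corrected))
    return seg.with_segments(new_segments, {"step": "rubberband_baseline"})


def minmax_normalize(
    seg: SegmentedSpectrum, anchor: float | None = None, anchor_tolerance: float = 15.0
) -> tuple[SegmentedSpectrum, dict]:
    """Min-max normalize jointly over all segments; report the max position.

    The global minimum maps to 0 and the global maximum to 1.  The anchor
    report is diagnostic only: it states where the global maximum lies and
    whether that is within `anchor_tolerance` of the expected ~1615 cm^-1
    silica overtone.  Normalization is never forced to the anchor.
    """
    anchor = 1615.0 if anchor is None else anchor
    w_all, y_all = seg.concatenated()
    ymin, ymax = float(y_all.min()), float(y_all.max())
    if ymax <= ymin:
        raise ValueError(f"{seg.specimen_id}: constant spectrum, cannot normalize")
    scale = ymax - ymin
    max_wavenumber = float(w_all[int(np.argmax(y_all))])
    report = {
        "specimen_id": seg.specimen_id,
        "max_wavenumber": max_wavenumber,
        "anchor": anchor,
        "max_at_anchor": abs(max_wavenumber - anchor) <= anchor_tolerance,
        "pre_normalization_max": ymax,
        "pre_normalization_min": ymin,
    }
    new_segments = [
        (win, w, (y - ymin) / scale) for win, w, y in seg.segments
    ]
    out = seg.with_segments(
        new_segments,
        {"step": "minmax_normalize", "anchor": anchor, "scale": scale, "offset": ymin},
    )
    return out, report


def savgol_derivative(
    s: Spectrum | SegmentedSpectrum,
    window: int = 9,
    polyorder: int = 2,
    deriv: int = 2,
):
    """Savitzky-Golay derivative (default: second) per uniform segment.

    Edges use scipy's polynomial-interpolation mode, i.e. the fit on the
    one-sided window, so no data are invented beyond segment ends.  The
    derivative is with respect to wavenumber (delta honoured).
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")

    def one(w: np.ndarray, y: np.ndarray) -> np.ndarray:
        if len(w) < window:
            raise ValueError("segment shorter than the filter window")
        steps = np.diff(w)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError(
                "non-uniform grid; resample to a common grid before the "
                "Savitzky-Golay derivative"
            )
        return savgol_filter(
            y, window, polyorder, deriv=deriv, delta=steps[0], mode="interp"
        )

    if isinstance(s, Spectrum):
        return Spectrum(
            s.specimen_id, s.wavenumbers, one(s.wavenumbers, s.intensities),
            metadata=dict(s.metadata),
        )
    new_segments = [(win, w, one(w, y)) for win, w, y in s.segments]
    return s.with_segments(
        new_segments,
        {"step": "savgol_derivative", "window": window, "polyorder": polyorder,
         "deriv": deriv},
    )


def _window_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def resample_segments(
    seg: SegmentedSpectrum, step: float
) -> SegmentedSpectrum:
    """Linearly interpolate each segment onto the window-aligned grid."""
    new_segments = []
    for (lo, hi), w, y in seg.segments:
        grid = _window_grid(lo, hi, step)
        grid = grid[(grid >= w[0] - 1e-9) & (grid <= w[-1] + 1e-9)]
        if len(grid) < 2:
            raise ValueError(
                f"{seg.specimen_id}: segment {(lo, hi)} too narrow to resample"
            )
        new_segments.append(((lo, hi), grid, np.interp(grid, w, y)))
    return seg.with_segments(new_segments, {"step": "resample", "step_cm1": step})


def resample_common_grid(sset: SpectrumSet, step: float = 2.0,
                         cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """Resample raw spectra of a set onto one shared ascending grid.

    Linear interpolation only; a spectrum that does not cover the common
    overlap range raises an error naming the specimen.
    """
    los = [s.wavenumbers[0] for s in sset]
    his = [s.wavenumbers[-1] for s in sset]
    lo, hi = max(los), min(his)
    if hi - lo < step:
        worst = sset.spectra[int(np.argmax(los))].specimen_id
        raise ValueError(f"no common overlap across set (check specimen {worst!r})")
    grid = _window_grid(np.ceil(lo / step) * step, hi, step)
    out = []
    for s in sset:
        out.append(
            Spectrum(
                s.specimen_id, grid, np.interp(grid, s.wavenumbers, s.intensities),
                metadata=dict(s.metadata),
            )
        )
    prov = dict(sset.provenance)
    prov["resampled_step"] = step
    return SpectrumSet(out, provenance=prov)


def preprocess_spectrum(
    s: Spectrum, cfg: PreprocessConfig | None = None
) -> tuple[SegmentedSpectrum, dict]:
    """Full per-spectrum chain: truncate/cut -> resample -> rubberband -> min-max."""
    cfg = cfg or PreprocessConfig()
    seg = truncate_and_cut(s, cfg)
    seg = resample_segments(seg, cfg.resample_step)
    seg = rubberband_baseline(seg)
    seg, report = minmax_normalize(seg, cfg.normalize_anchor, cfg.anchor_tolerance)
    return seg, report


def preprocess_pipeline(
    sset: SpectrumSet, cfg: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, list[SegmentedSpectrum], list[dict]]:
    """Preprocess a whole set and assemble the specimens x wavenumber matrix.

    Returns ``(feature_matrix, segmented_spectra, anchor_reports)``.  The
    matrix rows follow input order; columns are the concatenated
    retained-window grid, labelled by wavenumber.  Deterministic: repeated
    runs are bit-identical.
    """
    cfg = cfg or PreprocessConfig()
    segs = []
    reports = []
    rows = []
    grid = None
    for s in sset:
        seg, rep = preprocess_spectrum(s, cfg)
        w, y = seg.concatenated()
        if grid is None:
            grid = w
        elif len(w) != len(grid) or not np.array_equal(w, grid):
            raise ValueError(
                f"{s.specimen_id}: grid mismatch after preprocessing; spectra "
                f"must cover the full retained windows"
            )
        segs.append(seg)
        reports.append(rep)
        rows.append(y)
    matrix = pd.DataFrame(
        np.vstack(rows), index=sset.specimen_ids, columns=np.round(grid, 6)
    )
    matrix.index.name = "specimen_id"
    return matrix, segs, reports
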