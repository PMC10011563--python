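"""Reading and writing single-specimen FTIR spectra.

Spectra arrive as two-column text files (wavenumber, absorbance) or as
JCAMP-DX files; specimen metadata (taxon, group, thin section) comes from a
delimited sidecar table keyed on specimen id.  Internally wavenumbers are
always stored ascending in cm^-1; plotting may reverse the axis, storage
never does.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = ("eukaryote", "prokaryote", "unknown")


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed; message names file and line."""


@dataclass
class Spectrum:
    """One specimen's wavenumber/absorbance trace plus identity metadata.

    Parameters
    ----------
    specimen_id:
        Unique identifier, used as the exact join key for metadata.
    wavenumbers:
        Strictly ascending spectral coordinates, cm^-1.
    intensities:
        Absorbance in arbitrary units, same length as `wavenumbers`.
    metadata:
        Free-form mapping; recognised keys are ``taxon``, ``group``
        (one of {eukaryote, prokaryote, unknown}), ``thin_section``,
        ``collection``.
    """

    specimen_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size or w.size < 2:
            raise ValueError(
                f"{self.specimen_id}: wavenumbers and intensities must be "
                f"1-D, equal length and have >= 2 points"
            )
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise ValueError(f"{self.specimen_id}: non-finite values in spectrum")
        order = np.argsort(w, kind="stable")
        w, y = w[order], y[order]
        if np.any(np.diff(w) <= 0):
            raise ValueError(
                f"{self.specimen_id}: duplicate wavenumbers; grid must be "
                f"strictly monotonic"
            )
        self.wavenumbers = w
        self.intensities = y
        group = self.metadata.get("group")
        if group is not None and group not in VALID_GROUPS:
            raise ValueError(
                f"{self.specimen_id}: group {group!r} not in {VALID_GROUPS}"
            )

    @property
    def group(self) -> str | None:
        return self.metadata.get("group")


@dataclass
class SpectrumSet:
    """Ordered collection of spectra with unique specimen ids."""

    spectra: list[Spectrum]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.spectra]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate specimen ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, key: int | str) -> Spectrum:
        if isinstance(key, str):
            for s in self.spectra:
                if s.specimen_id == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]

    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen_id for s in self.spectra]

    def groups(self) -> list[str | None]:
        return [s.group for s in self.spectra]


_NUM = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"


def _parse_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two numeric column file (comma, tab or whitespace separated).

    One optional header line is tolerated; any later non-numeric row is an
    error naming the file and line.
    """
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = re.split(r"[,\t;]|\s+", line)
            parts = [p for p in parts if p]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError:
                if lineno == 1 and not xs:  # header line
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if len(xs) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    return np.array(xs), np.array(ys)


def _parse_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader for ##XYDATA=(X++(Y..Y)) and ##XYPOINTS.

    Honours XFACTOR/YFACTOR scaling and checks the per-line abscissa against
    FIRSTX/DELTAX.  Compressed ordinate forms (SQZ/DIF/DUP) are not
    supported.
    """
    text = path.read_text()
    fields: dict[str, str] = {}
    data_mode = None
    data_lines: list[str] = []
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                data_mode = "xydata"
                continue
            if key == "XYPOINTS":
                data_mode = "xypoints"
                continue
            if key == "END":
                data_mode = None
                continue
            fields[key] = val
            data_mode = None
        elif data_mode is not None:
            data_lines.append(line.strip())
    if not data_lines:
        raise SpectrumParseError(f"{path}: no XYDATA/XYPOINTS block found")
    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        nums = [float(t) for t in re.findall(_NUM, line)]
        if not nums:
            continue
        if "," in line or ";" in line:
            # XYPOINTS: explicit pairs
            if len(nums) % 2:
                raise SpectrumParseError(f"{path}: odd XYPOINTS token count")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
        else:
            # XYDATA (X++(Y..Y)): first token is the abscissa of the first Y
            x0 = nums[0]
            yline = nums[1:]
            deltax = float(fields.get("DELTAX", 0.0))
            if not deltax and "FIRSTX" in fields and "LASTX" in fields and "NPOINTS" in fields:
                npts = int(float(fields["NPOINTS"]))
                if npts > 1:
                    deltax = (float(fields["LASTX"]) - float(fields["FIRSTX"])) / (
                        npts - 1
                    ) / xfactor
            for j, y in enumerate(yline):
                xs.append(x0 + j * deltax)
                ys.append(y)
    x = np.array(xs) * xfactor
    y = np.array(ys) * yfactor
    return x, y


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Load the specimen metadata sidecar (columns: specimen_id, taxon, group,
    thin_section; extra columns are carried through)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "specimen_id" not in df.columns:
        raise ValueError(f"{path}: metadata table must have a specimen_id column")
    return df


def read_spectra(
    paths: Sequence[str | Path],
    format: str = "csv",
    metadata_table: str | Path | None = None,
) -> SpectrumSet:
    """Read spectra from `paths` and attach metadata by exact specimen id.

    The specimen id is the file stem.  Wavenumbers are sorted ascending
    regardless of on-disk order; metadata rows that match no file are
    reported as warnings, not errors.
    """
    if format not in ("csv", "jcamp"):
        raise ValueError(f"unknown format {format!r}")
    meta: dict[str, dict] = {}
    if metadata_table is not None:
        df = read_metadata_table(metadata_table)
        meta = {
            str(row["specimen_id"]): {
                k: row[k]
                for k in df.columns
                if k != "specimen_id" and pd.notna(row[k])
            }
            for _, row in df.iterrows()
        }
    spectra = []
    seen: set[str] = set()
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        sid = p.stem
        if sid in seen:
            raise ValueError(f"duplicate specimen_id {sid!r} from {p}")
        seen.add(sid)
        if format == "csv":
            w, y = _parse_two_column(p)
        else:
            w, y = _parse_jcamp(p)
        spectra.append(Spectrum(sid, w, y, metadata=dict(meta.pop(sid, {}))))
    for sid in meta:
        warnings.warn(f"metadata row {sid!r} matched no spectrum file")
    return SpectrumSet(
        spectra, provenance={"source_files": [str(p) for p in paths], "format": format}
    )


def write_spectra(sset: SpectrumSet, dir: str | Path, format: str = "csv") -> list[Path]:
    """Write one two-column CSV per spectrum plus a metadata sidecar table.

    Returns the spectrum file paths (metadata.csv is written alongside).
    """
    if format != "csv":
        raise ValueError(f"unsupported write format {format!r}")
    if len(sset) == 0:
        raise ValueError("cannot write an empty SpectrumSet")
    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    rows = []
    for s in sset:
        p = out / f"{s.specimen_id}.csv"
        np.savetxt(
            p,
            np.column_stack([s.wavenumbers, s.intensities]),
            delimiter=",",
            header="wavenumber,intensity",
            comments="",
            fmt="%.10g",
        )
        paths.append(p)
        rows.append(
            {
                "specimen_id": s.specimen_id,
                "taxon": s.metadata.get("taxon", ""),
                "group": s.metadata.get("group", ""),
                "thin_section": s.metadata.get("thin_section", ""),
            }
        )
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)
    return paths
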