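"""Absorbance spectra on a uniform wavelength grid.

The package works with zero-order UV-Vis absorption spectra recorded on a
1-nm (or any uniform) grid. A :class:`WavelengthGrid` is stored by
``(start, end, step)`` rather than as a float list so that the grid can be
materialised on demand without accumulation error; a :class:`SpectraSet`
couples such a grid with a samples-by-wavelengths absorbance matrix, and a
:class:`ConcentrationTable` holds the paired analyte concentrations in
µg/mL.

CSV is the single on-disk format. Two dialects are accepted on read,
distinguished by the first header token:

* wavelength-major — ``wavelength_nm,<id1>,<id2>,...`` with one row per
  grid point (this is what :func:`write_spectra_csv` emits);
* sample-major — ``sample_id,<λ1>,<λ2>,...`` with one row per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GridError, RangeError, ShapeError, SpectraParseError

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "ConcentrationTable",
    "read_spectra_csv",
    "write_spectra_csv",
    "restrict_range",
    "read_concentrations_csv",
    "write_concentrations_csv",
]

_REL_TOL = 1e-6  # relative tolerance when checking grid uniformity


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm, stored as (start, end, step)."""

    start_nm: float
    end_nm: float
    step_nm: float = 1.0

    def __post_init__(self):
        # start == end is tolerated as a degenerate single-point grid so that
        # range restriction can return one channel
        if self.start_nm > self.end_nm:
            raise GridError(f"start {self.start_nm} must be <= end {self.end_nm}")
        if not self.step_nm > 0:
            raise GridError(f"step must be > 0, got {self.step_nm}")
        ratio = (self.end_nm - self.start_nm) / self.step_nm
        if abs(ratio - round(ratio)) > _REL_TOL * max(1.0, ratio):
            raise GridError(
                f"(end - start) = {self.end_nm - self.start_nm} is not an "
                f"integer multiple of step {self.step_nm}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an on-grid wavelength; GridError if off-grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        if abs(pos - round(pos)) > _REL_TOL or not 0 <= round(pos) < self.n_points:
            raise GridError(f"{wavelength_nm} nm is not on the grid")
        return int(round(pos))

    @classmethod
    def from_wavelengths(cls, wavelengths) -> "WavelengthGrid":
        """Infer a uniform grid from an explicit wavelength vector."""
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise GridError("need at least two wavelengths to infer a grid")
        steps = np.diff(w)
        step = steps[0]
        if step <= 0 or np.any(np.abs(steps - step) > _REL_TOL * max(1.0, abs(step))):
            raise GridError("wavelengths are not uniformly spaced")
        return cls(float(w[0]), float(w[-1]), float(step))


@dataclass
class SpectraSet:
    """Sample-indexed absorbance matrix (AU) on a shared wavelength grid.

    Rows are samples, columns are grid points. Negative absorbances are
    permitted (baseline artifacts) but all values must be finite.
    """

    grid: WavelengthGrid
    sample_ids: list[str]
    absorbance: np.ndarray

    def __post_init__(self):
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, self.grid.n_points)
        n, p = self.absorbance.shape
        if n != len(self.sample_ids):
            raise ShapeError(f"{len(self.sample_ids)} sample ids but {n} spectra rows")
        if p != self.grid.n_points:
            raise ShapeError(f"grid has {self.grid.n_points} points but matrix has {p} columns")
        if n and not np.all(np.isfinite(self.absorbance)):
            raise SpectraParseError("absorbance matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def restrict(self, low_nm: float, high_nm: float) -> "SpectraSet":
        return restrict_range(self, low_nm, high_nm)


@dataclass
class ConcentrationTable:
    """Per-sample analyte concentrations in µg/mL."""

    sample_ids: list[str]
    analyte_names: list[str]
    concentrations: np.ndarray

    def __post_init__(self):
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.analyte_names = [str(a) for a in self.analyte_names]
        n, k = self.concentrations.shape
        if n != len(self.sample_ids) or k != len(self.analyte_names):
            raise ShapeError(
                f"concentration matrix {self.concentrations.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.analyte_names)} analytes"
            )
        if np.any(self.concentrations < 0):
            raise SpectraParseError("concentrations must be >= 0")

    def column(self, analyte: str) -> np.ndarray:
        try:
            j = self.analyte_names.index(analyte)
        except ValueError:
            raise KeyError(f"unknown analyte {analyte!r}; have {self.analyte_names}")
        return self.concentrations[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.concentrations, index=self.sample_ids, columns=self.analyte_names
        )


def _numeric(df: pd.DataFrame, path) -> np.ndarray:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~df.isna()
    if bad.to_numpy().any() or out.isna().to_numpy().any():
        rows = np.nonzero(out.isna().any(axis=1).to_numpy())[0]
        raise SpectraParseError(
            f"{path}: non-numeric or missing cell in data row(s) {rows.tolist()[:5]}"
        )
    return out.to_numpy(dtype=float)


def read_spectra_csv(path) -> SpectraSet:
    """Read a SpectraSet from CSV, auto-detecting the dialect.

    ``wavelength_nm`` as the first header token means wavelength-major
    (columns are samples); ``sample_id`` means sample-major (columns are
    wavelengths).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectraParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 1:
        raise SpectraParseError(f"{path}: empty file")
    first = df.columns[0].strip()
    if first == "wavelength_nm":
        wl = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        if wl.isna().any():
            raise SpectraParseError(f"{path}: non-numeric wavelength cell")
        grid = WavelengthGrid.from_wavelengths(wl.to_numpy())
        body = _numeric(df.iloc[:, 1:], path) if df.shape[1] > 1 else np.empty((len(df), 0))
        return SpectraSet(grid, list(df.columns[1:]), body.T)
    if first == "sample_id":
        try:
            wl = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise SpectraParseError(f"{path}: non-numeric wavelength header") from exc
        grid = WavelengthGrid.from_wavelengths(wl)
        body = _numeric(df.iloc[:, 1:], path)
        return SpectraSet(grid, df.iloc[:, 0].tolist(), body)
    raise SpectraParseError(
        f"{path}: first header token must be 'wavelength_nm' or 'sample_id', got {first!r}"
    )


def write_spectra_csv(spectra: SpectraSet, path):
    """Write wavelength-major CSV with >= 6 significant digits."""
    df = pd.DataFrame(
        spectra.absorbance.T, columns=spectra.sample_ids, index=spectra.grid.wavelengths()
    )
    df.index.name = "wavelength_nm"
    df.to_csv(path, float_format="%.9g")
    return path


def restrict_range(spectra: SpectraSet, low_nm: float, high_nm: float) -> SpectraSet:
    """Subset to grid points λ with low_nm <= λ <= high_nm (closed interval).

    The instrument scans 200–400 nm but modelling excludes the low-signal
    region above 350 nm, so restriction to 200–350 keeps 151 channels on a
    1-nm grid; 350 itself is retained.
    """
    g = spectra.grid
    lo = max(low_nm, g.start_nm)
    # first grid index >= lo and last index <= hi
    i0 = math.ceil((lo - g.start_nm) / g.step_nm - _REL_TOL)
    i1 = math.floor((min(high_nm, g.end_nm) - g.start_nm) / g.step_nm + _REL_TOL)
    if i1 < i0 or i0 >= g.n_points or i1 < 0:
        raise RangeError(f"[{low_nm}, {high_nm}] nm does not intersect the grid")
    wl = g.wavelengths()
    sub = WavelengthGrid(float(wl[i0]), float(wl[i1]), g.step_nm)
    return SpectraSet(sub, list(spectra.sample_ids), spectra.absorbance[:, i0 : i1 + 1].copy())


def write_concentrations_csv(table: ConcentrationTable, path):
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.9g")
    return path


def read_concentrations_csv(path) -> ConcentrationTable:
    df = pd.read_csv(path, dtype=str)
    if df.columns[0].strip() != "sample_id":
        raise SpectraParseError(f"{path}: first column must be 'sample_id'")
    body = _numeric(df.iloc[:, 1:], path)
    return ConcentrationTable(df.iloc[:, 0].tolist(), list(df.columns[1:]), body)
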