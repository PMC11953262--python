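"""Design-of-experiments generators for calibration and validation sets.

Two designs are used. The calibration set is a 25-run balanced fraction of
the 5^3 full factorial: factors A and B take all 25 level pairs over
{0..4} and factor C follows the cyclic (Latin-square) rule
``C = (A + B) mod 5``, which guarantees uniform level usage and pairwise
orthogonality. The validation set is a 3-factor central composite design
(CCD): the 2^3 cube at coded ±1, six axial points at coded ±alpha, and
replicated centre points — with alpha = 1.5 and six centre replicates the
total is the 20 runs used for external validation.

Coded levels map to physical concentrations (µg/mL) via
``physical = center + coded * unit``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError
from .spectra import ConcentrationTable

__all__ = [
    "DesignSpec",
    "DesignTable",
    "five_level_partial_factorial",
    "central_composite",
    "coded_to_physical",
]


@dataclass(frozen=True)
class DesignSpec:
    """Concentration levels and kind of a symmetric DOE.

    ``center`` must be the midpoint of ``low`` and ``high``; the defaults
    are the 2–10 µg/mL range (centre 6) within the method's linear dynamic
    range.
    """

    n_factors: int = 3
    center: float = 6.0
    low: float = 2.0
    high: float = 10.0
    kind: str = "partial_factorial_5level"
    axial_alpha: float = 1.5
    center_reps: int = 6

    def __post_init__(self):
        if not (self.low < self.center < self.high):
            raise DesignError(f"need low < center < high, got {self.low}/{self.center}/{self.high}")
        if abs(self.center - 0.5 * (self.low + self.high)) > 1e-9 * self.high:
            raise DesignError("center must be the midpoint of low and high")
        if self.axial_alpha <= 0:
            raise DesignError("axial_alpha must be > 0")
        if self.center_reps < 1:
            raise DesignError("center_reps must be >= 1")
        if self.kind not in ("partial_factorial_5level", "central_composite"):
            raise DesignError(f"unknown design kind {self.kind!r}")


@dataclass
class DesignTable:
    """Runs of a DOE in coded and physical (µg/mL) units."""

    run_ids: list[str]
    coded: np.ndarray
    physical: ConcentrationTable
    spec: DesignSpec
    unit: float = field(default=2.0)  # µg/mL per coded unit

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, name in enumerate(self.physical.analyte_names):
            cols[f"coded_{name}"] = self.coded[:, j]
        for j, name in enumerate(self.physical.analyte_names):
            cols[f"conc_{name}_ugml"] = self.physical.concentrations[:, j]
        df = pd.DataFrame(cols, index=self.run_ids)
        df.index.name = "run_id"
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, float_format="%.9g")
        return path


_DEFAULT_ANALYTES = ("propranolol", "rosuvastatin", "valsartan")


def coded_to_physical(coded, center: float, unit: float):
    """Map coded level(s) to physical concentration center + coded*unit."""
    if unit <= 0:
        raise DesignError(f"unit must be > 0, got {unit}")
    phys = center + np.asarray(coded, dtype=float) * unit
    if np.any(phys < 0):
        raise DesignError("coded level maps to a negative concentration")
    return phys if np.ndim(coded) else float(phys)


def five_level_partial_factorial(spec: DesignSpec, analyte_names=_DEFAULT_ANALYTES) -> DesignTable:
    """25-run cyclic fraction of the 5^3 factorial, coded levels -2..+2.

    Each factor uses each of the five levels exactly five times, and any
    two factors jointly realise all 25 level pairs exactly once.
    """
    if spec.n_factors != 3:
        raise DesignError(f"partial factorial is defined for 3 factors, got {spec.n_factors}")
    rows = []
    for a, b in itertools.product(range(5), range(5)):
        rows.append((a, b, (a + b) % 5))
    coded = np.array(rows, dtype=float) - 2.0
    unit = (spec.high - spec.center) / 2.0
    physical = coded_to_physical(coded, spec.center, unit)
    run_ids = [f"cal{r + 1:02d}" for r in range(25)]
    table = ConcentrationTable(run_ids, list(analyte_names), physical)
    return DesignTable(run_ids, coded, table, spec, unit)


def central_composite(spec: DesignSpec, unit: float | None = None,
                      analyte_names=_DEFAULT_ANALYTES) -> DesignTable:
    """Central composite design: cube, axial (star), then centre runs.

    ``unit`` is the physical width of one coded unit in µg/mL; by default
    it is chosen so the axial points at ±alpha land exactly on the low and
    high levels, i.e. unit = (high - center)/alpha, keeping the validation
    runs inside the calibration range.
    """
    if spec.kind != "central_composite":
        raise DesignError("spec.kind must be 'central_composite'")
    k = spec.n_factors
    if unit is None:
        unit = (spec.high - spec.center) / spec.axial_alpha
    if unit <= 0:
        raise DesignError(f"unit must be > 0, got {unit}")
    cube = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -spec.axial_alpha
        axial[2 * j + 1, j] = spec.axial_alpha
    center = np.zeros((spec.center_reps, k))
    coded = np.vstack([cube, axial, center])
    physical = spec.center + coded * unit
    bad = np.nonzero((physical <= 0).any(axis=1))[0]
    if bad.size:
        raise DesignError(
            f"runs {bad.tolist()} have non-positive concentrations "
            f"(center {spec.center}, unit {unit}, alpha {spec.axial_alpha})"
        )
    run_ids = [f"val{r + 1:02d}" for r in range(len(coded))]
    names = list(analyte_names)[:k] if len(analyte_names) >= k else [
        f"factor{j + 1}" for j in range(k)
    ]
    table = ConcentrationTable(run_ids, names, physical)
    return DesignTable(run_ids, coded, table, spec, unit)
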