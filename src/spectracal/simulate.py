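"""Synthetic ternary-mixture UV-Vis spectra.

The real instrument data behind this method are not publicly deposited, so
this module generates surrogate spectra with the statistical structure the
calibration method assumes: per-analyte absorptivity profiles built from
Gaussian bands, Beer–Lambert additivity over mixture components, additive
instrument noise, a small random linear baseline drift, and an optional
stray-light term that introduces a saturating nonlinearity at high
absorbance.

The default library emulates three cardiovascular drugs whose absorption
maxima sit at 214 nm (propranolol), 243 nm (rosuvastatin) and 246 nm
(valsartan); the last two overlap almost completely (3 nm apart), which is
exactly the regime where univariate quantification fails and multivariate
calibration is required. Band positions and widths are an emulation of the
published band shapes, not a reproduction: amplitudes are normalised so a
10 µg/mL single-analyte spectrum peaks at ~1.0 AU in a 1 cm cell.

Seed policy: ``simulate_dataset`` derives one sub-seed per run from the
master seed via ``numpy.random.SeedSequence([master_seed, run_index])``,
so any subset of runs reproduces independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, RangeError
from .spectra import ConcentrationTable, SpectraSet, WavelengthGrid

__all__ = [
    "GaussianBand",
    "AnalyteProfile",
    "NoiseModel",
    "NOISE_DEFAULT",
    "NOISE_NONLINEAR",
    "default_ternary_library",
    "simulate_spectrum",
    "simulate_dataset",
]


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band.

    ``amplitude`` is the molar-absorptivity-like coefficient at band
    centre, in AU·mL·µg^-1·cm^-1.
    """

    center_nm: float
    width_nm: float  # Gaussian sigma
    amplitude: float

    def __post_init__(self):
        if self.width_nm <= 0:
            raise DomainError("band width must be > 0")
        if self.amplitude <= 0:
            raise DomainError("band amplitude must be > 0")

    def epsilon(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        d = np.asarray(wavelengths_nm, dtype=float) - self.center_nm
        return self.amplitude * np.exp(-0.5 * (d / self.width_nm) ** 2)


@dataclass(frozen=True)
class AnalyteProfile:
    """Absorptivity profile of one analyte as a sum of Gaussian bands."""

    name: str
    bands: tuple[GaussianBand, ...]

    def __post_init__(self):
        if not self.bands:
            raise DomainError(f"profile {self.name!r} needs at least one band")

    def epsilon(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        return sum(b.epsilon(wl) for b in self.bands)

    def scaled(self, factor: float) -> "AnalyteProfile":
        return AnalyteProfile(
            self.name,
            tuple(GaussianBand(b.center_nm, b.width_nm, b.amplitude * factor) for b in self.bands),
        )


@dataclass(frozen=True)
class NoiseModel:
    """Instrument realism knobs.

    sd_au
        standard deviation of i.i.d. additive Gaussian noise per channel,
        in AU; 0.002 AU is a typical double-beam instrument noise floor.
    stray_light
        dimensionless stray-light fraction; > 0 bends high absorbances
        below the Beer–Lambert line (saturating nonlinearity).
    baseline_drift_au
        maximum magnitude of a random linear baseline ramp across the
        scanned range, in AU.
    """

    sd_au: float = 0.002
    stray_light: float = 0.0
    baseline_drift_au: float = 0.001

    def __post_init__(self):
        if self.sd_au < 0:
            raise DomainError("sd_au must be >= 0")
        if not 0 <= self.stray_light < 1:
            raise DomainError("stray_light must be in [0, 1)")
        if self.baseline_drift_au < 0:
            raise DomainError("baseline_drift_au must be >= 0")


NOISE_DEFAULT = NoiseModel()
# preset with mild stray light so a nonlinear network has curvature to exploit
NOISE_NONLINEAR = NoiseModel(sd_au=0.002, stray_light=5e-4, baseline_drift_au=0.001)
NOISE_NONE = NoiseModel(sd_au=0.0, stray_light=0.0, baseline_drift_au=0.0)

# raw band shapes (centre nm, sigma nm, relative amplitude); each profile is
# normalised afterwards so its on-grid maximum absorptivity is 0.1 AU·mL/µg
_RAW_LIBRARY = (
    ("propranolol", ((214.0, 7.0, 1.0), (288.0, 12.0, 0.22))),
    ("rosuvastatin", ((243.0, 12.0, 1.0), (215.0, 9.0, 0.45))),
    ("valsartan", ((246.0, 14.0, 1.0), (207.0, 9.0, 0.50))),
)
_LAMBDA_MAX = {"propranolol": 214.0, "rosuvastatin": 243.0, "valsartan": 246.0}
_PEAK_EPSILON = 0.1  # AU·mL/µg so that 10 µg/mL * 1 cm peaks at 1.0 AU


def default_ternary_library(grid: WavelengthGrid) -> list[AnalyteProfile]:
    """Three overlapping analyte profiles with maxima at 214/243/246 nm."""
    wl = grid.wavelengths()
    profiles = []
    for name, bands in _RAW_LIBRARY:
        lam = _LAMBDA_MAX[name]
        if not (grid.start_nm <= lam <= grid.end_nm):
            raise RangeError(f"grid does not cover the {lam} nm maximum of {name}")
        prof = AnalyteProfile(name, tuple(GaussianBand(*b) for b in bands))
        eps = prof.epsilon(wl)
        profiles.append(prof.scaled(_PEAK_EPSILON / float(eps.max())))
    return profiles


def _stray_transform(a_ideal: np.ndarray, s: float) -> np.ndarray:
    # observed absorbance when a fraction s of source light bypasses the sample
    return -np.log10(10.0 ** (-a_ideal) + s) + np.log10(1.0 + s)


def simulate_spectrum(grid: WavelengthGrid, profiles, conc, noise: NoiseModel = NOISE_DEFAULT,
                      path_cm: float = 1.0, seed: int = 0) -> np.ndarray:
    """One mixture spectrum: A = stray(Σ ε_k c_k L) + drift + e.

    The stray-light transform applies to the ideal Beer–Lambert absorbance
    before drift and noise are added; with the same seed the output is
    bit-identical.
    """
    conc = np.asarray(conc, dtype=float)
    if len(conc) != len(profiles):
        raise DomainError(f"{len(conc)} concentrations for {len(profiles)} profiles")
    if np.any(conc < 0):
        raise DomainError("concentrations must be >= 0")
    if path_cm <= 0:
        raise DomainError("path length must be > 0")
    wl = grid.wavelengths()
    ideal = path_cm * sum(c * p.epsilon(wl) for c, p in zip(conc, profiles))
    ideal = np.asarray(ideal, dtype=float) if np.ndim(ideal) else np.zeros_like(wl)
    if noise.stray_light > 0:
        ideal = _stray_transform(ideal, noise.stray_light)
    rng = np.random.default_rng(seed)
    out = ideal
    if noise.baseline_drift_au > 0:
        span = grid.end_nm - grid.start_nm
        ramp = (wl - grid.start_nm) / span if span > 0 else np.zeros_like(wl)
        out = out + rng.uniform(-noise.baseline_drift_au, noise.baseline_drift_au) * ramp
    if noise.sd_au > 0:
        out = out + rng.normal(0.0, noise.sd_au, size=wl.shape)
    return np.asarray(out, dtype=float)


def simulate_dataset(design, profiles, noise: NoiseModel = NOISE_DEFAULT, seed: int = 0,
                     grid: WavelengthGrid | None = None,
                     path_cm: float = 1.0) -> tuple[SpectraSet, ConcentrationTable]:
    """Simulate one spectrum per design run; sample ids are the run ids."""
    if grid is None:
        grid = WavelengthGrid(200.0, 400.0, 1.0)
    conc = design.physical.concentrations
    if conc.shape[1] != len(profiles):
        raise DomainError(
            f"design has {conc.shape[1]} analytes but {len(profiles)} profiles supplied"
        )
    rows = []
    for i in range(conc.shape[0]):
        sub_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0])
        rows.append(simulate_spectrum(grid, profiles, conc[i], noise, path_cm, sub_seed))
    absorbance = np.vstack(rows) if rows else np.empty((0, grid.n_points))
    names = [p.name for p in profiles]
    spectra = SpectraSet(grid, list(design.run_ids), absorbance)
    table = ConcentrationTable(list(design.run_ids), names, conc.copy())
    return spectra, table
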