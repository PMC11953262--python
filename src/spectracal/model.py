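"""Model/Results surface tying the calibration workflow together.

:class:`AnnCalibration` is built from a :class:`~spectracal.spectra.SpectraSet`
and a paired :class:`~spectracal.spectra.ConcentrationTable` for one analyte;
``fit()`` optionally scans the hidden-layer size, optionally runs firefly
wavelength selection, retrains the final network at full budget on the
winning mask, and returns a :class:`CalibrationResults` carrying the
trained network, the selection trace and the cross-validation error.
``CalibrationResults.validate`` scores an independent validation set and
returns the full figures-of-merit report; ``summary()`` renders a compact
table.

Example
-------
>>> cal = AnnCalibration(spectra, conc, analyte="propranolol")
>>> res = cal.fit(select_wavelengths=True)
>>> res.predict(validation_spectra)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import ann as _ann
from . import firefly as _fa
from . import metrics as _metrics
from .exceptions import ShapeError
from .spectra import ConcentrationTable, SpectraSet, read_concentrations_csv, read_spectra_csv

__all__ = ["AnnCalibration", "CalibrationResults"]


class AnnCalibration:
    """Neural calibration model for one analyte on a fixed wavelength grid."""

    def __init__(self, spectra: SpectraSet, concentrations: ConcentrationTable,
                 analyte: str, ann_config: _ann.AnnConfig | None = None,
                 fa_params: _fa.FaParams | None = None):
        if spectra.sample_ids != concentrations.sample_ids:
            raise ShapeError("spectra and concentration sample ids do not match")
        self.spectra = spectra
        self.concentrations = concentrations
        self.analyte = analyte
        self.y = concentrations.column(analyte)
        self.ann_config = ann_config or _ann.AnnConfig()
        self.fa_params = fa_params or _fa.FaParams()

    @classmethod
    def from_csv(cls, spectra_path, concentrations_path, analyte, **kwargs):
        return cls(read_spectra_csv(spectra_path), read_concentrations_csv(concentrations_path),
                   analyte, **kwargs)

    def fit(self, select_wavelengths: bool = True, scan_neurons: tuple[int, int] | None = None,
            fitness_config: _ann.AnnConfig | None = None) -> "CalibrationResults":
        """Train the calibration network.

        ``fitness_config`` is the reduced-budget ANN used inside the FA
        fitness loop (defaults to the main config with ``max_epochs=200``
        and a single restart); the returned model is always retrained at
        the full budget on the winning mask.
        """
        X = self.spectra.absorbance
        config = self.ann_config
        scan = None
        if scan_neurons is not None:
            scan = _ann.scan_hidden_neurons(X, self.y, scan_neurons[0], scan_neurons[1], config)
            config = replace(config, n_hidden=scan.selected_n_hidden)
        inner = fitness_config or replace(config, max_epochs=200, n_restarts=1)
        selection = None
        mask = None
        if select_wavelengths:
            selection = _fa.fa_select(X, self.y, self.fa_params, inner)
            mask = selection.mask
        model = _ann.train_ann(X, self.y, config, wavelength_mask=mask)
        cv = _ann.loo_cross_validate(X, self.y, inner, wavelength_mask=mask)
        return CalibrationResults(self, model, selection, cv, scan)


@dataclass
class CalibrationResults:
    """Fitted calibration: trained network, selection trace, diagnostics."""

    calibration: AnnCalibration
    trained: _ann.TrainedModel
    selection: _fa.SelectionResult | None
    cross_validation: _ann.LooResult
    neuron_scan: _ann.ScanResult | None = None

    @property
    def analyte(self) -> str:
        return self.calibration.analyte

    @property
    def rrmsecv(self) -> float:
        return self.cross_validation.rrmsecv

    @property
    def rrmsec(self) -> float:
        return self.trained.training_rrmsec

    @property
    def n_selected(self) -> int:
        return int(self.trained.wavelength_mask.sum())

    def predict(self, spectra) -> np.ndarray:
        """Predict concentrations (µg/mL) for a SpectraSet or matrix."""
        X = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(spectra)
        return _ann.predict(self.trained, X)

    def validate(self, spectra_val, conc_val: ConcentrationTable,
                 intraday_values=None, interday_values=None,
                 comparison=None) -> _metrics.ValidationReport:
        pred_val = self.predict(spectra_val)
        ref_val = conc_val.column(self.analyte)
        pred_cal = self.predict(self.calibration.spectra)
        return _metrics.build_validation_report(
            self.analyte, pred_cal, self.calibration.y, pred_val, ref_val,
            intraday_values=intraday_values, interday_values=interday_values,
            comparison=comparison,
        )

    def summary(self) -> str:
        lines = [
            f"ANN calibration results — {self.analyte}",
            "=" * 44,
            f"hidden neurons        {self.trained.config.n_hidden}",
            f"transfer              {self.trained.config.hidden_transfer}-"
            f"{self.trained.config.output_transfer}",
            f"wavelengths used      {self.n_selected} / {self.trained.wavelength_mask.size}",
            f"training RRMSEC %     {self.rrmsec:.4f}",
            f"LOO RRMSECV %         {self.rrmsecv:.4f}",
        ]
        if self.selection is not None:
            lines.append(f"FA generations        {self.selection.generations_run}")
            lines.append(f"FA best RRMSECV %     {self.selection.best_rrmsecv:.4f}")
        for w in self.trained.warnings:
            lines.append(f"note: {w}")
        return "\n".join(lines)
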