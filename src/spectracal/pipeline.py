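"""End-to-end workflow: simulate → calibrate → select → validate → report.

Every stage writes plain-text artifacts (CSV/JSON/markdown) into one
output directory and is regenerable from the run configuration plus the
master seed. Stages communicate through those artifacts, so the CLI can
rerun any stage in isolation; :func:`run_pipeline` chains them all.

In synthetic mode the spectra come from :mod:`spectracal.simulate`; in
real-spectra mode the configuration points at user CSVs and the
downstream path is identical. Since no reference-method (HPLC) data can
exist for simulated samples, the method-comparison table is computed
against a *synthetic* reference method: five determinations drawn around
the nominal value with a 1.5%-RSD normal error, the precision class of a
routine pharmaceutical HPLC assay.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .ann import AnnConfig, loo_cross_validate, train_ann, TrainedModel
from .design import DesignSpec, DesignTable, central_composite, five_level_partial_factorial
from .exceptions import ConfigError, SpectracalError, StageError
from .firefly import FaParams, fa_select
from .metrics import build_validation_report, compare_methods, recovery_pct
from .model import AnnCalibration
from .simulate import NoiseModel, default_ternary_library, simulate_dataset, simulate_spectrum
from .spectra import (ConcentrationTable, SpectraSet, WavelengthGrid, read_concentrations_csv,
                      read_spectra_csv, restrict_range, write_concentrations_csv,
                      write_spectra_csv)

__all__ = ["RunConfig", "run_pipeline"]

ANALYTES = ("propranolol", "rosuvastatin", "valsartan")


@dataclass
class RunConfig:
    """Single configuration object for the whole workflow."""

    seed: int = 1
    grid: WavelengthGrid = field(default_factory=lambda: WavelengthGrid(200.0, 400.0, 1.0))
    restrict_low_nm: float = 200.0
    restrict_high_nm: float = 350.0
    design: DesignSpec = field(default_factory=DesignSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    ann: AnnConfig = field(default_factory=lambda: AnnConfig(n_hidden=2, n_restarts=2,
                                                             max_epochs=300))
    fa: FaParams = field(default_factory=lambda: FaParams(n_fireflies=8, max_generations=12,
                                                          stagnation_window=6))
    select_wavelengths: bool = True
    analytes: tuple[str, ...] = ANALYTES
    # real-spectra mode: paths to existing CSVs (overrides simulation)
    calibration_spectra_csv: str | None = None
    calibration_concentrations_csv: str | None = None
    validation_spectra_csv: str | None = None
    validation_concentrations_csv: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            kw = {}
            if "seed" in raw:
                kw["seed"] = int(raw["seed"])
            if "grid" in raw:
                g = raw["grid"]
                kw["grid"] = WavelengthGrid(float(g["start"]), float(g["end"]),
                                            float(g.get("step", 1.0)))
            if "restrict" in raw:
                kw["restrict_low_nm"], kw["restrict_high_nm"] = map(float, raw["restrict"])
            for key, typ in (("design", DesignSpec), ("noise", NoiseModel),
                             ("ann", AnnConfig), ("fa", FaParams)):
                if key in raw:
                    kw[key] = typ(**raw[key])
            if "select_wavelengths" in raw:
                kw["select_wavelengths"] = bool(raw["select_wavelengths"])
            if "analytes" in raw:
                kw["analytes"] = tuple(raw["analytes"])
            for key in ("calibration_spectra_csv", "calibration_concentrations_csv",
                        "validation_spectra_csv", "validation_concentrations_csv"):
                if key in raw:
                    kw[key] = raw[key]
            return cls(**kw)
        except ConfigError:
            raise
        except (KeyError, TypeError, ValueError, SpectracalError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "grid": {"start": self.grid.start_nm, "end": self.grid.end_nm,
                     "step": self.grid.step_nm},
            "restrict": [self.restrict_low_nm, self.restrict_high_nm],
            "design": dataclasses.asdict(self.design),
            "noise": dataclasses.asdict(self.noise),
            "ann": dataclasses.asdict(self.ann),
            "fa": dataclasses.asdict(self.fa),
            "select_wavelengths": self.select_wavelengths,
            "analytes": list(self.analytes),
        }


def _write_json(path, payload):
    with open(path, "w") as fh:
        fh.write(json.dumps(payload, indent=1, sort_keys=True))
    return path


def _seed_for(config: RunConfig, *tags) -> int:
    # zlib.crc32 is a stable string hash (Python's hash() is salted per process)
    key = [int(config.seed)] + [zlib.crc32(t.encode()) if isinstance(t, str) else int(t)
                                for t in tags]
    return int(np.random.SeedSequence(key).generate_state(1)[0])


def stage_design(config: RunConfig, outdir) -> dict[str, DesignTable]:
    cal_spec = dataclasses.replace(config.design, kind="partial_factorial_5level")
    val_spec = dataclasses.replace(config.design, kind="central_composite")
    cal = five_level_partial_factorial(cal_spec, config.analytes)
    val = central_composite(val_spec, analyte_names=config.analytes)
    cal.to_csv(os.path.join(outdir, "design_calibration.csv"))
    val.to_csv(os.path.join(outdir, "design_validation.csv"))
    return {"calibration": cal, "validation": val}


def stage_simulate(config: RunConfig, outdir, designs) -> dict:
    """Simulate (or load) spectra and write the CSV pairs + JSON sidecar."""
    profiles = default_ternary_library(config.grid)
    datasets = {}
    if config.calibration_spectra_csv:
        datasets["calibration"] = (read_spectra_csv(config.calibration_spectra_csv),
                                   read_concentrations_csv(config.calibration_concentrations_csv))
        datasets["validation"] = (read_spectra_csv(config.validation_spectra_csv),
                                  read_concentrations_csv(config.validation_concentrations_csv))
    else:
        for name, offset in (("calibration", 0), ("validation", 1)):
            spectra, conc = simulate_dataset(designs[name], profiles, config.noise,
                                             seed=_seed_for(config, "simulate", offset),
                                             grid=config.grid)
            datasets[name] = (spectra, conc)
    for name, (spectra, conc) in datasets.items():
        write_spectra_csv(spectra, os.path.join(outdir, f"spectra_{name}.csv"))
        write_concentrations_csv(conc, os.path.join(outdir, f"concentrations_{name}.csv"))
    _write_json(os.path.join(outdir, "simulation.json"), {
        "seed": config.seed,
        "noise": dataclasses.asdict(config.noise),
        "profiles": [
            {"name": p.name,
             "bands": [dataclasses.asdict(b) for b in p.bands]} for p in profiles
        ],
        "mode": "real" if config.calibration_spectra_csv else "synthetic",
    })
    return datasets


def _restricted(config: RunConfig, datasets):
    out = {}
    for name, (spectra, conc) in datasets.items():
        out[name] = (restrict_range(spectra, config.restrict_low_nm, config.restrict_high_nm),
                     conc)
    return out


def stage_models(config: RunConfig, outdir, datasets) -> dict:
    """Per-analyte calibration: optional FA selection + final training."""
    cal_spectra, cal_conc = datasets["calibration"]
    results = {}
    for k, analyte in enumerate(config.analytes):
        ann_cfg = dataclasses.replace(config.ann, seed=_seed_for(config, "ann", k))
        fa_par = dataclasses.replace(config.fa, seed=_seed_for(config, "fa", k))
        cal = AnnCalibration(cal_spectra, cal_conc, analyte, ann_config=ann_cfg,
                             fa_params=fa_par)
        res = cal.fit(select_wavelengths=config.select_wavelengths)
        tag = "fa" if config.select_wavelengths else "full"
        res.trained.to_json(os.path.join(outdir, f"model_{analyte}.json"))
        if res.selection is not None:
            payload = res.selection.to_dict()
            payload["seed"] = config.seed
            _write_json(os.path.join(outdir, f"selection_{analyte}.json"), payload)
        results[analyte] = (res, tag)
    return results


def stage_validate(config: RunConfig, outdir, datasets, models) -> dict:
    """Figures of merit + synthetic reference-method comparison per analyte."""
    val_spectra, val_conc = datasets["validation"]
    profiles = default_ternary_library(config.grid)
    reports = {}
    for k, analyte in enumerate(config.analytes):
        res, tag = models[analyte]
        # precision series: replicate centre-point mixtures re-simulated
        # within one day (intra) and across three days (inter)
        centre = np.full(len(config.analytes), config.design.center)
        intra, inter = [], []
        for rep in range(6):
            s = simulate_spectrum(config.grid, profiles, centre, config.noise,
                                  seed=_seed_for(config, "intraday", k, rep))
            full = SpectraSet(config.grid, ["rep"], s.reshape(1, -1))
            sub = restrict_range(full, config.restrict_low_nm, config.restrict_high_nm)
            intra.append(float(res.predict(sub)[0]))
        for day in range(3):
            for rep in range(2):
                s = simulate_spectrum(config.grid, profiles, centre, config.noise,
                                      seed=_seed_for(config, "interday", k, day, rep))
                full = SpectraSet(config.grid, ["rep"], s.reshape(1, -1))
                sub = restrict_range(full, config.restrict_low_nm, config.restrict_high_nm)
                inter.append(float(res.predict(sub)[0]))
        proposed = [recovery_pct(v, config.design.center) for v in intra[:5]]
        ref_rng = np.random.default_rng(_seed_for(config, "reference", k))
        reference = 100.0 * (1.0 + ref_rng.normal(0.0, 0.015, size=5))
        comparison = compare_methods(proposed, reference)
        report = res.validate(val_spectra, val_conc, intraday_values=intra,
                              interday_values=inter, comparison=comparison)
        report.to_json(os.path.join(outdir, f"validation_{analyte}.json"))
        reports[analyte] = (report, tag)
    return reports


def stage_report(config: RunConfig, outdir, models, reports):
    lines = ["# Calibration run report", "",
             f"spectracal {__version__}, master seed {config.seed}", ""]
    for analyte in config.analytes:
        res, tag = models[analyte]
        report, _ = reports[analyte]
        lines.append(f"## {analyte} ({tag} spectrum model)")
        lines.append("")
        lines.append("```")
        lines.append(res.summary())
        lines.append("```")
        lines.append("")
        lines.append(report.to_markdown())
    path = os.path.join(outdir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return path


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; abort with the stage name on the first failure."""
    os.makedirs(outdir, exist_ok=True)
    completed = []
    artifacts = {"outdir": outdir}

    def run(name, fn, *args):
        try:
            out = fn(config, outdir, *args)
        except Exception as exc:
            raise StageError(name, str(exc), completed) from exc
        completed.append(name)
        return out

    designs = run("design", stage_design)
    datasets = run("simulate", stage_simulate, designs)
    restricted = _restricted(config, datasets)
    models = run("models", stage_models, restricted)
    reports = run("validate", stage_validate, restricted, models)
    run("report", lambda c, o: stage_report(c, o, models, reports))
    _write_json(os.path.join(outdir, "run_log.json"), {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": completed,
        "rrmsecv": {a: models[a][0].rrmsecv for a in config.analytes},
        "n_selected": {a: models[a][0].n_selected for a in config.analytes},
    })
    artifacts.update(designs=designs, datasets=datasets, models=models, reports=reports)
    return artifacts
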