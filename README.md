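# spectracal

Multivariate calibration of severely overlapping UV-Vis spectra with
firefly-algorithm wavelength selection and single-hidden-layer neural
networks.

## The problem

Ternary drug mixtures — here modelled on propranolol (λmax 214 nm),
rosuvastatin (243 nm) and valsartan (246 nm) — cannot be quantified by
direct UV spectrophotometry because their absorption bands overlap almost
completely (the second and third maxima are 3 nm apart). `spectracal`
implements the full chemometric workflow that makes the determination
possible anyway:

1. **Designed calibration/validation sets** — a 25-run balanced five-level
   partial factorial (cyclic fraction of 5³, levels 2–10 µg/mL, centre 6)
   for calibration and a 20-run central composite design (α = 1.5, six
   centre replicates) for external validation.
2. **Synthetic spectra** — Gaussian-band absorptivity profiles combined by
   Beer–Lambert additivity, with instrument noise, baseline drift and
   optional stray-light nonlinearity (no public instrument data exist for
   this system, so the simulator is a first-class, tested module).
3. **Neural calibration** — one network per analyte, single hidden layer
   (`purelin` or `tansig`), trained by Levenberg–Marquardt on min-max
   scaled inputs: damping µ starts at the configured "learning rate", ×10
   on a rejected step, ÷10 on an accepted one.
4. **Firefly wavelength selection** — binary masks over the 151-channel
   modelling grid (200–350 nm at 1 nm), fitness = leave-one-out RRMSECV,
   canonical attraction β₀·exp(−γr²), elitist bookkeeping and a
   stagnation-window convergence rule.
5. **Validation statistics** — slope/intercept/R² of predicted vs actual,
   ICH LOD/LOQ (3.3σ/S, 10σ/S), RRMSEC/RRMSEP and bias-corrected RRMSEP,
   recovery %, RSD %, and pooled t / variance-ratio F method comparison.

The central figure of merit is the relative root-mean-square error

    RRMSE% = 100 · sqrt( Σᵢ (ŷᵢ − yᵢ)² / n ) / ȳ

evaluated under leave-one-out cross-validation (RRMSECV), on the
calibration set (RRMSEC), or on the external validation set (RRMSEP).

## Worked example

```python
from spectracal.pipeline import RunConfig, run_pipeline

artifacts = run_pipeline(RunConfig(seed=1), "out")
res, _ = artifacts["models"]["propranolol"]
print(res.summary())
```

prints (computed, not typeset):

```
ANN calibration results — propranolol
============================================
hidden neurons        2
transfer              purelin-purelin
wavelengths used      63 / 151
training RRMSEC %     0.0000
LOO RRMSECV %         0.6381
FA generations        12
FA best RRMSECV %     0.6381
note: overparameterized: 131 weights for 25 samples; LM damping regularizes the fit
```

The firefly selector kept 63 of 151 channels and the selected-wavelength
model cross-validates at 0.64% relative error. Training error is ~0
because the over-parameterised linear network interpolates the 25
calibration samples — which is why model quality is judged by RRMSECV and
by the external validation set, never by RRMSEC. The corresponding
validation report (`artifacts["reports"]`) adds slope 0.9959, R² 0.9993,
LOD 0.18 µg/mL, RRMSEP 0.92% and mean recovery 100.2% for this seed.

The same workflow is scriptable from the shell:

```sh
spectracal all --out out                 # default synthetic workflow
spectracal simulate --config cfg.yaml --out out
spectracal predict --model out/model_propranolol.json \
                   --spectra out/spectra_validation.csv
```

Statsmodels-style objects are available for finer control:
`spectracal.AnnCalibration(spectra, conc, analyte).fit()` returns a
`CalibrationResults` with `predict`, `validate` and `summary`.

## Acceptance script

`scripts/acceptance.py` re-runs the complete default workflow from
scratch — designs, simulated spectra, firefly selection, training and
validation for all three analytes — and writes its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The full artifact set (designs, spectra, masks, models, validation
reports, run log) is left in `results/pipeline_artifacts/`.
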