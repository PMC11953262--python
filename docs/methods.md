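# Methods

## Model

Each analyte is quantified by an independent feedforward network with one
hidden layer and one linear output neuron. Inputs are the absorbance
values at the selected wavelengths of the 200–350 nm modelling window
(151 channels at 1 nm before selection; the 350–400 nm region is excluded
because its absorbance is too low to carry signal). Inputs and target are
min-max scaled to [−1, 1] per column; constant columns get unit scale and
a recorded warning. The default `purelin–purelin` configuration makes the
network algebraically linear — it is kept because it is the configuration
the method is defined with, and `tansig` is exposed for data with genuine
curvature (e.g. stray-light saturation). One network per analyte, never a
three-output net.

### Training

Weights minimise the SSE by Levenberg–Marquardt with the classic damping
schedule: µ starts at `learning_rate` (default 0.1), is multiplied by 10
whenever a candidate step fails to reduce the SSE and divided by 10 when
it succeeds; steps solve (JᵀJ + µI)δ = −Jᵀr with the analytic Jacobian.
Stopping: `max_epochs` (default 1000), gradient infinity-norm below
`grad_tol` (1e-7), or µ > 1e10. The best of `n_restarts` (default 5)
random initialisations is kept; initial weights are uniform in
±1/√(n_inputs) for the first layer and ±0.5 elsewhere. "Learning rate" is
interpreted as the initial damping because LM has no classical learning
rate; large values (10, 100) simply start the optimiser closer to
gradient descent and are tolerated well.

With 25 calibration samples and ≥ 50 masked channels the network is
over-parameterised; the damped LM step acts as a ridge-like regulariser
and the model record carries an explicit warning. Model quality is
therefore judged exclusively by leave-one-out RRMSECV and by external
validation, never by the (near-zero) training error.

### Cross-validation and architecture scan

`RRMSE% = 100·RMSE/mean(reference)` uniformly for RRMSEC / RRMSECV /
RRMSEP; the source material uses the abbreviations without defining the
normalisation, and mean-of-reference is the standard chemometric choice.
LOO fold seeds derive from the configuration seed and the fold index
only, so fitness evaluations of different wavelength masks share
identical folds. The neuron scan selects the smallest hidden-layer size
whose RRMSECV is within 5% (relative) of the scan minimum — a parsimony
tie-break against overfitting.

## Firefly wavelength selection

Canonical firefly algorithm on continuous positions in [0,1]^W with
threshold-0.5 binarisation for fitness (sigmoid sampling available as an
option): attraction β₀·exp(−γr²) with Euclidean r, movement toward every
brighter firefly plus a uniform perturbation scaled by α, positions
clipped to [0,1]. Fitness is the LOO RRMSECV of the masked channels;
masks with fewer than `min_selected` channels (default: hidden neurons
+ 2) score +∞. Convergence: best-so-far improvement below 1e-6 absolute
percentage points over `stagnation_window` (default 50) consecutive
generations. Fitness values are cached per mask.

Two deliberate deviations from a purely random population:

* one initial firefly is warm-started at the all-ones mask, so the
  selected subset can never cross-validate worse than the full spectrum
  under the same budget — the qualitative "selection does not hurt" claim
  becomes structural instead of stochastic;
* the search is elitist: the best mask ever evaluated is returned even if
  the population drifts away from it.

Inner-loop cost control: FA fitness uses a reduced training budget
(`max_epochs` 200, one restart); the final model is retrained at full
budget on the winning mask. The FA hyperparameter grid
(γ ∈ {0.1, 1, 10}, β₀ ∈ {0.5, 1, 2}, α ∈ {0.1, 0.2, 0.5}) is a stand-in
assembled from standard firefly-literature values; grid-search ties break
toward the smaller mask, then grid order.

## Experimental designs

* Calibration: the 25-run cyclic (Latin-square) fraction of 5³ —
  C = (A+B) mod 5 on levels {0..4}, centred to coded −2..+2, physical
  levels {2,4,6,8,10} µg/mL. The particular 25-run fraction is not
  documented for the original data; the cyclic generator is the standard
  balanced multilevel calibration design (uniform level usage, pairwise
  orthogonality, all level pairs once).
* Validation: 3-factor CCD — 8 cube points at ±1, 6 axial at ±1.5, 6
  centre replicates (6 chosen so 8+6+6 matches the documented 20 runs).
  The coded unit defaults to (high−center)/α ≈ 2.667 µg/mL so the axial
  points land exactly on the 2 and 10 µg/mL range limits, keeping
  validation inside the calibrated range; it is configurable.
* Run order is deterministic (cube, axial, centre); randomisation is left
  to the caller so fixtures stay reproducible.

## Synthetic spectra

The generator emulates, not reproduces, the real system: per-analyte
absorptivity profiles are sums of Gaussian bands (a 214 nm band plus a
weak 288 nm aromatic shoulder; 243 nm and 246 nm main bands with short-
wavelength shoulders for the other two), normalised so a 10 µg/mL
single-analyte spectrum peaks at 1.0 AU in a 1 cm cell. Mixture spectra
are Beer–Lambert additive; noise defaults are a 0.002 AU i.i.d. Gaussian
floor, a random linear baseline ramp of ≤ 0.001 AU, and stray light 0
(a `NOISE_NONLINEAR` preset with s = 5e-4 bends high absorbances below
the linear response, giving a nonlinear network something to exploit).
These defaults are typical of a routine double-beam instrument. Per-run
seeds derive from `SeedSequence([master_seed, run_index])`, so subsets
reproduce.

What a green test does **not** establish: the generator has no
Lorentzian/Voigt band shapes, no wavelength-correlated noise, no pH or
temperature effects and no real absorptivity ratios (those are only
qualitatively known), so agreement on synthetic fixtures demonstrates the
correctness of the algorithms, not instrument-level performance. Published
headline figures that depend on the undeposited instrument spectra are
mirrored qualitatively (sub-2% RRMSECV, ~1% RRMSEP, ≈60% dimensionality
reduction), never numerically.

In the pipeline's synthetic mode the reference-method comparison is run
against a *synthetic* reference: five determinations drawn as
nominal·(1 + N(0, 0.015)), the precision class of a routine HPLC assay.
With only five determinations per method the pooled t occasionally flags
a difference for particular seeds — an expected property of the test at
n = 5, visible in the worked example.

## Validation statistics

* LOD = 3.3σ/S and LOQ = 10σ/S with σ the (n−1) residual SD of the
  predicted-vs-actual validation regression and S its slope (ICH Q2(R1)
  convention, consistent with the forced LOQ/LOD ratio 10/3.3).
* Pooled-variance two-sample t (df = n₁+n₂−2, |t| reported, two-tailed
  p); variance-ratio F with the larger variance in the numerator and a
  doubled upper-tail p capped at 1. The tabulated two-sided 5% thresholds
  for 5+5 determinations are t(8) = 2.306 and F(4,4) = 6.39; the package
  always reports computed quantiles rather than hard-coding table values.
* Intra-day precision uses six re-simulated centre-point replicates;
  inter-day uses two replicates on each of three simulated days.

## Numerical choices and limitations

* Grid stored as (start, end, step); wavelengths materialised on demand;
  range restriction is closed on both ends (350 nm retained, 351+
  dropped); a single-point restriction yields a degenerate start == end
  grid.
* CSV is the only on-disk spectra format (wavelength-major written;
  sample-major also accepted on read); models and selection results
  serialise to JSON for exact reload.
* Determinism: every stochastic step (simulation, weight initialisation,
  LOO folds, FA population, grid-search cells) is keyed to the master
  seed through `SeedSequence` splitting, and pipeline reruns are
  bit-identical.
* Known limitations: LM forms JᵀJ explicitly (fine at ≤ a few thousand
  parameters, not for large nets); the FA is serial and single-objective;
  no derivative/smoothing preprocessing; no vendor file formats.
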