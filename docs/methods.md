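# Methods

## The problem

Differential-pulse voltammetry (DPV) of NSAID mixtures yields a single
current trace per sample in which the analyte oxidation peaks overlap:
paracetamol (0.446 V) and diclofenac (0.629 V, second oxidation near
1.02 V) are resolvable by eye, while naproxen (0.888 V) and aspirin
(0.880 V) merge into one envelope. Quantifying all four simultaneously is
therefore a multivariate calibration problem: learn a map from the full
trace (compressed) to the four concentrations.

## Synthetic voltammograms

The generator replaces electrode measurements with a parametric model
whose statistical structure matches what the calibration assumes:

    I(E) = b0 + b1·E + Σ_peaks s_p · c(owner_p) · exp(−(E − E_p)² / 2w_p²) + ε,
    ε ~ N(0, σ²)

* **Grid** — 177 points from 0 V in steps of 0.00585 V (the optimized step
  potential), ending at ≈1.030 V. The printed scan window ("0 to 1.05 V")
  and the printed point count cannot both hold exactly at this step; the
  point count and step are taken as authoritative.
* **Peak shape** — symmetric Gaussian with σ = 0.05 V, the standard
  idealization for DPV peaks; no functional form is prescribed by the
  underlying experiments.
* **Sensitivities** — anchored to the pH-10 peak-current ratios of an
  equimolar four-drug mix (7.26 : 8.81 : 18.10 for paracetamol :
  diclofenac : naproxen+aspirin combined), with paracetamol fixed at
  0.1 µA per µmol L⁻¹. Naproxen and aspirin split their combined
  sensitivity equally; diclofenac's second peak carries 40 % of its
  primary sensitivity. Only relative magnitudes are anchored; the absolute
  scale is a free choice.
* **Interferents** — ascorbic acid contributes a small peak at 0.30 V
  (0.02 µA/µM); glucose and SDS are not redox-active and instead scale the
  baseline slope by (1 + 0.001·c) each. Defaults are fixed at
  80 / 18.5 / 22 µmol L⁻¹.
* **Baseline and noise** — linear baseline (0.5 µA intercept, 2 µA/V
  slope) and white Gaussian noise with σ equal to 1 % of the maximum clean
  current of the 81-sample training set (≈0.23 µA). Real DPV noise and
  baseline drift are unreported for this system; these are stand-ins
  chosen to be realistic for a carbon-paste electrode, not
  reconstructions.
* **Designs** — training: 3⁴ full factorial over {0.5, 40.25, 80} µmol L⁻¹
  (range endpoints plus arithmetic midpoint; only the range is
  prescribed). Testing: concentrations i.i.d. uniform on [0.5, 80].

What the generator deliberately omits: electron-transfer kinetics, pH
dependence, scan-rate effects, electrode fouling/drift between runs,
peak-potential shifts with concentration, and any nonlinearity of response
(saturation). Passing tests therefore demonstrate that the *pipeline
mechanics* recover parameters under the assumed linear-additive model —
they cannot certify performance on real electrode data, where the
PLS-vs-MLP contrast may differ (on this linear simulator PLS is already
near-perfect; the published experiments found PLS failing for
naproxen/aspirin, which points at nonlinear effects the simulator does not
emulate).

## Experimental designs

Full factorials enumerate levels lexicographically in coded units
(three-level designs use {−1, 0, +1}). The Box–Behnken design places, for
every factor pair, the four (±1, ±1) edge midpoints with the remaining
factors at 0, plus center points (default 3, fixing the four-factor run
count at 24 + 3 = 27). Run order is deterministic; no randomization is
applied (reproducibility; run order has no meaning for a simulator).
Coded→physical mapping is the affine map low + (x+1)/2·(high−low).
The physical windows of the four DPV factors behind the published coded
models were never printed; the shipped defaults bracket the published
optimum (step potential [0.002, 0.01] V, interval time [0.25, 1.25] s,
modulation time [0.05, 0.25] s, modulation amplitude [0.025, 0.125] V) and
physical-unit optima are only meaningful relative to a user-supplied
window.

## Response surfaces

A full quadratic in k coded factors (1 + 2k + k(k−1)/2 coefficients; 14
for k = 4) fitted by unweighted least squares; fitting requires a
design of expansion rank 14 and at least 15 runs. The multi-response
optimizer maximizes a weighted sum of min-max-normalized responses (each
response scaled to [0, 1] over a dense grid of the coded cube, default 41
points per axis, equal weights) and then polishes the best grid point with
bounded L-BFGS-B; normalization constants are frozen from the grid so the
off-grid objective is well defined, and the polished point is only
accepted if it improves on the grid optimum. The published desirability
settings of the original multi-response optimization were not printed;
min-max normalization with equal weights is this package's choice.

## Wavelet compression

Level-3 discrete wavelet transform with Daubechies-4 (8-tap filters) and
symmetric half-point boundary extension with full-convolution lengths —
the one standard convention under which 177 → 92 → 49 → 28, matching the
published 28 × 81 compressed matrix. Only approximation coefficients are
retained (no detail thresholding). Reconstruction inverts the cascade with
detail bands zeroed and trims to the original length. The "comparison
factor" between an original and reconstructed trace is their Pearson
correlation; the formula behind the published 0.9823 was not stated, and
correlation is the conventional similarity score with the right bounds.
On default synthetic sets the mean comparison factor is ≈0.996 — smooth
Gaussian-peak signals compress better than the published real
voltammograms did.

## PLS calibration

NIPALS partial least squares (via scikit-learn's `PLSRegression`,
`scale=False`) on mean-centered blocks, default 12 components as
published. `select_components` minimizes mean k-fold (default 10-fold,
contiguous deterministic folds) cross-validated RMSE over the four
analytes, breaking ties toward fewer components. At full rank PLS
reproduces the multivariate OLS solution; this is the main correctness
oracle in the tests.

## MLP calibration

Architecture 28×16×8×4: identity input stage ("purelin" input interpreted
as no trainable input activation), tanh hidden layers, linear output.
Inputs and targets are min-max scaled to [−1, 1] (constant columns map to
a unit span); predictions are returned in original units.

Training minimizes F = β·ΣE² + α·Σw² by Levenberg–Marquardt with an
explicit per-residual Jacobian (636 parameters, validated against finite
differences). The schedule has three numerical choices that matter, all
driven by the fact that the network is over-parameterized relative to the
81×4 training residuals:

1. **Noise-matched input augmentation.** Each epoch, the training batch is
   the 81 original samples plus 10 copies jittered with fresh Gaussian
   noise at the known measurement σ (white trace noise passes through the
   orthogonal db4 analysis at the same σ, so the jitter is applied
   directly to the coefficients). This is Tikhonov-type regularization
   matched to the instrument noise. Without it, the net interpolates the
   noisy training set and amplifies the nearly collinear naproxen/aspirin
   direction, making external-set predictions erratic; with it, the
   external-set correlation is stable (R ≈ 0.95–0.99 across seeds).
2. **Error-goal stopping on the clean set.** Training stops when the mean
   squared error of the *un-augmented* training set on scaled targets
   falls to 0.015 (or at 2000 epochs). Evaluating the goal on the
   augmented batch would stop the optimizer mid-descent at a
   noise-realization-dependent point.
3. **Warm-up before evidence updates.** MacKay's evidence re-estimation of
   (α, β) assumes the weights sit near a minimum of the current objective;
   applied from a random initialization it inflates α and traps the net in
   an over-regularized basin. The hyperparameters are therefore frozen at
   (α = 0, β = 1) for a warm-up (default 200 epochs or until the trust
   region collapses), after which evidence updates engage, with the
   effective parameter count γ clipped to 0.99·N to keep β positive in the
   over-parameterized regime.

Weights initialize uniform in [−0.5, 0.5] from a seeded generator; the
whole procedure is deterministic given the seed. A full-batch
gradient-descent solver with the published learning rate (0.05) and
momentum (0.5) is provided as `solver="sgd"`; those two settings are
meaningless for LM and are accepted only for that mode.

## Figures of merit

Obtained-vs-expected OLS per analyte; R is the Pearson correlation, Δm and
Δb are two-sided 95 % t-based half-widths (t quantile at n−2 degrees of
freedom times the coefficient standard errors), σ_res = √(SSE/(n−2)).
Recovery Ry = (100/N)·Σ yᵢ/y_exp,i; undefined when any expected value is
zero. LOD = 3σ/m and LOQ = 10σ/m with σ = σ_res of the *testing*
regression and m its slope — "standard deviation of the response" is
ambiguous (blank SD and replicate SD are unavailable for a simulator), and
the residual SD uses only quantities the workflow itself computes.
Regression intercepts are tabulated in mol L⁻¹ by default (matching the
magnitudes conventional in such tables) with µmol L⁻¹ available.

Note that Ry is dominated by low-concentration samples: a ±5 µmol L⁻¹
absolute error at 0.5 µmol L⁻¹ is a ±1000 % recovery term. Training-set
recoveries over the factorial design (27 samples at exactly 0.5 µmol L⁻¹)
are therefore intrinsically volatile even for models with excellent R.

## Pipeline and reproducibility

`run_full_pipeline` executes design → simulate → compress → calibrate →
evaluate with a single global seed from which per-stage seeds are derived
by SHA-256 hashing of the stage name (kept below 2³¹). Every artifact is
regenerable from config + seed; the artifact writer records SHA-256
content hashes in a manifest and leaves files untouched when their hash is
already current. On disk, voltammogram and coefficient matrices are stored
features × samples (the field's convention for such tables) while
concentration tables are one row per sample.

Problem sizes used throughout (tests and the acceptance script): 81
training samples, 10 external test samples, 177-point traces, 28
coefficients — the study's own dimensions; nothing is scaled down.

## Known limitations

* The simulator's linearity makes PLS nearly perfect, so the published
  qualitative PLS-vs-ANN contrast (PLS failing on naproxen/aspirin) does
  not reproduce here; only the mechanism — overlapped peaks demand
  multivariate treatment — is demonstrated.
* The MLP's published training recipe (Bayesian regularization together
  with a learning rate and momentum) is internally inconsistent; this
  package treats LM+evidence as the primary solver and gradient descent
  as an alternative, and its augmentation/stopping schedule is its own
  design (see above).
* Physical-unit optima of the DPV factors depend on factor windows that
  were never published.
* LOD/LOQ from a 10-sample external regression have large sampling
  variance; they indicate magnitude, not certified detection capability.
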