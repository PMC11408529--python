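# Methods

This note documents the models, algorithms and numerical choices behind
`vrpresence`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The analysis problem

A within-subjects VR study presents each participant with three
environments engineered to induce low, medium and high presence, in
three counterbalanced rounds, after a one-minute eyes-open baseline.
Recorded signals are 20-channel EEG (10-20 montage, 250 Hz, µV) and
single-channel wrist EDA (4 Hz, µS). The analysis asks whether the
presence level can be decoded from 5-s windows of these signals, which
features carry the information, and whether self-reported presence
(13-item questionnaire, summed 0–78) separates the conditions.

## Epoching

Each 105-s condition recording is split into 5-s windows with 30 %
overlap (hop = round(3.5 · fs) samples): 29 epochs at both 250 Hz and
4 Hz. Windows are 0-based half-open sample intervals; a partial trailing
window is dropped. 105 s is the smallest whole-second duration
consistent with a 29-window grid at this hop; shorter nominal durations
cannot produce that count.

## EEG preprocessing

Order of stages is fixed and asserted: notch → band-limit → z-score →
wICA.

* **Notch**: second-order IIR notch at 50 Hz, quality factor 30,
  applied forward-backward (zero phase).
* **Band-limiting**: Butterworth order 6, high-pass 1 Hz then low-pass
  30 Hz, both zero-phase (`sosfiltfilt`). Zero-phase filtering is used
  throughout so epoch-level waveform latencies are preserved; the
  effective magnitude response is the square of the single-pass design.
* **Normalisation**: per channel, per recording, to zero mean and unit
  sd. Normalising per recording (rather than over a whole dataset)
  prevents any cross-recording leakage. A consequence worth noting:
  absolute band-power changes become band-*share* changes, which is
  what the relative-power features then measure.
* **wICA**: FastICA (as many components as channels, unit-variance
  whitening) unmixes the channels; each component is decomposed with a
  5-level discrete wavelet transform (`coif5`); coefficients with
  |c| > K·σ̂ℓ·√(2 ln N) (K = 1) are kept as artifact, everything else
  zeroed; the artifact-only components are remixed to channel space and
  subtracted. σ̂ℓ is a **level-wise** MAD scale estimate: after 1–30 Hz
  band-limiting the input is strongly coloured, so a single fine-scale
  noise estimate would be orders of magnitude too small and would
  misclassify ordinary slow activity as artifact. With level-wise
  thresholds, a stationary Gaussian component loses essentially nothing
  (threshold ≈ 4.5 σ per level) while blink transients — large, smooth,
  concentrated in the coarse levels — are captured and removed.
* **FastICA convergence**: on recordings with little non-Gaussian
  content the whitened data are rotation-degenerate and the fixed-point
  criterion has no attractor; the iteration-capped unmixing (200
  iterations, tolerance 1e-3, one retry with a fresh seed) is still a
  valid decomposition and is used, with `converged=False` recorded in
  the provenance log. `WicaConfig(strict_convergence=True)` turns this
  situation into an error instead.

## EDA preprocessing and decomposition

Chebyshev type-I low-pass (order 4, 0.5 dB ripple, 1 Hz cutoff,
zero-phase; at 4 Hz sampling the cutoff sits at half Nyquist), then
z-normalisation, then decomposition. Normalise-then-decompose is the
default (a switch exposes the alternative) — the decomposition is
scale-equivariant, so only the reported units change.

The decomposition solves

    minimise  ½‖y − Hq − Bℓ − Cd‖² + λ₁·1ᵀq + ½λ₂‖ℓ‖²   s.t. q ≥ 0

with H the Toeplitz operator of the Bateman kernel
h(t) = e^(−t/τd) − e^(−t/τr) (τr = 0.7 s, τd = 2.0 s, unit peak), B a
cubic B-spline basis with knots every 10 s, C a linear drift + offset,
λ₁ = 8e-4, λ₂ = 1e-2 (the cvxEDA method's reference parameterisation).
The program is a strictly convex QP and is solved **exactly**: the
unconstrained tonic variables are eliminated through their normal
equations (Cholesky), and the reduced nonnegative problem in q is
rewritten via a second Cholesky factor as a nonnegative least-squares
problem (`scipy.optimize.nnls`, an active-set method with a finite
termination guarantee). No iterative tuning, no convergence tolerance
to pick; reconstruction tonic + phasic + residual = input holds to
machine precision, and identical inputs give bit-identical solutions.

*Kernel discretisation.* The kernel is point-sampled on the post-onset
sample grid, h[k] = h((k+1)/fs), rather than interval-averaged. With the
driver defined on the same grid, this makes the discrete response the
exact convolution image of a grid-aligned impulse, so a single
skin-conductance event deconvolves to a single driver spike; an
interval-averaged kernel distorts the peak-to-tail ratio and smears
≈ 20 % of the recovered driver mass along the decay tail.

## Features (181 columns)

* **Band decomposition**: complex-Morlet (6-cycle) filter bank with
  centre frequencies every 1 Hz across θ 4–8, α 9–12, β 13–25 Hz,
  realised in the frequency domain (a Gaussian comb, σ_f = f_c/6,
  normalised to unit peak response inside the band) — mathematically the
  summed real part of the Morlet wavelet transform over the band's
  centres. In-band sinusoids away from the edges pass with ≥ 95 % power;
  attenuation at the band edges and the breadth of the upper-β
  transition (σ_f ≈ 4 Hz at 25 Hz) are inherent to the 6-cycle Morlet
  and are left as such. The band definitions deliberately leave 8–9 and
  12–13 Hz uncovered; no attempt is made to close those gaps.
* **Relative band power**: epoch RMS of the band-limited signal divided
  by the same channel/band's RMS over the entire 60-s baseline
  recording (the baseline is not epoch-averaged).
* **Differential entropy**: DE = ½ ln(2πσ²) with σ² the epoch's
  band-limited time-domain variance. The conventional ·e term inside
  the logarithm is deliberately omitted; the resulting constant offset
  (½) is irrelevant to classification and to condition contrasts.
  Variances at or below 1e-12 are an error.
* **Higuchi fractal dimension**: curve-length slope estimate with
  kmax = 10; estimates for bounded signals lie in [1, 2] and are clamped
  with a warning otherwise (white noise lands a hair above 2 at finite
  length); a constant epoch is defined to have dimension 1.
* **Ratio indices** (18): five homologous frontal-θ/parietal-α pairs
  (Fz/Pz, F3/P3, F7/P7, F4/P4, F8/P8 — homologous pairing is the
  package's convention; only the two channel sets are prescribed), seven per-channel θ/β
  (FP1, Fz, F3, F7, F4, F8, FP2), six per-channel β/(θ+α) (Fz, F7, F8,
  P7, P8, Pz), all computed from the epoch's raw RMS band powers.
* **EDA statistics** (10): mean, median, sd (n−1), Pearson (non-excess)
  kurtosis and Shannon entropy (16-bin amplitude histogram, natural
  log, empty bins contribute zero) of the tonic and phasic components
  per epoch. Constant windows take sd = 0, kurtosis = 0, entropy = 0.
  The electrodermal block is fixed at these 10 statistics; an optional
  normalised-PSD summary is deliberately excluded to keep the registry
  at 181 columns.

The registry order is deterministic (17 channels × 3 bands × 3
features, then the three ratio families, then EDA) and is golden-file
tested.

## Synthetic-study generator

The generator emulates the *statistical phenomenology* the pipeline is
sensitive to, not the biophysics:

* **EEG**: per channel, independent Gaussian noise band-limited by the
  same Morlet bank the extractor uses (so generator and extractor agree
  on band definitions), with per-(condition, region, band) variance
  multipliers relative to baseline (base band RMS θ/α/β =
  4/5/3 µV); a 1/f background (exponent 1, 3 µV RMS); 50 Hz line
  interference (5 µV); and Poisson trains (15/min) of 400-ms
  raised-cosine blink transients (100 µV at FP1/FP2, half at F7/F8).
  The default effect map raises prefrontal θ and β and mid-parietal β
  for high presence, frontal β (with suppressed mid-frontal α) for
  medium, and parietal θ / mid-frontal α for low — magnitudes
  (0.6–2.2×) are free calibration parameters of the generator.
* **EDA**: tonic level 2 µS plus smoothed random drift, a Poisson train
  of Bateman-kernel SCRs with condition-dependent rates (baseline 2,
  low 3, medium 5, high 8 events/min; gamma-distributed amplitudes,
  mean 0.4 µS), and white measurement noise.
* **Design**: first-round condition order drawn uniformly from the six
  permutations; the remaining rounds are the cyclic Latin-square
  completion (direction randomised). One baseline per subject.
* **Questionnaire**: truncated-normal totals with the emulated study's
  condition means and SDs, plus a shared per-subject offset carrying
  80 % of the variance (`ipq_icc = 0.8`). The within-subject analysis
  (Friedman) presumes exactly this trait-like structure; with fully
  independent draws the medium–low gap (2.4 points against an SD of
  ~11) would be undetectable at n = 22, and no within-subject design
  would have been run. Marginal means and SDs are preserved.

Everything derives from a single seed via independent named streams;
identical configurations give bit-identical studies.

What the generator does **not** emulate — volume conduction and
channel correlations, non-stationarity within a recording, movement and
muscle artifacts other than blinks, per-item questionnaire structure,
inter-subject variability in effect direction. Passing recovery tests
on synthetic studies therefore demonstrates the pipeline's
correctness, not the real-world effect sizes; real-data accuracies
cannot be inferred from them.

## Selection and evaluation

* **LOSO**: one fold per subject; all fitting (scaler, model, GA
  selection when enabled) is confined to the training subjects of the
  fold. A held-out subject with a single class is flagged, not dropped.
* **Models**: one multiclass model per family with the study's
  hyperparameters (kNN k = 13, leaf size 1; MLP 1×25 logistic, LBFGS
  solver — the nominal learning rate 1e-4 is recorded but inert for a
  quasi-Newton full-batch solver; XGBoost α = 1, depth 7, η = 0.01, 100
  estimators; random forest √p features, 20 estimators, min leaf = 5 %
  of training epochs; SVM sigmoid, C = 100, γ = 0.001; unpenalised
  Newton-type logistic regression). Features are standardised on the
  training fold. Per-class one-vs-rest F1 and AUC (Mann-Whitney rank
  statistic) are computed from the multiclass model's simplex scores;
  this treats one-vs-rest as an evaluation framing rather than three
  separate binary fits.
* **GA selection**: bitmask genetic algorithm — population 60,
  40 generations, tournament 3, uniform crossover 0.9, per-bit mutation
  1/181, elitism 2, all-zero masks repaired; fitness is mean accuracy
  of a subject-grouped 5-fold inner CV; ties break toward fewer
  features. These GA constants are the package's own desk-scale
  defaults. Selection is nested per outer fold: a single global
  selection shared across folds would let the selector see the held-out
  subjects and is deliberately avoided.
* **Calibration convention**: on an exchangeable (null) study, chance
  level is assessed against a 99 % binomial band whose trial count is
  the number of *condition presentations* (subject × round ×
  condition), not the number of epochs: the 29 overlapping epochs
  within one presentation are strongly dependent and would understate
  the variance of the null accuracy several-fold.

## Attribution and statistics

* **Shapley values**: the exact coalition average is infeasible at 181
  features, so φᵢ is estimated by uniform permutation sampling with
  absent features imputed from the background (training-fold feature
  means; the background never includes test rows). Within every sampled
  permutation the marginal contributions telescope, so the efficiency
  identity Σφᵢ = v(x) − v(background) holds *exactly* at any number of
  permutations; sampling error affects only the split between features.
  Exact enumeration over all 2^d coalitions is provided for d ≤ 16 and
  serves as the test oracle.
* **Friedman + Dunn-Bonferroni**: Friedman χ² on within-subject
  mid-ranks (tie-corrected, via scipy); Dunn pairwise z tests on mean
  ranks, p-values Bonferroni-multiplied by the 3 comparisons. An
  all-tied table returns χ² = 0, p = 1.
* **Repeated-measures ANOVA + Tukey**: one-way RM-ANOVA by direct sums
  of squares with subject blocking (F on (k−1), (k−1)(n−1) df); Tukey
  HSD on condition means through the studentised-range distribution.
  Sphericity correction is not applied (k = 3, balanced, simulated
  data); this is a known limitation for real data.
* Shapiro-Wilk is delegated to scipy (contract: returns W and p).

## Problem sizes and determinism

The calibration and recovery studies run at 8 subjects (3 rounds ×
3 conditions × 105 s + 60 s baseline each, ≈ 2,100 epochs), the scale at
which the full pipeline, six-family LOSO and attribution complete in
minutes on one CPU; structural checks of the 22-subject design (fold
counts, counterbalancing, manifest arithmetic) run on design-shaped
tables, since they do not depend on signal content. The null-study
fixture omits blinks and line noise (condition-independent nuisance
terms, irrelevant to exchangeability) and accordingly skips the wICA
stage. Every random quantity — generator, ICA, GA, Shapley sampling,
model seeds — is derived from named seeds; reruns are bit-identical.

## Known limitations

* The wICA variant thresholds wavelet coefficients of *all* components
  rather than first classifying components as ocular — no robust
  automatic blink-component classifier is attempted. With level-wise
  universal thresholds this is conservative for neural content but
  would also remove any genuine high-amplitude transient.
* The β band's upper transition is broad (6-cycle Morlet at 25 Hz);
  sinusoids a few Hz above the edge are only partially attenuated.
* The GA is evaluated at desk scale in the tests (reduced population /
  generations); its defaults match the documented configuration but a
  60×40 run nested in every LOSO fold is computationally heavy.
* Real-data quantities (93 % accuracy, specific SHAP rankings, feature
  ANOVA F values) are not reproducible without the private recordings;
  the package's claims are correctness and calibration claims on
  synthetic ground truth.
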