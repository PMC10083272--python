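# Methods

This note records the models, parameter choices and numerical decisions
behind `anthomap`, and what its synthetic validation does and does not
demonstrate.

## The measurement model

A pushbroom hyperspectral camera records counts I_λ per pixel per band.
Reflectance is recovered by flat-field calibration against a white
reference panel W_λ and a dark-current image D_λ,

    R_λ = (I_λ − D_λ) / (W_λ − D_λ),

which cancels the source's spatial intensity gradient (present in both
I and W) and the sensor offset. Cells where W − D ≤ 1e-6 are radiometrically
undefined; they are set to 0 and counted in a warning rather than
propagating infinities. Output is clipped to [0, 1.5] — mild specular
highlights can exceed the panel. Calibration is exactly invariant to an
affine sensor re-gain I → aI + b applied to all three images, absent
clipping.

Reference anthocyanin contents come from pH-differential
spectrophotometry: cyanidin-3-glucoside changes absorbance reversibly
between pH 1.0 and 4.5, read at 520 nm against a 700 nm turbidity
baseline,

    A = (A520 − A700)_pH1.0 − (A520 − A700)_pH4.5,
    content = A·MW·DF·V / (ε·l·M)  [mg/g fresh weight],

with MW = 449.2 g/mol, DF = 25, V = 10 ml, ε = 26900 l/(mol·cm),
l = 1 cm, M ≈ 0.5 g. The constants live in `ChemistryConstants` because
other anthocyanin references use different MW/ε conventions. Negative A
(possible for near-zero pigment under measurement noise) is propagated
with a warning, not clamped, so noise statistics survive into the
synthetic study's labels.

## ROI extraction

Fruit pixels are NIR-bright against the dark acquisition board: a pixel
is fruit iff R at the band nearest 800 nm is ≥ 0.2 (the threshold is
the *minimum* fruit reflectance). Green stalk tissue is bright at
550 nm and chlorophyll-dark at 670 nm, so a pixel is retained in the
ROI iff the signed difference R(550) − R(670) ≤ 0.04 (the *maximum*
retained difference); anthocyanin-rich flesh sits at or below zero.
Both rule directions and an absolute-difference variant are
configurable. Nearest-band lookup resolves ties toward the lower
wavelength. No morphological cleanup is applied — the rules are pure
per-pixel thresholds.

From each scene the pipeline takes the ROI mean spectrum (sample-level
modeling) and 400 uniformly sampled distinct ROI pixels (deep-feature
training); sampling is seeded and a contiguous-window variant
(`block=True`) exists for users who read the 20×20 sampling convention
literally.

## Pretreatment

Analysis is restricted to the closed window 450–1050 nm (379 bands on
the default grid) to drop noisy spectral edges, then each spectrum is
SNV-standardized: centered by its own mean and divided by its own
sample (n−1) standard deviation; a population-sd variant is available.
SNV is applied identically to ROI means and to single-pixel spectra, so
the mapping path replays the training transform exactly; the frozen
chain (window, SNV convention, selector, model) is serialized together
in a model bundle.

## Variable selection

**SPA** grows, from every candidate start band, a chain of minimally
collinear bands: at each step all remaining (mean-centered) columns are
deflated by the newest chain member and the largest residual norm
joins the chain. Each (start, k) prefix is scored by the RMSE of an
ordinary least-squares fit on a seeded 1/3 holdout, and the global
minimizer is returned. OLS holdout scoring is the algorithm's classic
evaluator; the winning start's RMSE-vs-k path is kept as a diagnostic.

**CARS** runs 50 Monte-Carlo rounds. Each round fits PLS (components
≤ 10, chosen by an inner 3-fold CV) on a random 80% calibration subset
and reduces the surviving band set by weighted sampling *without*
replacement, weights ∝ |PLS regression coefficient|, down to the count
dictated by the exponential decline r_i = a·e^(−k·i) calibrated to run
from all p bands at round 1 to 2 bands at round 50. Sampling without
replacement to the exact EDF count makes the retained-count diagnostic
non-increasing from p by construction; the classic with-replacement
draw yields a noisier unique-count path with the same competitive
spirit. Each round's surviving set is judged by 10-fold RMSECV over all
samples, and the minimizing round wins.

**SAE.** A mirror-symmetric sigmoid stack 379-300-150-h-150-300-379
(h = 13) is trained to reconstruct SNV pixel spectra: greedy layer-wise
pretraining of the three constituent auto-encoders, then end-to-end
fine-tuning, all by plain minibatch SGD (batch 200, constant learning
rate 0.001, 40 epochs per stage). Two numerical choices matter:

* *Input squash.* SNV output is unbounded; it is affinely mapped
  per band into [0.05, 0.95] (train-set min/max, stored in the model)
  so a sigmoid output layer can reconstruct it.
* *Inter-stage code rescaling.* A sigmoid code typically occupies a
  narrow slice of (0, 1); feeding it raw to the next auto-encoder
  starves that stage of signal and the deep features collapse toward
  constants — which also leaves the downstream regression severely
  ill-conditioned. Each stage's code is therefore rescaled per unit to
  [0.1, 0.9] before pretraining the next stage, and the affine maps are
  folded into the stacked weights afterwards, so the final model is a
  plain sigmoid stack with well-spread features.
* *Loss convention.* Reconstruction loss is the squared error summed
  over output units and averaged over the minibatch; averaging over
  units as well would scale gradients by 1/379 and the stated learning
  rate would make negligible progress in 40 epochs.

Regression features are the encodings of each sample's mean SNV
spectrum; per-pixel encodings are used only in the mapping path.

## Regression and optimization

**ELM**: H = sigmoid(XW + b) with 90 hidden neurons; output weights are
the minimum-norm least-squares solution via SVD with a relative
singular-value floor of 1e-8 — hidden directions the training data
barely excites carry no signal and would otherwise receive huge
cancelling weights that explode on slightly off-manifold inputs (e.g.
single pixels).

**LS-SVM**: the standard regularized linear system over the RBF kernel
k(u, v) = exp(−γ‖u−v‖²) with bias; (C, γ) ∈ [0.01, 100]². A singular
system gets one 1e-10 jitter retry.

**GA**: real-coded; tournament selection of size 2, arithmetic
crossover (rate 0.9), per-gene Gaussian mutation (rate 0.05) whose
scale anneals exponentially from 10% to ≈0.5% of the gene range,
clipping to bounds, elitism of 1. The anneal supplies the late-stage
local refinement a fixed mutation scale cannot. For the ELM the genome
is the flattened hidden weights and offsets in [−1, 1]; for the LS-SVM
the genes are log10 C and log10 γ on [−2, 2] — arithmetic crossover in
linear coordinates cannot explore the decades near 0.01. Fitness is
5-fold cross-validated RMSE on the training set rather than training
RMSE: a 90-neuron ELM can interpolate 126 samples, so training error is
uninformative. Reference budgets are 300 generations (ELM) and 200
(LS-SVM) at population 20; the bundled study runs and the acceptance
script use 40 and 30 generations respectively — the CV-fitness
landscape is easy at this problem size and the search has converged for
practical purposes well before that.

Models are compared by R² = 1 − SS_res/SS_tot (about each set's own
mean; squared Pearson correlation is exported alongside) and RMSE, on a
stratified 7:3 split (each variety × stage cell split to nearest
integers, seeded).

## Per-pixel mapping

Distribution maps apply a trained bundle to every ROI pixel through the
frozen transform chain. The pipeline maps with the deep-feature kernel
bundle (SAE features + GA-tuned LS-SVM) by default, for a reason worth
stating. Single-pixel spectra carry sensor noise that ROI means average
away, so the mapping model must behave sensibly slightly off the
manifold of mean-spectrum features it was calibrated on. The SAE
encoder, trained on pixel spectra, keeps pixel features in-distribution
and nearly noise-free (a reference regressor given true per-pixel
labels recovers them with per-scene R² ≈ 0.95 on the synthetic study),
and the RBF machine extends the sample-level calibration smoothly into
that neighbourhood. An ELM output layer, being an interpolating
least-squares solution over 90 sigmoid neurons, is unbounded in hidden
directions the 126 training means never excite, and its per-pixel
predictions are unreliable however the output weights are regularized —
see limitations. Sample-level model comparison is unaffected: every
selector × model cell is trained and evaluated on ROI mean spectra
exactly as described above.

On these synthetic conditions the LS-SVM cells edge out the ELM cells
at sample level (RMSEP ≈ 0.042–0.057 vs 0.054–0.062 mg/g); which
family wins is a property of the data, and real-fruit studies can
legitimately rank them the other way.

## The synthetic study

No public dataset accompanies the problem, so validation runs on
rendered scenes with known truth. Flesh reflectance is a smooth rising
baseline minus Gaussian absorbers: an anthocyanin band at 535 nm
(width 70 nm, spanning 500–700 nm) with a 650 nm shoulder depressing
the 590–800 nm region, both scaling as 1 − e^(−0.35·c) in the
concentration c (mg/g); a narrow chlorophyll trough at 680 nm fading
with maturity; water/sugar bands at 840 and 970 nm; clipped to
[0.01, 0.99]. The slow saturation rate keeps d(reflectance)/dc
appreciable across the whole 0.3–4.5 mg/g study range — the regime in
which spectra of adjacent maturity stages remain separable, as observed
in ripe fruit. Stalks render as chlorophyll-rich tissue
(R(550) − R(670) ≈ +0.10), the board as flat R = 0.05.

A scene is six jittered ellipses with 2-px stalk spurs on a 120×120
grid. Per-pixel concentration is the sample mean times a smooth
lognormal field (Gaussian-filtered white noise, σ = 4 px), with
within-fruit CV 0.40/0.30/0.25 for S1/S2/S3 — patchiest at red
maturity, and everywhere comfortably above the per-pixel sensor-noise
floor, as the visible within-fruit structure of real pigment maps
requires. Raw counts are dark level (100) + halogen-shaped source ×
separable quadratic illumination gradient (±10%, present in raw and
white alike) × reflectance + Gaussian noise of 0.005 reflectance units;
the white adds 0.2% noise, the dark 2 counts.

The default study: 2 varieties × 3 stages × 30 samples; stage means
(A: 0.7/2.0/3.6, B: 0.4/1.4/2.8 mg/g) rise with maturity with variety A
above B; sample means scatter lognormally (CV 0.18) around them.
Reference absorbance quadruples are back-computed from each scene's
realized truth mean through the inverted content formula (at the
scene's own jittered mass), plus 0.002 absorbance units of per-reading
noise — so chemistry forward of generator inverse is exact at zero
noise.

What passing does **not** show: the generator's concentration-to-
spectrum map is a low-dimensional parametric family, far simpler than
real fruit optics (no skin/flesh layering, curvature shading, specular
highlights, touching fruit, or instrument drift), and the within-fruit
field is a stationary lognormal texture, not biology. Synthetic
results demonstrate that the pipeline recovers what its inputs encode —
not field performance.

## Problem sizes and runtime

The bundled end-to-end runs use the full 180-scene study (72,000
sampled pixel spectra) with the SAE trained on a 12,000-row random
subsample and the reduced GA budgets above; one full grid takes about
four minutes on one CPU, and `scripts/acceptance.py` about 10–15
minutes in total. The test suite trains small-epoch SAE instances and
9-per-variety studies where full scale adds nothing to the property
being checked.

## Known limitations

* ELM/LS-SVM extrapolate poorly outside the training concentration
  range; maps of fruit far beyond ~4.5 mg/g saturate.
* ELM bundles are not suitable for per-pixel mapping: the closed-form
  output layer is unconstrained off the mean-spectrum manifold, and
  per-pixel labels that would pin it down are unobservable (only
  sample-level reference contents exist). Map with the kernel bundle.
* Scenes at the very bottom of the content range (lowest-stage variety
  B) map poorly regardless of model: their within-fruit spread sits
  near the per-pixel noise floor and the calibration has few samples
  below them.
* On synthetic spectra the all-band GA-ELM can match or beat the
  selected-variable ELMs in cross-validated RMSE, depending on the
  study realization: the rendered spectra are smooth and low-rank with
  independent band noise, so using all 379 bands is pure averaging
  gain. The benefit of wavelength selection observed on real spectra
  comes from nuisance structure (drift, correlated noise, scatter
  residuals) the generator deliberately does not model; the selection
  engines are validated instead by their recovery benchmarks. For the
  LS-SVM the benefit does appear — selection mitigates RBF distance
  concentration in high dimension.
* The SPA search is exhaustive over start bands but chains are
  unsupervised; on designs with no collinearity structure it can miss
  the optimal subset (its classic failure mode).
* ENVI support covers the common BIL/float dialect written by the
  package itself plus BSQ/BIP reads; vendor-specific extensions are out
  of scope.
* `run_study` resumes only the expensive simulate+extract stage from
  its cache; model stages rerun.
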