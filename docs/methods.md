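# Methods

## Image conventions and metrics

Images are 8-bit grayscale rasters with ridges dark (0) and paper bright
(255); they are never auto-inverted. Segmentation masks are boolean
rasters of the same shape (on disk: PNG, nonzero = inside the print).
Wider inputs (16-bit TIFF, float) are linearly mapped so the array
maximum lands on 255; 8-bit input passes through unchanged.

All intensity and contrast statistics are computed over in-mask pixels
only — background is not fingerprint signal. A `--whole-canvas` style
switch is deliberately *not* provided at the metric level; callers who
want canvas statistics can pass a full-true mask.

**Blocks.** Block statistics tile the *mask bounding box* from its
top-left corner with `block_size`² tiles (default 50 px). A tile is
retained iff its in-mask pixel count reaches 50% of a full tile. The
anchor choice makes every block statistic exactly invariant to
translating the print (with its mask) inside the canvas, and the coverage
rule keeps boundary slivers from dominating the block SDs. Fewer than two
retained blocks leave the block SDs undefined (NaN with a warning);
pairs with undefined metrics are excluded from modeling with a log entry.

**DEAI** is −|mean − 127.5|: zero when dark and bright pixels balance,
increasingly negative for washed-out or inked-over prints. **Michelson
contrast** is (Imax − Imin)/(Imax + Imin); the degenerate all-black case
is defined as 0 with a warning.

**Ridge reliability.** The print is filtered with 8 even-symmetric Gabor
kernels (orientations kπ/8; wavelength 9 px ≈ ridge period at 500 dpi
scale, isotropic σ = 4 px, DC-free). In each 16×16 window the squared
responses are summed into one energy per orientation. A window is *high
reliability* when

1. the top energy is at least 1% of the window's maximum attainable
   energy (window area × (127.5 × Σ|kernel|)²) — this floor rejects flat
   and purely noisy windows; and
2. the top energy is ≥ 1.5× the strongest energy at any orientation *not
   adjacent* to the winner.

Reliability is the fraction of in-mask windows (same 50% coverage rule)
that qualify. Excluding the two adjacent channels from the dominance
competition is a deliberate design choice: a discrete 8-filter bank
splits a single ridge flow across neighbouring channels, so
adjacent-channel energy signals sampling, not ambiguity. With a literal
top/second rule, windows whose true orientation falls midway between two
filter orientations can never look unique, capping clean-print
reliability near 0.65 regardless of image quality. All four parameters
(window, wavelength, τ, ε) are exposed via `RidgeReliabilityParams` for
sensitivity analysis. On synthetic prints, clean whorls/loops score ≥
0.95, i.i.d. noise scores ≈ 0.1, and a flat field scores 0.

**Standardization and collinearity.** Continuous predictors are z-scored
with cohort statistics persisted in a `FeatureStandardizer`, so held-out
pairs are transformed on the training scale. Interactions are products of
standardized mains (binary core/delta flags stay 0/1). The collinearity
screen iterates: while any pairwise |r| > 0.5 among continuous mains, the
member of the worst pair with the larger mean |r| to all other mains is
dropped (ties: later canonical column order); survivors must all have
VIF < 5 or the largest-VIF column is dropped and the loop repeats.
Interactions lose a dropped main's interaction column with it. The drop
rule had to be chosen here (which member to remove is genuinely open);
mean absolute correlation removes the most globally redundant column and
is deterministic.

## The accuracy model

Per-trial correctness is Bernoulli with

    logit P(correct_ij) = β₀ + x_ij'β + printID_i + expertID_j,

printID and expertID independent Gaussian intercepts. The marginal
likelihood is approximated by Laplace's method in the spherical
parameterization u = σb, b ~ N(0, I):

    ℓ(β, σ) = log f(y | η̂) − ½ b̂'b̂ − ½ log det(Λ'Z'WZΛ + I)

with b̂ the penalized-likelihood mode at (β, σ). Estimation runs in three
stages: (0) plain-GLM starting values for β; (1) a fast profiling pass
that maximizes over σ with (β, b) at the *joint* penalized mode — cheap
but biased, used only for starting values; (2) bounded quasi-Newton
(L-BFGS-B) over (β, σ) of the true Laplace objective, with an inner
Newton solver for b̂ only. The inner Hessian is diagonal for one grouping
factor and is solved via the Schur complement of the (small) second
block for two crossed factors, so inner iterations cost O(n). Stage 2 is
essential: profiling β at the joint mode (stage 1's objective) attenuates
the intercept by ~10–15% at realistic variance levels because the
log-determinant depends on β. On shared datasets the fit agrees with
`lme4::glmer` to four decimals in coefficients, variance and
log-likelihood.

Fixed-effect standard errors come, by default, from the β block of the
inverse of the full numerically-differentiated observed information over
(β, σ). This propagates variance-parameter uncertainty into the
intercept SE — conditional (Schur-complement) SEs understate it by
~15% at print-level variance ≈ 2 and give below-nominal 2-SE coverage in
recovery simulations. Conditional SEs remain available
(`se_method="conditional"`) and are used internally where only AIC is
compared. Wald z statistics are reported but treated with the usual
caution for unbalanced mixed models; model reduction uses AIC and LRTs
only.

Numerical choices: inner mode tolerance 1e-11 (relative), outer ftol
1e-11, finite-difference step 1e-3 (relative), σ bounded in [0, 10]
(variance ≤ 100), starting variance 0.5. A fixed effect whose estimate
exceeds 15 on the logit scale raises a separation error naming the
column — with standardized features that magnitude only arises from
(quasi-)separation, e.g. a constant response. AIC counts one parameter
per fixed effect plus one per variance component.

**Backward selection** greedily removes the fixed effect whose removal
most lowers AIC, stopping when no removal helps. Interactions must leave
before their mains (hierarchy preserves interpretability; the alternative
is available via `hierarchy=False`). Candidate fits warm-start from the
parent model's estimates; the winning model is refit with full SEs.

**Linear mixed models** for response time, difficulty and confidence keep
both random intercepts (both variances are substantively interesting
there) and are fitted by REML through `statsmodels.MixedLM` with variance
components emulating the crossed design. Response time is z-scored per
examiner before fitting — examiners differ widely in pace — with a
global-z option.

## Evaluation

Observed pair accuracy is the fraction of correct judgments across the
examiners who saw that pair; a *perfect pair* scored exactly 1.0.
Predicted pair accuracy is the inverse-logit of the linear predictor; for
pairs in the fitted data the print-level BLUP can be included (in-sample
assessment), for held-out pairs the print offset is 0. Fit quality is
adjusted R² — 1 − (1 − R²)(n − 1)/(n − k − 1) with k fixed effects, a
formula chosen here as the standard definition — and RMSE over pairs.

Validation splits pairs 90/10 with explicit stratification on
perfect/non-perfect (each stratum contributes its proportional share of
test pairs, at least one), deterministic under a seed. The classifier
sweeps the threshold over all observed predicted values plus {0, 1} and
keeps the training-accuracy maximizer, breaking ties toward the higher
threshold (flagging more pairs as error-prone is the conservative
direction for a forensic screen). A fixed percentage grid is deliberately
not used — the optimum should be data-driven, not a grid artifact.

Mean per-pair difficulty rating can be added as a standardized extra
predictor (`augment_with_difficulty`); the report flags it as subjective,
since unlike the image metrics it depends on raters.

## The synthetic generator

`generate_known` builds a ridge-orientation field for a pattern class —
zero-pole model for loops/whorls/tented arches (orientation = ½Σ arg(z −
core) − ½Σ arg(z − delta); a whorl counts its core twice), a smooth
singularity-free bump flow for plain arches — then renders ridges by
iterated oriented filtering of noise (5 iterations over 16 orientation
bins) inside an elliptical boundary. `degrade_to_latent` applies, in
order: sub-region crop (disk intersection bisected to the target area
fraction), dark Gaussian-blob smudges, a smooth multiplicative
contrast-attenuation field, global intensity bias, additive Gaussian
noise, and clipping. Zero-strength settings reproduce the input exactly.

`simulate_panel` draws examiner judgments from the crossed logistic model
itself. Defaults are the published accuracy-model scale: β₀ = 3.385,
slopes from the reported coefficient set (|β| 0.33–0.80), print variance
2.154, expert variance 0.1; pairs run in batches of 20 (ten matches, ten
close non-matches), ~10 examiners per batch, two batches per examiner —
at 200 pairs this yields ~2,000–2,400 trials. Difficulty is a noisy
monotone discretization of the pair-level linear predictor onto 1–6,
confidence is 7 − difficulty plus independent noise (their correlation is
≈ −0.85 at default noise), and response time is log-normal increasing in
difficulty. The rating link is *not* claimed realistic — no generative
model for ratings exists to copy — it only preserves the qualitative
structure (ratings anticorrelate; both track difficulty).

Ground-truth difficulty is injected through the images themselves:
degradation moves the metrics, the metrics move x'β, and the print-level
intercept carries residual pair difficulty beyond the features. Refitting
on a generated study therefore exercises the full measurement chain, and
parameter-recovery tests are meaningful end-to-end. Non-match pairs use a
same-class, different-seed known print, standing in for the close
non-matches an AFIS search would return.

What the generator does **not** emulate: elastic skin distortion,
realistic minutiae statistics, sensor/powder artifacts, examiner response
strategies (e.g. always-maximum confidence), or inconclusive responses.
Passing tests therefore demonstrate that the *pipeline* recovers the
structure it assumes, not that the fitted coefficients transfer to real
casework imagery.

## Problem sizes used in the test suite

The suite favours many small seeded replicates over single large runs:
metric oracles sweep 1,000 random images up to 200×200; GLM-equivalence
uses 20 simulated panels; parameter recovery runs 50 replicates at 200
pairs × 12 examiners/pair with print variance 2; selection sanity runs 50
replicates of 3 true + 8 null predictors at 150 pairs × 8 examiners;
classifier checks run 25 simulated studies of 100 pairs. Image-based
end-to-end checks run once at 40 pairs on 192-px canvases; the statistics
of the measurement chain, not image count, carry the evidence there.

## Known limitations

* The ridge-reliability operator is a documented stand-in for whichever
  proprietary operator a production system would use; only its qualitative
  behaviour (clean ridges high, noise/smudge low) is load-bearing.
* Laplace ML for binary responses with few trials per group mildly
  underestimates variance components; at ~10–12 trials per pair the bias
  is negligible for the uses here, but panels with 2–3 examiners per pair
  would need adaptive quadrature, which this package does not implement.
* The classifier reports raw confusion counts and accuracy only — no ROC
  machinery; the accuracy-maximizing threshold is the published protocol.
* Variance estimates on the zero boundary make the full observed
  information indefinite; SEs then silently fall back to conditional
  ones, which is conservative for every parameter except the intercept.
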