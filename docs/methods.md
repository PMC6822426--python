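# Methods

## Model

The core model regresses a scalar drug-sensitivity readout y (normalized
inhibition AUC, bounded to [0, 1]) on an autoscaled samples × features
abundance matrix X by orthogonal projections to latent structures
(O-PLS). For a scalar response O-PLS has exactly one predictive
component; its weight vector is the (unit-norm) covariance direction
w ∝ Xᵀy, computed once from the starting matrix. Orthogonal components
are extracted NIPALS-style: with t = Xw and candidate loading
p = Xᵀt/tᵀt, the orthogonal weight is w_o = p − (wᵀp)w (normalized), the
orthogonal scores t_o = Xw_o, the loading p_o = Xᵀt_o/t_oᵀt_o, and the
variation t_o p_oᵀ is deflated from X before the next component. Because
w_o ⊥ w, the identity yᵀt_o = ‖Xᵀy‖ · wᵀw_o = 0 makes the orthogonal
scores exactly uncorrelated with the response, and w_oᵀp_o = 1 makes
predictions invariant to displacements along p_o. After K deflations the
predictive component is finalized on the filtered matrix with inner
coefficient b = tᵀy/tᵀt. The whole model is linear, and collapses to a
single net coefficient vector (`OplsModel.coefficient_vector`) used as an
independent oracle in the perturbation tests.

Assumptions: a single predictive latent direction suffices (scalar y);
features are exchangeable after autoscaling; missingness is ignorable
once low-detection features are removed.

### Component selection

Q²Y = 1 − PRESS/TSS under seeded 7-fold cross-validation, refitting the
full component structure per fold (fold centering included). Orthogonal
components are added sequentially; the K-th candidate is retained iff
Q²Y(K) − Q²Y(K−1) > 0.05, stopping at the first failure. Q²Y may be
negative; it is never floored. The retention threshold applies only to
orthogonal components — the single predictive component is always kept.
The fold partition is a seeded random permutation; a deterministic
assignment can be recovered by fixing the seed, which is stored in the
model's `cv_config`.

### Response scaling

The response is centered internally and predictions are returned on the
original scale; y is not variance-scaled (`y_std` is stored as 1.0 in
the serialized model, so the convention is explicit and the alternative
is reproducible). The feature matrix handed to `fit_opls` is expected to
be autoscaled; the fit additionally re-centers on its own training rows
and stores the residual center, so scaling learned on a superset of the
training samples does not bias predictions.

### VIP

VIP_j = sqrt(p · Σ_m w²_mj SS_m / Σ_m SS_m) over the predictive and all
retained orthogonal components, where SS_m = b²_m t_mᵀt_m is the
response variance explained by component m (the common 1/yᵀy factor
cancels). Orthogonal components have b_m = 0 exactly, so they contribute
nothing and the identity mean(VIP²) = 1 follows from the unit-norm
weights. VIP > 1 marks a feature as important; the sign of its
predictive weight assigns it to the resistance (negative) or sensitivity
(positive) side of the signature.

## Curation parameters

- detection threshold 0.25 (inclusive): a feature must be non-missing in
  at least 25% of samples.
- imputation: feature mean before autoscaling, equivalent to zero after;
  neutral under mean-centering. Chosen because the remaining missingness
  after the detection filter has no stated mechanism.
- autoscaling uses the n−1 (sample) standard deviation; zero-variance
  features are dropped with a warning and recorded in `ScalingParams`.
- resistance label: AUC < 0.2, strictly.
- stratified split: strata = tumor-type group × resistance label; one
  member of each stratum is reserved for test and one for train before
  the remaining test slots are drawn at random (default test_n = 6 of
  26), so the split is random but never loses a stratum from either side.

## Benchmark protocol

Baselines consume the same autoscaled matrix as O-PLS: LASSO with
5-fold-CV penalty, random forest with 100 trees averaged over 5 fixed
seeds, and ε-SVR (C = 1, ε = 0.1) with linear and 2nd-degree polynomial
kernels. Hyperparameters are re-tuned inside every LOOCV fold. Win
counts against the reference use strict inequality on per-sample
absolute errors; exact ties count half a win each and the total is
rounded before the exact two-sided binomial test (minlike rule,
p₀ = 0.5). "Exact binomial sign test" is our reading of the informal
name "binomial t-test" for this comparison. Note that ε-SVR has an
error floor of order ε even on noiseless data (residuals inside the
tube are not penalized), so it is not expected to reach zero error
where the exact-fit models do.

## Dose-response analysis

Percent inhibition: blank-corrected signals with A_min = blank-corrected
vehicle mean, y = (A_min − x)/A_min × 100; replicate wells averaged per
dose; negative values (growth stimulation) are kept. Values slightly
above 100% (noise on complete kills) are accepted at fit time.

Hill fit: y = 100/(1 + (IC50/x)^h) with fixed 0–100 asymptotes, bounded
least squares (IC50 ∈ [min dose/100, 100·max dose], h ∈ [0.1, 10]),
initialized at the measured dose nearest 50% inhibition (geometric mean
of the range as fallback) with h₀ = 1. Fits with IC50 on a bound, a flat
profile (< 5 percentage-point span), or failed convergence are flagged
unreliable and refused by the synergy calculation rather than
propagated — IC50s extrapolated beyond the tested range are exactly the
values that mislead.

Inhibition AUC: trapezoidal integral of fractional inhibition clipped to
[0, 1] over log10 dose, divided by the log10 range; 0 = inactive across
the range, 1 = complete inhibition throughout. This is the package's own
normalization for synthetic curves; externally supplied AUC values are
consumed as-is and never recomputed.

Loewe index for a fixed-ratio (1:r) combination: the combination curve is
fitted on the drug-1 concentration axis; at its IC50 c the per-drug
exposures are x¹ = c and x² = r·c, and the index is x¹/X¹ + x²/X² with
X¹, X² the monotherapy IC50s. Index < 1 flags synergy. At index ≈ 1 the
flag is a knife-edge call under noise, so additive ground truth is
validated on the index value, not the flag.

## Synthetic data

`generate_rppa_like` draws y ~ U(0, 1) (the response span seen in
pan-cancer sensitivity panels), sets the predictive latent score
t = standardized(y), and builds X = t pᵀ + s·t_o p_oᵀ + σ·noise, with
t_o driven by a binary tumor-type label (jittered, independent of y) and
signed unit loadings on the planted features. Default σ = 0.5 targets a
univariate signal fraction of 1/(1 + σ²) = 0.8 per planted feature.
Missingness is feature-biased (a "poorly detected" tenth of features
absorbs most of it) so the detection filter does real work. Presets:
`default` (n = 30, p = 200, 10 planted, confound strength 1),
`confounded` (strength 3, 40 orthogonal-factor features), `null` (no
signal). Plate simulation inverts the percent-inhibition transform
around a nominal vehicle level of 10⁴ counts with duplicate wells,
vehicle and blank rows, and Gaussian noise expressed as % of the vehicle
level; `generate_combo_experiment` places the combination IC50 at
c* = λ/(1/IC50₁ + r/IC50₂) so the true Loewe index equals the planted
interaction λ.

What the generator does not emulate: antibody-specific noise,
heavy-tailed abundance marginals, correlated missingness with abundance,
plate edge effects, or multi-factor confounding. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not performance claims about any real RPPA panel.

## Problem sizes and numerics

Test and acceptance runs use n ≈ 20–30 samples, p ≈ 60–200 features,
10–50 seed replicates per property, and 10-point two-fold dose series —
sizes chosen to match the scale of the motivating cell-line panel while
keeping the full suite fast. Orthogonality invariants hold to 1e-8/1e-6;
scaling round-trips to 1e-10; NIPALS needs no iteration for scalar y
(closed-form weights), so determinism is exact for a fixed seed. Jointly
permuting samples leaves fitted weights/loadings unchanged to machine
precision for a fixed component count; the CV fold partition (hence
possibly the retained K) is tied to sample order through the seed.

## Known limitations

- Single scalar response only; no multi-response or kernel variants.
- Component retention uses one shared CV partition per fit; very small
  panels make Q²Y noisy and retention decisions with it.
- The in-silico clamp perturbs exactly the requested features, leaving
  correlated features untouched; it is a linear what-if, not a
  mechanistic signaling simulation.
- The Loewe analysis assumes both monotherapy curves and the combination
  curve are individually well-determined; partial inhibitors (< 50%
  max effect) are flagged unreliable rather than scored.
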