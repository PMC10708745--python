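# Methods

This note documents the models and procedures implemented in `vitispec`,
the assumptions and parameter choices behind them, and what the synthetic
experiments do and do not demonstrate.

## Problem setting

Three maturity indicators of wine grapes are estimated from a single
in-situ VNIR–SWIR reflectance point spectrum per sample: total soluble
solids (°Brix, dominated by glucose/fructose), pH, and titratable acidity
(TA, stored as tartaric-acid equivalents on the as-recorded scale of a few
to a few tens of units per liter).  Spectra live on the 350–2500 nm grid
at 1 nm native resolution (2151 points).  Before any modeling the grid is
decimated by keeping index 0 and every 10th point, yielding 216 input
features (350, 360, …, 2500 nm); all pre-treatment window sizes refer to
this decimated grid.

## Spectral pre-treatments

Nine "spectral sources" map reflectance R to a feature matrix:

| name | definition |
|---|---|
| REF | R |
| ABS | A = log₁₀(1/R) |
| ABS_SG1 / REF_SG1 | 1st Savitzky–Golay derivative of A / R |
| ABS_SNV / REF_SNV | per-spectrum SNV of A / R |
| ABS_SG1_SNV, ABS_SG2_SNV | SNV after the 1st / 2nd derivative of A |
| CR | R divided by its upper convex hull |

Numerical conventions, chosen once and relied on by the tests:

- SNV uses the population standard deviation (divide by n), the common
  chemometric convention; SNV is idempotent and invariant to positive
  affine maps of its input.
- Savitzky–Golay filters use polynomial order 3 and a 5-point window
  (≈ 50 nm on the decimated grid); edges are handled by evaluating the
  fitted local polynomial (same-length output), and derivatives are per
  index step, not per nm — downstream learners are insensitive to a
  constant scale.
- Continuum removal interpolates the upper convex hull (monotone-chain;
  degenerate collinear spectra correctly reduce to the endpoint chord) and
  divides, so output lies in (0, 1] and equals 1 at hull vertices,
  including both grid endpoints.
- Ingestion clips reflectance to [1e-6, 1] (with a warning) so log₁₀(1/R)
  stays finite, and auto-detects percent-scaled files (any value > 1.5).
- Every pre-treatment is a per-spectrum map with no cross-sample
  statistics, so feature matrices can be computed once without leaking
  information between cross-validation folds.

## Baseline learners and hyperparameter search

Single-output models: PLS regression (latent variables searched in
[1, 100]), random forests (trees ∈ {50, 100, 150, 200} × max-features rule
∈ {max, sqrt, log2}, where "max" means all features are split candidates),
and RBF-kernel SVR (ε ∈ {0.01, 0.025, 0.05, 0.075, 0.10, 0.15, 0.20} ×
C ∈ {2⁻², …, 2⁹}).  PLS and RF also fit all three targets jointly; ε-SVR
is single-response by construction.

Hyperparameters are selected per outer fold by 5-fold grid search on the
calibration rows only, minimizing the mean validation RMSE; for
multi-output fits each target's RMSE is first divided by its calibration
standard deviation so °Brix, pH units and acidity contribute comparably
(the single-output metric is plain RMSE).  Candidate lists are ordered
simplest-first (ascending latent variables; ascending trees; ascending C
then descending ε) and exact ties keep the earliest candidate, making
selection deterministic and parsimonious.  The PLS latent-variable cap is
min(100, n_train − 1, p) per inner fold; infeasible counts are excluded.

A performance detail with no statistical consequence: the PLS grid is
evaluated from a single decomposition per inner fold — the coefficient
matrix for k components is the truncation R[:, :k] Q[:, :k]ᵀ of the
full-rank fit in the centred/scaled space — which the test suite verifies
against independently fitted per-k models to 1e-8.

## The multi-input–multi-output attention CNN

The network ingests a (samples, 216, 3) stack of three complementary
pre-treatments — REF (albedo and scatter), ABS_SNV (baseline-corrected
shape), ABS_SG1 (fine absorption structure) — and predicts all three
indicators at once:

1. multi-head self-attention over the 216 wavelength positions: 8 heads,
   query/key/value dimension 64 per head, output projected back to width
   3 so the (L, 3) shape is preserved; weights are softmax-normalized
   over the key axis;
2. Conv1D(128, k=5, same) → dropout 0.2 → maxpool 2 →
   Conv1D(64, k=7) → dropout 0.2 → maxpool 2 → Conv1D(32, k=7) →
   flatten (54·32 = 1728) → dense 128 → 64 → 32;
3. three single-unit linear heads (brix, ph, ta).

All activations are ReLU; every convolutional kernel carries an L2 penalty
of 0.01; the optimizer is Adam at learning rate 0.001; the loss is the
equally weighted sum of the three per-output mean squared errors.

Training contract and the choices behind it:

- **Target standardization.** Outputs are z-scored per target on the
  training rows and de-standardized at prediction; equal-weight MSE on raw
  °Brix/pH/TA scales would otherwise be dominated by TA.
- **Input scaling.** Channels are standardized per channel (mean 0, sd 1
  over calibration samples × wavelengths), fitted on calibration rows
  only.  Standardization rather than min–max squashing matters: attention
  scores are quadratic in the input values, and inputs confined to [0, 1]
  leave the key-axis softmax near-uniform with vanishing query/key
  gradients — in diagnostics the min–max variant could not fit even a
  single mini-batch.
- **Unstated training budget.** Defaults: up to 500 epochs, batch 16,
  10 % validation split with early stopping at patience 50 and
  best-weight restoration; everything is driven by one seed.
- **Engine.** The network is implemented directly in NumPy (`vitispec.nn`)
  with manual backpropagation and Adam; gradients of every layer are
  verified against float64 finite differences in the test suite.  Because
  the per-position feature dimension is only 3, attention scores are
  computed through the 3×3 head matrices Wq_h Wk_hᵀ (and the value/output
  path through Wv_h Wo_h), which reduces the dominant L×L contractions
  from inner dimension 64 to 3 without changing the function computed.
  Projections carry the query bias (a learnable per-key salience term in
  the scores); the key bias only shifts whole softmax rows and the value
  bias is a constant output offset absorbed by the output bias, so both
  are omitted as mathematically redundant.
- Pooling uses floor division, so any L ≥ 8 is accepted; for L = 216 the
  shape pipeline is 216 → 108 → 54 with flatten width 1728.
- One architecture is shared across varieties and retrained per variety
  and fold; no architecture search is performed (the configuration is
  fixed), though `ArchitectureSpec` exposes the sizes for external tuners.

## Evaluation protocol

Metrics on a held-out fold: RMSE; R² = 1 − SS_res/SS_tot about the
observed mean (exactly 1 for a perfect predictor, exactly 0 for the
constant mean predictor); RPIQ = (Q3 − Q1)/RMSE with quartiles under the
linear-interpolation convention (the default of `numpy.percentile`), which
RPIQ values depend on.

Model comparison uses nested stratified 5-fold cross-validation with
sampling dates as strata: each date's samples are shuffled and dealt
round-robin (per-date fold counts differ by at most one), the fold plan is
built once per variety and reused by every model family, hyperparameter
search sees calibration rows only, and reported means are arithmetic means
of per-fold metrics rather than pooled predictions.  Best-model selection
maximizes mean R² (per target for single-output models; averaged over the
three targets for multi-output ones), with ties broken by lower RMSE and
then lexicographic source name.

## Attention-based wavelength importance

For each variety and fold, the raw importance of wavelength m is

  imp(m) = Σ over test samples, heads, query positions, channels of
           A[n, h, q, m] · X[n, m, c],

i.e. the attention a wavelength *receives* as a key, weighted by the
spectral values there; X is the scaled channel stack the model actually
attended over.  Query positions are summed out — a one-value-per-wavelength
profile forces a reduction over all other axes, and importance is
attributed to the attended (key) wavelength.  Per-fold profiles are
aggregated as the mean of absolute values across folds and normalized by
the maximum, so the reported profile lies in [0, 1] with max exactly 1;
top-k wavelengths are reported descending, ties toward the shorter
wavelength.  Profiles are computed on left-out folds at test time and
reported per variety, never pooled across varieties.

## Synthetic campaign generator

The generator supplies ground truth for every stage without any field
data.  Defaults describe a 260-bunch, 7-visit campaign of one variety with
the Syrah value envelopes (°Brix ∈ [4.70, 26.50], pH ∈ [2.56, 3.83],
TA ∈ [3.9, 35.6]).

- **Targets.** A latent ripeness u ~ N(0,1) drives all three indicators:
  z_t = a_t·u + √(1−a_t²)·ε_t with loadings (0.95 for Brix; TA negative),
  mapped through Φ and the value envelope.  Latent correlations are
  calibrated as ρ = 2·sin(πr/6) so the envelope mapping yields Pearson
  magnitudes ≈ 0.8 (Brix–TA) and ≈ 0.72 (pH–TA); signs encode the inverse
  acidity/sugar relationship (Brix–TA < 0, pH–TA < 0, Brix–pH > 0).
  Printed correlation values are treated as magnitudes; the signs are an
  interpretation and are configurable.
- **Dates.** A sample's sampling date is the quantile bin of its latent
  ripeness across 7 visits (12 days apart from 2023-07-06), so ripeness
  rises with date index and date-stratified folds span the whole
  trajectory.
- **Spectra.** Pseudo-absorbance = linear baseline (0.25 → 0.40) plus
  Gaussian bands: maturity-linked bands at 730 nm (sugar O–H overtone,
  depth 0.35·b̃), 1510 nm (carboxylic-acid C=O overtone, 0.30·t̃ +
  0.05·p̃), 2120 nm (0.08·b̃ + 0.12·p̃) and 2320 nm (0.25·b̃); water bands
  at 1450/1940 nm with target-independent depths 0.35/0.55; a chlorophyll
  term at 680 nm fading with ripeness and a broad 550 nm pigment term
  deepening with it, so unripe berries are brighter across 500–700 nm
  (b̃, p̃, t̃ are envelope-normalized targets).  Reflectance =
  10^(−A) × uniform multiplicative scatter (default [0.9, 1.1]) + additive
  Gaussian noise (default sd 0.002), clipped to (0, 1].

What the generator does *not* emulate: instrument splice artifacts between
photodiode arrays, wavelength-dependent noise, variety-specific
biochemistry, weather effects, or the sampling bias of measuring three
berries against bunch-level chemistry.  Passing recovery tests therefore
demonstrates that the pipeline is correct and sensitive under clean,
strongly identified conditions — not that field performance matches.

### Problem sizes used by the test suite

The recovery experiments run a 300-sample, 7-date campaign at the default
noise level with fixed seeds: nested CV of the PLS family across all nine
sources, the attention CNN trained 100 epochs per fold, and a
permuted-target null.  Observed outcomes: best PLS mean outer R² for Brix
≈ 0.999; CNN mean outer R² ≈ 0.95–0.96 per target; null R² ≤ 0.
Unit-level model tests use a factor-50 decimation (L = 44) to stay fast.

### A known negative result

On the default synthetic campaign the attention-importance profile ranks
the 1890–2010 nm region — the 1940 nm water band and its red edge — above
all four maturity-linked bands.  Two effects compound: the water band is
the deepest spectral feature, so the channel-value factor of the
importance product peaks there, and the trained attention itself mildly
favors that region because water-band reflectance encodes the
multiplicative scatter level, which is genuinely useful for
normalization.  The planted maturity bands appear as secondary peaks
(750–760 nm, ~1530 nm, ~1410 nm; ranks 11–15 of 216) but not in the top
five.  This is a property of the method under these conditions, not an
implementation artifact: computing importance against unscaled channels
gives the same ranking, and the corresponding acceptance test is left
failing rather than weakening the check.  On real spectra the same caveat
applies — magnitude-weighted attention importance will up-weight strong
absorbers such as water regardless of their predictive role.

## Known limitations

- The CNN engine is CPU-only float32 NumPy; training cost is roughly two
  minutes per 240-sample fold at L = 216 for 100 epochs on one core.
- TA units follow the as-recorded scale of the value envelopes; no unit
  conversion is attempted.
- Repeated or significance-tested CV, MSC/detrending/wavelet
  pre-treatments, and gradient-based saliency are out of scope.
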