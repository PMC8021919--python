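# Methods

## Problem and scope

`brainage` implements a hierarchical brain-age prediction workflow for
structural brain volumes: conventional machine-learning baselines on
engineered morphometry features are used to understand which feature sets
carry age information, and an ensemble of 3D residual convolutional
regressors consumes the corresponding raw channel stacks directly.  The
package is exercised end-to-end on synthetic age-structured brain phantoms,
so every stage is testable without access to any (non-redistributable) MRI
cohort.

## Phantom generator

The generator emulates the statistical skeleton of a morphometry training
cohort, not its anatomy.

* **Ages** follow a shifted log-normal truncated to `[age_min, age_max]`
  (defaults 17–90 y).  The log-normal parameters are solved numerically so
  the *truncated* distribution has the configured mean and SD (defaults
  36.41 and 16.37 y), using the closed-form truncated moments and a root
  solve.  The right skew reproduces the young-adult-heavy composition (and
  thin middle-to-late adulthood tail) typical of public brain-age cohorts.
* **Channels**: six coregistered 3D maps per subject — a pseudo-T1 map,
  volume-like maps (`gmv`, `wmv`), density-like maps (`gmd`, `wmd`) and an
  age-independent `flair_stub` channel standing in for a synthesized FLAIR
  contrast.  Within an ellipsoidal brain mask tiled into `n_parcels`
  nearest-centroid parcels, the voxel value in parcel *p* of channel *c* is
  `baseline(c,p) + slope(c,p)·(age − age_mean) + N(0, noise_sd)`;
  background is exactly zero.  Baselines are uniform on [0.5, 1.5]; slope
  magnitudes default to 0.008/y for density channels, 0.004/y for volume
  channels and 0.003/y for the pseudo-T1, so density channels are the more
  age-informative set — emulating (not asserting) the ordering seen in real
  morphometry.  `noise_sd` defaults to 0.1 signal units per voxel.
* **Determinism**: every subject has an independent RNG stream keyed by
  SHA-256 of `(seed, subject_id)`, so cohorts are bit-reproducible and
  order-independent, and any subject can be re-rendered in isolation.

What the phantoms do *not* model: anatomy, tissue boundaries, site/scanner
effects, registration error, nonlinear age trajectories, age-by-sex
interactions.  Passing tests therefore demonstrate the correctness of the
pipeline's machinery and its statistical behavior under a known
ground-truth generative model — not predictive performance on real MRI.

## Preprocessing

Each channel is rescaled to [0, 1] by dividing by the per-channel maximum
over the *training* subjects only; the stored divisor is reused for
validation/test subjects, whose values may then exceed 1 and are clipped
back to 1 (the source data leave this case unspecified; clipping keeps the
input contract).  Rescaling is per-channel rather than global because the
channels live on unrelated intensity scales.  Grid conforming is trilinear
(`scipy.ndimage.map_coordinates`, order 1) with voxel-center alignment and
zero padding; the full-scale target grid is 121×145×121 at 1.5 mm, while
desk-scale runs use 16³ (the network's three stride-2 stages require each
axis divisible by 8).

## Feature extraction

* **Parcel-wise**: per-region mean of each channel over an integer atlas,
  ascending-label order.  At full scale a 442-region composite atlas with
  volume + density channels gives 884 features.
* **Spatial ICA**: for each channel, the training (subjects × masked-voxels)
  matrix is decomposed into K spatially independent maps by FastICA with
  PCA whitening to K dimensions (a generic substitute for probabilistic
  ICA tools; their internals are out of scope).  The analysis mask keeps
  voxels nonzero in ≥ 95% of training subjects.  Each subject is then
  summarized by the K beta weights of a single joint OLS regression of
  their masked voxel vector on all K maps plus an intercept (the
  dual-regression convention), yielding "integrity scores".  Full scale is
  K = 400 over four channels (1,600 features); desk default K = 20.
  Non-convergent ICA returns the best iterate with a warning and a
  `converged=False` flag.  The basis is fitted on training subjects only
  and frozen before being applied to held-out subjects.

## Conventional ML baselines

Ridge regression (λ grid {0.001, 0.01, 1, 10, 100}) and RBF-kernel SVR
(C and γ grids {0.001, 0.01, 0.1, 1, 10, 100, 1000}, ε at its conventional
default 0.1) under nested 10×10-fold cross-validation with negative MAE as
the inner selection score.  Features are z-scored inside each training
split (the RBF γ grid assumes standardized inputs); the scaler lives inside
the CV pipeline so no statistic crosses a fold boundary.  Folds are
randomized with a fixed seed, not age-stratified.  Final estimators are
selected by inner CV on all training rows, refitted on all rows, and carry
their feature-name schema: prediction aligns columns by name and rejects
missing columns.

## Residual age regressor

A 26-weighted-layer 3D ResNet: stem 3×3×3 convolution, 12 residual blocks
(each conv–BN–ReLU–dropout–conv–BN with shortcut add and trailing ReLU),
global average pooling and one linear output unit.  Blocks 3, 6 and 9 use a
stride-2 first convolution and a 1×1 stride-2 convolution (+BN) on the
shortcut, halving each spatial dimension.  Channel widths start at 16 and
double per stage (16-32-64-128); the desk variant divides all widths by 4.
Dropout (default rate 0.1) sits between the two convolutions of each block.
When the sex covariate is enabled it is encoded 0/1 and concatenated to the
pooled feature vector before the linear head.  Ages are regressed in years
without target normalization.

The stack is implemented in numpy with hand-derived backward passes
(im2col convolution, standard batch-norm backward, inverted dropout); every
layer's gradient is verified against central finite differences in the test
suite.

### Training and losses

SGD with momentum 0.9, weight decay 5e-4, initial learning rate 0.1,
decayed ×0.1 once 50% and again once 75% of the epochs have elapsed; batch
size 8; 300 epochs at full scale.  The base task loss is the mean absolute
error in years (the quantity all evaluation reports), optionally augmented
by one of two batch-level regularizers with weight `reg_weight`
(default 1e-4, chosen so the two terms are comparable at initialization):

* **Covariance loss** — with E = Y′ − Y the batch error vector,
  `L_cov = (1/N) Σ_ij (E_i Y_j)² = ‖E‖²‖Y‖²/N`, the mean over rows of the
  squared entries of the outer product E ⊗ Yᵀ.  This is the adopted reading
  of an ambiguous per-row summation over a matrix-valued expression; it
  preserves the printed 1/N prefactor, and the factorized form is used in
  code while the tests keep an independent naive double loop.
* **Ranking loss** — `L_rank = (1/N) Σ_ij (Y′_i Y′_j − Y_i Y_j)²`, the mean
  over rows of the squared difference between the prediction and
  ground-truth Gram (outer-product) matrices, preserving pairwise order
  structure within the batch.

Both have closed-form gradients (`2E‖Y‖²/N` and
`(4/N)(Y′_k‖Y′‖² − Y_k⟨Y,Y′⟩)`), finite-difference-verified.  Every epoch
ends with a validation pass (running batch-norm statistics, no dropout)
recording the validation MAE and the Spearman correlation of the brain-age
delta with age — the two numbers downstream selection filters on.  A
non-finite training loss aborts with the epoch index.

## Ensembling

* **Objective 1** (smallest MAE): five fixed member recipes —
  (t1, gmv, wmv); the same with the ranking regularizer; the same with the
  sex covariate; (t1, gmd, wmd); (t1, gmd, wmd, flair_stub) — each
  contributing its smallest-validation-MAE checkpoint; per-subject median
  aggregation (even counts average the central pair).
* **Objective 2** (smallest MAE with low age bias): all per-epoch
  checkpoints of all configurations form the candidate pool (6×300 = 1800
  at full scale); candidates with validation MAE < 3.8 y and |ρ| < 0.1 are
  ranked by MAE with deterministic tie-breaks (|ρ|, config id, epoch) and
  the top 8 aggregated by median.  The ρ filter uses the absolute value:
  reported bias correlations are typically negative, so a signed reading of
  "below 0.1" would be vacuous.  An empty selection warns and returns empty
  rather than raising; the caller decides whether to relax thresholds.

## Evaluation and bias correction

MAE, RMSE, R² between predicted and chronological age; Spearman correlation
(average ranks on ties) of delta = Y′ − Y with Y; and the KL divergence
KLD(P‖Q) between the chronological (P) and predicted (Q) age histograms on
shared 5-year bins spanning [15, 95] with additive smoothing ε = 1e-6
applied before normalization (the estimator choice — histogram vs KDE,
binning — was open; fixed bins in years keep the number interpretable).
Bias correction is delta-residualization in the Cole convention: OLS of
delta on age fitted on training predictions, the fitted trend subtracted
from each delta (never refitted on evaluation data).  In the pipeline the
line is fitted on *out-of-fold* cross-validation predictions of the
training sample: in-sample predictions of a refit estimator underestimate
the regression-to-the-mean slope and leave held-out bias uncorrected.  On the fitting set
this leaves corrected delta exactly uncorrelated with age; on held-out data
with the same bias structure it brings |Spearman| under the 0.1 criterion.

## Orchestration and problem sizes

A single YAML config drives the stages (simulate → preprocess → features →
train_ml → train_dl → ensemble → evaluate); one global seed fans out via
SHA-256 to per-stage seeds, so a config determines the run bit-for-bit.
Each run writes its artifacts and a manifest (config hash, version, seeds,
completed stages) under a run directory; a stage failure halts with the
stage name and keeps completed artifacts.

Package defaults are **desk scale**, chosen so the full pipeline and its
tests run comfortably on a single CPU: cohorts of 40–200 subjects on
24×28×24 grids (network input 16³), 60 parcels, K = 16–20 components,
quarter-width networks trained 2–30 epochs.  The documented full-scale
settings (121×145×121 at 1.5 mm, 442 parcels, K = 400, full widths, 300
epochs, ~2,500 subjects) use the same code paths via the same config keys.
The acceptance script (`scripts/acceptance.py`) runs a 140-subject cohort
with two ensemble members for 20 epochs.

## Known limitations

* The phantom's linear age effects make the task easier than real brain
  aging; desk-scale MAEs are not comparable to values achievable on MRI.
* The numpy network trains on CPU only; full-scale 121×145×121 training is
  impractical without an accelerator framework.
* Probabilistic ICA (mixture-model thresholding, variance normalization)
  is not reproduced; FastICA components can differ from MELODIC-style
  output beyond sign/permutation.
* The Objective-2 selection uses the designated validation split for its
  metrics; with few epochs and members the candidate pool can be empty at
  the full-scale thresholds, in which case the warning path applies.
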