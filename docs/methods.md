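# Methods

This note documents the models, estimators, and synthetic study conditions
implemented in `repgeom`, the choices made where the design was genuinely
open, and what the synthetic results do and do not show about real data.

## Effective dimensionality

For a representation with covariance eigenvalues λ₁ ≥ λ₂ ≥ … ≥ λₙ ≥ 0, the
effective dimensionality is the participation ratio

    ED = (Σᵢ λᵢ)² / Σᵢ λᵢ²,

a continuous count of the principal components that carry the variance:
ED = 1 when variance lies along a single direction and ED = n for an
isotropic cloud.  ED is invariant to scaling and to rotation of the feature
space, and bounded by the number of nonzero eigenvalues.

Eigenspectra are estimated by PCA on column-centered data via the singular
value decomposition of the centered matrix (numerically safer than forming
the covariance for wide matrices; a test asserts equivalence with the
explicit eigendecomposition up to 50×50).  The sample covariance uses the
n−1 denominator — immaterial to the scale-invariant ED, but fixed for
reproducibility.  When fewer than `n_channels` components are estimable
(n_stimuli − 1 < n_channels), the spectrum is zero-padded to `n_channels`;
the convention is ours, as no standard exists for this edge.  Centering is
always applied; an uncentered mode is deliberately not offered.  For
convolutional feature maps, global average pooling (spatial mean per
channel) precedes PCA by default so that the spectrum reflects variance of
image features rather than variance across space; ED on flattened maps is
available by simply skipping the pooling step.

Power-law structure of a spectrum is summarized by the least-squares slope
of log λᵢ vs log i over a user-chosen index range (exponent reported
positive for decaying spectra, exact on noiseless power laws); the 1/i
spectrum is the reference decay against which estimated spectra are
compared.

## Synthetic data generators

The generators define the study conditions for every analysis; their
defaults were chosen once as realistic for the scale of primate
electrophysiology benchmarks and are exercised unchanged by the tests.

* **Power-law feature clouds.**  Zero-mean Gaussians with population
  eigenvalues λᵢ = i^(−α) in a Haar-random orthonormal basis.  The analytic
  participation ratio of the truncated spectrum is the generator's ground
  truth; estimates at n_stimuli = 50 × n_channels come within 10 % of it.
* **Neural responses.**  Each simulated unit is a fixed random linear
  readout of the top `n_signal_dims` principal components of a feature
  cloud, plus independent Gaussian noise per trial repeat scaled so that
  per-unit signal/noise variance equals `snr`.  This makes the split-half
  reliability law exact in expectation: the correlation of two single-repeat
  copies is snr/(snr+1) (0.5 at snr = 1), which the tests verify by
  simulation.
* **Category clouds.**  M class centroids are drawn inside a single shared
  latent subspace of dimension `latent_dim` (random orthonormal embedding
  into `ambient_dim` channels), with per-coordinate scale calibrated through
  the chi-distribution mean so the expected pairwise centroid distance
  equals `separation`.  Within-class samples are uniform in a latent ball of
  radius `radius` (direction × radius·U^(1/d), the exact construction).  The
  subspace is shared across classes on purpose: `latent_dim` then is the
  latent dimensionality of the representation as a whole — the quantity ED
  estimates — and readout directions (centroid differences) live inside the
  same subspace as the within-class variation.  With independent per-class
  subspaces the radius normalization cancels the dimension dependence of
  projection distances exactly, and no concentration effect would be
  visible; the shared construction reproduces the ~√(D/d) concentration law
  that motivates the analysis.

All generators are driven by seeds derived from a global seed plus a stable
operation name (SHA-256, below 2³¹), so fixed seeds give bit-identical
outputs and changing one stage never perturbs another.

## Subspace-alignment simulation

All simulated representations are projections of a common *natural*
subspace: a Gaussian source with a slowly decaying spectrum (default
exponent 0.25) spanning `natural_dim` = 60 of `ambient_dim` = 100
dimensions.  An *ecological* (brain) basis is a random rotation within that
span; a *model* basis interpolates column-wise between an independent random
basis (alignment pressure AP = 0) and the ecological basis (AP = 1), then
re-orthonormalizes.  The mean squared canonical correlation between the two
bases grows monotonically in AP (property-tested against a Monte-Carlo
random-frame baseline at AP = 0).  Each subspace scales its projection
dimensions by the square root of a power-law gain spectrum; the exponent is
the knob, and the subspace's ED is reported as the analytic participation
ratio of that spectrum rather than re-estimated.  Observation noise of scale
`noise_sigma` is added to both projections after projection (a
`noise_before_projection` flag exposes the alternative, since either choice
is defensible).  Encoding performance is the mean held-out R² across
ecological dimensions from ordinary least squares (or PLS with at most 25
components; OLS falls back to PLS automatically when n_train ≤ model
dimensions), reported raw and clipped at 0 for summary tables.

The three regime presets are free design choices — each regime is defined by
the distribution of ED and AP it assumes, so each preset instantiates the
conditions under which its regime arises:

* **Dimensionality regime**: AP fixed at 0.25, model ED on a log grid from
  2 to 50, noise 0.1.  Models whose gain spectra decay quickly bury most
  dimensions beneath the noise floor, so ED strongly predicts performance.
* **Alignment regime**: model ED fixed (exponent 0.8), AP swept 0 → 1.
* **Joint regime**: AP is a log-Gaussian function of ED peaking at ED = 10
  (width 0.4), combined with a concentrated ecological spectrum (exponent
  1.5), low noise (0.05), and a capacity-limited PLS readout (25
  components).  Under these alignment-dominated conditions the score peaks
  at an interior ED.

Monotonicity of the alignment curve is judged up to twice the maximum
replicate standard error, since adjacent AP grid points can differ by less
than Monte-Carlo jitter.

## Encoding pipeline

The electrophysiology-style variant fits partial-least-squares regression
(25 latent components, scikit-learn's NIPALS with scaling off) from features
to trial-averaged unit responses under 10-fold cross-validation; folds are
contiguous blocks of a seeded shuffle, without stratification.  Per-unit
Pearson correlations between predictions and held-out responses are averaged
across folds (the default; correlating concatenated held-out predictions is
available as `aggregate="concatenate"` and agrees on clean data), aggregated
across units by the median, and normalized by the median split-half
reliability across units via the squared quotient (r/r_ceil)² — an explained
variance fraction relative to the noise ceiling.  The fMRI-style variant
uses 9-fold cross-validated ordinary least squares, per-fold-mean
correlations, and no ceiling normalization.  Units with zero test-fold
variance yield undefined correlations for that fold and are excluded from
that unit's aggregate with a logged count.

Split-half reliability averages, over 10 random partitions, the per-unit
correlation between the stimulus-wise means of two halves of the repeats.
The Spearman–Brown correction 2r/(1+r) is applied by default (flagged),
predicting the reliability of the full repeat set from half of it.  Note one
consequence of the convention: a perfect model predicting the mean of two
snr = 1 repeats can exceed a normalized score of 1, because the correlation
against the repeat-mean exceeds the corrected ceiling's square root.  Scores
are therefore comparable across models but are not capped at 1; the
monotone relationship with ED is the scientifically meaningful output.

Optional PCA feature reduction projects features onto the top components
(default 1000, capped at the reference's rank) estimated from an independent
reference feature set, centering by the reference mean; at full rank this
leaves encoding scores unchanged, which is tested.  The
representational-similarity alternative compares dissimilarity matrices
(1 − Pearson r across channels/units) by Spearman rank correlation of their
upper triangles and involves no parameter fitting.

## Prototype transfer

Category prototypes are per-class mean activation patterns; test samples are
assigned to the nearest prototype in Euclidean distance.  Accuracy is the
fraction of test samples whose true class ranks first, and the mean
reciprocal rank (MRR) averages 1/rank of the true class; exact distance ties
(measure-zero for continuous features) are broken by class-id order and
flagged.  Monte-Carlo cross-validation uses disjoint seeded splits per class
(defaults 50 train / 50 test per class, 10 iterations, 50 classes); accuracy
and MRR are averaged per iteration, then across iterations.  MRR obeys
MRR ≥ accuracy + (1 − accuracy)/M and equals 1 exactly when accuracy is 1.

## Projection distances

For categories i ≠ j with centroids μᵢ, μⱼ, the readout vector is
w = (μᵢ − μⱼ)/‖μᵢ − μⱼ‖; sample k of category i has projection distance
pₖ = |(xₖ − μᵢ)·w|, and the category radius Rᵢ = sqrt(mean per-dimension
variance, n−1 denominator) normalizes for feature scale, making the mean
normalized distance p̂ᵢⱼ = mean(p)/Rᵢ invariant to global rescaling.  The
full M×M matrix stores ordered pairs (it need not be symmetric); the
diagonal is undefined and stored as NaN, and per-model summaries average all
ordered off-diagonal entries.  The idealized demonstration samples points
uniformly in a unit d-ball and projects along a random unit vector: the mean
|projection| is 1/2 at d = 1 and 4/(3π) ≈ 0.4244 at d = 2, and decreases
toward 0 as d grows — the concentration effect that the category-cloud
analysis detects empirically.

## Problem sizes and tolerances

The default synthetic problem sizes (e.g. 5000×100 feature clouds for
spectrum estimation, 1000 stimuli × 100 channels × 30 units for the
encoding-vs-ED analysis, 20 replicates per simulation grid point, 10⁴
ball samples) were chosen so every analysis expresses its effect well above
Monte-Carlo jitter while remaining quick to rerun end to end.  Stochastic
assertions use 3-standard-error bands or a 10 % relative tolerance;
deterministic identities are asserted near machine precision.

## What the synthetic results do not show

The generators emulate statistical structure — power-law spectra, noisy
linear readouts, ball-shaped category clouds in a shared latent subspace —
not images, networks, or brains.  Passing tests demonstrate that the
estimators and pipelines recover known ground truth under these conditions
and that the qualitative dimensionality effects arise for geometric reasons;
they do not certify that any particular network family or cortical area
operates in a given regime, nor do they reproduce results that depend on
real activations or recordings.  Gaussian sources make linear readouts
optimal by construction; real representations are non-Gaussian, and
category subspaces need not be elliptical — the radius normalization is an
operational choice, not a geometric claim.
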