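# Methods

`objdim` implements a voxel-wise encoding analysis in which visual brain
responses are modelled as weighted combinations of 66 interpretable,
non-negative object dimensions derived from behavioural similarity
judgements. Because the full fMRI dataset is not required, the package
ships a first-class synthetic generator that reproduces the statistical
structure the analysis assumes and provides ground truth for every
recovery claim the tests make. This note documents the models, the
defaults and why they are set as they are, the numerical choices, and the
known limitations.

## Synthetic study generator

The generator emulates a rapid event-related object-vision study:
12 sessions, a fixed set of images presented once per session in every
session (default 100 "repeat" images, used for reliability estimation),
500-ms stimulus presentations followed by 4 s of fixation, and a
repetition time of 1.5 s. Trial counts per session default to desk-scale
values (120) rather than the original session length.

**Embedding.** Dimension values are exponential draws with exponentially
decaying column scales (decay rate 1.0 across the 66 columns, i.e. the
least important dimension has half the scale of the most important),
soft-thresholded at each column's 0.6 quantile so ~60% of entries are
exactly zero. Columns are re-sorted by decreasing standard deviation so
importance ordering holds exactly in finite samples. This reproduces the
sparse, non-negative, importance-ordered character of the behavioural
embedding without re-training it.

**Voxel ground truth.** Voxels belong to one of three tuning classes:
`sparse` (1–2 nonzero dimension weights), `dense` (at least 22 of 66),
or `noise` (no tuning and no stimulus-onset response). Nonzero weights are
Normal(1.0, 0.5) — positive-mean, so signal voxels are predominantly
positively tuned, as the rectified profile/sparseness analyses assume.
Each voxel also carries a true HRF index into the kernel library and a
noise SD. `calibrate_noise_sd` converts a target SNR (signal SD over noise
SD) or a target single-trial noise ceiling into per-voxel noise SDs.

**Lattice geometry.** Voxels live on an abstract 3-D lattice. The three
classes occupy compact slabs separated by empty planes wider than the
smoothing kernel's reach. This abstraction encodes two properties of the
data the analysis was designed for: functionally distinct tuning occupies
spatially coherent regions larger than the smoothing kernel, and the
voxels the model cannot predict (the later noise pool) lie overwhelmingly
far from modelled cortex. On a fully packed desk-scale lattice, smoothing
bleeds dense-blob weights into most pool voxels and inflates the pool's
log-sparseness spread by an order of magnitude, which no amount of data
fixes; the separation removes that artifact. Consequently the generator
does not exercise class-boundary adjacency effects (see Limitations).

**Time series.** BOLD signal is built on a microtime grid of TR/10
(so 500-ms events are representable at TR = 1.5 s): onset boxcars plus
mean-centred per-dimension modulators, convolved with the voxel's true
HRF, downsampled to scans, sessions concatenated. Noise is iid Gaussian
per scan; an AR(1) option (coefficient 0 by default) exists as an opt-in
stressor, since the data this emulates were denoised before modelling.
No drift, motion or session gain is simulated.

## Single-trial encoding

OLS with intercept maps the 66 dimension values to single-trial response
amplitudes per voxel. Performance is the fold-mean Pearson correlation
and R² under leave-one-session-out cross-validation. Significance uses a
permutation null (held-out trial order of the observed data permuted
within each fold, one shared permutation sequence across voxels,
fold-mean statistic, add-one p estimator so p ≥ 1/(1+n_perm); default
10,000 permutations, tests use 1,000) followed by Benjamini–Hochberg FDR
(BY available by flag). The noise ceiling is estimated from the repeat
images as nc = signal_var / (signal_var + noise_var), with noise_var the
across-repeat variance averaged over images and signal_var the variance
of image means minus noise_var/n_repeats, rectified at zero; model R² is
divided by nc where nc ≥ 0.02 (NaN elsewhere, never ±inf).

**Calibration caveat (important).** Permuting only the held-out data
holds the predictions fixed, but under leave-one-session-out each fold's
predictions are functions of the other folds' test data. On voxels with
no signal the fold-mean correlation is therefore overdispersed relative
to its permutation null (measured variance inflation ≈ 2 at 12 sessions),
making the p-values anticonservative in the tails. This is a property of
the procedure itself, not of this implementation; an exact test would
refit every fold under each permutation at ~100× the cost. Users should
treat these p-values as approximate and rely on the FDR threshold with
this caveat in mind.

**Weight-recovery regime.** With noise at a single-trial noise ceiling of
0.2 (noise variance four times signal variance) and 1,200 trials, the
per-weight OLS estimation error has a floor of about 4·66/1200 ≈ 0.22 of
the weight-row variance even for a perfectly conditioned design, capping
the attainable per-voxel correlation between fitted and true weights near
0.9 (measured median ≈ 0.79–0.86 depending on design diversity). Higher
ceilings or more trials are needed for near-perfect weight maps; the
parametric-modulation model, which uses every scan, recovers weights far
more accurately at matched SNR.

## Parametric modulation

The design per session is one onset regressor (all trials), 66 modulators
(event values mean-centred over all trials of the modelled run set, making
them orthogonal to the onset regressor at the event level), and an
unpenalized per-session intercept. Convolution happens on the microtime
grid and is truncated at run edges. The HRF library holds 20 peak-
normalized double-gamma kernels: 10 times-to-peak spanning 4–8 s crossed
with undershoot ratios {0.15, 0.35}, ordered by realized peak time.

Regularization is fractional ridge: the hyperparameter is the fraction
f = ‖β(λ)‖/‖β_OLS‖ of the unregularized coefficient norm to retain
(penalized columns only). The solver works in the SVD basis of the design
after projecting out unpenalized columns (exact for partially penalized
ridge); the penalty achieving each requested fraction is found by
interpolation on a log-penalty grid plus Newton refinement to a relative
tolerance of 1e-6, far inside the 0.01 accuracy the analysis needs. The
fraction grid is 0.10–0.90 in steps of 0.10 plus 0.90–1.00 in steps of
0.01 (19 unique values after de-duplication at 0.90).

Hyperparameters (HRF × fraction) are selected per voxel by exhaustive
12-fold between-session cross-validation (sessions are folds), scoring
held-out R² with per-session centring of prediction and data (a held-out
session's intercept is not identified). Ties break toward the smaller
time-to-peak, then the larger fraction. The final weights come from a
whole-data fit at the selected pair.

## Tuning profiles and representative images

A regional profile averages weights over the ROI's surviving voxels
within participant, then across participants, then sets negative entries
to zero — in that order, so sign cancellation across participants
happens before rectification. Voxels with noise ceiling below 2% are
excluded by default. Representative images are ranked by cosine
similarity between the rectified profile and each image's embedding row
(ties broken by image id; all-zero rows excluded with a warning).
Inter-participant consistency correlates, per dimension, the vector of
ROI-mean weights across participants (hemisphere-split ROIs are the
caller's responsibility when building the ROI set) and averages over
participant pairs.

## Representational sparseness

Weight maps are smoothed with a mask-renormalized Gaussian kernel
(FWHM 4 mm at 2-mm voxels, σ = 0.8493 voxels), rectified (negatives set
to zero, keeping n = 66 so maps stay comparable; a drop-entries mode
exists for sensitivity analysis), and scored with the Hoyer statistic
s(x) = (√n − ‖x‖₁/‖x‖₂)/(√n − 1), clamped to [0, 1] against rounding.
All-zero vectors get an undefined marker (NaN) rather than an exception.
The noise pool is the set of voxels with modulation cv R² < 1e-4 (strict
inequality); pool log-sparseness supplies mean and SD for one-sided
upper-tail z and p per voxel (s = 0 voxels are excluded before the log).
Clusters are 6-connected components of p < 0.05 voxels filtered by a
minimum size and sorted by peak z — a reproducible surrogate for
locating sparse regions by eye.

## Variance partitioning

Each category's most diagnostic dimension is the argmax of the
Mann–Whitney AUC (midrank ties; argmax ties toward the lower index); the
distinct selected dimensions form the dimension model, deliberately
smaller than the binary category model. Unique variance of a model is
the 12-fold between-session cross-validated OLS R² after orthogonalizing
both that model and the data against the other model (intercept
included); orthogonalization is computed once on the full data, as the
procedure is usually described — a leakage-safe fold-wise variant is
available by flag and agrees closely on clean data. The combined model
concatenates both design matrices (pseudoinverse solve, so duplicated
columns are harmless), and shared = combined − unique_A − unique_B holds
exactly by construction. Negative unique or shared values arise from CV
noise and are reported as computed. Note the held-out-mean R² definition
gives null models a small negative bias of roughly −(p/n_train +
1/n_test).

## Embedding extension

Per-dimension ridge regression maps standardized image features to
dimension values; the penalty (default grid: 9 log-spaced values in
[1e-3, 1e3]) is chosen per dimension by 5-fold CV on held-out explained
variance, ties toward the larger penalty, and the reported cv_score is
the held-out score of the chosen penalty. Predictions are not rectified:
negative predicted values are legitimate inputs to the encoding models,
and rectification belongs to the profile/sparseness stages.

## What the synthetic tests do and do not show

Passing tests demonstrate that every estimator recovers the structure it
targets when its assumptions hold (known HRFs from the same library,
linear responses, Gaussian noise, exact class geometry), at the noise
levels and problem sizes stated in each test. They do not demonstrate
robustness to HRFs outside the library, non-linear or saturating
responses, temporally correlated or non-Gaussian noise, imperfect
preprocessing, or class-boundary adjacency under smoothing — all absent
from the generator by design. Problem sizes in the test suite (hundreds
to a few thousand voxels, 40–120 trials per session) are chosen as the
smallest sizes at which the statistical claims are stable.

## Known limitations

- The permutation p-values inherit the anticonservativeness described
  above; this is documented rather than silently corrected because the
  test-data-only permutation is the procedure being implemented.
- The noise pool's log-normal model is assumed, not checked, per voxel.
- Cluster discovery parameters (6-connectivity, minimum size) are
  conventions of this artifact; the original analysis located clusters
  by visual inspection.
- The generator draws each sparse voxel's tuned dimensions independently,
  so neighbouring sparse voxels are *differently* tuned and smoothing
  dilutes their sparseness; real category-selective regions share tuning
  and would show stronger, not weaker, smoothed sparseness.
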