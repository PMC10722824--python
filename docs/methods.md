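# Methods

This note documents the models and numerical choices behind `gazevam`, the
assumptions they rest on, and what the synthetic-data experiments do and do
not establish.

## The diagnostic model

Two visual attention models (VAMs) are trained, one per cohort (TD, ASD).
Each VAM is a per-pixel binary classifier: given the 28-dimensional feature
vector of a pixel in a video frame group, predict whether members of that
cohort fixated it. Applying a cohort's VAM to every pixel of a frame yields
that cohort's *saliency map* for the frame. An individual is diagnosed by
comparing their own fixation map, frame group by frame group, with the two
cohorts' saliency maps: each group casts a vote for the more similar cohort,
and the majority wins. The fraction of ASD votes among cast votes is a
continuous score in [0, 1] used for ROC analysis.

The key assumption is that group-level attention differences (face and
social-scene orientation versus geometric preference, center biases) are
expressed consistently enough at the individual level that per-frame
similarity voting accumulates evidence. The model is purely spatial per
frame group; temporal order enters only through frame aggregation and fold
construction.

## Preprocessing

- **Data-loss screening.** A subject is excluded iff their fraction of
  invalid samples is strictly greater than the threshold (default 0.20).
  The boundary case (exactly 20%) is retained; the criterion is documented
  as strict because the protocol states the threshold without boundary
  semantics.
- **Inter-frame motion** is the mean absolute grayscale difference
  (grayscale = channel mean, intensities in [0, 1]). It is the simplest
  metric consistent with an "average motion" criterion; it is symmetric,
  bounded, and zero iff frames are equal. The interface is pluggable should
  an optical-flow metric be preferred.
- **Frame aggregation** scans left to right; a frame joins the current
  group iff the running mean of consecutive-pair motions inside the group,
  including the new pair, stays strictly below the threshold (default
  0.33). A pairwise-only variant (`rule="pairwise"`) is available. The
  running-mean rule has a notable dynamic: once a group has accumulated a
  low mean, isolated motion spikes are diluted and will not break it, so
  balanced group structures arise only when motion hovers near the
  threshold. The synthetic stimulus is designed with this in mind (below).
- **Fixation maps** place unit impulses at fixation centroids, smooth with
  an isotropic Gaussian (sigma = 2% of frame width by default,
  config-exposed), and normalize the maximum to 1. Cohort maps sum member
  subjects' impulses before smoothing. A fixation is credited to the one
  frame group containing its temporal midpoint. The alternative — crediting
  every group the fixation overlaps — is available (`assign="overlap"`) but
  is not the default because it leaks under cross-validation over frame
  groups: a fixation spanning a fold boundary would enter both a cohort's
  training map and the same subject's held-out map, and with visually
  similar neighboring groups the trained forest effectively memorizes it.
  Measured on exchangeable synthetic cohorts, the overlap rule inflates
  the null AUC to ~0.65–0.73; the midpoint rule restores it to ~0.5.

## Features

Channels 1–13 are steerable second-derivative-of-Gaussian subbands (scales
sigma = 1, 2, 4 pixels x orientations 0/45/90/135 degrees) plus a lowpass
residual (sigma = 8), each rectified and divided by its spatial mean, so
every subband averages exactly 1 and varies only between pixels. The image
mean is removed before filtering because the discrete derivative kernels
carry a small DC bias; a contrast-free frame would otherwise produce
nonzero bands. A degenerate zero-energy band falls back to the constant-1
map. Itti-style conspicuity (channels 14–16) uses red-green and
blue-yellow opponency, intensity, and oriented energy, each center-surround
filtered (|difference of Gaussians| at scale pairs 1–4 and 2–8) and
max-normalized with a 1e-9 floor so numerical dust on flat frames is not
amplified. Skin (17) is the classical YCbCr box rule in detector mode, or
the blurred ground-truth mask in fixtures mode. Face/people (22–23) come
from ground-truth masks or from a skin-blob bounding-box heuristic; the
synthetic-data tests always use ground-truth masks, so detector quality
never gates correctness. The center-screen map (24) is an isotropic
Gaussian (sigma = 0.5 H) and the center-scene map (28) the max of two
Gaussians, one per lateral half (sigma = 0.35 H), both renormalized to
peak exactly 1 after discretization and identical across frame groups by
construction. Movement (25) is the within-group mean absolute temporal
difference divided by a stimulus-global constant (the maximum per-pixel
temporal difference over the whole video). Social/geometric scene channels
(26–27) are mirrored soft half-indicators, masked to their own halves so
their supports stay disjoint.

## Model training

- **Pixel sampling.** Positives are drawn from pixels at or above the 0.80
  density quantile of the cohort fixation map (and strictly positive —
  on sparse maps the quantile itself can be zero), negatives from pixels
  at or below the 0.70 quantile; 50 of each per frame group by default,
  balanced, seeded. Frame groups without fixations are skipped with a
  warning.
- **MLP (nn).** One hidden layer of 10 logistic units, linear output,
  learning rate 0.01, at most 1000 epochs or training tolerance 1e-7.
  Bayesian-regularized backpropagation is approximated by a fixed L2
  weight-decay constant (default 1e-3): the evidence-maximization update
  of the classic trainbr procedure is out of scope, and L2 decay is its
  fixed-hyperparameter limit. Scores are the clipped linear outputs.
- **SVM.** Linear support-vector classifier (liblinear) with default
  regularization; continuous scores are the logistic squash of the signed
  margin, which preserves ranking (all AUC analyses are rank-based).
- **Random forest.** Bagged trees with the grid trees in {25, 50, 100, 200}
  x mtry in 3..9 (28 configurations) scored by out-of-bag accuracy; the
  grid is scored on a seeded subsample of at most 3000 rows (OOB estimates
  stabilize well below that) and the winner is refit on the full table.
  Ties keep the first configuration in grid order.
- **Feature selection.** ReliefF uses k = 60 nearest hits/misses on
  min-max-scaled features and keeps channels with weight strictly above
  the mean weight (all-equal weights therefore select nothing). The GA
  wrapper searches fixed-size subsets (default 15) with population 30,
  20 generations, tournament size 3, single-point-style crossover with
  repair, 5% swap mutation; fitness is the internal 3-fold CV AUC of a
  logistic-regression probe. Both are computed per fold on training data
  only.
- **Cross-validation** partitions frame groups into 5 contiguous
  chronological blocks (sizes differing by at most 1). Contiguity limits
  leakage between visually similar neighboring groups. Saliency maps are
  emitted only for held-out groups; within the CV driver they are
  predicted at stride 2 and bilinearly upsampled, a close approximation
  justified by the spatial smoothness of the maps (full-resolution
  prediction remains the `predict_saliency` default).

## Diagnosis and evaluation

Similarity is Pearson correlation (cosine and histogram intersection are
available for sensitivity analysis); a constant map has similarity 0 to
anything. A frame group abstains when the subject has no fixations on it
or on an exact tie (including identical saliency maps). At the subject
level, ties and all-abstain cases fall back to TD — conservative toward
no diagnosis — and are flagged. AUC is computed from the vote-fraction
scores by the rank (Mann-Whitney) formulation with midrank tie handling;
threshold metrics come from the predicted labels, with ASD as the positive
class. AUC sets are compared with the Wilcoxon signed-rank test (paired)
or the Mann-Whitney U test (unpaired), using exact small-sample null
distributions when n <= 25 and the data allow (no zero differences / no
ties), otherwise the standard corrected approximation.

Random-forest feature importance is permutation importance on a
caller-supplied evaluation set (mean accuracy drop over 5 permutations per
channel, negatives clipped, normalized to sum 1). A strict out-of-bag
permutation scheme was considered but would require reconstructing each
tree's bootstrap membership through private estimator state; the explicit
evaluation-set variant measures the same quantity on exchangeable data.

## The synthetic-data generator

The generator emulates the study conditions at desk scale: a 320x180,
30 fps, 10 s split-screen video (left: a skin-toned person proxy with a
face patch, drifting slowly; right: an animated high-contrast plaid), and
two cohorts of 20 subjects sampled at 250 Hz with 5% data loss. Gaze is a
sequence of dwell events (150–400 ms): per event an attractor is chosen
from the cohort's mixture, a target is drawn by inverse-CDF sampling from
the attractor's map, samples scatter around the target with 5 px Gaussian
jitter, and targets on moving masks ride the mask centroid (smooth
pursuit). Default mixtures give TD face weight 0.6 and ASD face weight 0.1
with a geometric-half preference — the preferential-looking contrast the
paradigm probes. Fixations are then re-derived with a dispersion filter
(radius 25 px, minimum 100 ms, 75 ms dropout-gap tolerance) standing in
for the vendor velocity-threshold filter, which is out of scope.

The stimulus's temporal structure is a global luminance sequence
alternating strong flicker runs (bright/dark every frame, ~0.5 motion)
with calmer zig-zag runs (~0.18 motion), plus slow plaid drift. This
keeps the consecutive-frame motion distribution spanning the whole sweep
range 0.05–0.35, so the default 0.33 threshold yields on the order of
10^2 frame groups with a mix of multi-frame groups and singletons, and
group counts decrease monotonically across the sweep. A perfectly static
stimulus (motion = 0) collapses to a single frame group at every
threshold, which is below the fold count; the sweep runner marks such
rows infeasible (AUC missing), identically at every threshold.

What the synthetic experiments show: the pipeline recovers a planted
cohort-level attention difference (cross-validated AUC >= 0.9 under the
default separated mixtures, chance under exchangeable mixtures) and ranks
a planted feature channel highly in importance. What they do not show:
performance on clinical recordings — real gaze has saccade dynamics,
pursuit, idiosyncratic and age-dependent biases, and real videos have
semantic content none of which the generator models. Detector-mode feature
quality (faces, people) on natural video is likewise untested.

## Degenerate inputs and tie-breaking

- Empty stimulus, empty recordings, zero-sample subjects: errors.
- Frame groups without cohort fixations: skipped in training with a
  warning; an entirely empty pixel table is an error in the CV driver.
- Exact similarity ties: abstain; subject-level ties: TD, flagged.
- One-class truth in a fold: AUC reported missing for that fold.
- All stochastic steps (generator, sampling, GA, forests, MLP) take
  explicit seeds; reports are byte-identical across reruns of one config.

## Problem sizes

Default experiment sizes (10 s stimulus, 40 subjects, ~100 frame groups,
50 pixel samples per class per group, 50-tree forests in the recovery
experiments) were chosen so a full cross-validated run completes in under
a minute on a single core while leaving the planted-signal recovery
margins comfortable.
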