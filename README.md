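# gazevam

Group-specific **visual attention models (VAMs)** for eye-tracking-based
classification of autism spectrum disorder (ASD) versus typical development
(TD), built around the split-screen preferential-looking paradigm: children
watch a video whose left half shows a social scene and whose right half
shows an animated geometric pattern, while an eye tracker records their
gaze. TD and ASD cohorts distribute their attention differently over such
stimuli (notably, a stronger geometric preference and weaker orientation to
faces in ASD), and that difference can be learned and used diagnostically.

## Method

The pipeline has four stages:

1. **Preprocessing.** Subjects whose eye-tracking data loss exceeds 20% are
   excluded. Consecutive video frames are aggregated into *frame groups*
   whenever the average inter-frame motion (mean absolute grayscale
   difference, in [0, 1]) stays below a threshold (default 0.33), so each
   group accumulates enough fixations to learn from. Per frame group and
   cohort, fixation centroids are accumulated into a Gaussian-smoothed,
   max-normalized *fixation map*.
2. **Features.** Each frame group's representative frame is described by 28
   per-pixel channels: 13 steerable-pyramid subbands (each normalized to
   spatial mean 1), Itti-style color/intensity/orientation conspicuity,
   skin, raw R/G/B, a horizon-line band, face and people maps, center-screen
   and per-scene center-bias Gaussians, within-group movement, and soft
   social/geometric half-scene indicators.
3. **Attention models.** For each cohort a per-pixel *fixed / not-fixed*
   classifier is trained on balanced samples drawn from the top and bottom
   quantiles of the cohort fixation maps. Three families are supported —
   a 10-hidden-unit MLP, a linear SVM, and a random forest with trees in
   {25, 50, 100, 200} and mtry in 3..9 chosen by out-of-bag score —
   optionally preceded by ReliefF (k = 60, keep weights above the mean) or
   a genetic-algorithm wrapper (15 features). Training uses 5-fold
   cross-validation over contiguous blocks of frame groups; saliency maps
   are predicted only for held-out groups.
4. **Diagnosis.** For every held-out frame group, a subject's fixation map
   is compared (Pearson correlation) with the TD and the ASD saliency map;
   the more similar map receives the vote. The subject is classified by
   majority vote, the ASD-vote fraction serves as a continuous score, and
   cohorts are evaluated with AUC (rank / Mann-Whitney formulation), F1,
   accuracy, sensitivity, precision and specificity. AUC sets from
   different configurations are compared with exact Wilcoxon signed-rank
   or Mann-Whitney tests; a threshold-sweep runner re-runs the pipeline
   over aggregation thresholds 0.05–0.35 (step 0.05) plus 0.08 and 0.33.

Because clinical recordings for this paradigm are not publicly available,
the package ships a first-class synthetic-data module: a seeded
split-screen stimulus generator with ground-truth masks, and a gaze
simulator that draws each cohort's fixations from configurable mixtures
over attractor maps (face, scene halves, center biases, uniform).

## Worked example

```python
from gazevam import (
    StimulusConfig, GazeSimConfig, generate_stimulus, simulate_gaze, run_analysis,
)

stimulus = generate_stimulus(StimulusConfig(duration_s=10.0), seed=1)
recordings = simulate_gaze(stimulus, GazeSimConfig(), seed=2)  # 20 TD + 20 ASD
report, extras = run_analysis(
    stimulus, recordings,
    algorithm="rf", hyperparams={"n_trees": 50, "mtry": 9}, seed=3,
)
print("frame groups:", extras["n_groups"])
print("mean AUC:", round(report.mean["auc"], 3))
```

Output:

```
frame groups: 107
mean AUC: 0.978
```

The default simulator gives the TD cohort a strong face preference (weight
0.6) and the ASD cohort a geometric-half preference (face weight 0.1); the
cross-validated voting diagnosis separates the cohorts with AUC ≈ 0.98.
With identical mixtures for both cohorts the same pipeline stays at chance
(AUC ≈ 0.5), confirming that the separation reflects the planted
attention difference rather than leakage.

The same pipeline is available from the shell:

```sh
gazevam run --seed 3 --out results/demo      # simulate + full analysis
gazevam sweep --seed 3 --out results/sweep   # aggregation-threshold sweep
```

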