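# dmnconnect

Resting-state functional-connectivity analysis of the default-mode network
(DMN), built as a tested, reusable pipeline: time-series conditioning of 4D
BOLD images, spatial independent component analysis per participant,
template-based selection of each participant's DMN component by a
goodness-of-fit statistic, and group inference with Monte-Carlo
cluster-extent family-wise-error correction. A first-class synthetic-data
module simulates two-cohort resting-state studies with planted coherent
networks and controlled regional group differences, so every stage of the
analysis can be validated against known ground truth.

The intended users are neuroimaging methodologists who want a compact,
fully seeded re-implementation of the classic ICA + template-matching
connectivity workflow whose statistical behavior (selection accuracy,
false-positive control, detection power) can be measured rather than
assumed.

## Method

Each participant's series `y(x, t)` on a common 3 mm grid is conditioned by
spatial smoothing (Gaussian, FWHM 6 mm), per-voxel temporal normalization
(mean 0, SD 1), regression of motion confounds, and a hard Fourier
band-pass of the residuals at 0.01–0.08 Hz. Spatial ICA factorizes the
masked series as `Y ≈ C · S`, with maximally independent spatial maps `S`
(voxels as samples) extracted by a deflationary fixed-point iteration with
the kurtosis contrast; maps are z-scored over the brain mask.

The participant's DMN component is chosen in two passes. A pooled
voxel-wise one-sample t-test over all participants' candidate maps,
thresholded at one-sided p < 0.005 with a Monte-Carlo-calibrated cluster
extent, yields a binary DMN template `T`. Each component map `z` is then
scored by the goodness of fit

    g(z) = mean(z | x ∈ T) − mean(z | x ∈ mask \ T),

and the component maximizing `g` is the best fit. Group analysis enters the
best-fit z-maps into per-group one-sample t-tests and a pooled-variance
two-sample t-test (df = n_A + n_B − 2) restricted to the logical OR of the
two group DMN maps. Significance is voxel-wise p < 0.005 combined with a
minimum cluster extent `k*`, the smallest k for which the empirical
probability that a smooth Gaussian null volume contains a suprathreshold
cluster of ≥ k voxels is at most α = 0.05.

## Worked example

Simulate the default study — 14 vs 13 participants, 180 frames at TR 2 s,
five planted networks, and a 50 % connectivity increase in a
hippocampus-like region plus decreases in dACC-like and caudate-like
regions of cohort A — then run the full analysis:

```python
from dmnconnect import (PipelineConfig, analyze_cohort, default_effect,
                        make_network_maps, synthesize_cohorts)

networks = make_network_maps(seed=1)
effect = default_effect(networks, magnitude=0.5)
subjects, _ = synthesize_cohorts(14, 13, networks, effect, seed=1)

config = PipelineConfig(seed_ica=2, seed_mc=3)
result = analyze_cohort(subjects, networks.mask, networks.affine,
                        tr_s=2.0, config=config,
                        prior_map=networks.component_maps[0])
```

which prints (see `result.fit_table` and `result.cluster_table`):

```
DMN template: 3248 voxels (extent threshold 17)
goodness of fit, best-fit component:   1.74 +/- 0.04
goodness of fit, second best-fit:      0.22 +/- 0.06
two-sample cluster-extent threshold: 10 voxels (alpha achieved 0.034)
 size_voxels  size_mm3  peak_x_mm  peak_y_mm  peak_z_mm  peak_stat  z_mean_A  z_sd_A  z_mean_B  z_sd_B
          83    2241.0       -1.5       13.5       22.5     -12.92      1.29    0.21      2.28    0.31
          61    1647.0      -13.5        7.5       -4.5     -11.86      1.31    0.18      2.09    0.25
          49    1323.0       22.5       -4.5      -19.5       5.34      3.21    0.55      2.30    0.34
```

The best-fit goodness-of-fit scores separate cleanly from the second-best
(the selector picked the planted DMN component for all 27 participants),
and exactly three clusters survive correction: two with negative t (cohort
A's planted dACC-like and caudate-like decreases — note the lower
cluster-mean z in group A) and one with positive t at the hippocampus-like
site. Peak coordinates are world mm (X left→right, Y posterior→anterior,
Z inferior→superior).

The same workflow is available from the shell:

```
dmnconnect simulate --out data/ --seed 1
dmnconnect run --data data/ --out results/ --seed 2
dmnconnect report --out results/
```

## Layout

- `src/dmnconnect/synth.py` — synthetic cohorts with planted networks
- `src/dmnconnect/preprocess.py` — smoothing, normalization, nuisance
  regression, band-pass
- `src/dmnconnect/ica.py` — spatial ICA (deflationary fixed point)
- `src/dmnconnect/template.py` — DMN template and goodness-of-fit selection
- `src/dmnconnect/inference.py` — t-maps, Monte-Carlo extents, cluster table
- `src/dmnconnect/runner.py`, `cli.py` — orchestration, config, CLI
- `docs/methods.md` — model, parameter and design notes
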