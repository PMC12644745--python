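# numadapt

Model-based fMRI analysis of **numerosity adaptation** in early visual
cortex, for researchers who study how recently viewed quantities change
neural responses to current ones.

Numerosity — the number of items in a view — is encoded in human visual
cortex both by *monotonic* responses, whose amplitude grows with the
spatial-frequency content of the display, and by *numerosity-tuned*
populations peaking at a preferred count. Adaptation is repulsive: after
prolonged exposure to a low or high numerosity, responses to a test
numerosity are suppressed, and the suppression grows along the visual
hierarchy. This package implements that whole analysis as a tested,
reusable pipeline, validated end to end on synthetic data with known
ground truth.

## The models

Every 1.4 s fMRI volume (TR) contains an **adaptor** display (constant 1,
constant 20, or yoked to the test — the three conditions) and a
**changing** display sweeping numerosities 1..7 with 20-dot baselines.
Displays keep total dot area constant, so dot count is carried by the
image's spatial-frequency content, quantified as the aggregate Fourier
power `P(n)` of the display.

Per voxel, two response models are compared:

- **monotonic**: neural amplitude ∝ `log P(n)` (or `log n`), giving a GLM
  whose *slope* β is the response amplitude per unit log predictor;
- **tuned pRF**: amplitude `exp(−(ln n − p)² / (2w²))`, fit by exhaustive
  grid search over preferred log numerosity `p` (step 0.01) and log width
  `w` (step 0.0074).

Both are convolved with a two-gamma HRF and include the adaptor regressor
(constant → absorbed by the baseline; identical to the test regressor in
the control condition → merged, doubling amplitude and halving the fitted
scale). Models are selected per voxel by odd/even-run cross-validation
with a sign-preserving amplitude rescale; tuned winners preferring
numerosities above 7 are re-labelled monotonic.

The adaptation effect per *map example* (one visual field map in one
hemisphere) is the gain-invariant **proportional slope reduction**

```
(β_low − β_high) / β_changing
```

tested with Wilcoxon signed-rank tests (FDR across maps), a two-factor
ANOVA (map + participant) with Tukey HSD, and cross-region Pearson
correlations. A behavioural loop (2AFC comparison against a 10-dot
reference, adaptive minimum-expected-entropy staircase, cumulative-Gaussian
PSE fits, Bonferroni-corrected paired t-tests) validates the repulsive
perceptual effect.

## Worked example

```python
import numadapt as na

# 1. study conditions: 4 participants, both hemispheres, all 7 maps
cfg = na.GroundTruthConfig(n_participants=4, voxels_per_map=6, seed=7)
voxels, truth = na.generate_voxel_dataset(cfg)

# 2. fit monotonic + tuned models, cross-validate, classify
fits = na.fit_voxels(voxels)

# 3. voxel selection -> map examples -> adaptation metric
examples = na.add_proportional_reduction(
    na.aggregate_map_examples(na.select_voxels(fits)))

# 4. group statistics
anova = na.map_effect_anova(examples)
```

Output:

```
336 voxels -> 55 map examples
  V1   proportional slope reduction = 0.201   (planted: 0.20)
  V2   proportional slope reduction = 0.298   (planted: 0.30)
  V3   proportional slope reduction = 0.401   (planted: 0.40)
  hV4  proportional slope reduction = 0.499   (planted: 0.50)
  LO1  proportional slope reduction = 0.600   (planted: 0.60)
  LO2  proportional slope reduction = 0.699   (planted: 0.70)
  V3AB proportional slope reduction = 0.799   (planted: 0.80)
map effect: F(6,45) = 11903.8, p = 2.7e-70
```

The generator planted a suppression gradient rising from V1 to V3A/B at
10% noise; the pipeline recovers each map's proportional reduction to the
third decimal, and the ANOVA detects the between-map difference. Voxels
with eccentric receptive fields, negative control slopes, or poor fits
were filtered out on the way (336 generated → 55 retained map examples).

The same stages run from the shell:

```
numadapt run --out results/ --seed 7          # simulate … report
numadapt simulate --config my.yaml --out d/   # one stage at a time
```

## Layout

- `src/numadapt/stimuli.py` — dot displays, Fourier power, run sequences
- `src/numadapt/hrf.py`, `design.py` — HRF kernels, predictors, designs
- `src/numadapt/models.py` — `MonotonicResponseModel`, `TunedResponseModel`,
  cross-validation and classification
- `src/numadapt/adaptation.py` — voxel selection, map examples, reduction
- `src/numadapt/stats.py` — signed-rank/FDR, ANOVA + Tukey, correlations
- `src/numadapt/behavior.py` — observer simulation, `PsychometricModel`,
  PSE comparisons
- `src/numadapt/synth.py` — ground-truth generators
- `src/numadapt/io.py`, `config.py`, `pipeline.py`, `cli.py` — artifacts,
  configuration, orchestration
- `docs/methods.md` — full model description, defaults and limitations
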