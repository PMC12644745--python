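# Methods

`numadapt` implements a model-based fMRI analysis of numerosity adaptation
in early visual cortex, together with a synthetic-data generator that
reproduces the statistical structure the analysis assumes, so the whole
pipeline can be validated end to end against known ground truth.

## Stimulus model

A numerosity display is a set of *n* equal-sized dots confined to a circle
of radius 0.75 degrees of visual angle around fixation. Total dot surface
area is held constant across numerosities (`A_total`, default chosen so a
single dot has a 0.5 deg diameter), so mean display luminance never covaries
with dot count; the dot radius at numerosity *n* is therefore
`sqrt(A_total / (n * pi))` analytically. Dot centres are drawn by rejection
sampling, uniform in the disc shrunk by one dot radius (every disc lies
fully inside the field), with a minimum centre spacing of 2.2 dot radii to
spread the dots and avoid perceptual grouping. The source protocol does not
print dot sizes, luminances or the spacing rule, so all three are explicit,
configurable defaults. Infeasible packings raise an error after a bounded
number of restarts rather than ever returning an invariant-violating
display.

Each scanning run lasts 264 TRs of 1.4 s (369.6 s). Every TR contains an
adaptor display (300 ms), a 400 ms blank, a changing display (300 ms) and a
400 ms blank. The changing numerosity follows four identical 66-TR cycles:
1–7 ascending at 3 TRs each, 12 TRs of 20 dots, 7–1 descending, 12 TRs of
20 — so each of 1..7 appears in exactly 24 TRs per run. The adaptor defines
the condition: constant 1 (low), constant 20 (high), or a copy of the
changing schedule (changing; the control). Ten percent of displays are
white "oddballs" for the in-scanner attention task; they are flagged in the
sequence but excluded from all response predictors.

## Aggregate Fourier power

The monotonic response model's stimulus quantity is the aggregate Fourier
power of the display image. The image mean (DC) is removed and FFT
magnitudes are summed over all remaining spatial-frequency bins. The
default aggregation sums `|F|` ("amplitude"); summing `|F|^2` ("energy")
is a one-argument switch. The default is the amplitude sum for a
structural reason: by Parseval, the full-band energy sum equals
`N^2 * var(pixels)`, and at fixed total dot area the pixel histogram — and
hence the energy — is essentially independent of numerosity. The amplitude
sum instead grows as dots shrink and the spectrum broadens, and empirically
increases strictly with numerosity over {1..7, 20} at fixed area (Spearman
rho = 1 over display averages), which is the property the monotonic model
requires of its predictor. Rasterisation defaults: 64 px/deg over a 2 x 2
deg extent, background 0.5, black dots 0.0, white dots 1.0.

## Response models

**Monotonic**: the neural amplitude at each TR is `log(power(n))` of the
presented numerosity (or `log n` in the alternate mode; both modes run
through identical code paths). **Tuned**: the amplitude is a log-Gaussian
tuning curve `exp(-(ln n - p)^2 / (2 w^2))` with preferred log numerosity
`p` and log-space width `w`.

Neural series are boxcars at the TR; sub-TR (300 ms) event structure is not
modelled. Series are upsampled to a 0.1 s grid, convolved with a canonical
two-gamma HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1 s,
peak:undershoot 6:1, peak-normalised; any user kernel can be injected since
the original study's HRF is not printed), and sampled back at TR onsets.
Convolution is circular over the run: the run is four identical cycles and
acquisition starts at steady state, so the periodic response is the right
one, and a constant input maps to an exactly constant output.

Both the adaptor and the changing display are modelled. In the low/high
conditions the adaptor regressor is constant and is absorbed by the GLM
baseline (dropped, recorded in the design's attributes). In the changing
condition it is identical to the changing regressor; the two are summed
into one column of doubled amplitude to keep the GLM full rank. This
halves the fitted slope relative to a changing-only design — a documented,
tested property, not an artefact. The tuned model passes the adaptor
numerosities through the same tuning curve as the changing ones (the
symmetric treatment; which function the original fits used for the adaptor
is not stated, so this is injectable).

## Fitting, cross-validation, classification

The monotonic model is fit by OLS; the slope of the stimulus column is the
voxel's response amplitude per unit log predictor, and `R^2 = 1 -
SS_res/SS_tot`. The tuned model is fit by exhaustive grid search: preferred
log numerosities 0.007 to 5.491 in steps of 0.01, widths 0.03 to 3 in steps
of 0.0074, excluding candidates with `p > log(14) + 2w` (they only predict
responses to the 20-dot baseline). The stated ranges are not integer
multiples of the steps, so the lattice runs from the lower endpoints
(last values 5.487 and 2.9968). Per candidate, amplitude (clipped at zero —
responses may rescale but not invert) and baseline are solved in closed
form and the minimum-SSE candidate wins; ties resolve deterministically to
the lowest preference, then the lowest width. Because every candidate
prediction is a linear combination of the eight HRF-convolved
per-numerosity indicator series, the search reduces to 8-dimensional
quadratic forms and costs a few milliseconds per voxel after a one-off
precomputation per run sequence.

Response classes are assigned in the changing-adaptor condition.
Odd-numbered and even-numbered runs (1-based acquisition order) are
averaged separately; each model is fit on each half and scored on the
complementary half with a free non-negative amplitude rescale and a re-fit
baseline (halves can come from different sessions with arbitrary signal
scale; whether the original evaluation also re-fit the baseline is not
stated, so it is a switch). The model with lower summed cross-fold SSE
wins; exact ties go to the simpler monotonic model. Tuned winners whose
preferred numerosity exceeds 7 are re-labelled monotonic (tuned preferences
above the sampled range almost always reflect monotonic responses), and
tuned voxels explaining less than 0.2 of the changing-condition variance
are excluded from tuned-response analyses. The cross-validated R^2 is
`1 - (summed cross-fold SSE) / (summed cross-fold SS_tot)`; no formula is
printed in the source, so this definition is the package's.

Final per-condition parameters come from the average of all runs of that
condition (averaging runs first mirrors the high-SNR averaging of the
acquisition protocol).

## Adaptation metric and group statistics

Monotonic-class voxels enter slope analyses if (1) their preferred visual
field eccentricity is below 1 deg (strict), (2) their slope in the control
(changing-adaptor) condition is positive — "control condition" is read as
the changing-adaptor condition, which the source calls its control — and
(3) the changing-condition variance explained is at least 0.1 (the plain
within-condition R^2 by default; the cross-validated value is a switch).
Slopes are averaged, unweighted, per *map example* (one visual field map in
one hemisphere); examples with mean R^2 below 0.1 in both the low and high
conditions are flagged excluded, and examples with no selected voxels are
simply absent.

The adaptation effect per example is the proportional slope reduction
`(slope_low - slope_high) / slope_changing` — invariant to any global
response gain, hence comparable across maps; undefined (dropped, with a
warning) when the control slope is not positive.

Inference: per-map two-sided Wilcoxon signed-rank tests (exact null for
n <= 25 without ties, normal approximation with tie correction otherwise;
all-zero differences return p = 1 with a warning), Benjamini–Hochberg FDR
across the family of seven maps; a two-factor ANOVA (map + participant) on
the proportional reductions, with participant as an additive fixed blocking
factor (with one observation per map example the additive two-way model is
the standard equivalent of the random-blocks formulation), type-II sums of
squares for unbalanced tables, and Tukey HSD on participant-demeaned values
(approximating comparisons of map marginal means under the additive model);
and Pearson correlations between per-hemisphere metrics with an
Anderson–Darling normality screen on the regression residuals. Tuned-effect
summaries per hemisphere — the low-minus-high difference in tuned-model R^2
and the slope of the preference change against the control-condition
preference — are computed from tuned fits per condition and correlated with
the proportional reduction across hemispheres.

## Behavioural validation

A simulated observer compares a variable test numerosity against a 10-dot
reference after low (1-dot), high (20-dot) or no adaptation. Responses are
Bernoulli with `P(test judged more) = Phi((test - PSE)/sigma)`. Test levels
are chosen by a greedy minimum-expected-entropy staircase: a posterior over
a (PSE, sigma) lattice (41 x 13 points) is updated after each response and
the next level minimises the expected posterior entropy, concentrating
trials near the running PSE estimate; a fixed-grid mode exists as a
fallback. Unanswered trials are recorded and re-queued. The psychometric
function is fit by Bernoulli maximum likelihood over raw trials (default)
or least squares on binned proportions (the two agree closely at large
samples; both are tested). No lapse-rate parameter is modelled. Paired
t-tests between the three condition pairs, preceded by Shapiro–Wilk checks
on the paired differences, are Bonferroni-corrected (x3, clipped at 1).

## Synthetic ground truth

The generator draws 8 participants x 2 hemispheres x 7 maps
(V1..V3, hV4, LO1, LO2, V3A/B) x 8 voxels. Per-map true proportional
reductions rise linearly along that order, 0.2 at V1 to 0.8 at V3A/B by
default; condition gains are `g_changing = 1`, `g_low = 1 + r/2`,
`g_high = g_low - r`, so the planted reduction is exactly `r`. Raw response
amplitudes (base slopes ~1.0 falling to ~0.6 along the hierarchy, with 10%
voxel-wise jitter) are arbitrary but realistic scalings. A minority of
voxels in hV4/LO1/LO2/V3A/B (10–20%) are numerosity-tuned, with preferences
uniform in log over 1.5–6, widths 0.3–0.9, and a +/-0.1 log-unit preference
shift between the low and high conditions so the tuned-effect summaries are
exercised. Eccentricities are uniform over 0.05–1.4 deg and 5% of monotonic
voxels get negative slopes, so the selection criteria are genuinely
exercised. Each condition gets 3 runs (the 10-run acquisition variant is a
config change) of noiseless model prediction plus white Gaussian noise,
default SD 10% of the voxel's noiseless changing-condition signal SD;
AR(1) noise is an option, since real fMRI noise is autocorrelated in a way
white noise does not emulate. The behavioural generator draws per-subject
true PSEs around condition means 12/10/8 (low/none/high; the repulsive
pattern, effect 2 test-numerosity units) with 0.5 between-subject SD.

What passing these simulations does *not* show: the generator produces no
spatial structure on the cortical surface, no physiological or motion
artefacts, no session-to-session amplitude drift (which motivates the
rescaled cross-validation in the first place), and its tuned/monotonic
populations are cleanly separated by construction. Real-data performance
depends on those factors and is not certified by this suite.

## Problem sizes and numerics

Default validation sizes: 896 synthetic voxels (fit in ~15 s on one core
thanks to the basis reduction), 100 + 100 zero-noise voxels for parameter
recovery, 200 replicates for the behavioural power/type-I loops (100 in the
acceptance script), and 20 display draws per numerosity for the power
table. Grid-search SSE ties are declared within 1e-9 of the series' total
variance to absorb floating-point cancellation in degenerate (e.g.
constant) series. The psychometric sigma is bounded in [0.05, 50]; fits at
the lower bound are flagged as complete separation. The ANOVA returns
F = 0, p = 1 when there is no between-map variation at all (a 0/0 case).
All generators and fits are deterministic functions of their inputs and
seeds.
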