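# Methods

## Data model and time-grid conventions

Epoched EEG is a `trials × channels × times` float32 block in microvolts,
with per-trial condition labels and subject identifiers
(`core_data.EpochedData`). Sample `i` sits at `t0 + i·1000/sfreq` ms and all
intervals are half-open `[t_start, t_end)`; the packaged default sampling
rate is 512 Hz, so an epoch cropped to `[0, 1500)` ms holds exactly 768
samples and sample latencies print as e.g. 156.25 ms (sample 80) or
162.11 ms (sample 83, 2-dp rounding of 162.109375). The rate and the
half-open convention are package inferences chosen so that the sample count
and the printed peak latencies are mutually consistent; they are defaults,
not constraints, and any uniform grid is accepted.

Epochs persist as a directory containing a raw little-endian float32 array
(`data.f32`) and a JSON sidecar with shape, rate, time origin, labels,
subjects and channel names — language-neutral, bit-exact and diff-able.
Import adapters for EEGLAB/FIF/BrainVision exports are extension points, not
core; the package consumes already-preprocessed epochs and performs no
filtering, re-referencing, ICA or baseline correction.

## Channel layout and adjacency

The packaged 128-electrode layout (ABC convention, A1…D32) is built from
MNE's `biosemi128` standard montage with positions normalized to the unit
sphere; 2-D coordinates for topography exports use an azimuthal-equidistant
projection. Spatial adjacency is a distance-threshold graph on the 3-D
positions. For the packaged layout the frozen default threshold is 0.35
(unit-sphere chord), giving minimum degree 2 and mean degree 4.5. For other
layouts `build_adjacency` defaults to the smallest threshold that guarantees
every channel at least two neighbors, padded 5% (`auto_adjacency_max_dist`)
— the minimum-degree-2 property is what the cluster-forming rule requires.
The true study montage's manually curated neighborhood is not published;
this graph is a stand-in, and a custom graph can be supplied anywhere one is
accepted.

The conventional analysis accepts 10-20 electrode names (P8, PO7, …) and
resolves them to ABC labels by injective nearest-position matching against
MNE's 10-05 montage (`map_1020_to_abc`); the assignment is a positional
approximation of an unpublished manual mapping.

## Synthetic generator

`simulate.simulate_epochs` draws

    x(trial) = Σ_components gain(condition) · (1 + amplitude jitter) ·
               amplitude · topography ⊗ Gaussian(latency + latency jitter, width)
             + pink noise + white noise

with per-channel pink noise synthesized in the frequency domain (1/f
amplitude scaling, random phases, per-trace SD normalization), optional
neighbor mixing for spatial correlation, and trial-level Gaussian jitter on
latency (ms) and amplitude (fractional). Everything is deterministic given
the seed. `null_dataset` replaces every component's condition gains with
their mean, making labels exchangeable — the substrate for type-I-error
studies.

Presets (the generator's defaults are the study conditions, not tuning
knobs):

- `preset_n170()`: 3 conditions (face / blurred / scrambled) × 26 subjects ×
  60 trials, the packaged 128-channel layout, 0–1500 ms at 512 Hz. A
  posterior P100-like component at 100 ms (equal gains, +5 µV), a bilateral
  occipito-temporal N170-like component at 170 ms (−6 µV; gains face 1.0,
  scrambled 0.9, blurred 0.5 — blurred weakest, matching the ordering the
  analysis is meant to recover) and a late posterior component at 300 ms
  with face-specific gain (−3 µV; 1.0 / 0.2 / 0.2). Noise: pink SD 2 µV,
  white SD 1 µV — strong enough that single trials are visibly noisy but a
  classifier can still learn; gains and amplitudes are fixture parameters,
  not measured quantities.
- `preset_desk(effect)`: the fast variant — 8 subjects × 30 trials,
  32 synthetic cap channels (Fibonacci lattice on the upper hemisphere),
  0–500 ms (256 samples). `effect="strong"` implants a sharply
  face-selective N170 (−8 µV; gains 1.0 / 0.1 / 0.5) used by the end-to-end
  recovery tests; `"standard"` mirrors the study-scale gain ordering.
- `preset_null()`: 8 subjects, 16 channels, 64 samples, one equal-gain
  component — the exchangeable-null harness.

What the generator does **not** emulate: biophysical forward models (no
dipoles or leadfields — topographies are abstract weight maps), ocular or
muscular artifacts, inter-subject topography variability, autocorrelated
component dynamics, and overlapping stimulus trains. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it assumes
(localized condition-dependent components in spatially correlated noise),
not that it handles every pathology of recorded EEG.

## Classifier

Architecture (`classify.ModelSpec`): BatchNorm at the input → four
convolutional blocks (1-D convolution along time with channels as input
feature maps; ascending filter counts 16→128, kernel 50 samples, exact-erf
GELU, L2 on all kernels, max pooling) → BatchNorm → flatten → dense
128/64/32 with ReLU → softmax output sized to the number of conditions.
Convolution along time with 128 input maps is the only orientation
consistent with a 50-sample kernel on 768-sample epochs. The first conv
layer uses Glorot-normal initialization, the rest Glorot-uniform.

Decisions where the protocol is underdetermined: pool size defaults to 2
per block (768 → 48 samples before flatten — the largest power-of-two
schedule that fits four blocks), L2 coefficient 1e-4, Adam learning rate
1e-3, BatchNorm "at the end" placed after the conv stack and before
flattening. All are config fields. Early stopping monitors validation
*loss* (patience 50) while the kept checkpoint is the epoch with the best
validation *accuracy* — the two metrics differ deliberately, reproducing the
training recipe as specified. `ModelSpec.desk()` scales the kernel with the
epoch length (50·256/768 ≈ 17) and halves filter/dense widths so CPU
training takes minutes.

The network is implemented directly in numpy (im2col convolutions, exact
backward passes verified against finite differences, Adam, float32
throughout) because the package needs exact input gradients of the class
probabilities for attribution; checkpoints serialize to `.npz` plus a JSON
spec and round-trip bitwise.

Splitting: the hold-out test set is all trials of `holdout_subjects`
randomly chosen subjects plus a stratified sample from the remaining
subjects, topping up to `test_fraction` of trials; cross-validation folds
are stratified and shuffled. Test accuracy is reported as mean ± SD over the
fold models; the confusion matrix (row-normalized over true classes) comes
from the last fold's model.

## Attribution

`attribute.GradientExplainer` implements expected gradients: for each trial
`x` and class `c`, draw `(b, α)` pairs (background trial, uniform path
position), evaluate the input gradient of the softmax probability at
`b + α(x−b)`, multiply by `(x−b)` and average. Defaults: background = 100
trials sampled uniformly from the training set (seeded, recorded in
provenance), 200 path samples for pipeline runs, 2000 where oracle-grade
accuracy is needed. The linear-model closed form
`attr_i → w_i (x_i − mean_b b_i)` and the completeness identity
`Σ_i attr_i ≈ f_c(x) − E_b f_c(b)` are the correctness gates in the test
suite. Draws are shared across classes per trial (one forward pass, one
backward pass per class), and the estimate is bitwise deterministic given
(model, inputs, background, seed).

Aggregations: the importance matrix is mean-over-trials of
sum-over-classes of |attr| — the mean (rather than sum) keeps scales
comparable across dataset sizes; per-class curves are mean-over-trials of
sum-over-channels of |attr|. Whether curves should average over all trials
or only the class's own trials is ambiguous; both are implemented
(`trial_scope`), default `all_trials`.

## SHERPA distillation

Peaks are strict local maxima: sample `i` is a peak iff its value exceeds
every neighbor within `extremum_order` samples (default 10 ≈ 19.5 ms at
512 Hz); endpoints are never peaks and flat plateaus yield none —
neighbor-comparison implementations that emit plateau edges will diverge
here, by design. Peaks are ranked by value and truncated to `top_k_peaks`
(default 2). Each retained peak becomes a window of `window_length_ms`
(default 40 ms) with the peak as its exact center, clipped to the grid with
a flag when necessary; electrode scores are the mean (not sum) of the
importance matrix over the window's samples so reports are comparable across
window lengths; quantile sets collect channels at or above the empirical
0.75 and 0.9 quantiles of those scores (≥-threshold rule, so the 0.9 set is
nested in the 0.75 set, and degenerate all-equal scores include every
channel).

## Comparator analyses

**Dependent F.** At each (channel, time), the one-way repeated-measures F
`MS_condition / MS_(condition × subject)` with df `(k−1, (k−1)(n−1))` —
26 subjects × 3 conditions gives df (2, 50) and a cluster-forming critical
value of 3.1826 at α = 0.05. Where every condition mean is bitwise identical
the statistic is defined as exactly 0 (the subtraction-based sum-of-squares
decomposition would otherwise leave ~1e-17 rounding dust). Partial η² is
`SS_effect/(SS_effect+SS_error)`; no sphericity correction is applied
(uncorrected dfs are reported). Pairwise comparisons are paired t tests with
df n−1, defined as t = 0, p = 1 on bitwise-identical conditions.

**Clustering.** Samples above the F critical value are grouped by temporal
adjacency (t ± 1 within a channel) and spatial adjacency (neighboring
channels at the same t). A cluster is retained only if, at some time point,
it contains a channel together with at least `min_channel_neighbors − 1`
(default 1, i.e. two adjacent channels in total) of that channel's spatial
neighbors — our reading of a minimum-neighboring-channels rule of 2; an
isolated single-channel excursion never survives. Cluster mass is the sum of
member F values.

**Permutation scheme.** Condition labels are relabeled independently within
each subject — the exchangeability-preserving scheme for a within-subject
design. The null distribution records the maximum retained-cluster mass per
permutation (0 if none), and `p = (1 + #{null ≥ observed}) / (1 + B)`, which
includes the observed statistic and so guarantees validity; p can never fall
below `1/(B+1)` (0.002 at the default B = 500).

**Conventional analysis.** Mean amplitude per subject × condition over the
chosen electrodes and window (defaults: P8/P7, PO8/PO7, P10/P9 and
165–205 ms), then the same rmANOVA machinery plus all pairwise paired t
tests.

## Orchestration, seeds, determinism

`workbench.run_pipeline` chains all stages into a run directory (epochs,
fold checkpoints, evaluation report, attribution tensor, importance
matrix/curves, SHERPA report, cluster result, ANOVA result, cross-method
comparison table, structured log, provenance JSON with config hash and
per-stage seeds). A single global seed fans out through named substreams
(`derive_seed(seed, stage)` = SHA-256 of `"seed:stage"`, reduced below
2³¹), so stages are independently reproducible and two runs with the same
seed produce byte-identical reports. `export_figure_data` re-derives the
figure-ready CSV bundles (contour matrix, per-class curves, per-window
topography tables, grand-average ERPs of the quantile electrode sets) from a
run directory deterministically.

## Problem sizes used by the test suite

The suite exercises the pipeline at sizes a single CPU handles in minutes,
as the package's own test-design choice: end-to-end recovery uses
`preset_desk("strong")` with the scaled model, 12 training epochs (patience
4), 64 attribution path samples and 60 explained test trials, repeated over
three seeds and asserted on medians; permutation calibration uses 200
reduced-geometry null datasets × 200 permutations; attribution oracles use
2000 path samples. Full-scale defaults (200 epochs, patience 50, 500
permutations, 200 path samples) remain the library defaults.

## Known limitations

- The classifier and explainer run on CPU; study-scale training (26 × 180
  trials × 128 × 768) is possible but slow — the architecture is sized for
  correctness and desk-scale validation, not throughput.
- Expected gradients inherit SHAP's difficulty with strongly correlated
  features; importance can spread across correlated neighbors (mitigated
  here by reporting window/electrode aggregates rather than single samples).
- The adjacency graph and the 10-20 aliasing are positional stand-ins for
  unpublished manual curation.
- Importance scores are descriptive: the package deliberately performs no
  significance test on SHAP values; inferential claims come from the
  comparator analyses.
- The generator's simplifications (above) bound what the synthetic-recovery
  tests can certify about recorded EEG.
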