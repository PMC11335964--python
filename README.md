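# sherpa-eeg

SHAP-based ERP analysis (SHERPA) for epoched EEG.

Conventional event-related potential (ERP) analysis requires the researcher
to pick electrodes and latency windows up front, which biases the analysis
and can miss unexpected effects; fully data-driven alternatives such as
cluster-based permutation tests control family-wise error but produce
clusters whose spatiotemporal extent is hard to interpret. SHERPA takes a
third route: train a convolutional neural network to classify single trials
into the experimental conditions, explain the classifier with gradient-based
SHAP attributions, and distill those attributions into objective ERP
coordinates — the most important time windows and electrode sets per
condition, each with a quantitative importance score in the units of the
classifier's output probabilities.

The package is aimed at EEG researchers who have preprocessed, epoched data
(trials × channels × time samples with condition labels) and want an
assumption-light way to locate condition-discriminating components, plus the
two standard analyses to validate the result against.

## What it computes

1. **Classification** (`classify`): a 1-D CNN over the time axis —
   BatchNorm → 4×(Conv(kernel 50, GELU, L2) → MaxPool) → BatchNorm →
   flatten → dense 128/64/32 (ReLU) → softmax. Training uses Adam on
   categorical cross-entropy, batch size 64, up to 200 epochs with early
   stopping (patience 50 on validation loss), five-fold cross-validation
   with best-validation-accuracy checkpointing, and a hold-out test set that
   mixes fully held-out subjects with stratified trials from seen subjects.
   Implemented in numpy with exact input gradients.

2. **Attribution** (`attribute`): expected gradients, the gradient-explainer
   estimator of SHAP values. For trial `x` and class output `f_c`,

       attr_i = E[ ∂f_c/∂x_i (b + α(x−b)) · (x_i − b_i) ],
       b ~ background trials, α ~ U(0,1)

   Attributions are additive: summed over features they approximate
   `f_c(x) − E_b f_c(b)` (completeness). Absolute values are averaged over
   trials and summed over classes into a channels × times importance matrix,
   and summed over channels into per-class importance curves.

3. **SHERPA distillation** (`sherpa`): strict local maxima of each class
   curve (neighborhood half-width `extremum_order`), a 40-ms window centered
   exactly on each retained peak, mean importance per electrode inside the
   window, and the 0.75/0.9-quantile electrode sets.

4. **Comparators** (`comparators`): a spatiotemporal cluster-based
   permutation test using the dependent (repeated-measures) F statistic,
   sample threshold at the F(α=0.05) critical value, spatial+temporal
   adjacency clustering with a minimum-neighboring-channels rule, max-sum
   cluster mass, and within-subject Monte-Carlo relabeling (default 500
   permutations); and the conventional researcher-driven one-way rmANOVA on
   mean amplitudes (165–205 ms at P8/P7, PO8/PO7, P10/P9 by default, with
   positional 10-20 → BioSemi ABC aliasing) plus pairwise paired t tests.

5. **Synthetic data** (`simulate`): a seeded generator of epoched ERP data —
   Gaussian-timecourse components (posterior P100, occipito-temporal N170,
   late component) with per-condition gains, trial-level amplitude and
   latency jitter, and pink + white noise — so the full pipeline is testable
   without any recorded data. `preset_n170()` mirrors a 26-subject,
   60-trial, 128-channel, 0–1500 ms study; `preset_desk()` is a reduced
   32-channel version for CPU-scale runs.

## Worked example

```bash
sherpa-eeg run-all --preset desk --seed 1 --max-epochs 12 --out runs/demo
```

simulates the reduced preset (3 conditions × 8 subjects × 30 trials,
32 channels, 0–500 ms at 512 Hz, strong face-selective N170-like component
at 170 ms), trains the scaled CNN with five-fold cross-validation, explains
the test trials, and runs both comparators. From `runs/demo`:

- `evaluation.json` — per-fold validation accuracies
  `[0.991, 1.0, 1.0, 0.972, 0.991]`; test accuracy mean 0.983, SD 0.004
  (chance is 1/3).
- `sherpa_report.json` — per condition, e.g. for the face class: peaks at
  167.97 ms (summed importance 0.0234) and 296.88 ms (0.0121), windows
  147.97–187.97 ms and 276.88–316.88 ms, 0.9-quantile electrodes
  `E05 E06 E13 E14` for the early window — exactly the channels carrying
  the implanted occipito-temporal component.
- `comparison.json` — the cluster permutation test finds a significant
  cluster (min p = 0.002 at 500 permutations) overlapping the SHERPA
  electrode set (`E05 E06 E08 E13 E14 E19 E21 E26`), and the rmANOVA on the
  strongest window electrodes gives F(2,14) = 3073.9, p < 1e-18, partial
  η² = 0.998 — all three methods converge on the implanted effect.

The peak latencies land on the 512-Hz sample grid (sample period
1000/512 = 1.953125 ms); an importance peak at sample 80 prints as
156.25 ms and a 40-ms window centered there spans 136.25–176.25 ms.

Equivalent library calls: `simulate_epochs(preset_desk(), seed=...)` →
`split_data` → `train_crossval` → `GradientExplainer(...).shap_values` →
`sherpa_report`, and `cluster_permutation_test` / `conventional_analysis`
for the comparators.

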