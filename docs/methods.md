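# Methods

## Problem setting

TOAST subtyping assigns an acute ischemic stroke to one of five etiologic
classes (LAA, CE, SAO, OC, UND) from a wide panel of clinical features.
Registries of this kind are severely imbalanced — the majority class (LAA)
is roughly 56 % of patients while OC is about 3–4 % — and nearly complete
(≈ 0.5 % missing cells, from transcription slips rather than informative
censoring). The package treats subtyping as multiclass classification on a
cohort table and couples it with a one-shot active-adaptation cycle.

## Preprocessing

Feature importance comes from an XGBoost multiclass model (100 trees,
depth 6, learning rate 0.3, single thread, fixed seed) using **gain**
importance normalized to sum to 1; gain is the conventional ranking signal
and features the ensemble never splits on get exactly 0. Features with
importance ≤ 0.005 are dropped (the threshold is inclusive on the drop
side); survivors are sorted by descending importance with ties broken by
original column order, so the ranking is fully deterministic.

Missing cells are filled with the per-feature **mode computed on the
training split only** and applied to train and test alike. Estimating the
mode on the training partition rather than the pooled data is a deliberate
leakage-avoidance choice; with ≈ 0.5 % missingness the two estimates are
practically identical. Mode ties resolve to the smallest value, making
imputation deterministic and idempotent. Feature values are **never
scaled**: every cell of the ranked sequence equals a raw table value, which
keeps the sequence clinically readable and is asserted by a test invariant.

Whether importance should be fitted once on the full training partition or
refitted per cross-validation fold is genuinely open; `cross_validate`
refits everything (imputation and importance) inside each training fold,
the strictly leakage-free reading, while single-split workflows fit on the
training partition.

## Network

Input is the ranked sequence reshaped to one channel. All convolutions use
**causal padding**: the input is left-padded with `kernel − 1` zeros, so
output position *i* of a convolution with stride *s* depends only on input
positions ≤ *i·s*. Stacking preserves the property multiplicatively, and a
perturbation test over all four variants asserts it exactly.

Default hyperparameters: conv1 = 32 filters, kernel 4, stride 1;
conv2 = 24 filters, kernel 3, stride 2; max-pool window 2, stride 2; dense
head width 64; five outputs. Variant wiring after the shared first causal
convolution (ReLU throughout):

* **V1** conv1 → conv2
* **V2** conv1 → max-pool
* **V3** conv1 → concat(max-pool, conv2)
* **V4** conv1 → concat(max-pool, conv2, stride-2-down-sampled conv1)

The branches have unequal temporal lengths (pool ⌊L/2⌋ vs. causal stride-2
⌈L/2⌉); concatenation crops every branch to the shortest length, keeping
the earliest positions so the causal alignment is preserved. The head is a
**global average pool over time** followed by dense → ReLU → dense →
softmax. Global pooling (rather than flattening) is what makes the V4−V3
parameter difference exactly conv1-filters × head-width (32 × 64 = 2048
weights) and yields the count ordering V2 < V1 < V3 < V4
(2597 < 4413 < 6461 < 8509 at the defaults); V2 owns no second-convolution
weights at all.

The network is implemented in NumPy with hand-written backward passes for
every layer, verified against central-difference numerical gradients for
all four variants and all eight losses (max relative error ≈ 1e−6).
Weights use He-style initialization from the spec seed; the optimizer is
Adam at its conventional defaults (lr 1e−3, β₁ 0.9, β₂ 0.999). Training
defaults are 100 epochs, batch size 32, shuffled by a seeded generator;
`epochs=0` is an exact no-op, and identical seeds reproduce identical
weights bit-for-bit.

## Losses

The KL-focal objective is the per-sample sum of the focal term on the
true-class probability (scalar form, not a per-class sum) and the
divergence KL(P‖Q) taken **prediction-first**, averaged over the batch.
γ defaults to 2, the canonical focal setting. Because KL(P‖Q) is infinite
against a one-hot Q, Q is label-smoothed (default 0.05) and both
distributions are clipped at 1e−7 and renormalized; gradients treat the
clip as identity (straight-through), which keeps every loss and gradient
finite on degenerate one-hot inputs. The FL and KL terms are summed
unweighted; γ, the smoothing and the clip are all config-exposed. The
comparison menu (mae, mape, mse, msle, categorical cross-entropy, forward
KL(Q‖P), plain focal) consists of thin probability-space losses with
analytic gradients, present only for the harness.

## Uncertainty and the active cycle

Entropy uses natural logarithms (maximum ln 5 ≈ 1.609 at uniform); margin
is top-1 minus top-2 probability. The mixed criterion is implemented
literally as α·(p₁ log p₁) + (1−α)·(p₁−p₂), minimized, with α = 0.3; note
the first term is the top-class confidence-entropy contribution, not the
full entropy — substituting the full negative entropy is available as
`mixed_variant="entropy_full"` because the two readings differ and the
literal form is the primary one. Selection takes ⌊fraction·n⌋ samples
(floor, fraction default 0.5) with stable lowest-index tie-breaking.

The default query pool is the training partition itself: selected samples
are appended as duplicates, i.e. the cycle re-weights the hardest labeled
samples. This is the only reading under which per-class addition counts
can be reported against the original class distribution; a conventional
held-out pool (`pool_policy="holdout"`) is also provided. Fine-tuning
continues from the current weights with a fresh Adam state, defaulting to
the same epoch budget as initial training, and runs once
(`n_cycles = 1`).

## Evaluation

Predicted class is the row argmax (ties to the lowest class index).
Per-class precision/recall/F1 are aggregated **support-weighted**, the only
convention under which weighted recall is algebraically identical to
accuracy — an identity asserted exactly over 1000 random prediction
matrices. AUC is one-vs-rest, support-weighted by default with a macro
option. Cross-validation is stratified by default given the 3–5 % minority
classes, and refuses stratification when a class has fewer members than
folds, suggesting the non-stratified mode. Classes absent from a test fold
are excluded from averages with a warning.

## Synthetic cohort

The generator emulates the registry's shape, not its physiology. Labels
are drawn to match the class counts exactly. Informative continuous
features are unit-variance normals with per-class location offsets
`effect_size × N(0,1)` drawn once per feature; informative categorical
features (2–6 levels) get per-class logit perturbations of the same scale;
non-informative features are class-independent. Missingness is injected
completely at random at the configured rate (default 0.0047, i.e. 99.53 %
integrity). Defaults: 2,310 patients, counts 1290/107/550/81/282, 122
features, 30 informative, half categorical, `effect_size = 1.0` — chosen
as a clearly-learnable-but-noisy regime in which the held-out accuracy of
the default network sits well above the 0.56 majority share without
saturating.

What the generator does **not** model: covariance between clinical
features, informative missingness, label noise from inter-rater
disagreement, or the real features' marginal distributions. Passing tests
therefore demonstrate that the pipeline recovers planted class structure
under realistic imbalance and sparsity — not clinical-grade performance on
hospital data.

Percentage summaries round half-up, so counts 1290/107/550/81/282 print as
56/5/24/4/12 % and addition rates 545/47/400/49/159 over those bases print
as 42/44/73/60/56 %.

## Sizing of shipped checks

The end-to-end checks (acceptance tests and `scripts/acceptance.py`) train
with 30 epochs for both initial training and fine-tuning instead of the
100-epoch library default: on this cohort the loss curve is flat well
before epoch 30, and the reduced budget keeps a full five-seed paired
comparison to a few minutes on one CPU. All other defaults are the library
defaults.

## Known limitations

* The exact layer hyperparameters behind a specific published parameter
  count are not recoverable from defaults; the package fixes the variant
  topology and count ordering instead, with every width/kernel/stride
  config-overridable.
* Adam state does not persist across separate `train` calls; fine-tuning
  continues weights, not optimizer moments.
* The NumPy network is single-threaded and CPU-bound; it is sized for
  registry-scale tabular data (thousands of rows, ~100 features), not
  larger corpora.
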