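# toastnet

An interpretable classifier for the five TOAST etiologic subtypes of acute
ischemic stroke — large-artery atherosclerosis (LAA), cardioembolism (CE),
small-artery occlusion (SAO), other determined cause (OC) and undetermined
cause (UND) — built for clinical-ML researchers working with imbalanced
tabular registries.

## The model

A neurologist adjudicates a TOAST subtype sequentially: the most telling
findings first, then progressively less important ones, never revising an
early interpretation in light of a minor feature. `toastnet` encodes that
procedure directly:

1. **Importance-ranked sequences.** A gradient-boosted tree ensemble scores
   every feature; features with normalized importance ≤ 0.005 are dropped
   and the survivors are ordered most-important-first, turning each patient
   into a sequence *x*₀, *x*₁, …, *x*ₜ. Missing cells are filled with the
   per-feature training-set mode; values are never scaled.
2. **Causal convolution.** The network predicts
   *Y*ₜ = *f*(*x*₀, …, *x*ₜ) with left-padded (causal) convolutions, so the
   activation at rank *t* provably cannot depend on features ranked after
   *t*. Four variants (V1–V4) differ in what follows the first causal
   convolution — a second strided causal convolution, max pooling, or their
   channel-wise fusion; V4 additionally fuses the first convolution's own
   output and is the default.
3. **KL-focal loss.** Training minimizes
   FL(*p*) + KL(*P*‖*Q*), where FL(*p*) = −(1−*p*)^γ log *p* down-weights
   easy samples (γ = 2) and the divergence between the predicted
   distribution *P* and the label-smoothed target *Q* preserves predictive
   diversity during fine-tuning.
4. **Active model adaptation.** One TRAIN → QUERY → APPEND → FINETUNE
   cycle: every pool sample is scored by a mixed uncertainty criterion
   α·(*p*₁ log *p*₁) + (1−α)·(*p*₁−*p*₂) (α = 0.3; *p*₁, *p*₂ the top-2
   class probabilities), the most uncertain ⌊0.5·n⌋ samples are appended to
   the training set, and the model is fine-tuned from its current weights.

Because real TOAST registries are private, the package ships a synthetic
cohort generator reproducing the structure of a 2,310-patient registry:
subtype counts 1290/107/550/81/282 (56/5/24/4/12 %), 122 mixed
categorical/continuous features, and 99.53 % average data integrity.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
import toastnet as tn
from toastnet import preprocessing as prep
from toastnet.evaluation import fit_fold, compute_metrics
from toastnet.synthetic_cohort import CohortTable

cohort = tn.generate_cohort(tn.CohortSpec(seed=0))
counts, pct = tn.summarize_distribution(cohort)
print("cohort:", cohort.n_patients, "patients; subtype %:", pct.tolist())

idx = np.arange(cohort.n_patients)
tr, te = train_test_split(idx, test_size=0.2, stratify=cohort.labels, random_state=0)
t_train = CohortTable(cohort.data.iloc[tr].reset_index(drop=True), cohort.labels[tr], dict(cohort.kinds))
t_test = CohortTable(cohort.data.iloc[te].reset_index(drop=True), cohort.labels[te], dict(cohort.kinds))

factory = lambda L: tn.build_network(tn.NetworkSpec(variant="V4", sequence_length=L, seed=0))
model, before, seq_train = fit_fold(t_train, t_test, factory, tn.LossConfig(),
                                    epochs=30, batch_size=32, seed=0)
print(f"before cycle: accuracy {before.accuracy:.4f}  AUC {before.auc:.4f}  "
      f"macro-F1 {before.per_class['f1'].mean():.4f}")

cc = tn.CycleConfig(strategy="mixed", alpha=0.3, fraction=0.5, finetune_epochs=30, seed=0)
model, _, _, report = tn.run_active_cycle(seq_train.values, t_train.labels, model, cc)
rec = report.cycles[0]
print(f"appended {rec.size_after - rec.size_before} samples; per-class additions "
      f"{rec.class_counts.tolist()} (+{rec.rates_pct.tolist()} %)")

seq_test = prep.to_sequence(prep.impute_mode(t_train, [t_test])[1], seq_train.ordering)
after = compute_metrics(t_test.labels, tn.predict_proba(model, seq_test.values))
print(f"after cycle:  accuracy {after.accuracy:.4f}  AUC {after.auc:.4f}  "
      f"macro-F1 {after.per_class['f1'].mean():.4f}")
```

Output:

```
cohort: 2310 patients; subtype %: [56, 5, 24, 4, 12]
before cycle: accuracy 0.8810  AUC 0.9762  macro-F1 0.6820
appended 924 samples; per-class additions [400, 82, 192, 65, 185] (+[39, 96, 44, 100, 82] %)
after cycle:  accuracy 0.9004  AUC 0.9848  macro-F1 0.8215
```

The query criterion preferentially duplicates hard minority-class samples
(note the +96 % / +100 % additions for CE and OC versus +39 % for the
majority LAA), which is what lifts the macro-F1 from 0.68 to 0.82 while
overall accuracy moves only modestly — the cycle mostly repairs the rare
subtypes.

A command-line surface wraps the same pipeline:

```sh
toastnet generate --seed 0 --out-dir out          # cohort.csv
toastnet preprocess out/cohort.csv --out-dir out  # ranked.csv + importance.csv
toastnet train out/ranked.csv --out-dir out       # model.npz
toastnet active out/ranked.csv out/model.npz --out-dir out
toastnet evaluate out/ranked.csv out/model_finetuned.npz --out-dir out
toastnet compare --config grid.yaml --out-dir out # variants x losses x strategies
```

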