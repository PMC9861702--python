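# synmoe

Joint prediction of drug-combination **synergy** and **adverse drug–drug
interactions (DDI)** with a multi-gate mixture-of-experts network, plus the
full protocol around it: synthetic cohort generation, order-augmented
training with early stopping, five-fold cross-validation, ablation
variants, a metric suite, and post-hoc candidate screening.

## Who this is for

Computational drug-discovery researchers who want to study multi-task
synergy prediction end to end at desk scale: how soft parameter sharing
behaves across five synergy scores (Loewe, Bliss, ZIP, HSA, S) and two
classification targets, how task-specific gating avoids the multi-task
"seesaw effect", and how multi-score consistency turns raw predictions
into credible candidate lists.

## The model

For a drug pair (x, y) with descriptor vectors d_x, d_y and a cell line
with expression profile c_r, M expert subnetworks (three families: dense
on [d_x, d_y, c_r]; bi-additive, Tower_x([d_x, c_r]) + Tower_y([d_y, c_r]);
bi-interaction, Layer_add(a+b) + Layer_prod(a⊙b) over the tower outputs
a, b) each produce a d-dimensional latent I_num. Every task k owns a gating
network with softmax weights W_k over the experts, a fused representation

    O_k = Σ_num  W_k[num] · I_num ,

and a prediction tower. The objective is

    L = Σ_reg 1·MSE + Σ_cls 10·SCE(ε) ,

where SCE is label-smoothing cross-entropy: weight (1−ε) on the true class
and ε on the other. Training augments every pair in both drug orders,
stops early on validation loss (patience 100), and averages both orders at
prediction time, so predictions are exactly symmetric under drug swap.
Everything runs on an in-repo float64 reverse-mode autodiff core that is
gradient-checked against finite differences.

See `docs/methods.md` for the full model description, the synthetic-data
generator's assumptions, and the design decisions.

## Worked example

```python
import numpy as np
from synmoe import (SimConfig, generate_dataset, ModelConfig, TrainConfig,
                    train_model, make_folds, evaluate_model, predictions_frame,
                    screen_candidates, ScreenRule)

sim = SimConfig(n_samples=2000, replicate_prob=0.0, seed=11,
                noise_sd={t: 1.0 for t in ("loewe", "bliss", "zip", "hsa", "s")})
dataset = generate_dataset(sim)
print(f"cohort: {len(dataset)} combinations, "
      f"{np.mean([s.synergy_label for s in dataset.samples]):.3f} synergy-positive")

folds = make_folds(len(dataset), k=5, seed=11)
train_idx, val_idx, test_idx = folds.roles(0)
model, history = train_model(dataset, ModelConfig.reduced(seed=11),
                             TrainConfig(max_epochs=200, learning_rate=1e-3, seed=11),
                             (train_idx, val_idx))
report = evaluate_model(model, dataset, test_idx)
print(f"held-out Loewe: RMSE {report.per_task['loewe']['rmse']:.2f}, "
      f"Spearman {report.per_task['loewe']['spearman']:.2f}, "
      f"R2 {report.per_task['loewe']['r2']:.2f}")
print(f"synergy AUROC {report.per_task['synergy']['auroc']:.2f}, "
      f"DDI AUROC {report.per_task['ddi']['auroc']:.2f}")

preds = predictions_frame(model, [dataset.samples[i] for i in test_idx], dataset.store)
kept = screen_candidates(preds, [ScreenRule("prob_threshold", threshold=0.9),
                                 ScreenRule("ddi_exclude", threshold=0.5)])
print(f"screening: kept {len(kept)} of {len(preds)} test combinations "
      f"(median support {int(kept['support'].median())})")
```

Output (a few minutes on one CPU):

```
cohort: 2000 combinations, 0.062 synergy-positive
held-out Loewe: RMSE 1.70, Spearman 0.98, R2 0.95
synergy AUROC 0.91, DDI AUROC 0.97
screening: kept 3 of 400 test combinations (median support 5)
```

Reading it: the cohort reproduces the ~1:15 synergy class imbalance; the
reduced model recovers the synthetic Loewe surface almost perfectly on
held-out combinations (RMSE 1.70 against a score s.d. near 9); ranking
quality carries over to the synergy call (AUROC 0.91) and the chemistry-
driven DDI label is nearly solved (AUROC 0.97). The screen keeps only test
combinations with confident synergy probability and low predicted
interaction risk — each survivor has all five predicted scores above 5
(support 5), the multi-score consistency that marks a credible candidate.

## Command line

```bash
synmoe simulate --out-dir cohort/ --seed 7          # tables + truth sidecar
synmoe train    --data-dir cohort/ --config run.yaml --checkpoint model.npz
synmoe cv       --data-dir cohort/ --folds 5 --out cv.json
synmoe ablate   --data-dir cohort/ --variant BIE --out bie.json
synmoe predict  --checkpoint model.npz --data-dir cohort/ --out preds.csv
synmoe evaluate --checkpoint model.npz --data-dir cohort/ --out metrics.json
synmoe screen   --predictions preds.csv --rules rules.yaml --out candidates.csv
```

Ablation presets cover the task-transfer grid (`onlyDDS`, `Loewe`,
`removeLoewe`, `REG`, `DDI`, `full`, `onegate`) and the expert grid under a
fixed budget of six experts (`DCE`, `BAE`, `BIE`, `DCE+BAE`, …, `all`).

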