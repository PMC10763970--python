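# selfstack

Ensemble classifiers for **imbalanced multi-class clinical tabular data**,
built around the *self-stacking classifier* (SSC): a stacked ensemble whose
base learners and meta-learner are all random forests, differing only in
their random seeds. The package targets thyroid-disease screening tables in
the UCI `thyroid0387` dialect — 9 000+ patient records with serum hormone
measurements (TSH, T3, TT4, T4U, FTI, TBG), t/f clinical flags and
single-letter diagnosis codes, where the healthy class outnumbers each
disease class roughly 20:1 — but works on any schema of the same shape. It
is intended for ML practitioners and biostatisticians studying how class
balancing and homogeneous ensembling interact on such cohorts.

## The method

Given a training set *T* = {(xᵢ, yᵢ)} with classes *C*:

1. **Down-sampling.** Classes with at least 200 records are retained; each
   is cut to its *first* 230 records in file order, yielding a perfectly
   balanced cohort (5 × 230 on the thyroid table).
2. **Self-stacking.** *m* = 4 random forests (200 trees, depth ≤ 50, seeds
   `s+0 … s+3`) are each trained through *k*-fold cross-validation (*k* = 5);
   the out-of-fold predictions form the meta-feature matrix
   *T*ₛ = {(RF₁(xᵢ), …, RF₄(xᵢ)), yᵢ}, so no row is ever predicted by a
   model that saw it. A fifth forest — the meta-learner — is fit on *T*ₛ
   (labels one-hot encoded), and the base forests are refit on all of *T*
   for inference:
   `SSC(x) = RF_meta(RF₁(x), …, RF₄(x))`.
3. **Self-voting baselines.** Three same-spec forests combined by majority
   label (hard) or summed class probabilities (soft), ties to the lowest
   class index.
4. **Evaluation.** Accuracy plus *macro* precision/recall/F1 from a
   one-vs-rest reduction of the confusion matrix (macro averaging weights
   every class equally — the right choice under imbalance), 10-fold
   cross-validation (mean ± sample SD), and paired t-tests between models'
   evaluation-score vectors (8 paired scores across the two data settings,
   df = 7).

A seeded synthetic-cohort generator reproduces the thyroid table's class
skew, feature mix and `?` missingness so the entire pipeline is testable
without downloading anything.

## Worked example

```python
from selfstack import (GeneratorConfig, StackConfig, balance_cohort,
                       class_counts, encode_features, fit_self_stack,
                       generate_cohort, metric_report, split_train_test)

cohort = generate_cohort(GeneratorConfig(seed=7, effect_size=2.0))
print(cohort.n, class_counts(cohort))
# 8145 {'-': 6771, 'K': 436, 'G': 359, 'I': 346, 'F': 233}

balanced, plan = balance_cohort(cohort)          # floor 200, keep first 230
print(balanced.n, plan.selected_classes)
# 1150 ['-', 'K', 'G', 'I', 'F']

split = split_train_test(encode_features(balanced), ratio=0.2, seed=7)
stack = fit_self_stack(split.train, StackConfig(master_seed=7))
report = metric_report(split.test.y, stack.predict(split.test.X),
                       split.train.class_map)
print(report.to_markdown())
```

prints

```
| Class | Precision | Recall | F1 | Support |
|---|---|---|---|---|
| - | 0.95 | 1.00 | 0.98 | 42 |
| F | 0.98 | 1.00 | 0.99 | 49 |
| G | 0.98 | 0.98 | 0.98 | 42 |
| I | 1.00 | 1.00 | 1.00 | 49 |
| K | 0.98 | 0.92 | 0.95 | 48 |
| Macro average | 0.98 | 0.98 | 0.98 | |

Accuracy: 0.978
```

i.e. on this synthetic cohort (class signal `effect_size=2.0`) the SSC
classifies 97.8 % of the 230 held-out patients correctly, and every class —
including the rarest — reaches ≥ 0.92 precision and recall; with real
hormone profiles the same pipeline applies unchanged via
`read_thyroid_table`.

## Command line

```bash
selfstack simulate --preset thyroid-skew --seed 7 --out synth.csv
selfstack balance  --in synth.csv --min-class-size 200 --per-class 230 \
                   --out balanced.csv --plan plan.json
selfstack split    --in balanced.csv --ratio 0.2 --train-out tr.csv --test-out te.csv
selfstack train    --model ssc --train tr.csv --out model.bin
selfstack evaluate --model model.bin --test te.csv --report report.json
selfstack compare  --reports report.json other.json
selfstack run      --config experiment.yaml     # full protocol, report bundle
```

`selfstack ingest --in thyroid0387.data --out cohort.csv` normalizes the raw
UCI file (diagnosis suffix stripping, code validation) when you have it.

## Layout

| Module | Role |
|---|---|
| `selfstack.data_io` | schema, reader/writer, diagnosis parsing, encoding, 80:20 split |
| `selfstack.balancing` | class selection and keep-first-N down-sampling |
| `selfstack.ensembles` | base-learner specs, SSC, hard/soft self-voting |
| `selfstack.evaluation` | confusion matrix, macro metrics, k-fold CV, paired t-test |
| `selfstack.synthetic` | seeded imbalanced cohort generator |
| `selfstack.workflow` / `selfstack.cli` | experiment orchestration and the `selfstack` command |

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
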