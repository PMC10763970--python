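# Methods

## Problem setting

Thyroid screening tables pair serum hormone measurements (TSH, T3, TT4,
T4U, FTI, TBG) and binary clinical flags with a single-letter diagnosis
code per patient; the healthy class (`-`) dwarfs every disease class. Two
pathologies follow: classifiers trained on the raw distribution learn the
majority class at the minority classes' expense, and support-weighted
metrics hide that failure. The package addresses the first with
down-sampling and the second with macro-averaged one-vs-rest metrics.

## Data model and encoding

A `FeatureSchema` types every column as binary, continuous, categorical,
identifier or target. The raw `thyroid0387` dialect stores the diagnosis
as `"<codes>|<record id>"`; the reader strips the suffix and decomposes
compound code strings per character. Records whose diagnosis holds more
than one code are excluded from modelling cohorts (the task is single-label
multi-class); they are counted and logged, never silently dropped.

The source data does not come with a prescribed preprocessing recipe, so
the encoder makes the minimal deterministic choices and records them:
t/f (and F/M sex) flags map to 1/0; `referral_source` is integer-coded in
first-appearance order; missing continuous values take the column median
and missing binary/categorical values the column mode, both learned on the
fitting cohort and re-applied verbatim to any later cohort so train and
test matrices stay aligned; `patient_id` is dropped; `*_measured`
indicator flags are dropped only when constant. The heavily missing TBG
column is retained and imputed like any other continuous column; a
configurable drop list exists for users who prefer to remove it. Class
codes are indexed in sorted order (`-` sorts before the letters), making
the class map reproducible across runs.

The 80:20 train/test split holds out `round(0.2·n)` rows — 230 of the
1150-row balanced cohort. With shuffling, a generator seeded explicitly
permutes rows before cutting; without, the file tail is the test set.
The split is deliberately not stratified, so per-class test counts vary
with the seed, matching the evaluation protocol it implements.

## Balancing

`select_classes` keeps classes with at least `min_class_size` (default
200) records; on the thyroid counts that is exactly {`-`, K, G, I, F}.
`downsample_first_n` then keeps each class's first `per_class_n`
(default 230) records *in file order* — "first" is read as file order
because it is the only deterministic reading; no shuffling or
deduplication precedes the cut. A class shorter than the cut is an error
by default (`allow_short` opts into keep-all with a logged warning).

## Self-stacking classifier

`m` = 4 base random forests differ only in seeds derived from the master
seed (`master_seed + j`); no other perturbation is applied because
forest randomization is the intended source of diversity. Meta-features
are built by k-fold cross-validation (k = 5 by default; the architecture
only requires "k-fold", and 5 is standard stacked-generalization
practice): for each fold, a fresh base learner is fit on the complement
and predicts the held-out rows, so row *i*'s meta-features come from
models that never saw row *i*. In the default **label** mode each base
learner contributes its predicted class, one-hot encoded before reaching
the meta-learner so that no ordinal structure over class indices is
invented; **proba** mode passes the C-vector of class probabilities
instead (classes absent from a fold's training part get probability 0).
The meta-learner (another forest, seed `master_seed + m`) is fit on the
meta-features; the base learners are then refit on the full training set
for inference — the standard stacked-generalization convention for
inference-time base models. Prediction replays the exact training-time
encoding.

Degenerate cases are defined, not left to chance: single-class training
data is an error; an empty prediction input returns an empty label
vector; a feature-width mismatch is an error.

## Self-voting ensembles

Three same-spec forests (seeds `master_seed + j`) are combined at
prediction time: hard voting takes the modal label, soft voting the
argmax of summed probability vectors (equivalently the mean — positive
scaling does not move an argmax). Votes are computed from the fitted
members at prediction time; nothing is tallied during training. All ties
— hard, soft, and inside the meta-learner's one-hot argmax — break to the
lowest class index, which keeps every ensemble a pure function of its
inputs.

## Evaluation protocol

Per-class precision, recall and F1 come from one-vs-rest reduction of the
C×C confusion matrix; every 0/0 is defined as 0 (a class never predicted
and never present scores zero rather than propagating NaN). Macro scores
are unweighted class means; accuracy is the trace over the total. k-fold
cross-validation (default k = 10) uses a seeded shuffled partition, scores
each fold with a freshly built model, and reports the mean and the sample
(n−1) standard deviation; wall time is recorded for the manifest but never
asserted anywhere, being hardware-dependent.

Model comparison uses a paired two-sided t-test, t = mean(d)/(sd(d)/√n),
df = n−1. The pairing is over each model's evaluation-score vector:
accuracy plus the three macro metrics, under the original and the
down-sampled settings — eight paired observations, hence df = 7. This is
the one construction consistent with that df; an independent two-sample
variant is not provided. Identical score vectors give t = 0; a non-zero
constant difference has zero variance and is reported as an infinite t
with p = 0. Statistical power is deliberately out of scope: the package
computes test statistics and p-values only.

Printed tables round half-up at 2 decimals (3 where finer precision is
meaningful); rounding happens only in the Markdown layer, never in stored
JSON, so every printed number is recomputable from the machine report.

## Synthetic cohorts

The generator emulates what matters for exercising the pipeline: the
published class skew (`{F: 233, I: 346, G: 359, K: 436, -: 6771}` by
default), a hormone-like block of strictly positive continuous features
(exponentiated Gaussians, so medians and skew resemble serum assays),
t/f flag features, an uninformative referral-source category, and `?`
missingness at 5 % of continuous entries. Class signal is controlled by
exactly two dials: `effect_size` shifts each class's Gaussian means by a
fixed ±1/0 signature matrix (pinned under its own constant seed so all
cohort seeds share one class geometry), and `flip_rate` skews the flag
probabilities away from ½ by a ±1 signature. At zero both, labels are
independent of features and any classifier sits at the majority-class
proportion — the property the chance-level tests assert. The default
`effect_size` of 1.0 yields a moderately hard problem (forest accuracy
well above chance, below ceiling); the `separable` preset (effect 4.0,
flip 0.4, 230 rows per class × 5 classes) mirrors the balanced working
size and is the reference input for the ≥ 0.95 accuracy checks.

What the generator does **not** emulate: the real table's covariance
structure between hormones, its age distribution, its missingness
mechanism (real `?` entries are informative, mirrored by the `*_measured`
flags), or its label noise. Passing tests therefore demonstrate that the
machinery is correct and that the ensembles behave as designed under
controlled signal, not that real-data scores will match.

## Problem sizes

The test suite and the acceptance script run at the balanced working size
(1150 rows, 5 × 230) for the headline checks and smaller cohorts (40–60
rows per class, 15–30-tree forests) for mechanism tests, sizes at which
results are already stable across seeds.

## Known limitations

- Heterogeneous stacking (mixing model families) is not exposed, although
  the stacking machinery itself would trivially allow it.
- Probabilities are not calibrated; soft voting sums raw forest estimates.
- The GBM default `max_depth = 200` is kept as tuned even though such
  trees saturate long before that depth; it is effectively "unlimited".
- `LogisticRegression` in current scikit-learn no longer accepts
  `multi_class`; the option is accepted in a spec dict and dropped, since
  the saga solver is multinomial natively.
- Experiment reports are byte-reproducible given a config; timing lives
  only in the manifest for that reason.
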