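# advbeat

Inter-patient ECG heartbeat classification with a subject-adversarial
convolutional neural network.

## The problem

Automatic heartbeat classifiers are only clinically useful if they work
on *patients they have never seen*. Under the inter-patient evaluation
protocol, training beats (the DS1 half of the MIT-BIH arrhythmia
database) and test beats (DS2) come from disjoint patients, and the
dominant failure mode is that a network learns subject-specific
morphology instead of class-specific physiology: with only 22 training
patients, "who the beat came from" is an easy shortcut for "what kind of
beat it is".

`advbeat` attacks this directly. Given training triplets (X, y, s) —
the beat tensor, its AAMI class label y ∈ {N, S, V, F, Q}, and the
subject ID s ∈ {1, …, S} treated as a nuisance variable — a
convolutional encoder f(X̃; θₑ) is trained jointly with a class
classifier q_θc(y|h) and a subject adversary q_θa(s|h) under the
min–max objective

    min_{θe,θc} max_{θa}  L = L_c − λ·L_a,

where L_c and L_a are the classifier and adversary cross-entropies and
λ > 0 trades class discrimination against subject invariance. The saddle
point is found in a single loop with a gradient-reversal layer: the
adversary head descends L_a, while its gradient into the shared encoder
is sign-flipped and scaled by λ. At λ = 0 the model reduces exactly to
an ordinary CNN classifier.

## What's in the box

* **`advbeat.mitdb`** — WFDB record/annotation ingestion, the beat-symbol
  → AAMI class mapping, and the de Chazal DS1/DS2 inter-patient split
  (22 + 22 records; the four paced records 102/104/107/217 excluded).
* **`advbeat.preprocess`** — beat segmentation (the half-open window
  from 50 samples after the previous R peak to 100 samples after the
  current one, so window length = RR + 50), linear resampling to 128
  samples, per-beat baseline removal, and the two rhythm features:
  pre-RR ratio (current pre-RR over the record mean) and near-pre-RR
  ratio (over the mean of the previous ten). Beat + replicated ratios
  form the 3×128×2 network input (768 scalars).
* **`advbeat.model`** — the encoder (7 convolution layers: a 3×3 stem
  plus three residual blocks with dilated second convolutions and
  average-pooling shortcuts; a channel+temporal attention module after
  each block; global average pooling to 64 features) and the two affine
  softmax heads. Implemented on `advbeat.nn`, a compact NumPy
  reverse-mode autodiff core validated against central differences.
* **`advbeat.training`** — the adversarial objective, gradient-reversal
  (or alternating) updates, Adam with the validation-loss schedule
  (LR 1e-3 → 1e-4 after 10 stale epochs, stop after 20, best-validation
  checkpoint), and a logistic-regression subject probe that measures how
  identifiable subjects remain in any representation.
* **`advbeat.evaluation`** — confusion matrices, per-class Sen/Pre/F1,
  overall accuracy, the pathological-class summary
  pat_F1 = (F1_S + F1_V)/2, and record-level report tables.
* **`advbeat.synthetic`** — a Gaussian-bump ECG generator producing
  multi-subject, multi-class annotated records with a controllable
  subject confound, so the whole pipeline (including the invariance
  claim) is testable without any download.

## Worked example

```python
from advbeat import generate_cohort, TrainConfig, train
from advbeat import confusion, per_class_metrics
from advbeat.training import evaluate_invariance_probe

# 8 synthetic subjects, 300 beats each; the last 4 subjects are held out
cohort = generate_cohort(n_subjects=8, beats_per_subject=300, seed=2)
model, history = train(
    (cohort.train_x, cohort.train_y, cohort.train_s),
    TrainConfig(lambda_adv=0.005, max_epochs=15, seed=2),
)
rep = per_class_metrics(confusion(cohort.test_y, model.predict(cohort.test_x)))
probe = evaluate_invariance_probe(model.encode(cohort.test_x),
                                  cohort.test_subject, seed=2)
print(f"held-out acc {100*rep.accuracy:.1f}%  pat_F1 {100*rep.pat_f1:.1f}%  "
      f"subject probe {100*probe:.1f}%")
```

This prints

```
held-out acc 96.8%  pat_F1 85.6%  subject probe 54.8%
```

meaning: on the four never-seen subjects the model classifies 96.8% of
beats correctly, the mean F1 over the two pathological classes (S, V) is
85.6%, and a fresh probe can still recover the test subject's identity
from the learned features 54.8% of the time (chance 25%; on raw inputs
the same probe reaches ~84%, so the encoder has discarded most — not
all — subject information). Training the same cohort at λ = 0 leaves
the probe at ~61%: the adversary measurably strips subject identity.

A shell workflow over WFDB files mirrors this:

```sh
advbeat simulate   --out-dir data --n-subjects 8 --beats 300 --seed 2
advbeat preprocess --data-dir data --out-dir cache
advbeat train      --cache-dir cache --out-dir run
advbeat evaluate   --cache-dir cache --checkpoint run/checkpoint.npz \
                   --out-dir eval --split DS1
advbeat sweep-lambda --out sweep.csv --seed 2
```

`preprocess` also accepts a local copy of the MIT-BIH arrhythmia
database (WFDB `.hea`/`.dat`/`.atr` files) and then uses the DS1/DS2
split manifest automatically.

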