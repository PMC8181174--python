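# Methods

## Data model and preprocessing

A record is a two-lead ECG sampled at 360 Hz with R-peak annotations
carrying one-character beat symbols. Symbols are grouped into the five
AAMI superclasses — {N,L,R,e,j}→N, {A,a,J,S}→S, {V,E}→V, {F}→F, {Q}→Q —
and any other symbol (rhythm marks, noise marks, paced beats, artefact
codes) is excluded entirely; this exclusion rule is the only one under
which the published per-symbol and per-class totals of the DS1/DS2
distribution are mutually consistent. The inter-patient split fixes DS2
as the 22 published test records, excludes the four paced records
(102, 104, 107, 217, identifiable by their `/` beats), and defines DS1
as the 22-record complement. Training subject IDs 1..22 are assigned in
sorted-record order; records 201/202 share a patient, but 202 sits in
DS2, so one ID per DS1 record is collision-free.

Segmentation takes, for each beat after the first, the half-open sample
window [prev_R + 50, cur_R + 100), giving the exact identity
L = RR + 50; anchoring the start to the *previous* R peak keeps the full
P-QRS-T complex in view as the heart rate changes. Windows that overrun
the record end are completed by edge replication (so test-set beat
counts track annotation counts); a window starting past the end is
skipped with a warning. Each channel is resampled to 128 points by
linear interpolation — exact on affine signals, the identity at L = 128 —
and each beat/channel is centred by subtracting its own scalar mean.
"Subtracting the average of the heartbeat segments" could also be read
as removing a cross-beat mean template; that would erase class-shared
morphology rather than baseline offsets, so the per-beat scalar mean is
the default and the template variant sits behind
`remove_baseline(mode="template")`.

Rhythm enters through two unitless ratios of the current pre-RR
interval: to the record-wide mean pre-RR (removing the subject's basal
rate — deliberately non-causal, as the whole recording is available in
this setting) and to the mean of the previous min(10, available) pre-RR
intervals (tracking slow drift). With no prior interval the ratio
defaults to 1.0, though segmentation already drops that beat. Both are
invariant to uniform time rescaling. The network input stacks the
128×2 beat with each ratio replicated into a 128×2 row: 3×128×2, 768
scalars. No amplitude normalisation beyond baseline removal is applied,
and no filtering or R-peak detection: annotations are trusted.

## Architecture

The encoder's stem is a 3×3 valid convolution over the 3-row input,
which collapses the row axis (3→1); since the kernel always spans all
three rows, it is implemented as a width-3 one-dimensional convolution
over 6 interleaved (row, lead) channels. Three residual blocks follow
(16, 64, 64 filters; blocks 2–3 open with stride 2), each block being
conv → BN → ReLU → dilated conv (rate 3) → BN, with the shortcut added
before the block's final ReLU. "Same" padding uses ceiling-division
output lengths, which stride 2 forces (126 → 63 → 32). Downsampling
shortcuts are average pooling (kernel 2, stride 2, ceil); new channels
are zero-padded. That yields 7 main-path convolutions and feature maps
1×126×16 → 1×126×16 → 1×63×64 → 1×32×64, then global average pooling to
h ∈ R⁶⁴.

After each block sits a spatiotemporal attention module (3 total):
channel attention first (average- and max-pooled channel descriptors
through a shared two-layer bottleneck, reduction 8, summed and passed
through a sigmoid), then temporal attention (channel-wise mean and max
maps convolved with a width-7 kernel into a sigmoid gate). Both gates
multiply the feature map elementwise, weights strictly in (0, 1).
Where the residual addition meets batch normalisation is an
interpretation: BN is applied per convolution, and the addition precedes
only the block's closing ReLU.

Both heads are single affine layers with softmax: C = 5 classes and
S = number of training subjects. Initialisation is He-uniform for
weights and zero for biases, drawn from one seeded generator so two
builds from the same seed are bit-identical.

The network, including the reverse-mode differentiation it trains
under, is implemented directly on NumPy (`advbeat.nn`) in float64; every
operator's gradient is tested against central differences, and the
convolution forward pass against an independent `scipy.signal`
cross-correlation oracle.

## Training

The joint objective L = L_c − λ·L_a is optimised as a single-loop
gradient-reversal update: one Adam step per batch in which θc receives
∂L_c/∂θc, θa receives ∂L_a/∂θa (unscaled — an equivalent game with a
better-conditioned adversary; λ applies only on the encoder-bound
path), and θe receives ∂L_c/∂θe − λ·∂L_a/∂θe. This matches the
simultaneous reading of the min–max objective and is deterministic and
unit-testable; a two-phase alternating update is available via
`TrainConfig(update_scheme="alternating")`. Defaults: λ = 0.005, Adam
at 1e-3, batch 128, 20% of beats held out for validation at beat level
(record-level holdout would also be defensible; beat level is the
default reading of "randomly chosen"). When validation L_c — the
scheduling signal, which is also how "best-performing model" is
interpreted — fails to reach a new minimum for 10 consecutive epochs the
learning rate drops once to 1e-4; after 20 such epochs training stops
and the best-validation parameters are restored. No class rebalancing
or augmentation is applied. All randomness (split, init, shuffling)
derives from the single config seed; runs are bit-reproducible.

Subject identifiability is measured by `evaluate_invariance_probe`: a
fresh multinomial logistic-regression probe (scikit-learn) fitted on
half the beats of a representation and scored on the other half.

## The synthetic cohort

Beats are sums of five Gaussian bumps (P, Q, R, S, T; base amplitudes
0.15/−0.10/1.00/−0.15/0.30 mV, widths 25/10/12/10/50 ms, centres −200/
−35/0/+35/+300 ms around R) scaled per lead (gains 1.0/0.6). Each
subject draws a basal RR from U(0.6, 1.1) s, per-wave amplitude factors
within ±30%, width factors within ±20%, lead-gain factors within ±30%,
plus Gaussian noise (σ = 0.08 mV), sinusoidal wander (0.15 mV at
~0.3 Hz) — together the inter-subject morphology/rhythm variability the
adversary is meant to cancel. `confound_strength` ∈ [0, 1] scales every
subject-specific deviation; at 0 subjects are identical and a subject
probe on raw beats sits at chance.

Class effects: S beats arrive early (RR × 0.6) with the P wave scaled to
0.3; V beats arrive early (RR × 0.55) with no P wave, QRS width × 2.2,
QRS amplitude × 1.5, and a compensatory pause (× 1.4) on the following
beat; N beats carry ±5% RR jitter. S/V prematurity is additionally
jittered ±25% per beat around those means: real ectopic prematurity is
broadly spread and overlaps the normal range, and without that spread
the rhythm features alone make the task trivially separable — the
generator's noise and prematurity spread were set so the synthetic task
sits in a regime where S detection is genuinely hard and
subject-confounded, as it is in real recordings. Records round-trip
through the package's WFDB writer/reader, so the ingestion path used for
real data is the one the generator exercises.

What the cohort does *not* model: non-Gaussian noise (muscle artefact,
electrode motion), non-stationary heart-rate trends, fusion (F) and
unknown (Q) classes by default, multiform ectopy within a subject, and
lead-placement effects beyond a scalar gain. Passing the synthetic
invariance tests therefore demonstrates the *mechanism* — the adversary
removes subject information without destroying class information — not
clinical-grade performance on real ECG.

## Experiment sizes and numerical choices

Routine runs (tests, acceptance script) use 8 subjects × 300 beats with
4 held out, ≤15 epochs, batch 128 — small enough for a laptop-class
single-CPU run, large enough that the probe and class metrics are
stable. Probabilities are clamped at 1e-12 before logs; batch-norm uses
ε = 1e-5, momentum 0.1, with running statistics for evaluation; pooling
tie-breaks and padding conventions are fixed by the ceil-mode rules
above; degenerate metric cases (a class absent from truth and
prediction) report 0 with an explicit `undefined` flag and are printed
as "—" in record-level tables.

## Known limitations

* On the synthetic cohort the classification task saturates for the V
  class (wide QRS is conspicuous), so effects that in real data appear
  as precision differences between adversarial weights are compressed;
  in particular, large λ (0.1) does not reliably degrade S/V precision
  here, because once the class loss is near zero Adam's per-parameter
  normalisation makes the encoder's invariance pressure nearly
  independent of λ's magnitude. The λ-ordering observed on real data
  should not be expected from this generator at these sizes.
* The adversary is a single affine layer; a stronger adversary would
  bound subject information in h more tightly.
* The WFDB layer covers signal formats 16 and 212, single-segment
  records, one `.dat` per record — sufficient for the arrhythmia
  database and the generator, not a general WFDB implementation.
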