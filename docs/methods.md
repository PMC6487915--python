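# Methods

## The staging model

Sleep scoring assigns one of Y = 5 stages (W, N1, N2, N3, REM) to every
30-second PSG epoch. `sleepmt` treats this as a *joint classification and
prediction* problem: a single network receives the time-frequency image of
epoch n and emits 2τ+1 stage distributions — one for the epoch itself and
one per neighbor in the output context [n−τ, n+τ]. The working assumption is
first-order stage persistence: adjacent epochs usually share a label, so one
epoch's signal is genuinely informative about its neighbors' stages. At
inference, epoch n therefore holds an ensemble of up to 2τ+1 decisions (its
own classification plus each neighbor's prediction about it), fused by
additive (mean) or multiplicative (product) voting before the argmax.
Multiplicative voting suppresses stages on which the decisions diverge more
strongly than additive voting; with τ = 0 the whole framework reduces
exactly to standard single-epoch classification.

### Front-end

Each channel of a 30-s epoch at 100 Hz is transformed by STFT with 2-s
symmetric Hamming windows, 50% overlap and a 256-point FFT. Frames are
windows fully inside the signal (no padding), so F = nfft/2 + 1 = 129 and
T = ⌊(3000 − 200)/100⌋ + 1 = 29. Power is mapped through
log(|STFT|² + ε) with ε = 10⁻¹⁰ so silent frames stay finite. A
nonnegative M×F filter bank (M = 20) reduces each image to M×T; filtering
is applied after the log, and a `filter_before_log` switch exists for
experimentation. The bank is either the regular triangular bank (M
triangles linearly spaced over [0, fs/2], 50% overlap) or a discriminative
bank: the first, nonnegativity-constrained linear layer of a small softmax
network (M×F filter layer → flatten → 256-unit ReLU layer → Y-way softmax)
trained on single-epoch classification, with weights clamped to ≥ 0 after
every Adam step. The pretrainer is a deliberately simple stand-in that
preserves the purpose of discriminative filter-bank learning — emphasizing
stage-informative sub-bands — without reproducing any particular published
training protocol. Channel images are stacked to X ∈ ℝ^{P×M×T}, and images
are z-scored per channel-and-band using training-set statistics (the
standardization choice is ours; it is switchable).

### Network

The default architecture is three layers: R = 3 sets of Q over-time
convolutional filters with temporal widths w ∈ {3, 5, 7}, each filter
spanning all P channels and M bands (valid cross-correlation over time,
stride 1, ReLU); 1-max pooling per feature map, yielding a Q·R feature
vector (convolution + 1-max pooling acts as learned template matching, the
retained value being the template's best matching score anywhere in the
epoch); dropout (rate 0.2) on the pooled vector; and a multi-task softmax
head. The head is one affine map (Q·R) → (2τ+1)·Y with softmax applied per
Y-block — the subtasks share the feature vector but not their weights
(weight sharing across heads is unspecified territory; independent heads are
the simplest choice). Weights use seeded variance-scaling uniform
initialization.

The loss is the mean over examples of the summed per-subtask
cross-entropies plus (λ/2)‖θ‖², λ = 10⁻³, implemented as a nonnegative
quantity that training minimizes, with probabilities clipped at 10⁻¹² inside
the log. Everything — forward, backward, Adam — is implemented in numpy with
hand-derived gradients; the test suite validates them against central finite
differences to 10⁻⁴ relative error for both architectures.

Configuration variants: `arch="deep_baseline"` swaps in a conventional deep
CNN (3×3 conv ×96 → 2×1 max-pool → 3×3 conv ×96 → 2×2 max-pool → two
1024-unit dense layers, dropout 0.2 after each pool and dense layer, same
multi-task head; convolutions are 'same'-padded). `scheme="one_to_one"`
forces τ = 0; `scheme="many_to_one"` concatenates `input_context` = 3
neighboring images along the time axis (preserving P and M, mirroring the
reading order of a contextual input) and emits a single decision.

### Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) at learning rate 10⁻⁴, batch size
200, 200 training epochs by default. Every batch is class-balanced: an
equal number of examples per stage (the center-epoch label defines the
class), drawn with replacement within class and reshuffled every epoch; one
training epoch is ⌈N/batch⌉ such batches. The checkpoint with the best
validation metric is retained. "Best overall validation accuracy" is
ambiguous for a multi-task model; we select on the classification-subtask
accuracy and expose `selection_metric="aggregated"` as the alternative.
Training examples whose context window would cross a recording boundary are
dropped (the simplest unbiased choice); at inference every epoch is still
labelled because boundary ensembles simply aggregate over the contributors
that exist, normalizing by the actual count.

### Numerical and tie-break conventions

- Argmax ties resolve to the lowest stage index. Multiplicative scores are
  computed as a direct product (exactly symmetric across stages, so exact
  ties are deterministic) for ensembles of ≤ 20 contributors, and in the
  log domain with a 10⁻¹² floor beyond that.
- The 1/(2τ+1) factor of multiplicative voting leaves the scores
  unnormalized; it is retained for symmetry with additive voting and never
  affects the argmax.
- Epoch indexing is 0-based with half-open windows [n·30 s, (n+1)·30 s).
- Reported percentages use half-up rounding to one decimal.
- Confusion matrices are stored rows = reference, columns = predicted;
  sensitivity is diagonal/row-total and selectivity diagonal/column-total.
  The shipped benchmark matrices are stored in the orientation that makes
  their published per-class values arithmetically consistent.

## The synthetic generator

The generator reproduces exactly the two statistical properties the method
relies on, and no more.

**Hypnograms** come from a first-order Markov chain over the five stages.
The default transition matrix is diagonal-dominant with off-diagonal
structure following the usual nocturnal routes (W→N1→N2→{N3, REM}, N3→N2,
REM→{W, N2}); its diagonal was tuned once so the stationary adjacent-pair
agreement Σₛ πₛA[s,s] equals 0.8330 — the persistence level of large scored
cohorts — with a realistic stationary stage mix (W 0.18, N1 0.06, N2 0.46,
N3 0.12, REM 0.17). Known limitation: the two-step agreement of this chain
is 0.726, whereas scored cohorts show ~0.79. That gap is structural — a
first-order chain with one-step agreement 0.833 and a realistic stationary
distribution cannot push two-step agreement much above 0.74, because real
hypnograms have longer-than-geometric bout durations. Matching bout-length
distributions would need a semi-Markov model, which the staging framework
itself does not assume.

**Signals** are white Gaussian noise shaped in the FFT domain — exact band
control, no filter transients, deterministic per seed. Stage templates
follow canonical signatures (relative powers are free generator parameters,
not empirical claims): W = 8–12 Hz alpha + high EMG; N1 = 4–7 Hz theta;
N2 = 12–15 Hz sigma over a theta background; N3 = high-amplitude 0.5–4 Hz
delta; REM = 4–8 Hz theta, large slow EOG, minimal EMG. Three variability
sources keep the task realistically hard rather than trivially separable:
a shared 1/f pink background, lognormal per-epoch band-power jitter
(σ = 0.6), and per-epoch stage blending (each epoch mixes its template with
a random other stage's template with weight ~ U(0, 0.6), emulating
transitional and ambiguous epochs). These were calibrated against the
~80% single-epoch accuracy regime reported for real cohorts; with them, the
desk-scale network classifies single epochs at ~0.74 and the fused ensemble
reaches ~0.85, reproducing the qualitative pattern of the real-data studies.

What the generator does **not** emulate — artifacts, arousals, K-complex or
spindle morphology, inter-subject variability, non-geometric bout durations
— bounds what passing tests mean: they demonstrate the pipeline's
correctness and the framework's mechanism (neighbor predictions carry
fusible information under stage persistence), not clinical-grade accuracy
on real PSG.

## Desk-scale experimental conditions

The behavioral tests run the full pipeline at a size chosen for a single
CPU: 5 recordings × 200 epochs per seed (3 train / 1 validation / 1 test),
Q = 25, widths {3, 5, 7}, τ = 1, 30 training epochs, 5 seeds (≈ 30 s per
seed). For this short schedule (~90 optimizer steps) the fixture uses
learning rate 10⁻³; the protocol default of 10⁻⁴ is tuned to the full
200-epoch schedule and barely moves the weights in 90 steps. On the seed
means, classification accuracy exceeds both prediction subtasks, and
multiplicative voting exceeds classification alone — the directional claims
the framework rests on. Full-scale settings (Q up to 1000, hundreds of
recordings, cross-validation) are supported by the same code paths but are
not exercised by the tests.

## Known limitations

- Pure-numpy training is practical at desk scale but slow for Q = 1000 on
  full cohorts; the implementation favors transparency and testability.
- The discriminative filter-bank pretrainer is a functional stand-in, not a
  reproduction of any specific published pretraining recipe.
- EDF reading is an optional extra (requires `mne`); only signal channels
  are read, not annotation tracks.
- No HMM/transition-prior smoothing of the output hypnogram; fusion is
  per-epoch voting by design.
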