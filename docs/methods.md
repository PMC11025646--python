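# Methods

This note documents the models and procedures implemented in `lmalign`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not establish.

## Language model

The model is a unidirectional-attention (causal) transformer over integer
token ids. Each of the `n_layers` blocks applies, in pre-norm residual style,

    x ← x + Attn(LN₁(x));   x ← x + FF(LN₂(x))

with multi-head scaled dot-product attention, a GELU feedforward layer, a
final layer norm, and an untied linear head producing next-token logits.
Residual placement is not uniquely determined by a four-block description
(layer norm, attention, layer norm, feedforward); the pre-norm GPT-2
convention is adopted. Positions are learned embeddings; the layer-0
activation is the sum of token and position embeddings.

Causality is exact rather than approximate: future positions are masked to
−∞ before the softmax, so the attention weight on any future value vector is
exactly zero and activations at position *t* are bit-wise invariant to tokens
after *t* at every layer. The test suite asserts the spec-level bound
(< 10⁻⁶) but the implementation achieves 0.

The implementation is NumPy (float64) with a hand-written analytic backward
pass, verified against central finite differences (agreement ≤ 10⁻¹⁰ across
parameter types). At the scales used here (2–4 layers, 32–128 units, contexts
of 16–64) this trains hundreds of steps per second on one CPU; the 12 × 768
reference configuration is expressible but not exercised by the tests.

### Initialization schemes

* `default` — conventional scaled-normal transformer initialization:
  embedding, attention, feedforward, and output weights ~ N(0, 0.02²), biases
  zero, layer-norm gain 1 / bias 0.
* `gaussian(mean, sd)` — *every* weight, including layer-norm gains and
  biases, drawn from N(mean, sd²). With (0, 0.02) this is the controlled
  untrained variant used to separate the contribution of architecture from
  that of a tuned initialization. A gaussian-initialized untrained model still
  propagates finite activity through all layers (tested), so any failure to
  predict responses is not a propagation collapse.

### Training and token accounting

Adam (default lr 10⁻³–2·10⁻³ in the experiments, β = 0.9/0.999) on the mean
next-token cross-entropy over randomly positioned context-length windows.
Token accounting is exact integer arithmetic:
`tokens_per_step = context × batches_per_device × n_devices ×
grad_accumulations`, and `tokens_seen = tokens_per_step × steps`. Checkpoint
schedules are logarithmic (`base_steps` × multipliers 0, 0.001, 0.01, 0.1, 1,
10 by default); each checkpoint stores weights, step, tokens seen, and a
sliding-window validation perplexity on a held-out split (tail 10% of the
corpus, capped at 4,096 tokens) so the best-validation checkpoint can be
selected.

## Perplexity

H = −(1/N) Σ log₂ P(xᵢ | context), PPL = 2^H. Long streams are scored with
overlapping windows (context C, stride S): the first window scores all its
positions after the first token; each later window scores only its final S
positions, so every token after the first is scored exactly once with at
least C − S tokens of context. Open choices resolved here: the stream's first
token is never scored (it has no context) and is excluded from N; logs are
base 2 throughout; a token assigned probability 0 makes the result infinite
and is flagged (`n_zero_prob`) rather than dropped.

## Encoding pipeline

Sentence representation: the activation of the sentence's last word at a
given layer, averaging across tokens for multi-token words. Punctuation
attached to the final word is averaged in with it — selection is defined at
the word level, and the mean is token-order invariant. Sentences are
presented to the model in isolation by default.

Cross-validation: k = 5 contiguous near-equal folds in stimulus order, with
the remainder r giving one extra item to the last r folds (243 items →
48, 48, 49, 49, 49). Fold construction is validated against that worked case;
other published splits of a 384-item block do not follow any simple
near-equal contiguous rule, so no claim is made there.

Regression: ordinary least squares with an intercept (without it, predictions
cannot match response means). When units + 1 exceed the training rows the
problem is underdetermined and the minimum-norm (pseudoinverse) solution is
used; ridge regularization is available as an option but off by default.
Scoring: per-voxel Pearson r between held-out predictions and observations,
averaged over folds; per participant, the median over voxels, averaged over
experiment blocks, divided by the ceiling. Medians of even-length vectors are
the mean of the central pair. The layer sweep maximizes the
participant-median normalized score, breaking ties toward the lower layer.

## Behavioral pipeline

Reading times are filtered to [100 ms, 3,000 ms] *inclusive* ("outside the
range" excludes only the strict exterior); filtering is idempotent and the
removed count is reported. Per participant, word occurrences are assigned to
five folds under two constraints: occurrences of the same word type within a
sentence share a fold, and each sentence's occurrences are spread across
folds as evenly as possible. A *global* same-type constraint is infeasible
(function words appear in nearly every sentence and would collapse the
folds), so the constraint is scoped to sentences; users should be aware this
is an interpretation, not the only possible one. Assignment is greedy:
word-type groups, largest first (ties shuffled by seed), go to the fold least
loaded within the sentence, then globally. Word representations come from the
last model layer, averaging multi-token words; because attention is causal,
the activation at a word's position equals what the model would produce on
the sentence truncated at that word.

## Synthetic data: what it emulates and what it does not

* **Corpora** — unigram or first-order Markov sources with analytic entropy
  rate (stationary distribution by eigen-decomposition). They exercise
  next-token learnability and perplexity floors, not natural-language syntax,
  long-range dependencies, or subword structure.
* **Neural benchmarks** — responses are a *shared* linear readout of a
  feature matrix plus *participant-specific* i.i.d. Gaussian noise, which
  makes the "average participant" noise ceiling analytic per voxel:
  c = √(σ²ₛ / (σ²ₛ + σ²ₙ)), equal to 1 when noise is 0 and decreasing in
  noise. Real fMRI noise is neither i.i.d. nor Gaussian, and real signal is
  not an exact linear readout of any model layer; passing recovery tests
  shows the *pipeline* is unbiased under its own assumptions, not that those
  assumptions hold for brains.
* **Reading times** — affine in surprisal plus Gaussian noise, with a chosen
  fraction of values replaced by draws from [0, 100) ∪ (3000, 5000] ms to
  exercise both sides of the range filter. The attenuation of the RT–surprisal
  correlation by noise has a closed form used as a test oracle.

All generators are bit-identical under a fixed seed.

## The standing experiments

`lmalign.experiments` freezes three study designs (shared by the tests and
`scripts/acceptance.py`). Their sources are 64-token first-order Markov
chains with Dirichlet(0.2) rows — peaked enough to learn, and wider than the
32-unit embedding so token identity is not linearly recoverable from an
untrained embedding; that gap is what makes predictivity sensitive to
training.

* **Ceiling recovery** — 200 sentences, 50 voxels, 32 units, 5 participants,
  noise sd 0.2 (ceiling ≈ 0.98). Regressing from the true features, the
  median per-voxel r must sit within 0.05 of the analytic ceiling and the
  normalized score within 0.1 of 1. The residual gap is finite-sample
  regression attenuation: with p parameters and n training rows the held-out
  correlation is ≈ √(σ²ₛ / (σ²ₛ + σ²ₙ(1 + p/n))), which at higher noise
  exceeds the band — the noise level is chosen where the pipeline's bias is
  negligible, not to hide it.
* **Layer recovery** — benchmarks generated from layer 2 of a trained
  3-layer model; the sweep must pick that layer in ≥ 90% of 10 replicates.
  Residual connections make adjacent layers almost exactly linearly related,
  so at appreciable noise the generating layer is unidentifiable in principle
  at this scale (every layer predicts it equally well); recovery is assessed
  near the noiseless limit (noise sd 0.001) where the generating layer's
  exact self-predictivity stands out.
* **Scaling trend** — 2-layer models trained for 600 steps on 10³, 10⁴, and
  10⁵ tokens (5 seeds each); the benchmark is generated from the last layer
  of a separate "mature" model trained on 2 × 10⁵ tokens, standing in for a
  system that has fully learned the source. Median validation perplexity must
  be non-increasing and median best-layer predictivity non-decreasing across
  budgets. 600 steps makes the models data-limited rather than step-limited
  (the 10³ corpus is memorized and generalizes poorly; the 10⁵ corpus still
  improves), which is where the scaling question has power.

## Numerical choices and degenerate inputs

* float64 throughout; layer-norm ε = 10⁻⁵; Adam ε = 10⁻⁸.
* Zero-variance columns in the Pearson computation yield NaN rather than a
  silent 0.
* t tests: pooled-variance Student's t by default (Welch via a flag),
  two-sided. Zero pooled variance with equal means → t = 0, p = 1; with
  unequal means → error.
* MAD is unscaled (no 1.4826 factor): it is an error bar, not a σ estimate.
* Cross-validation folds with fewer than 3 test items are rejected
  (correlation ill-defined).
* Probability vectors must sum to 1 within 10⁻⁹; checkpoint-schedule
  multipliers must land on integer steps.

## Limitations

* The transformer is CPU/NumPy and desk-scale by design; it demonstrates the
  mechanics and scaling *shape*, not full-scale language modeling.
* Synthetic benchmarks cannot stand in for real neural or reading-time data;
  ceilings for real benchmarks must be supplied as constants (the pipeline
  accepts them but does not estimate them by subsampling).
* Markov sources have no genuine long-range structure, so context-length
  effects beyond one token are weakly exercised.
* The word-fold constraint is a documented interpretation of an ambiguous
  requirement (see above).
* Tokenization for text corpora is word/punctuation level with contractions
  split at a discarded apostrophe; no byte-pair encoding is provided, and no
  claim is made about subword tokenizers.
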