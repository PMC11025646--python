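# lmalign

How much training does a language model need before its internal
representations align with human responses to language? `lmalign` is a tested,
reusable pipeline for studying that question at controlled scale: it trains
small unidirectional-attention (causal) transformer language models with exact
token-budget accounting, evaluates them with sliding-window perplexity, and
measures how well their layer activations linearly predict neural (fMRI-style,
voxel × sentence) and behavioral (self-paced reading time) benchmarks, with
noise-ceiling normalization and the accompanying statistical comparisons.

It is aimed at computational cognitive neuroscientists and NLP researchers who
want the *mechanics* of neural encoding analyses — cross-validated voxelwise
regression, ceiling normalization, layer sweeps, training-amount scaling
curves — as a library they can run end to end on synthetic data with known
ground truth, or point at their own benchmarks.

## The method

**Language model.** A GPT-2-style causal transformer (pre-norm residual
blocks: layer norm → self-attention → layer norm → feedforward), implemented
in NumPy with an analytic backward pass and Adam. The reference configuration
is 12 layers × 768 units with a 1,024-token context; experiments here run
desk-scale variants (2–4 layers, 32–128 units) that preserve every property
under test. Training checkpoints follow a logarithmic schedule and carry exact
token accounts: one optimizer step consumes
`context × batches × devices × grad_accumulations` tokens (e.g.
1,024 × 8 × 16 × 4 = 524,288).

**Perplexity.** PPL = 2^H with H = −(1/N) Σᵢ log₂ P(xᵢ | context), evaluated
with overlapping windows (context 1,024, stride 512 by default) so every token
after the first is scored exactly once.

**Encoding model.** For each model layer, every sentence is represented by the
activation of its last word (multi-token words are token-averaged). Sentences
are split into five contiguous near-equal folds; an ordinary least-squares map
(minimum-norm when underdetermined) from activations to voxel responses is fit
on four folds and evaluated on the fifth by per-voxel Pearson r, averaged over
folds. A participant's score is the median r over voxels, averaged over
experiment blocks and divided by the noise ceiling — the expected predictivity
of the best possible model of an average participant given measurement noise.
Reading times are handled analogously from the last layer, after filtering RTs
outside [100 ms, 3,000 ms] and with word-level folds that never put the same
within-sentence word type on both sides of a split.

**Synthetic ground truth.** Generators produce (i) token streams from unigram
or first-order Markov sources with analytic entropy rate (so the optimal
perplexity 2^H is known), (ii) multi-participant voxel responses as a shared
linear readout of features plus participant-specific Gaussian noise (so the
ceiling √(σ²ₛ / (σ²ₛ + σ²ₙ)) is analytic per voxel), and (iii) reading times
affine in surprisal with injected out-of-range outliers. Every downstream
stage is validated against these closed forms.

**Statistics.** Independent two-sample t tests (pooled-variance Student's t)
against a reference model's participant scores, Bonferroni-corrected; summary
statistics are the median across participants with the unscaled median
absolute deviation as the error bar.

## Worked example

```python
import numpy as np
from lmalign import TransformerConfig, TransformerLM
from lmalign.lm.train import TrainingHyperparams, train_lm, select_best_checkpoint
from lmalign.synthetic import (SyntheticCorpusSpec, SyntheticNeuralSpec,
                               generate_corpus, generate_neural_benchmark)
from lmalign.encoding import layer_sweep, model_sentence_features

# a first-order Markov "language" with known entropy rate
rng = np.random.default_rng(0)
T = rng.dirichlet(np.full(32, 0.3), size=32)
corpus, H = generate_corpus(SyntheticCorpusSpec(32, 1, T, 50_000, seed=1))
print(f"source entropy rate: {H:.3f} bits/token (optimal PPL {2**H:.2f})")

cfg = TransformerConfig(n_layers=2, d_model=32, n_heads=4, d_ff=128,
                        context_size=16, vocab_size=32)
model = TransformerLM.init(cfg, seed=2)
ckpts = train_lm(model, corpus,
                 TrainingHyperparams(batch_size=8, learning_rate=2e-3, seed=0),
                 n_steps=400)
best = select_best_checkpoint(ckpts)
print(f"validation perplexity after {best.step} steps "
      f"({best.tokens_seen:,} tokens): {best.val_perplexity:.2f}")

# a synthetic neural benchmark generated from the model's own last layer
sents = [[[int(t)] for t in
          generate_corpus(SyntheticCorpusSpec(32, 1, T, 8, seed=100 + i))[0]]
         for i in range(150)]
feats = model_sentence_features(model, sents)
bench, truth = generate_neural_benchmark(
    SyntheticNeuralSpec(n_participants=3, n_voxels=30, n_sentences=150,
                        noise_sd=0.001, seed=5), feats[-1])
results, best_layer = layer_sweep(feats, bench)
print(f"analytic noise ceiling: {bench.ceiling:.3f}")
for r in results:
    print(f"layer {r.layer}: normalized score {r.median_normalized:.3f}")
print(f"best layer: {best_layer}")
```

prints

```
source entropy rate: 3.572 bits/token (optimal PPL 11.89)
validation perplexity after 400 steps (51,200 tokens): 13.62
analytic noise ceiling: 1.000
layer 0: normalized score 0.991
layer 1: normalized score 0.998
layer 2: normalized score 1.000
best layer: 2
```

The trained model's perplexity (13.62) sits just above the source's analytic
optimum (11.89); the layer sweep assigns the benchmark to layer 2 — the layer
it was generated from — and its normalized score reaches the ceiling, while
the other layers fall measurably short.

A thin CLI wraps the same functionality: `lmalign train`, `lmalign eval-ppl`,
`lmalign corpus-stats`, `lmalign contamination`, `lmalign eval-brain`,
`lmalign eval-behavior` (see `lmalign --help`).

## Documentation

`docs/methods.md` describes the model, the synthetic generators and what they
do and do not emulate, the numerical choices, and known limitations.
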