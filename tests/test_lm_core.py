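"""Transformer LM: initialization schemes, causal structure, token-budget
accounting, checkpoint schedules, and training behavior."""

import numpy as np
import pytest

from lmalign import (
    CheckpointSchedule,
    InitScheme,
    TrainingBudget,
    TransformerConfig,
    TransformerLM,
    steps_for_one_pass,
    tokens_seen,
)
from lmalign.lm.model import init_params
from lmalign.lm.train import (
    TrainingHyperparams,
    load_checkpoint,
    save_checkpoint,
    select_best_checkpoint,
    train_lm,
)
from lmalign.synthetic import SyntheticCorpusSpec, generate_corpus


class TestInit:
    def test_gaussian_init_moments(self):
        """Gaussian scheme: attention weights sampled from N(0, 0.02^2)."""
        cfg = TransformerConfig(
            n_layers=1, d_model=64, n_heads=4, d_ff=128, context_size=8, vocab_size=7
        )
        params = init_params(cfg, InitScheme("gaussian", 0.0, 0.02), seed=0)
        w = params["h0.attn.wqkv"].ravel()  # 64 * 192 > 1e4 weights
        assert w.size >= 10_000
        assert abs(w.mean()) < 3 * 0.02 / np.sqrt(w.size)
        assert abs(w.std() - 0.02) < 0.05 * 0.02

    def test_gaussian_sd_zero_gives_zero_weights(self, tiny_config):
        params = init_params(tiny_config, InitScheme("gaussian", 0.0, 0.0), seed=0)
        for k, v in params.items():
            assert np.all(v == 0.0), k

    def test_same_seed_bit_identical(self, tiny_config):
        a = init_params(tiny_config, InitScheme(), seed=5)
        b = init_params(tiny_config, InitScheme(), seed=5)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            InitScheme("xavier")

    def test_gaussian_untrained_activations_finite(self):
        """A gaussian-initialized untrained model propagates finite activity
        through every layer (no collapse)."""
        cfg = TransformerConfig(
            n_layers=4, d_model=32, n_heads=4, d_ff=64, context_size=16, vocab_size=11
        )
        model = TransformerLM(cfg, init_params(cfg, InitScheme("gaussian", 0.0, 0.02), seed=1))
        acts = model.layer_activations(np.arange(11)[:10])
        assert len(acts) == 5
        for a in acts:
            assert np.all(np.isfinite(a))


class TestForward:
    def test_log_probs_normalized(self, tiny_model):
        lp = tiny_model.log_probs(np.array([1, 2, 3, 4]))
        assert np.exp(lp).sum(axis=-1) == pytest.approx(np.ones(4), abs=1e-6)

    def test_single_token_input(self, tiny_model):
        lp = tiny_model.log_probs(np.array([3]))
        assert lp.shape == (1, tiny_model.config.vocab_size)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-6)

    def test_causal_invariance_logits_and_all_layers(self, tiny_model):
        """Perturbing token t leaves logits and every layer's activations at
        positions < t unchanged (max |delta| < 1e-6)."""
        toks = np.array([1, 2, 3, 4, 5, 6, 7, 8])
        t = 5
        perturbed = toks.copy()
        perturbed[t] = 9
        d_logits = np.abs(tiny_model.logits(toks)[:t] - tiny_model.logits(perturbed)[:t]).max()
        assert d_logits < 1e-6
        for a, b in zip(
            tiny_model.layer_activations(toks), tiny_model.layer_activations(perturbed)
        ):
            assert np.abs(a[:t] - b[:t]).max() < 1e-6

    def test_out_of_vocab_token_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.logits(np.array([1, 99]))

    def test_sequence_longer_than_context_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.logits(np.zeros(17, dtype=int))

    def test_layer_count_embedding_plus_blocks(self):
        cfg = TransformerConfig(
            n_layers=12, d_model=24, n_heads=4, d_ff=32, context_size=8, vocab_size=7
        )
        model = TransformerLM.init(cfg, seed=0)
        acts = model.layer_activations(np.array([1, 2, 3]))
        assert len(acts) == 13  # embedding layer (index 0) + 12 blocks

    def test_activations_deterministic(self, tiny_model):
        toks = np.array([1, 2, 3])
        a = tiny_model.layer_activations(toks)
        b = tiny_model.layer_activations(toks)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestTokenAccounting:
    @pytest.mark.parametrize(
        "budget, expected",
        [
            ((1024, 128, 1, 1, 1000), 131_072_000),
            ((1024, 128, 1, 1, 2000), 262_144_000),
            ((1024, 128, 1, 1, 14250), 1_867_776_000),
            ((1024, 8, 16, 4, 20), 10_485_760),
            ((1024, 8, 16, 4, 200), 104_857_600),
            ((1024, 8, 16, 4, 0), 0),
        ],
    )
    def test_tokens_seen_exact(self, budget, expected):
        assert tokens_seen(TrainingBudget(*budget)) == expected

    def test_tokens_per_step(self):
        assert TrainingBudget(1024, 8, 16, 4).tokens_per_step == 524_288

    def test_one_pass_step_count(self):
        steps = steps_for_one_pass(9_036_044_288, TrainingBudget(1024, 8, 16, 4))
        # 17.2K steps to 3 significant figures
        assert round(steps / 1000, 1) == 17.2

    @pytest.mark.parametrize(
        "corpus, budget, expected",
        [
            (524_288, (1024, 8, 16, 4), 1.0),
            (2048, (1024, 1, 1, 1), 2.0),
        ],
    )
    def test_one_pass_exact_cases(self, corpus, budget, expected):
        assert steps_for_one_pass(corpus, TrainingBudget(*budget)) == expected

    def test_schedule_steps(self):
        sched = CheckpointSchedule(base_steps=20_000)
        assert sched.steps() == [0, 20, 200, 2000, 20_000, 200_000]

    def test_schedule_rejects_fractional_steps(self):
        with pytest.raises(ValueError):
            CheckpointSchedule(base_steps=10, multipliers=(0.001,))

    def test_tokens_seen_nondecreasing_in_steps(self):
        sched = CheckpointSchedule(base_steps=100, multipliers=(0.0, 0.1, 1.0, 10.0))
        seen = [
            tokens_seen(TrainingBudget(64, 2, 1, 1, s)) for s in sched.steps()
        ]
        assert seen == sorted(seen)


class TestTraining:
    def test_memorization_ppl_approaches_one(self):
        """Training on one repeated 32-token sequence drives perplexity to 1."""
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 16, 32)
        cfg = TransformerConfig(
            n_layers=2, d_model=32, n_heads=4, d_ff=128, context_size=32, vocab_size=16
        )
        model = TransformerLM.init(cfg, seed=1)
        ckpts = train_lm(
            model,
            np.tile(seq, 60),
            TrainingHyperparams(batch_size=8, learning_rate=3e-3, seed=0),
            n_steps=400,
            val_tokens=np.tile(seq, 4),
        )
        assert ckpts[-1].val_perplexity < 1.1

    def test_uniform_source_ppl_approaches_vocab_size(self):
        """On a uniform unigram source with V=50 the optimal perplexity is 50;
        a trained model approaches it from above within 10%."""
        spec = SyntheticCorpusSpec(50, 0, np.full(50, 1 / 50), 60_000, seed=3)
        tokens, rate = generate_corpus(spec)
        assert 2**rate == pytest.approx(50.0)
        cfg = TransformerConfig(
            n_layers=2, d_model=32, n_heads=4, d_ff=128, context_size=32, vocab_size=50
        )
        model = TransformerLM.init(cfg, seed=2)
        ckpts = train_lm(
            model,
            tokens,
            TrainingHyperparams(batch_size=8, learning_rate=1e-3, seed=0),
            n_steps=200,
        )
        ppl = ckpts[-1].val_perplexity
        assert ppl <= 55.0
        assert ppl >= 49.5  # cannot beat the source entropy (minus MC error)

    def test_checkpoints_at_scheduled_steps(self):
        sched = CheckpointSchedule(base_steps=20, multipliers=(0.0, 0.05, 0.5, 1.0))
        cfg = TransformerConfig(
            n_layers=1, d_model=16, n_heads=2, d_ff=32, context_size=8, vocab_size=6
        )
        model = TransformerLM.init(cfg, seed=0)
        tokens = np.random.default_rng(1).integers(0, 6, 400)
        ckpts = train_lm(model, tokens, TrainingHyperparams(batch_size=2, seed=0), schedule=sched)
        assert [c.step for c in ckpts] == [0, 1, 10, 20]
        assert [c.tokens_seen for c in ckpts] == [0, 16, 160, 320]
        best = select_best_checkpoint(ckpts)
        assert best.val_perplexity == min(c.val_perplexity for c in ckpts)

    def test_empty_corpus_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            train_lm(tiny_model, np.array([], dtype=int), n_steps=1)

    def test_checkpoint_roundtrip(self, tmp_path, tiny_config):
        model = TransformerLM.init(tiny_config, seed=3)
        tokens = np.random.default_rng(0).integers(0, 11, 300)
        ckpts = train_lm(model, tokens, TrainingHyperparams(batch_size=2, seed=0), n_steps=2)
        path = tmp_path / "ckpt.h5"
        save_checkpoint(path, ckpts[-1], tiny_config)
        loaded, cfg = load_checkpoint(path)
        assert cfg == tiny_config
        assert loaded.step == ckpts[-1].step
        assert loaded.val_perplexity == pytest.approx(ckpts[-1].val_perplexity)
        assert all(np.array_equal(loaded.params[k], ckpts[-1].params[k]) for k in loaded.params)
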