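"""Training loop with Adam, logarithmic checkpointing, and exact token
accounting. Checkpoints carry a validation perplexity so the best-validation
checkpoint can be selected for downstream evaluation."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..perplexity import sliding_window_perplexity
from .config import CheckpointSchedule, TrainingBudget
from .model import TransformerLM

__all__ = [
    "TrainingHyperparams",
    "Checkpoint",
    "train_lm",
    "select_best_checkpoint",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainingHyperparams:
    batch_size: int = 8
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    val_fraction: float = 0.1  # tail of the corpus held out for validation
    max_val_tokens: int = 4096


@dataclass
class Checkpoint:
    step: int
    tokens_seen: int
    params: dict
    val_perplexity: float = np.nan

    def model(self, config) -> TransformerLM:
        return TransformerLM(config, self.params)


class _Adam:
    def __init__(self, params: dict, hp: TrainingHyperparams):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.hp = hp

    def step(self, params: dict, grads: dict) -> None:
        hp = self.hp
        self.t += 1
        b1t = 1.0 - hp.beta1**self.t
        b2t = 1.0 - hp.beta2**self.t
        for k, g in grads.items():
            self.m[k] = hp.beta1 * self.m[k] + (1 - hp.beta1) * g
            self.v[k] = hp.beta2 * self.v[k] + (1 - hp.beta2) * g * g
            params[k] -= (
                hp.learning_rate * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + hp.adam_eps)
            )


def _validation_ppl(model: TransformerLM, val_tokens: np.ndarray) -> float:
    ctx = model.config.context_size
    res = sliding_window_perplexity(
        model.log2_next_token_probs, val_tokens, context_size=ctx, stride=max(1, ctx // 2)
    )
    return res.ppl


def train_lm(
    model: TransformerLM,
    corpus: np.ndarray,
    hyperparams: TrainingHyperparams | None = None,
    schedule: CheckpointSchedule | None = None,
    n_steps: int | None = None,
    val_tokens: np.ndarray | None = None,
) -> list[Checkpoint]:
    """Train in place on an integer token stream; return scheduled checkpoints.

    Each step samples ``batch_size`` random windows of ``context_size + 1``
    tokens from the training split and applies one Adam update on the mean
    next-token cross-entropy. A checkpoint is recorded *after* the scheduled
    number of updates (step 0 = untrained), with
    ``tokens_seen = step * context_size * batch_size`` and a sliding-window
    validation perplexity on the held-out split.
    """
    hp = hyperparams or TrainingHyperparams()
    corpus = np.asarray(corpus, dtype=np.int64)
    ctx = model.config.context_size
    if corpus.size <= ctx:
        raise ValueError("corpus must be longer than the context size")
    if schedule is None and n_steps is None:
        raise ValueError("provide a schedule or n_steps")
    steps = schedule.steps() if schedule is not None else [n_steps]
    if n_steps is not None and schedule is not None:
        steps = sorted(set(steps) | {n_steps})
    total_steps = max(steps)

    if val_tokens is None:
        n_val = min(hp.max_val_tokens, max(ctx + 1, int(hp.val_fraction * corpus.size)))
        n_val = min(n_val, corpus.size - (ctx + 1))
        train_tokens, val_tokens = corpus[: corpus.size - n_val], corpus[corpus.size - n_val:]
        if val_tokens.size < 2:
            train_tokens, val_tokens = corpus, corpus[: ctx + 1]
    else:
        train_tokens = corpus
        val_tokens = np.asarray(val_tokens, dtype=np.int64)
    if train_tokens.size <= ctx:
        raise ValueError("training split shorter than context size")

    budget = TrainingBudget(context_tokens=ctx, batches_per_device=hp.batch_size)
    rng = np.random.default_rng(hp.seed)
    opt = _Adam(model.params, hp)
    scheduled = set(steps)
    checkpoints: list[Checkpoint] = []

    def record(step: int) -> None:
        checkpoints.append(
            Checkpoint(
                step=step,
                tokens_seen=budget.tokens_per_step * step,
                params=copy.deepcopy(model.params),
                val_perplexity=_validation_ppl(model, val_tokens),
            )
        )

    if 0 in scheduled:
        record(0)
    n_starts = train_tokens.size - ctx  # window start positions
    for step in range(1, total_steps + 1):
        starts = rng.integers(0, n_starts, size=hp.batch_size)
        batch = np.stack([train_tokens[s : s + ctx + 1] for s in starts])
        _, grads = model.loss_and_grads(batch)
        opt.step(model.params, grads)
        if step in scheduled:
            record(step)
    return checkpoints


def select_best_checkpoint(checkpoints: list[Checkpoint]) -> Checkpoint:
    """Checkpoint with the smallest validation perplexity (earliest on ties)."""
    if not checkpoints:
        raise ValueError("no checkpoints")
    return min(checkpoints, key=lambda c: (c.val_perplexity, c.step))


# ------------------------------------------------------------------ storage


def save_checkpoint(path, checkpoint: Checkpoint, config) -> None:
    """Write a checkpoint to HDF5: one dataset per parameter plus metadata
    attributes (step, tokens seen, validation perplexity, architecture)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["step"] = checkpoint.step
        f.attrs["tokens_seen"] = checkpoint.tokens_seen
        f.attrs["val_perplexity"] = checkpoint.val_perplexity
        for k in ("n_layers", "d_model", "n_heads", "d_ff", "context_size", "vocab_size"):
            f.attrs[k] = getattr(config, k)
        g = f.create_group("params")
        for k, v in checkpoint.params.items():
            g.create_dataset(k, data=v)


def load_checkpoint(path):
    """Read a checkpoint written by :func:`save_checkpoint`; returns
    ``(Checkpoint, TransformerConfig)``."""
    import h5py

    from .config import TransformerConfig

    with h5py.File(path, "r") as f:
        config = TransformerConfig(
            **{
                k: int(f.attrs[k])
                for k in ("n_layers", "d_model", "n_heads", "d_ff", "context_size", "vocab_size")
            }
        )
        params = {k: np.asarray(v) for k, v in f["params"].items()}
        ckpt = Checkpoint(
            step=int(f.attrs["step"]),
            tokens_seen=int(f.attrs["tokens_seen"]),
            params=params,
            val_perplexity=float(f.attrs["val_perplexity"]),
        )
    return ckpt, config
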