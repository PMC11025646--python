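"""Sliding-window perplexity of any next-token scorer.

Perplexity is ``PPL = 2**H`` with ``H = -(1/N) * sum_i log2 P(x_i | context)``.
Long streams are scored with overlapping windows (context ``C``, stride ``S``):
the first window scores every position after its first token; each subsequent
window advances by ``S`` and scores only its final ``S`` positions, so every
token after the first is scored exactly once with at least ``C - S`` tokens of
context. The first token of the stream is never scored (it has no context) and
is excluded from ``N``.

A *scorer* is any callable mapping a 1-D token array of length T to a
``[T, vocab]`` array of base-2 log probabilities for the next token at each
position. :class:`UniformScorer` and :class:`MarkovScorer` provide analytic
references; a trained :class:`~lmalign.lm.model.TransformerLM` exposes the
same protocol via ``log2_next_token_probs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerplexityResult",
    "sliding_window_perplexity",
    "UniformScorer",
    "MarkovScorer",
]


@dataclass(frozen=True)
class PerplexityResult:
    H: float  # entropy, bits/token
    ppl: float  # 2**H
    n_tokens: int  # number of scored tokens
    context_size: int
    stride: int
    n_zero_prob: int = 0  # tokens assigned probability 0 (infinite PPL flag)

    @property
    def is_infinite(self) -> bool:
        return self.n_zero_prob > 0


def sliding_window_perplexity(
    scorer,
    tokens,
    context_size: int = 1024,
    stride: int = 512,
) -> PerplexityResult:
    """Score a token stream with overlapping windows (see module docstring).

    A token given probability 0 makes the result infinite; this is flagged via
    ``n_zero_prob`` rather than silently dropped.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if stride < 1 or stride > context_size:
        raise ValueError("require 1 <= stride <= context_size")
    L = tokens.size
    if L < 2:
        raise ValueError("need at least 2 tokens to score")

    total = 0.0
    n_scored = 0
    n_zero = 0
    scored_upto = 1  # first unscored target index
    end = min(context_size, L)
    while True:
        start = max(0, end - context_size)
        window = tokens[start:end]
        lp = np.asarray(scorer(window))  # [len(window), vocab], log2
        targets = np.arange(scored_upto, end)
        rel = targets - start
        vals = lp[rel - 1, tokens[targets]]
        zero = np.isneginf(vals)
        n_zero += int(zero.sum())
        total += float(vals[~zero].sum())
        n_scored += targets.size
        scored_upto = end
        if end >= L:
            break
        end = min(end + stride, L)

    if n_zero:
        H = np.inf
    else:
        H = -total / n_scored
    ppl = float(2.0**H) if np.isfinite(H) else np.inf
    return PerplexityResult(
        H=float(H),
        ppl=ppl,
        n_tokens=n_scored,
        context_size=context_size,
        stride=stride,
        n_zero_prob=n_zero,
    )


class UniformScorer:
    """Assigns 1/V to every token; PPL on any stream is exactly V."""

    def __init__(self, vocab_size: int):
        self.vocab_size = vocab_size
        self._row = np.full(vocab_size, -np.log2(vocab_size))

    def __call__(self, tokens) -> np.ndarray:
        return np.tile(self._row, (np.asarray(tokens).size, 1))


class MarkovScorer:
    """The true conditional model of a unigram or first-order Markov source.

    Its perplexity on the source's own output converges to
    ``2**entropy_rate`` — the analytic optimum no trained model can beat.
    """

    def __init__(self, distribution: np.ndarray, order: int):
        if order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        self.order = order
        self.distribution = np.asarray(distribution, dtype=float)

    def __call__(self, tokens) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.int64)
        with np.errstate(divide="ignore"):
            if self.order == 0:
                row = np.log2(self.distribution)
                return np.tile(row, (tokens.size, 1))
            logT = np.log2(self.distribution)
        return logT[tokens]
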