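"""Synthetic data generators with analytically known structure.

Every downstream stage of the pipeline (language-model training, perplexity,
neural encoding, reading-time regression) can be exercised against these
generators because their ground truth is known in closed form:

* token streams from unigram or first-order Markov sources carry an analytic
  entropy rate, so the optimal perplexity on them is ``2**entropy_rate``;
* multi-participant voxel responses are a shared linear readout of a feature
  matrix plus participant-specific i.i.d. Gaussian noise, so the noise ceiling
  ``sqrt(signal_var / (signal_var + noise_var))`` is analytic per voxel;
* reading times are affine in word surprisal plus Gaussian noise, with an
  optional fraction of out-of-range outliers to exercise RT filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticCorpusSpec",
    "SyntheticNeuralSpec",
    "SyntheticBehavioralSpec",
    "GroundTruth",
    "generate_corpus",
    "generate_neural_benchmark",
    "generate_reading_times",
    "markov_entropy_rate",
    "stationary_distribution",
]

_PROB_TOL = 1e-9


def _validate_stochastic(dist: np.ndarray, order: int) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if order == 0:
        if dist.ndim != 1:
            raise ValueError("order-0 source needs a probability vector")
        rows = dist[None, :]
    else:
        if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
            raise ValueError("order-1 source needs a square transition matrix")
        rows = dist
    if np.any(rows < -_PROB_TOL):
        raise ValueError("probabilities must be nonnegative")
    if not np.allclose(rows.sum(axis=1), 1.0, atol=_PROB_TOL):
        raise ValueError("each distribution must sum to 1 (tolerance 1e-9)")
    return dist


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """A memoryless (order 0) or first-order Markov (order 1) token source."""

    vocab_size: int
    source_order: int
    distribution: np.ndarray
    total_tokens: int
    seed: int

    def __post_init__(self) -> None:
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be positive")
        if self.source_order not in (0, 1):
            raise ValueError("source_order must be 0 or 1")
        if self.total_tokens < 1:
            raise ValueError("total_tokens must be >= 1")
        dist = _validate_stochastic(self.distribution, self.source_order)
        if dist.shape[-1] != self.vocab_size:
            raise ValueError("distribution size does not match vocab_size")
        object.__setattr__(self, "distribution", dist)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1, normalized to sum 1)."""
    transition = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def markov_entropy_rate(transition: np.ndarray) -> float:
    """Entropy rate (bits/token) of a stationary first-order Markov source:
    ``-sum_i pi_i sum_j T_ij log2 T_ij`` with 0 log 0 = 0."""
    transition = np.asarray(transition, dtype=float)
    pi = stationary_distribution(transition)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(transition > 0, transition * np.log2(transition), 0.0)
    return float(-(pi @ plogp.sum(axis=1)))


def _unigram_entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def generate_corpus(spec: SyntheticCorpusSpec) -> tuple[np.ndarray, float]:
    """Sample ``total_tokens`` tokens from the source.

    Returns ``(tokens, entropy_rate)`` where entropy_rate is in bits/token.
    Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.total_tokens
    if spec.source_order == 0:
        tokens = rng.choice(spec.vocab_size, size=n, p=spec.distribution)
        rate = _unigram_entropy(spec.distribution)
    else:
        T = spec.distribution
        pi = stationary_distribution(T)
        # inverse-CDF sampling against per-state cumulative rows: one uniform
        # per token, fully determined by the seed
        cum = np.cumsum(T, axis=1)
        u = rng.random(n)
        tokens = np.empty(n, dtype=np.int64)
        state = int(rng.choice(spec.vocab_size, p=pi))
        tokens[0] = state
        for i in range(1, n):
            state = int(np.searchsorted(cum[state], u[i], side="right"))
            state = min(state, spec.vocab_size - 1)
            tokens[i] = state
        rate = markov_entropy_rate(T)
    return tokens.astype(np.int64), rate


@dataclass(frozen=True)
class GroundTruth:
    """Per-voxel generative variances and the analytic noise ceiling.

    The ceiling is the expected Pearson correlation between the noiseless
    signal and a single noisy measurement of it:
    ``sqrt(signal_variance / (signal_variance + noise_variance))``,
    which equals 1 when noise_variance is 0.
    """

    signal_variance: np.ndarray
    noise_variance: np.ndarray

    @property
    def analytic_ceiling(self) -> np.ndarray:
        total = self.signal_variance + self.noise_variance
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.sqrt(np.where(total > 0, self.signal_variance / total, 1.0))
        return c


@dataclass
class SyntheticNeuralSpec:
    n_participants: int
    n_voxels: int
    n_sentences: int
    noise_sd: float
    seed: int
    readout_weights: np.ndarray | None = None  # [units x voxels]; sampled if None
    readout_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_voxels, self.n_sentences) < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class NeuralBenchmark:
    """Per-participant voxel x sentence responses with group labels and a ceiling.

    ``responses[p]`` is a ``[n_voxels, n_sentences]`` array for participant p.
    ``experiments`` partitions sentence indices into experiment blocks.
    """

    responses: list[np.ndarray]
    voxel_groups: np.ndarray
    ceiling: float
    experiments: np.ndarray = field(default=None)  # block label per sentence

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("at least one participant required")
        n_sent = self.responses[0].shape[1]
        if self.experiments is None:
            self.experiments = np.zeros(n_sent, dtype=np.int64)
        if not 0 < self.ceiling <= 1:
            raise ValueError("ceiling must lie in (0, 1]")
        for r in self.responses:
            if r.shape[1] != n_sent:
                raise ValueError("all participants must cover the same sentences")

    @property
    def n_participants(self) -> int:
        return len(self.responses)


def generate_neural_benchmark(
    spec: SyntheticNeuralSpec, features: np.ndarray
) -> tuple[NeuralBenchmark, GroundTruth]:
    """Simulate multi-participant voxel responses from a shared linear readout.

    Every participant's voxel v sees ``(features @ W)[:, v]`` plus its own
    i.i.d. N(0, noise_sd^2) noise; the shared-signal / private-noise split is
    what makes the "average participant" noise ceiling analytic.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] != spec.n_sentences:
        raise ValueError("features must be [n_sentences x units]")
    rng = np.random.default_rng(spec.seed)
    n_units = features.shape[1]
    W = spec.readout_weights
    if W is None:
        W = rng.normal(0.0, spec.readout_scale / np.sqrt(n_units), size=(n_units, spec.n_voxels))
    else:
        W = np.asarray(W, dtype=float)
        if W.shape != (n_units, spec.n_voxels):
            raise ValueError("readout_weights must be [units x voxels]")
    signal = features @ W  # [sentences x voxels]
    responses = [
        (signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)).T
        for _ in range(spec.n_participants)
    ]
    truth = GroundTruth(
        signal_variance=signal.var(axis=0),
        noise_variance=np.full(spec.n_voxels, spec.noise_sd**2),
    )
    ceiling = float(np.median(truth.analytic_ceiling))
    # two equal-size experiment blocks in stimulus order, mirroring a
    # benchmark composed of two independent experiments
    blocks = (np.arange(spec.n_sentences) >= spec.n_sentences // 2).astype(np.int64)
    bench = NeuralBenchmark(
        responses=responses,
        voxel_groups=np.zeros(spec.n_voxels, dtype=np.int64),
        ceiling=max(ceiling, np.finfo(float).tiny),
        experiments=blocks,
    )
    return bench, truth


@dataclass(frozen=True)
class SyntheticBehavioralSpec:
    """Reading times affine in surprisal: RT = intercept + slope * s + noise,
    with ``outlier_fraction`` of values replaced by draws outside the
    [100 ms, 3000 ms] range (uniform over [0, 100) and (3000, 5000])."""

    intercept_ms: float
    slope_ms_per_bit: float
    noise_sd_ms: float
    outlier_fraction: float
    n_participants: int
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be nonnegative")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")


def generate_reading_times(
    spec: SyntheticBehavioralSpec,
    surprisal: np.ndarray,
    words: list[str] | None = None,
    sentence_ids: np.ndarray | None = None,
):
    """Per-participant word-level reading times from word surprisal (bits).

    ``words`` and ``sentence_ids`` optionally attach word strings and sentence
    structure to the stream (defaults: distinct placeholder words, one
    sentence). Returns a pandas DataFrame with columns
    (participant, story, sentence, word_index, word, rt_ms, is_outlier).
    """
    import pandas as pd

    surprisal = np.asarray(surprisal, dtype=float)
    if not np.all(np.isfinite(surprisal)):
        raise ValueError("surprisal must be finite")
    rng = np.random.default_rng(spec.seed)
    n = surprisal.size
    if words is None:
        words = [f"w{i}" for i in range(n)]
    if sentence_ids is None:
        sentence_ids = np.zeros(n, dtype=np.int64)
    sentence_ids = np.asarray(sentence_ids)
    if len(words) != n or sentence_ids.size != n:
        raise ValueError("words and sentence_ids must match surprisal length")
    # word_index restarts within each sentence
    word_index = np.zeros(n, dtype=np.int64)
    for s in np.unique(sentence_ids):
        m = sentence_ids == s
        word_index[m] = np.arange(m.sum())
    frames = []
    for p in range(spec.n_participants):
        rt = (
            spec.intercept_ms
            + spec.slope_ms_per_bit * surprisal
            + rng.normal(0.0, spec.noise_sd_ms, size=n)
        )
        is_out = np.zeros(n, dtype=bool)
        n_out = int(round(spec.outlier_fraction * n))
        if n_out:
            idx = rng.choice(n, size=n_out, replace=False)
            low = rng.random(n_out) < 0.5
            vals = np.where(
                low, rng.uniform(0.0, 100.0, n_out), rng.uniform(3000.0, 5000.0, n_out)
            )
            # keep strictly outside the inclusive [100, 3000] retention range
            vals = np.where(vals == 100.0, 99.9, vals)
            vals = np.where(vals == 3000.0, 3000.1, vals)
            rt[idx] = vals
            is_out[idx] = True
        frames.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "story": 0,
                    "sentence": sentence_ids,
                    "word_index": word_index,
                    "word": words,
                    "rt_ms": rt,
                    "is_outlier": is_out,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
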