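"""Configuration types for the causal transformer: architecture, weight
initialization, token-budget accounting, and checkpoint schedules."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TransformerConfig",
    "InitScheme",
    "TrainingBudget",
    "CheckpointSchedule",
    "tokens_seen",
    "steps_for_one_pass",
]


@dataclass(frozen=True)
class TransformerConfig:
    """Architecture of a unidirectional-attention (causal) transformer.

    The full-scale reference configuration is 12 layers of 768 units with a
    1,024-token context; desk-scale experiments use 2-4 layers of 32-128
    units, which preserve every architectural property under test.
    """

    n_layers: int = 12
    d_model: int = 768
    n_heads: int = 12
    d_ff: int = 3072
    context_size: int = 1024
    vocab_size: int = 50257

    def __post_init__(self) -> None:
        for name in ("n_layers", "d_model", "n_heads", "d_ff", "context_size", "vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass(frozen=True)
class InitScheme:
    """Weight initialization.

    ``default`` is the conventional scaled-normal transformer initialization:
    embedding / attention / feedforward / output weights ~ N(0, 0.02^2),
    biases 0, layer-norm gain 1 and bias 0.

    ``gaussian`` draws every weight — including the layer-norm gains and
    biases — from N(mean, sd^2). With the reference values (mean 0, sd 0.02)
    this is the controlled untrained variant used to isolate the contribution
    of architecture from that of a tuned initialization.
    """

    name: str = "default"
    mean: float = 0.0
    sd: float = 0.02

    def __post_init__(self) -> None:
        if self.name not in ("default", "gaussian"):
            raise ValueError(f"unknown init scheme {self.name!r}")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class TrainingBudget:
    """Exact token accounting for a training run.

    One optimizer step consumes
    ``context_tokens * batches_per_device * n_devices * grad_accumulations``
    tokens; e.g. 1,024 * 8 * 16 * 4 = 524,288 tokens per step.
    """

    context_tokens: int
    batches_per_device: int
    n_devices: int = 1
    grad_accumulations: int = 1
    n_steps: int = 0

    def __post_init__(self) -> None:
        for name in ("context_tokens", "batches_per_device", "n_devices", "grad_accumulations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")

    @property
    def tokens_per_step(self) -> int:
        return (
            self.context_tokens
            * self.batches_per_device
            * self.n_devices
            * self.grad_accumulations
        )


def tokens_seen(budget: TrainingBudget) -> int:
    """Total tokens consumed over ``budget.n_steps`` steps, exact integer."""
    return budget.tokens_per_step * budget.n_steps


def steps_for_one_pass(corpus_tokens: int, budget: TrainingBudget) -> float:
    """Number of optimizer steps needed for one full pass over a corpus
    (a real number; callers round for reporting)."""
    if corpus_tokens < 0:
        raise ValueError("corpus_tokens must be nonnegative")
    return corpus_tokens / budget.tokens_per_step


@dataclass(frozen=True)
class CheckpointSchedule:
    """Logarithmic checkpoint schedule: ``base_steps`` defines 100% and each
    multiplier scales it (reference multipliers: 0, 0.001, 0.01, 0.1, 1, 10,
    giving steps 0, 20, 200, 2,000, 20,000, 200,000 for base 20,000)."""

    base_steps: int
    multipliers: tuple[float, ...] = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0)

    def __post_init__(self) -> None:
        if self.base_steps < 1:
            raise ValueError("base_steps must be positive")
        if any(m < 0 for m in self.multipliers):
            raise ValueError("multipliers must be nonnegative")
        for m in self.multipliers:
            s = m * self.base_steps
            if abs(s - round(s)) > 1e-9:
                raise ValueError(f"multiplier {m} yields non-integer step {s}")
        object.__setattr__(self, "multipliers", tuple(self.multipliers))

    def steps(self) -> list[int]:
        """Strictly increasing deduplicated list of checkpoint steps."""
        return sorted({int(round(m * self.base_steps)) for m in self.multipliers})
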