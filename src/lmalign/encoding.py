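"""Cross-validated linear encoding of neural responses from LM activations.

The comparison pipeline: extract a per-sentence representation from each model
layer (the last word's activation, averaging multi-token words), split the
sentences into k contiguous near-equal folds, fit a least-squares linear map
from activations to voxel responses on the training folds, predict the
held-out sentences, and score each voxel by the fold-averaged Pearson
correlation between predicted and observed responses. Per participant, the
score is the median correlation over (language-responsive) voxels, averaged
over experiment blocks and divided by the noise ceiling. A layer sweep runs
the pipeline per layer and selects the layer with the highest
participant-median normalized score.

With more units than training sentences the least-squares problem is
underdetermined; the minimum-norm solution (via SVD-based ``lstsq``) is used,
with optional ridge regularization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import NeuralBenchmark

__all__ = [
    "FoldSpec",
    "PredictivityResult",
    "make_folds",
    "fit_linear_map",
    "predict_linear_map",
    "cross_validated_predictivity",
    "participant_score",
    "combine_and_normalize",
    "score_benchmark",
    "layer_sweep",
    "sentence_representation",
    "model_sentence_features",
    "pearson_columns",
    "save_neural_benchmark",
    "load_neural_benchmark",
]


@dataclass(frozen=True)
class FoldSpec:
    """Assignment of ``n_items`` items to ``k`` cross-validation folds."""

    n_items: int
    k: int
    assignment: np.ndarray  # fold index per item

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64)
        if a.size != self.n_items:
            raise ValueError("assignment must cover every item exactly once")
        if a.min() < 0 or a.max() >= self.k:
            raise ValueError("fold index out of range")
        object.__setattr__(self, "assignment", a)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)

    def sizes(self) -> list[int]:
        return [int((self.assignment == f).sum()) for f in range(self.k)]


def make_folds(n_items: int, k: int = 5) -> FoldSpec:
    """Contiguous near-equal folds in stimulus order.

    With remainder ``r = n_items % k``, the last ``r`` folds receive one extra
    item, e.g. 243 items in 5 folds gives sizes (48, 48, 49, 49, 49).
    """
    if k < 1:
        raise ValueError("k must be positive")
    if n_items < k:
        raise ValueError("need at least k items")
    base, r = divmod(n_items, k)
    sizes = [base + (1 if f >= k - r else 0) for f in range(k)]
    assignment = np.repeat(np.arange(k), sizes)
    return FoldSpec(n_items=n_items, k=k, assignment=assignment)


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in input")


def fit_linear_map(X: np.ndarray, Y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Least-squares weights (with intercept) mapping X [n x units] to
    Y [n x voxels]; returns [units + 1 x voxels], last row the intercept.

    Underdetermined systems get the minimum-norm solution; ``ridge > 0``
    switches to ridge regression on the augmented design.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    _check_finite(X, Y)
    A = np.hstack([X, np.ones((X.shape[0], 1))])
    if ridge > 0:
        d = A.shape[1]
        G = A.T @ A + ridge * np.eye(d)
        return np.linalg.solve(G, A.T @ Y)
    W, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return W


def predict_linear_map(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.hstack([X, np.ones((X.shape[0], 1))]) @ W


def pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two [n x m] matrices (NaN for
    zero-variance columns)."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    num = (A * B).sum(axis=0)
    den = np.sqrt((A * A).sum(axis=0) * (B * B).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def cross_validated_predictivity(
    X: np.ndarray, Y: np.ndarray, folds: FoldSpec, ridge: float = 0.0
) -> np.ndarray:
    """Fold-averaged per-voxel Pearson r between held-out predictions and
    observations, for activations X [items x units] and responses
    Y [items x voxels]."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if folds.n_items != X.shape[0]:
        raise ValueError("folds inconsistent with row count")
    rs = []
    for f in range(folds.k):
        test = folds.test_indices(f)
        if test.size < 3:
            raise ValueError("a fold has fewer than 3 test items")
        train = folds.train_indices(f)
        W = fit_linear_map(X[train], Y[train], ridge=ridge)
        pred = predict_linear_map(W, X[test])
        rs.append(pearson_columns(pred, Y[test]))
    return np.mean(rs, axis=0)


def participant_score(per_voxel_r: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Median per-voxel correlation over the selected voxels."""
    r = np.asarray(per_voxel_r, dtype=float)
    if mask is not None:
        r = r[np.asarray(mask)]
    if r.size == 0:
        raise ValueError("empty voxel group")
    return float(np.median(r))


def combine_and_normalize(block_scores, ceiling: float) -> float:
    """Mean over experiment blocks, divided by the noise ceiling."""
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    scores = np.asarray(block_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no block scores")
    return float(scores.mean() / ceiling)


@dataclass
class PredictivityResult:
    """Scores for one layer of one model on one benchmark."""

    layer: int
    per_voxel_r: list[np.ndarray]  # per participant, fold-averaged
    participant_raw: np.ndarray  # per participant, block-averaged median r
    participant_normalized: np.ndarray  # raw / ceiling
    median_normalized: float
    mad_normalized: float


def _score_participant(
    X: np.ndarray, responses: np.ndarray, experiments: np.ndarray, k: int, ridge: float
) -> tuple[np.ndarray, float]:
    """Per-voxel fold-averaged r (pooled over blocks) and the block-averaged
    median-over-voxels score for one participant."""
    Y = responses.T  # [sentences x voxels]
    block_scores = []
    per_voxel_blocks = []
    for block in np.unique(experiments):
        idx = np.flatnonzero(experiments == block)
        folds = make_folds(idx.size, k)
        r = cross_validated_predictivity(X[idx], Y[idx], folds, ridge=ridge)
        per_voxel_blocks.append(r)
        block_scores.append(participant_score(r))
    return np.mean(per_voxel_blocks, axis=0), float(np.mean(block_scores))


def score_benchmark(
    features: np.ndarray,
    benchmark: NeuralBenchmark,
    layer: int = 0,
    k: int = 5,
    ridge: float = 0.0,
) -> PredictivityResult:
    """Run the full comparison of one layer's sentence features against a
    neural benchmark; scores are normalized by the benchmark ceiling."""
    raws, voxel_rs = [], []
    for resp in benchmark.responses:
        r, raw = _score_participant(features, resp, benchmark.experiments, k, ridge)
        voxel_rs.append(r)
        raws.append(raw)
    raws = np.asarray(raws)
    normalized = raws / benchmark.ceiling
    return PredictivityResult(
        layer=layer,
        per_voxel_r=voxel_rs,
        participant_raw=raws,
        participant_normalized=normalized,
        median_normalized=float(np.median(normalized)),
        mad_normalized=float(np.median(np.abs(normalized - np.median(normalized)))),
    )


def layer_sweep(
    features_per_layer: list[np.ndarray],
    benchmark: NeuralBenchmark,
    k: int = 5,
    ridge: float = 0.0,
) -> tuple[list[PredictivityResult], int]:
    """Score every layer; the best layer maximizes the participant-median
    normalized score (ties broken by the lowest layer index)."""
    if not features_per_layer:
        raise ValueError("need at least one layer")
    results = [
        score_benchmark(X, benchmark, layer=i, k=k, ridge=ridge)
        for i, X in enumerate(features_per_layer)
    ]
    scores = np.asarray([r.median_normalized for r in results])
    best = int(np.argmax(scores))  # argmax returns the first (lowest) maximum
    return results, best


def sentence_representation(
    activations: list[list[np.ndarray]], last_word_spans: list[tuple[int, int]]
) -> list[np.ndarray]:
    """Per-layer sentence representations from per-sentence activations.

    ``activations[s][l]`` is the [tokens x units] activation of layer l on
    sentence s; ``last_word_spans[s]`` is the half-open token span (start,
    end) of the sentence's final word. The sentence representation is the
    final word's activation, averaging across tokens when the word spans
    several (the mean makes it invariant to token order within the word).

    Returns a list of [sentences x units] matrices, one per layer.
    """
    if len(activations) != len(last_word_spans):
        raise ValueError("one span per sentence required")
    if not activations:
        raise ValueError("no sentences")
    n_layers = len(activations[0])
    out = []
    for layer in range(n_layers):
        rows = []
        for acts, (start, end) in zip(activations, last_word_spans):
            if end <= start:
                raise ValueError("empty word span")
            rows.append(acts[layer][start:end].mean(axis=0))
        out.append(np.asarray(rows))
    return out


def model_sentence_features(model, sentences: list[list[list[int]]]) -> list[np.ndarray]:
    """Extract per-layer sentence features from a model.

    Each sentence is a list of words, each word a list of token ids; the
    sentence is presented to the model in isolation and the last word's
    activation (token-averaged) is taken at every layer.
    """
    acts, spans = [], []
    for sent in sentences:
        if not sent or any(len(w) == 0 for w in sent):
            raise ValueError("empty sentence or word")
        tokens = [t for w in sent for t in w]
        acts.append(model.layer_activations(np.asarray(tokens)))
        n_last = len(sent[-1])
        spans.append((len(tokens) - n_last, len(tokens)))
    return sentence_representation(acts, spans)


# ------------------------------------------------------------------ storage


def save_neural_benchmark(path, benchmark: NeuralBenchmark) -> None:
    """HDF5 schema: datasets ``responses/p<i>`` ([voxels x sentences] per
    participant), ``voxel_groups``, ``experiments``; root attribute
    ``ceiling``."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["ceiling"] = benchmark.ceiling
        f.create_dataset("voxel_groups", data=np.asarray(benchmark.voxel_groups))
        f.create_dataset("experiments", data=np.asarray(benchmark.experiments))
        g = f.create_group("responses")
        for i, resp in enumerate(benchmark.responses):
            g.create_dataset(f"p{i}", data=resp)


def load_neural_benchmark(path) -> NeuralBenchmark:
    import h5py

    with h5py.File(path, "r") as f:
        n = len(f["responses"])
        responses = [np.asarray(f["responses"][f"p{i}"]) for i in range(n)]
        return NeuralBenchmark(
            responses=responses,
            voxel_groups=np.asarray(f["voxel_groups"]),
            ceiling=float(f.attrs["ceiling"]),
            experiments=np.asarray(f["experiments"]),
        )
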