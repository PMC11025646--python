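"""Reading-time predictivity.

Self-paced reading times are filtered to the [100 ms, 3,000 ms] range
(inclusive), each participant's word occurrences are split into k
cross-validation folds under two constraints — repeated occurrences of the
same word type within a sentence share a fold, and each sentence's words are
spread across folds as evenly as possible — and reading times are regressed
on last-layer word representations. The per-participant score is the
fold-averaged Pearson correlation between predicted and observed reading
times, divided by the benchmark's noise ceiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encoding import FoldSpec, fit_linear_map, predict_linear_map

__all__ = [
    "RT_MIN_MS",
    "RT_MAX_MS",
    "filter_rts",
    "word_folds",
    "rt_predictivity",
    "load_behavioral_csv",
    "save_behavioral_csv",
]

RT_MIN_MS = 100.0
RT_MAX_MS = 3000.0

_COLUMNS = ["participant", "story", "sentence", "word_index", "word", "rt_ms"]


def filter_rts(benchmark: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Retain records with 100 <= RT <= 3000 ms (boundaries inclusive).

    Returns the filtered frame and the number of removed records. Idempotent:
    filtering a filtered frame removes nothing.
    """
    keep = (benchmark["rt_ms"] >= RT_MIN_MS) & (benchmark["rt_ms"] <= RT_MAX_MS)
    return benchmark.loc[keep].reset_index(drop=True), int((~keep).sum())


def word_folds(records: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldSpec:
    """Assign one participant's word occurrences to k folds.

    Constraints: (a) occurrences of the same word type within a sentence are
    assigned to the same fold, so a word never appears in both the train and
    test side of a split through within-sentence repetition; (b) within each
    sentence, occurrences are spread across folds as evenly as possible.

    Greedy assignment: per sentence, word-type groups (largest first, ties
    shuffled by seed) go to the fold currently least loaded within the
    sentence, then globally.
    """
    n = len(records)
    if n < k:
        raise ValueError("fewer word occurrences than folds")
    rng = np.random.default_rng(seed)
    assignment = np.full(n, -1, dtype=np.int64)
    global_load = np.zeros(k, dtype=np.int64)
    pos = records.reset_index(drop=True)
    for _, sent in pos.groupby(["story", "sentence"], sort=True):
        groups: dict[str, list[int]] = {}
        for idx, word in zip(sent.index, sent["word"]):
            groups.setdefault(word, []).append(idx)
        items = list(groups.items())
        order = rng.permutation(len(items))
        items = sorted(
            (items[i] for i in order), key=lambda kv: -len(kv[1])
        )  # stable: keeps the seeded shuffle among equal-sized groups
        sent_load = np.zeros(k, dtype=np.int64)
        for _, idxs in items:
            # least loaded within the sentence, then globally, then lowest id
            f = int(np.lexsort((np.arange(k), global_load, sent_load))[0])
            assignment[idxs] = f
            sent_load[f] += len(idxs)
            global_load[f] += len(idxs)
    return FoldSpec(n_items=n, k=k, assignment=assignment)


def rt_predictivity(
    representations: np.ndarray,
    filtered: pd.DataFrame,
    ceiling: float,
    k: int = 5,
    seed: int = 0,
    ridge: float = 0.0,
) -> pd.DataFrame:
    """Per-participant ceiling-normalized reading-time predictivity.

    ``representations`` has one row per record of ``filtered`` (last-layer
    word representations, token-averaged for multi-token words). Returns a
    frame with columns (participant, raw_r, normalized).
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    representations = np.asarray(representations, dtype=float)
    if representations.shape[0] != len(filtered):
        raise ValueError("one representation row per retained record required")
    rows = []
    for pid, grp in filtered.groupby("participant", sort=True):
        loc = grp.index.to_numpy()
        X = representations[loc]
        y = grp["rt_ms"].to_numpy(dtype=float)
        folds = word_folds(grp.reset_index(drop=True), k=k, seed=seed)
        rs = []
        for f in range(folds.k):
            test = folds.test_indices(f)
            train = folds.train_indices(f)
            if test.size < 3:
                raise ValueError("a fold has fewer than 3 test items")
            W = fit_linear_map(X[train], y[train][:, None], ridge=ridge)
            pred = predict_linear_map(W, X[test])[:, 0]
            c = np.corrcoef(pred, y[test])[0, 1]
            rs.append(c)
        raw = float(np.mean(rs))
        rows.append({"participant": pid, "raw_r": raw, "normalized": raw / ceiling})
    return pd.DataFrame(rows)


def load_behavioral_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return frame


def save_behavioral_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)
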