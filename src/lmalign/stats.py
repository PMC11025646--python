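"""Statistical comparisons and report export.

Model (or checkpoint) participant scores are compared with independent
two-sample t tests (pooled-variance Student's t by default, Welch optional)
against a reference model's scores, with Bonferroni correction over the
number of comparisons. Summary statistics are the median across participants
and the unscaled median absolute deviation (an error bar, not a standard
deviation estimate, so no 1.4826 consistency factor).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ScoreSummary",
    "two_sample_ttest",
    "bonferroni",
    "summarize_scores",
    "compare_to_reference",
    "report",
]


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    df: float
    p_value: float
    p_corrected: float
    n_comparisons: int


@dataclass(frozen=True)
class ScoreSummary:
    median: float
    mad: float  # unscaled median absolute deviation
    n: int


def two_sample_ttest(
    scores_a, scores_b, equal_var: bool = True, n_comparisons: int = 1
) -> TestResult:
    """Independent two-sample t test (two-sided); pooled-variance Student's t
    unless ``equal_var=False`` (Welch).

    Degenerate inputs: zero pooled variance with equal means gives t = 0,
    p = 1; zero pooled variance with unequal means is an error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
            df = a.size + b.size - 2
            return TestResult(t, float(df), p, bonferroni(p, n_comparisons), n_comparisons)
        raise ValueError("zero variance with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    p = float(res.pvalue)
    return TestResult(
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=p,
        p_corrected=bonferroni(p, n_comparisons),
        n_comparisons=n_comparisons,
    )


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m); never decreases a p-value."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def summarize_scores(scores) -> ScoreSummary:
    scores = np.asarray(scores, dtype=float)
    if scores.size < 1:
        raise ValueError("need at least one score")
    med = float(np.median(scores))
    return ScoreSummary(median=med, mad=float(np.median(np.abs(scores - med))), n=scores.size)


def compare_to_reference(
    score_sets: dict[str, np.ndarray], reference: np.ndarray, equal_var: bool = True
) -> pd.DataFrame:
    """t test of every model's participant scores against the reference
    model's, Bonferroni-corrected for the number of models compared."""
    m = len(score_sets)
    rows = []
    for name in sorted(score_sets):
        res = two_sample_ttest(score_sets[name], reference, equal_var=equal_var, n_comparisons=m)
        rows.append({"model": name, **asdict(res)})
    return pd.DataFrame(rows)


def report(run_results: pd.DataFrame, out_dir, manifest: dict | None = None) -> dict:
    """Export score tables and a JSON run manifest.

    ``run_results`` is a tidy frame with at least columns (model, layer,
    participant, raw, normalized) and optionally (perplexity, voxel_group).
    Writes, with deterministic ordering:

    * ``scores.csv`` — the input rows sorted by (model, layer, participant);
    * ``layer_summary.csv`` — per (model, layer): median and MAD of
      normalized scores across participants;
    * ``perplexity_scores.csv`` — one row per model: perplexity vs. the
      median normalized score (only if a perplexity column is present);
    * ``manifest.json`` — seeds/configs passed by the caller.

    Returns the paths written.
    """
    required = {"model", "layer", "participant", "raw", "normalized"}
    missing = required - set(run_results.columns)
    if missing:
        raise ValueError(f"missing columns in run results: {sorted(missing)}")
    if len(run_results) == 0:
        raise ValueError("no completed evaluations to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    scores = run_results.sort_values(["model", "layer", "participant"]).reset_index(drop=True)
    paths["scores"] = out / "scores.csv"
    scores.to_csv(paths["scores"], index=False)

    rows = []
    for (model, layer), grp in scores.groupby(["model", "layer"], sort=True):
        s = summarize_scores(grp["normalized"].to_numpy())
        rows.append(
            {"model": model, "layer": layer, "median_normalized": s.median, "mad": s.mad, "n": s.n}
        )
    paths["layer_summary"] = out / "layer_summary.csv"
    pd.DataFrame(rows).to_csv(paths["layer_summary"], index=False)

    if "perplexity" in scores.columns:
        rows = []
        for model, grp in scores.groupby("model", sort=True):
            rows.append(
                {
                    "model": model,
                    "perplexity": float(grp["perplexity"].iloc[0]),
                    "median_normalized": float(
                        grp.groupby("layer")["normalized"].median().max()
                    ),
                }
            )
        paths["perplexity_scores"] = out / "perplexity_scores.csv"
        pd.DataFrame(rows).to_csv(paths["perplexity_scores"], index=False)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as f:
        json.dump(manifest or {}, f, indent=2, sort_keys=True)
    return paths
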