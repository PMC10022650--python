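"""Human-coder validation of LSS scores.

Three independent coders label each sampled document "good", "neutral" or
"bad" (the emotional state it conveys).  The labels aggregate to an integer
scale from -2 (unanimously good) to +2 (unanimously bad); category-wise mean
LSS scores and the Pearson correlation between the two scales quantify how
well the automatic scale tracks human judgment.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LABELS",
    "aggregate_annotations",
    "aggregate_annotation_table",
    "category_summary",
    "score_annotation_correlation",
]

LABELS = ("good", "neutral", "bad")


def aggregate_annotations(labels: Sequence[str]) -> int:
    """Collapse exactly three coder labels into a -2..+2 human score.

    +2 / -2 when all three say "bad" / "good"; +1 / -1 when exactly two say
    "bad" / "good"; 0 for every other outcome.  Order of coders never
    matters.
    """
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 labels, got {len(labels)}")
    bad = set(labels) - set(LABELS)
    if bad:
        raise ValueError(f"unknown label(s) {sorted(bad)}; expected one of {LABELS}")
    counts = Counter(labels)
    if counts["bad"] == 3:
        return 2
    if counts["good"] == 3:
        return -2
    if counts["bad"] == 2:
        return 1
    if counts["good"] == 2:
        return -1
    return 0


def aggregate_annotation_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a (doc_id, coder1, coder2, coder3) table to human scores."""
    required = {"doc_id", "coder1", "coder2", "coder3"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    scores = [
        aggregate_annotations((r.coder1, r.coder2, r.coder3))
        for r in annotations.itertuples(index=False)
    ]
    return pd.DataFrame({"doc_id": annotations["doc_id"].to_numpy(), "human_score": scores})


def _join(aggregated: pd.DataFrame, scored: pd.DataFrame) -> pd.DataFrame:
    joined = aggregated.merge(scored[["doc_id", "lss_score"]], on="doc_id", how="inner")
    joined = joined.dropna(subset=["lss_score"])
    if joined.empty:
        raise ValueError("no annotated documents with an LSS score")
    return joined


def category_summary(
    aggregated: pd.DataFrame, scored: pd.DataFrame, z: float = 1.96
) -> pd.DataFrame:
    """Mean LSS score per human-score level with normal-approximation 95% CI.

    Returns one row per occupied level: level, n, mean_lss, ci_low, ci_high.
    For n = 1 the SD is undefined and the CI is flagged degenerate (NaN
    bounds).  Levels with no documents are simply absent.
    """
    joined = _join(aggregated, scored)
    rows = []
    for level, grp in joined.groupby("human_score"):
        vals = grp["lss_score"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            sem = float(vals.std(ddof=1)) / np.sqrt(n)
            lo, hi = mean - z * sem, mean + z * sem
        else:
            lo = hi = float("nan")
        rows.append({"level": int(level), "n": n, "mean_lss": mean,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).sort_values("level").reset_index(drop=True)


def score_annotation_correlation(
    aggregated: pd.DataFrame, scored: pd.DataFrame
) -> float:
    """Pearson correlation between human scores and LSS scores."""
    joined = _join(aggregated, scored)
    if len(joined) < 3:
        raise ValueError("need at least 3 annotated, scored documents")
    h = joined["human_score"].to_numpy(dtype=float)
    s = joined["lss_score"].to_numpy(dtype=float)
    if np.std(h) == 0 or np.std(s) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(stats.pearsonr(h, s).statistic)
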