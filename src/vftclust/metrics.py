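"""Cluster characteristics with the standard inclusion conventions.

Conventions shared by every clustering method:

* mean cluster size averages over all clusters *including singletons*
  (cluster size = word count minus 1, so the closed form
  ``mean_cluster_size = n_tokens / (switches + 1) - 1`` holds exactly);
* switches = number of clusters (including singletons) minus 1;
* rule violations stay in the clustered sequence but are removed from the
  total word count;
* mean sequential relatedness averages the defined (non-OOV) adjacent
  pair scores over the full sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clusters import Clustering
from .relatedness import RelatednessScore
from .transcripts import Transcript

__all__ = ["ClusterMetrics", "cluster_metrics", "metrics_table", "summarize_metrics"]

METRIC_COLUMNS = [
    "transcript_id", "task", "method", "total_word_count",
    "mean_cluster_size", "switches", "mean_sequential_relatedness",
    "n_oov_pairs",
]


@dataclass(frozen=True)
class ClusterMetrics:
    total_word_count: int
    mean_cluster_size: float | None  # None for an empty transcript
    switches: int | None
    mean_sequential_relatedness: float | None
    n_oov_pairs: int
    method: str


def cluster_metrics(
    transcript: Transcript,
    clustering: Clustering,
    scores: Sequence[RelatednessScore] | None = None,
) -> ClusterMetrics:
    """Compute the cluster characteristics of one transcript.

    ``scores``, when given, must hold one relatedness score per adjacent
    token pair (length ``n_tokens - 1``).
    """
    n = len(transcript.tokens)
    if clustering.n_tokens != n:
        raise ValueError(
            f"clustering covers {clustering.n_tokens} tokens, transcript has {n}"
        )
    total = sum(1 for t in transcript.tokens if not t.is_violation)
    if n == 0:
        mean_size, switches = None, None
    else:
        mean_size = sum(clustering.sizes) / clustering.n_clusters
        switches = clustering.switches
    mean_rel: float | None = None
    n_oov = 0
    if scores is not None:
        if len(scores) != max(n - 1, 0):
            raise ValueError("scores must have one entry per adjacent token pair")
        defined = [s.value for s in scores if not s.oov]
        n_oov = sum(1 for s in scores if s.oov)
        if defined:
            mean_rel = float(np.mean(defined))
    return ClusterMetrics(
        total_word_count=total,
        mean_cluster_size=mean_size,
        switches=switches,
        mean_sequential_relatedness=mean_rel,
        n_oov_pairs=n_oov,
        method=clustering.method,
    )


def metrics_table(
    records: Sequence[tuple[Transcript, Clustering, Sequence[RelatednessScore] | None]],
) -> pd.DataFrame:
    """One row of cluster characteristics per (transcript, clustering)."""
    rows = []
    for item in records:
        tr, cl, scores = item if len(item) == 3 else (*item, None)
        m = cluster_metrics(tr, cl, scores)
        rows.append(
            {
                "transcript_id": tr.transcript_id,
                "task": tr.task,
                "method": m.method,
                "total_word_count": m.total_word_count,
                "mean_cluster_size": m.mean_cluster_size,
                "switches": m.switches,
                "mean_sequential_relatedness": m.mean_sequential_relatedness,
                "n_oov_pairs": m.n_oov_pairs,
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def summarize_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per task/method column group."""
    value_cols = [
        "total_word_count", "mean_cluster_size", "switches",
        "mean_sequential_relatedness",
    ]
    if table.empty:
        return pd.DataFrame(columns=["task", "method", "metric", "mean", "sd", "n"])
    out = []
    for (task, method), grp in table.groupby(["task", "method"], sort=True):
        for col in value_cols:
            vals = grp[col].dropna().astype(float)
            if len(vals) == 0:
                continue
            out.append(
                {"task": task, "method": method, "metric": col,
                 "mean": float(vals.mean()),
                 "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                 "n": int(len(vals))}
            )
    return pd.DataFrame(out)
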