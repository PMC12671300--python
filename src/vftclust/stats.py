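"""Association statistics relating cluster characteristics to
neuropsychological scores.

Pearson correlation is the default; Spearman rank correlation is used for
ordinal scales (e.g. a dysarthria item against the speech-recognition
error rate); a Mann-Whitney U test compares groups with non-normal
scores.  A correlation network summarizes the significant associations:
edges between cluster characteristics and test scores are kept, edges
between two test scores are dropped, test scores with no significant link
to any cluster characteristic are dropped, and characteristic-
characteristic edges are retained but unlabeled.  P values are unadjusted
by default (an optional Benjamini-Hochberg mode is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "pearson",
    "spearman",
    "mann_whitney_u",
    "correlation_network",
    "edges_to_dot",
]


@dataclass(frozen=True)
class AssociationResult:
    x: str
    y: str
    method: str  # "pearson", "spearman" or "mannwhitney"
    statistic: float
    p_value: float
    n: int


def _pairwise_complete(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def pearson(x: Sequence[float], y: Sequence[float], xname: str = "x", yname: str = "y") -> AssociationResult:
    """Product-moment correlation; two-sided p from the t transform with
    n-2 degrees of freedom.  Missing values are dropped pairwise."""
    xs, ys = _pairwise_complete(x, y)
    if len(xs) < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(xs, ys)
    return AssociationResult(xname, yname, "pearson", float(res.statistic),
                             float(res.pvalue), len(xs))


def spearman(x: Sequence[float], y: Sequence[float], xname: str = "x", yname: str = "y") -> AssociationResult:
    """Rank correlation with midrank ties (Pearson on ranks)."""
    xs, ys = _pairwise_complete(x, y)
    if len(xs) < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.spearmanr(xs, ys)
    return AssociationResult(xname, yname, "spearman", float(res.statistic),
                             float(res.pvalue), len(xs))


def mann_whitney_u(a: Sequence[float], b: Sequence[float], xname: str = "a", yname: str = "b") -> AssociationResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is U for the first group.  The p value is
    computed by exact enumeration for small tie-free samples (both groups
    of 8 or fewer) and by the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return AssociationResult(xname, yname, "mannwhitney", float(res.statistic),
                             float(res.pvalue), len(a) + len(b))


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, pvals[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj


def correlation_network(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[dict]:
    """Edge list of significant Pearson correlations, filtered for display.

    ``metrics``: participant-indexed cluster characteristics; ``scores``:
    participant-indexed neuropsychological test results.  Both are wide
    tables sharing their index.  Edges with p < alpha are computed for
    all variable pairs, then: test-test edges are dropped; tests with no
    surviving edge to a metric are dropped entirely; metric-metric edges
    are kept but flagged unlabeled.  Edge weight is |r|.
    """
    common = metrics.index.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("metrics and scores share no participant ids")
    metrics = metrics.loc[common]
    scores = scores.loc[common]
    mcols = list(metrics.columns)
    tcols = list(scores.columns)
    wide = pd.concat([metrics, scores], axis=1)

    candidates = []
    cols = mcols + tcols
    for i, u in enumerate(cols):
        for v in cols[i + 1 :]:
            if u in tcols and v in tcols:
                continue  # never shown: correlations between two tests
            try:
                res = pearson(wide[u], wide[v], u, v)
            except ValueError:
                continue
            candidates.append(res)
    if not candidates:
        return []
    pvals = np.array([c.p_value for c in candidates])
    if adjust:
        pvals = _bh_adjust(pvals)
    edges = [
        {"x": c.x, "y": c.y, "r": c.statistic, "p": float(p), "n": c.n,
         "weight": abs(c.statistic),
         "kind": "metric-metric" if (c.x in mcols and c.y in mcols) else "metric-test",
         "labeled": not (c.x in mcols and c.y in mcols)}
        for c, p in zip(candidates, pvals)
        if p < alpha
    ]
    # drop tests isolated from every cluster characteristic
    linked_tests = {
        e["x"] for e in edges if e["kind"] == "metric-test" and e["x"] in tcols
    } | {e["y"] for e in edges if e["kind"] == "metric-test" and e["y"] in tcols}
    return [
        e for e in edges
        if e["kind"] == "metric-metric"
        or (e["x"] in linked_tests or e["x"] in mcols)
        and (e["y"] in linked_tests or e["y"] in mcols)
    ]


def edges_to_dot(edges: list[dict]) -> str:
    """Render an edge list as a Graphviz DOT graph (weights on edges,
    correlation labels only on metric-test edges)."""
    lines = ["graph correlations {"]
    for e in edges:
        label = f' [label="{e["r"]:.2f}"]' if e.get("labeled") else ""
        lines.append(f'  "{e["x"]}" -- "{e["y"]}"{label};')
    lines.append("}")
    return "\n".join(lines)
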