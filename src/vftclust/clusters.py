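"""Shared cluster/clustering containers used by all clustering methods.

A clustering is an ordered partition of a produced word sequence into
contiguous clusters.  Cluster size follows the Troyer convention: the
number of words in the cluster minus one, so a singleton has size 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Cluster", "Clustering", "segment_by_links"]


@dataclass(frozen=True)
class Cluster:
    """Half-open span [start, end) of token indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid cluster span [{self.start}, {self.end})")

    @property
    def size(self) -> int:
        """Word count in the cluster minus 1 (singleton -> 0)."""
        return self.end - self.start - 1


@dataclass(frozen=True)
class Clustering:
    """Ordered, contiguous, covering partition of ``n_tokens`` positions.

    ``links`` records, for each adjacent pair (i, i+1), why the pair was
    joined: a frozenset of matched rule names / shared categories, or a
    relatedness-score marker.  An empty set means the pair was not joined
    (a switch occurs there).
    """

    method: str  # "list_based", "rule_based" or "relatedness"
    clusters: tuple[Cluster, ...]
    n_tokens: int
    links: tuple[frozenset, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        object.__setattr__(self, "links", tuple(self.links))
        pos = 0
        for c in self.clusters:
            if c.start != pos:
                raise ValueError("clusters must be contiguous and ordered")
            pos = c.end
        if pos != self.n_tokens:
            raise ValueError("clusters must cover all tokens")
        if self.links and len(self.links) != max(self.n_tokens - 1, 0):
            raise ValueError("links must have one entry per adjacent pair")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    @property
    def switches(self) -> int:
        """Number of clusters (including singletons) minus 1."""
        return max(self.n_clusters - 1, 0)

    def labels(self) -> list[int]:
        """Per-token cluster index (useful for partition comparisons)."""
        out = []
        for k, c in enumerate(self.clusters):
            out.extend([k] * (c.end - c.start))
        return out


def segment_by_links(method: str, links: list[frozenset], n_tokens: int) -> Clustering:
    """Build a clustering from adjacent-pair join decisions.

    ``links[i]`` non-empty means tokens i and i+1 belong to one cluster;
    maximal joined runs form clusters and unjoined tokens are singletons.
    """
    clusters: list[Cluster] = []
    if n_tokens > 0:
        start = 0
        for i, link in enumerate(links):
            if not link:
                clusters.append(Cluster(start, i + 1))
                start = i + 1
        clusters.append(Cluster(start, n_tokens))
    return Clustering(method=method, clusters=tuple(clusters), n_tokens=n_tokens,
                      links=tuple(links))
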