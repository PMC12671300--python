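"""Semantic-relatedness clustering: word embeddings, cosine relatedness,
threshold segmentation, and hyperparameter grid search.

The core idea: train a word2vec model on a large text corpus so that each
word is a point in a high-dimensional semantic space; the relatedness of
two words is the cosine of their vectors.  A fluency transcript is read
as the sequence of its adjacent word pairs, and a cluster is a maximal
run in which every sequential pair's relatedness exceeds a fixed
threshold (0.40 for the semantic task, 0.30 for the phonematic task by
default).  Hyperparameters (dimensionality, window, algorithm) and the
threshold are chosen by a grid search supervised by category-list
membership of random word pairs, so that no patient data enters model
selection.
"""

from __future__ import annotations

import gzip
import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._normalize import normalize_word
from .clusters import Clustering, segment_by_links
from .lexicon import CategoryLexicon, sample_supervision_pairs
from .word2vec import train_word2vec

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "EmbeddingModel",
    "RelatednessScore",
    "ThresholdConfig",
    "GridSearchResult",
    "DEFAULT_THETA",
    "train_embeddings",
    "relatedness",
    "sequential_relatedness",
    "identify_relatedness_clusters",
    "sweep_thresholds",
    "evaluate_pair_scores",
    "default_grid",
    "grid_search",
    "load_word2vec_text",
    "save_word2vec_text",
]

#: Cluster-defining relatedness thresholds per task.
DEFAULT_THETA = {"semantic": 0.40, "phonematic": 0.30}

#: Theta values evaluated in threshold sweeps: 0.00, 0.01, ..., 1.00.
THETA_GRID = np.round(np.arange(0, 101) * 0.01, 2)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Word2vec training hyperparameters.

    Defaults reflect the configuration selected by grid search for both
    fluency tasks: 500 dimensions, window 10, skip-gram.  ``min_count``
    and ``epochs`` follow common word2vec practice and are recorded in
    model metadata.
    """

    dimensions: int = 500
    window: int = 10
    algorithm: str = "skipgram"  # or "cbow"
    min_count: int = 5
    epochs: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.dimensions, self.window, self.min_count, self.epochs) < 1:
            raise ValueError("dimensions, window, min_count and epochs must be >= 1")
        if self.algorithm not in ("skipgram", "cbow"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass(frozen=True)
class ThresholdConfig:
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")

    @classmethod
    def for_task(cls, task: str) -> "ThresholdConfig":
        return cls(DEFAULT_THETA[task])


@dataclass(frozen=True)
class RelatednessScore:
    """Cosine relatedness of a word pair, or an out-of-vocabulary marker."""

    value: float | None
    oov: bool = False

    def __post_init__(self) -> None:
        if (self.value is None) != self.oov:
            raise ValueError("value must be present exactly when not OOV")


class EmbeddingModel:
    """Vocabulary plus fixed-dimension vectors with a cosine contract.

    Lookup tries the exact normalized form, then a capitalized variant
    (German nouns are capitalized in typical training corpora), then
    reports out-of-vocabulary.
    """

    def __init__(
        self,
        vocab: dict[str, int],
        vectors: np.ndarray,
        config: EmbeddingConfig | None = None,
    ) -> None:
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(vocab):
            raise ValueError("vectors must be a (len(vocab), dim) matrix")
        self.vocab = dict(vocab)
        self.vectors = vectors
        self.config = config
        norms = np.linalg.norm(vectors, axis=1)
        if len(vocab) and np.any(norms == 0):
            raise ValueError("zero-norm vector in model")
        self._unit = vectors / norms[:, None] if len(vocab) else vectors

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def index(self, word: str) -> int | None:
        w = normalize_word(word)
        idx = self.vocab.get(w)
        if idx is None and w:
            idx = self.vocab.get(w[0].upper() + w[1:])
        if idx is None:
            idx = self.vocab.get(word)
        return idx

    def __contains__(self, word: str) -> bool:
        return self.index(word) is not None

    def vector(self, word: str) -> np.ndarray | None:
        idx = self.index(word)
        return None if idx is None else self.vectors[idx]


def train_embeddings(
    corpus: Iterable[Sequence[str]] | str,
    cfg: EmbeddingConfig,
) -> EmbeddingModel:
    """Train a word2vec model on a tokenized-sentence corpus.

    ``corpus`` is a sequence of token lists, or a path to a plain-text
    file with one whitespace-tokenized sentence per line.  Training is
    single-threaded and bit-reproducible under ``cfg.seed``.
    """
    if isinstance(corpus, str):
        with open(corpus, encoding="utf-8") as fh:
            sentences = [line.split() for line in fh if line.strip()]
    else:
        sentences = [list(s) for s in corpus]
    vocab, vecs = train_word2vec(
        sentences,
        dim=cfg.dimensions,
        window=cfg.window,
        algorithm=cfg.algorithm,
        min_count=cfg.min_count,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )
    return EmbeddingModel(vocab, vecs, cfg)


def relatedness(w1: str, w2: str, model: EmbeddingModel) -> RelatednessScore:
    """Cosine of the two word vectors; OOV when either word is unknown."""
    v1, v2 = model.vector(w1), model.vector(w2)
    if v1 is None or v2 is None:
        return RelatednessScore(None, oov=True)
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        raise ValueError("zero-norm vector encountered")
    return RelatednessScore(float(np.dot(v1, v2) / denom))


def sequential_relatedness(
    words: Sequence[str], model: EmbeddingModel
) -> list[RelatednessScore]:
    """Relatedness of each adjacent word pair (word1-word2, word2-word3, ...)."""
    if len(words) < 2:
        raise ValueError("need at least 2 words for sequential relatedness")
    return [relatedness(words[i], words[i + 1], model) for i in range(len(words) - 1)]


def identify_relatedness_clusters(
    words: Sequence[str],
    model: EmbeddingModel,
    thr: ThresholdConfig,
) -> Clustering:
    """Threshold segmentation of a word sequence into semantic clusters.

    Adjacent words join one cluster iff their relatedness is defined and
    strictly greater than theta; out-of-vocabulary pairs never join.
    """
    if len(words) == 0:
        return Clustering("relatedness", (), 0)
    scores = (
        sequential_relatedness(words, model) if len(words) > 1 else []
    )
    links = [
        frozenset({f"relatedness={s.value:.6f}"})
        if (not s.oov and s.value > thr.theta)
        else frozenset()
        for s in scores
    ]
    return segment_by_links("relatedness", links, len(words))


def segment_scores(scores: Sequence[float | None], theta: float) -> Clustering:
    """Threshold segmentation directly from a sequence of pair scores
    (``None`` marks an out-of-vocabulary pair)."""
    links = [
        frozenset({"joined"}) if (s is not None and s > theta) else frozenset()
        for s in scores
    ]
    return segment_by_links("relatedness", links, len(scores) + 1)


# ---------------------------------------------------------------------------
# Hyperparameter optimization

@dataclass(frozen=True)
class GridSearchResult:
    best_config: EmbeddingConfig
    best_theta: float
    best_score: float
    table: list[dict]  # one row per (config, theta)
    n_pairs: int
    n_oov_pairs: int
    seed: int


def _classification_score(labels: np.ndarray, preds: np.ndarray, metric: str) -> float:
    tp = np.sum(preds & labels)
    tn = np.sum(~preds & ~labels)
    fp = np.sum(preds & ~labels)
    fn = np.sum(~preds & labels)
    if metric == "balanced_accuracy":
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        return float((sens + spec) / 2)
    if metric == "accuracy":
        return float((tp + tn) / len(labels))
    if metric == "f1":
        return float(2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else 0.0
    raise ValueError(f"unknown metric {metric!r}")


def sweep_thresholds(
    scores: Sequence[float],
    labels: Sequence[bool],
    metric: str = "balanced_accuracy",
) -> tuple[float, float, list[tuple[float, float]]]:
    """Sweep theta over {0.00, 0.01, ..., 1.00}, classifying a pair as
    same-list iff score > theta; returns (best_theta, best_score, table).

    When several thetas tie on the best score (a plateau, typical for
    well-separated classes), the middle theta of the plateau is returned:
    a threshold deep inside the plateau transfers better to new word
    pairs than one at its edge.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    table = []
    for theta in THETA_GRID:
        preds = scores > theta
        table.append((float(theta), _classification_score(labels, preds, metric)))
    best = max(sc for _, sc in table)
    plateau = [th for th, sc in table if sc == best]
    return plateau[len(plateau) // 2], best, table


def evaluate_pair_scores(
    model: EmbeddingModel,
    pairs: Sequence[tuple[str, str, bool]],
) -> tuple[list[float], list[bool], int]:
    """Score supervision pairs with a model; OOV pairs are dropped and
    counted.  Returns (scores, labels, n_oov)."""
    scores, labels, n_oov = [], [], 0
    for w1, w2, same in pairs:
        s = relatedness(w1, w2, model)
        if s.oov:
            n_oov += 1
        else:
            scores.append(s.value)
            labels.append(same)
    return scores, labels, n_oov


def default_grid() -> list[EmbeddingConfig]:
    """The default hyperparameter lattice: dimensions {200, 500, 1000} x
    windows {4, 10} x algorithms {cbow, skipgram} — 12 combinations."""
    return [
        EmbeddingConfig(dimensions=d, window=w, algorithm=a)
        for d, w, a in itertools.product(
            (200, 500, 1000), (4, 10), ("cbow", "skipgram")
        )
    ]


def grid_search(
    corpus: Sequence[Sequence[str]] | str,
    lex: CategoryLexicon,
    grid: Sequence[EmbeddingConfig] | None = None,
    n_pairs: int = 200,
    seed: int = 1,
    metric: str = "balanced_accuracy",
) -> GridSearchResult:
    """Choose embedding hyperparameters and theta by supervised sweep.

    For each grid combination a model is trained on ``corpus`` (with a
    training seed derived from ``seed``), all supervision pairs drawn from
    the category lexicon are scored, and theta is swept over the 101-point
    grid; the combination and theta maximizing the classification score
    are returned along with the full score table.
    """
    grid = list(grid) if grid is not None else default_grid()
    pairs = sample_supervision_pairs(lex, n_pairs, seed)
    best = None
    table: list[dict] = []
    total_oov = 0
    for k, cfg in enumerate(grid):
        cfg_seeded = replace(cfg, seed=(seed + k) % (2**31))
        model = train_embeddings(corpus, cfg_seeded)
        scores, labels, n_oov = evaluate_pair_scores(model, pairs)
        total_oov = n_oov  # same pair set for every combination
        if not scores:
            raise ValueError("all supervision pairs are out of vocabulary")
        theta, score, sweep = sweep_thresholds(scores, labels, metric)
        for th, sc in sweep:
            table.append(
                {"dimensions": cfg.dimensions, "window": cfg.window,
                 "algorithm": cfg.algorithm, "theta": th, "score": sc}
            )
        if best is None or score > best[2]:
            best = (cfg_seeded, theta, score)
    assert best is not None
    logger.info(
        "grid search best: %s theta=%.2f score=%.4f (%d OOV pairs dropped)",
        best[0], best[1], best[2], total_oov,
    )
    return GridSearchResult(
        best_config=best[0], best_theta=best[1], best_score=best[2],
        table=table, n_pairs=n_pairs, n_oov_pairs=total_oov, seed=seed,
    )


# ---------------------------------------------------------------------------
# word2vec text format I/O

def save_word2vec_text(model: EmbeddingModel, path) -> None:
    """Write the standard word2vec text format: a "V d" header, then one
    "word v1 ... vd" line per word.  ``.gz`` paths are gzip-compressed."""
    opener = gzip.open if str(path).endswith(".gz") else open
    words = sorted(model.vocab, key=model.vocab.get)
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {model.dim}\n")
        for w in words:
            vec = " ".join(repr(float(x)) for x in model.vectors[model.vocab[w]])
            fh.write(f"{w} {vec}\n")


def load_word2vec_text(path) -> EmbeddingModel:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("line 1: expected 'vocab_size dim' header")
        n, dim = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.empty((n, dim))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"line {i + 2}: expected word + {dim} values, got {len(parts) - 1}"
                )
            vocab[parts[0]] = i
            vectors[i] = [float(x) for x in parts[1:]]
    return EmbeddingModel(vocab, vectors)
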