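"""A compact, reproducible word2vec trainer (skip-gram and CBOW with
negative sampling), written with numpy.

The trainer is deliberately single-threaded: given a fixed seed, two runs
produce bit-identical vectors, which matters for auditable clinical
pipelines.  It follows the standard word2vec recipe: vocabulary pruned by
minimum frequency, unigram^0.75 noise distribution for negative sampling,
per-position dynamic window shrinking, and a linearly decaying learning
rate.  It is adequate for corpora up to a few hundred thousand tokens;
for full Wikipedia-scale training, train externally and load the vectors
in standard word2vec text format.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["train_word2vec"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def build_vocab(
    sentences: Iterable[Sequence[str]], min_count: int
) -> tuple[dict[str, int], np.ndarray]:
    """Frequency-pruned vocabulary with deterministic ordering
    (by descending count, then alphabetically)."""
    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    kept = sorted(
        ((w, c) for w, c in counts.items() if c >= min_count),
        key=lambda wc: (-wc[1], wc[0]),
    )
    vocab = {w: i for i, (w, _) in enumerate(kept)}
    freqs = np.array([c for _, c in kept], dtype=np.float64)
    return vocab, freqs


def train_word2vec(
    sentences: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    algorithm: str = "skipgram",
    min_count: int = 5,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    seed: int = 1,
) -> tuple[dict[str, int], np.ndarray]:
    """Train word vectors; returns (vocabulary, input-vector matrix).

    ``sentences`` must be a re-iterable sequence of token lists.
    """
    if algorithm not in ("skipgram", "cbow"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    sentences = [list(s) for s in sentences if s]
    if not sentences:
        raise ValueError("empty corpus")
    vocab, freqs = build_vocab(sentences, min_count)
    if not vocab:
        raise ValueError(f"no word reaches min_count={min_count}")
    V = len(vocab)
    rng = np.random.default_rng(seed)
    syn0 = rng.uniform(-0.5 / dim, 0.5 / dim, size=(V, dim))
    syn1 = np.zeros((V, dim))
    noise = freqs**0.75
    noise /= noise.sum()

    encoded = [
        np.array([vocab[w] for w in sent if w in vocab], dtype=np.intp)
        for sent in sentences
    ]
    encoded = [s for s in encoded if len(s) > 1]
    if not encoded:
        raise ValueError("no sentence has 2 or more in-vocabulary words")

    total_steps = epochs * sum(len(s) for s in encoded)
    step = 0
    for _epoch in range(epochs):
        for sent in encoded:
            n = len(sent)
            # dynamic windows drawn up-front for the sentence
            shrink = rng.integers(1, window + 1, size=n)
            for pos in range(n):
                lr = max(min_alpha, alpha * (1.0 - step / total_steps))
                step += 1
                b = int(shrink[pos])
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                context = np.concatenate((sent[lo:pos], sent[pos + 1 : hi]))
                if len(context) == 0:
                    continue
                center = int(sent[pos])
                if algorithm == "skipgram":
                    # one update per (center -> context word) pair
                    for c in context:
                        negs = rng.choice(V, size=negative, p=noise)
                        targets = np.concatenate(([c], negs))
                        labels = np.zeros(len(targets))
                        labels[0] = 1.0
                        h = syn0[center]
                        f = _sigmoid(syn1[targets] @ h)
                        g = (labels - f) * lr
                        syn0[center] = h + g @ syn1[targets]
                        syn1[targets] += np.outer(g, h)
                else:  # cbow: mean of context predicts the center word
                    negs = rng.choice(V, size=negative, p=noise)
                    targets = np.concatenate(([center], negs))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    h = syn0[context].mean(axis=0)
                    f = _sigmoid(syn1[targets] @ h)
                    g = (labels - f) * lr
                    grad_h = g @ syn1[targets]
                    syn1[targets] += np.outer(g, h)
                    syn0[context] += grad_h / len(context)
    return vocab, syn0
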